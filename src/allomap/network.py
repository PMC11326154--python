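"""Residue-network pooling and sector-overlap statistics.

Residues whose crystallographic difference-density score or HDX
difference exceeds a threshold are pooled (union across variants and
techniques) into one network, then compared to externally supplied
residue sectors by Jaccard ratio and an exact hypergeometric tail test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: default network thresholds: difference-density score and |delta %D|
IADDAT_CUTOFF = 0.3
HDX_CUTOFF = 7.0


@dataclass(frozen=True)
class ResidueSet:
    """A labelled residue set with an explicit membership universe."""

    label: str
    members: frozenset[int]
    universe: frozenset[int]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")
        if not self.members <= self.universe:
            raise ValueError("members must be a subset of the universe")

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue_index": sorted(self.members)})


@dataclass
class NetworkOverlapResult:
    """Overlap of one network with one sector."""

    network_label: str
    sector_label: str
    universe_size: int
    network_size: int
    sector_size: int
    intersection: int
    union: int
    jaccard: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "network": self.network_label,
            "sector": self.sector_label,
            "universe_size": self.universe_size,
            "network_size": self.network_size,
            "sector_size": self.sector_size,
            "intersection": self.intersection,
            "union": self.union,
            "jaccard": self.jaccard,
            "hypergeometric_p": self.p_value,
        }


# ---------------------------------------------------------------------------


def threshold_residues(
    profile,
    cutoff: float,
    absolute: bool = False,
    label: str = "thresholded",
    include_no_data_in_universe: bool = False,
) -> ResidueSet:
    """Residues whose profile value strictly exceeds the cutoff.

    Accepts either a difference-density profile (``scores``) or a residue
    HDX profile (``values`` + no-data flags). No-data residues never enter
    the members; they enter the universe only on request.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if hasattr(profile, "scores"):
        vals = np.asarray(profile.scores, dtype=float)
        res = np.asarray(profile.residue_index, dtype=int)
        nodata = np.zeros(len(vals), dtype=bool)
    else:
        vals = np.asarray(profile.values, dtype=float)
        res = np.asarray(profile.residue_index, dtype=int)
        nodata = np.asarray(profile.no_data, dtype=bool)
    if len(vals) == 0:
        raise ValueError("empty profile")
    v = np.abs(vals) if absolute else vals
    with np.errstate(invalid="ignore"):
        hit = (v > cutoff) & ~nodata
    universe = res if include_no_data_in_universe else res[~nodata]
    return ResidueSet(
        label=label,
        members=frozenset(int(r) for r in res[hit]),
        universe=frozenset(int(r) for r in universe),
    )


def pool_sets(sets: list[ResidueSet], label: str = "pooled") -> ResidueSet:
    """Union of members over sets, on the intersection of their universes."""
    if not sets:
        raise ValueError("nothing to pool")
    universe = frozenset.intersection(*(s.universe for s in sets))
    if not universe:
        raise ValueError("residue sets have disjoint universes")
    if any(universe != s.universe for s in sets):
        logger.info(
            "pooling over universe intersection of size %d", len(universe)
        )
    members = frozenset.union(*(s.members for s in sets)) & universe
    return ResidueSet(label=label, members=members, universe=universe)


def jaccard(x: ResidueSet, y: ResidueSet) -> float:
    """Intersection-over-union of two residue sets; 0 when both empty."""
    union = x.members | y.members
    if not union:
        return 0.0
    return len(x.members & y.members) / len(union)


def hypergeometric_overlap(network: ResidueSet, sector: ResidueSet) -> float:
    """Upper-tail P(X >= k) of the overlap under random draws from the universe.

    With universe size N, sector size K, network size n and observed
    overlap k, this is the survival function of the hypergeometric
    distribution (inclusive of k), evaluated with numerically stable
    log-space internals.
    """
    universe = network.universe & sector.universe
    n_univ = len(universe)
    if n_univ < len(network.members) or n_univ < len(sector.members):
        raise ValueError("universe smaller than a set defined on it")
    k = len(network.members & sector.members)
    p = float(
        stats.hypergeom.sf(
            k - 1, n_univ, len(sector.members), len(network.members)
        )
    )
    return min(p, 1.0)


def summarize_overlaps(
    network: ResidueSet, sectors: list[ResidueSet]
) -> list[NetworkOverlapResult]:
    """One overlap result per sector (sizes, Jaccard, hypergeometric p)."""
    if not sectors:
        raise ValueError("need at least one sector")
    out = []
    for sec in sectors:
        out.append(
            NetworkOverlapResult(
                network_label=network.label,
                sector_label=sec.label,
                universe_size=len(network.universe & sec.universe),
                network_size=len(network.members),
                sector_size=len(sec.members),
                intersection=len(network.members & sec.members),
                union=len(network.members | sec.members),
                jaccard=jaccard(network, sec),
                p_value=hypergeometric_overlap(network, sec),
            )
        )
    return out


def overlap_report(results: list[NetworkOverlapResult]) -> str:
    """Human-readable summary naming the sector with the larger Jaccard."""
    lines = []
    for r in results:
        signif = "significant" if r.p_value < 0.05 else "not significant"
        lines.append(
            f"{r.sector_label}: |sector|={r.sector_size}, overlap={r.intersection}, "
            f"Jaccard={r.jaccard:.3f}, hypergeometric P={r.p_value:.3g} ({signif}) "
            f"[universe N={r.universe_size}]"
        )
    best = max(results, key=lambda r: r.jaccard)
    lines.append(f"largest Jaccard overlap: {best.sector_label} ({best.jaccard:.3f})")
    return "\n".join(lines)


def write_overlaps_json(results: list[NetworkOverlapResult], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)
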