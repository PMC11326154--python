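"""Hydrogen-deuterium exchange difference analysis at peptide and residue level.

Converts peptide centroid masses to back-exchange-corrected deuteration
percentages, builds mutant-minus-reference Woods-plot rows with a
no-change band, and interpolates peptide differences to residue level
for structural mapping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mass added per exchanged amide deuterium (Da)
DEUTERIUM_MASS = 1.00628

#: sentinel timepoint for fully deuterated control rows
FD = "FD"

#: default half-width (percentage points) of the no-change band
NO_CHANGE_BAND = 5.0

CSV_COLUMNS = ["sequence", "start", "end", "timepoint", "replicate", "centroid_mass"]


# ---------------------------------------------------------------------------
# amide counting


def count_exchangeable_amides(sequence: str) -> int:
    """Number of backbone amides of a peptide that report on exchange.

    The peptide's first residue has no amide in the fragment; the amide of
    the second residue back-exchanges too fast to measure and is discounted
    whenever residue 2 is not proline (prolines have no amide NH at all).
    Both bookkeeping routes collapse to

        N_ex = L - 2 - (# prolines at positions 3..L)

    which is asserted against the explicit formulation on every call.

    Raises
    ------
    ValueError
        If the peptide is shorter than 2 residues or has no usable amide.
    """
    seq = sequence.strip().upper()
    length = len(seq)
    if length < 2:
        raise ValueError(f"peptide {sequence!r} too short to carry amide signal")
    compact = length - 2 - seq[2:].count("P")

    # explicit route: L-1 backbone amides, minus prolines at 2..L, minus the
    # fast-exchanging position-2 amide when residue 2 is not proline
    explicit = (length - 1) - seq[1:].count("P") - (0 if seq[1] == "P" else 1)
    assert compact == explicit, "amide bookkeeping mismatch"

    if compact <= 0:
        raise ValueError(f"peptide {sequence!r} has no exchangeable amides")
    return compact


# ---------------------------------------------------------------------------
# containers


@dataclass
class PeptideUptakeTable:
    """Peptide-level deuterium uptake with optional fully deuterated controls.

    ``data`` columns: sequence, start, end, timepoint, replicate,
    centroid_mass.  ``timepoint`` holds seconds as float, or the string
    sentinel :data:`FD` for fully deuterated control rows.  ``m0`` maps each
    peptide key (sequence, start, end) to its undeuterated reference mass.
    """

    data: pd.DataFrame
    m0: dict[tuple[str, int, int], float]
    d_frac: float = 0.90

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"uptake table missing columns: {missing}")
        for _, row in self.data.iterrows():
            if row["end"] < row["start"]:
                raise ValueError("peptide end < start")
            if len(row["sequence"]) != row["end"] - row["start"] + 1:
                raise ValueError(
                    f"sequence length mismatch for peptide "
                    f"{row['sequence']} {row['start']}-{row['end']}"
                )
        for key in self.peptides():
            if key not in self.m0:
                raise ValueError(f"no undeuterated reference mass for peptide {key}")

    def peptides(self) -> list[tuple[str, int, int]]:
        seen: dict[tuple[str, int, int], None] = {}
        for _, row in self.data.iterrows():
            seen[(row["sequence"], int(row["start"]), int(row["end"]))] = None
        return list(seen)

    def has_fd(self) -> bool:
        return bool((self.data["timepoint"].astype(str) == FD).any())

    def fd_mass(self, key: tuple[str, int, int]) -> float | None:
        """Mean FD-control centroid mass for a peptide, or None."""
        sel = self._select(key)
        fd = sel[sel["timepoint"].astype(str) == FD]
        if fd.empty:
            return None
        return float(fd["centroid_mass"].mean())

    def _select(self, key: tuple[str, int, int]) -> pd.DataFrame:
        seq, start, end = key
        d = self.data
        return d[(d["sequence"] == seq) & (d["start"] == start) & (d["end"] == end)]

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df["m0"] = [
            self.m0[(r["sequence"], int(r["start"]), int(r["end"]))]
            for _, r in df.iterrows()
        ]
        df["d_frac"] = self.d_frac
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PeptideUptakeTable":
        df = pd.read_csv(path)
        if "m0" not in df.columns:
            raise ValueError("uptake CSV must carry an m0 column")
        # timepoint column mixes seconds with the FD sentinel
        tp = pd.to_numeric(df["timepoint"], errors="coerce")
        df["timepoint"] = [
            FD if np.isnan(v) else float(v) for v in tp
        ]
        d_frac = float(df["d_frac"].iloc[0]) if "d_frac" in df.columns else 0.90
        m0 = {}
        for _, r in df.iterrows():
            m0[(r["sequence"], int(r["start"]), int(r["end"]))] = float(r["m0"])
        return cls(
            data=df[CSV_COLUMNS].copy(), m0=m0, d_frac=d_frac
        )


@dataclass
class WoodsRow:
    """One peptide of a mutant-minus-reference difference (Woods) plot."""

    peptide_id: str
    sequence: str
    start: int
    end: int
    delta_pct: float
    classification: Literal["protected", "deprotected", "no-change"]


@dataclass
class ResidueHDXProfile:
    """Residue-level deuteration difference, percentage points.

    Residues covered by no peptide carry ``no_data`` True and a NaN value,
    never an imputed zero.
    """

    residue_index: np.ndarray
    values: np.ndarray  # percentage points; NaN where no data
    coverage: np.ndarray  # peptides covering each residue
    timepoint: float
    scheme: str

    @property
    def no_data(self) -> np.ndarray:
        return self.coverage == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_index": self.residue_index,
                "delta_pct_deuteration": self.values,
                "coverage": self.coverage,
                "no_data": self.no_data,
            }
        )


# ---------------------------------------------------------------------------
# deuteration percentages


def percent_deuteration(
    sequence: str,
    m_t: float,
    m0: float,
    m_fd: float | None = None,
    d_frac: float = 0.90,
    mass_tolerance: float = 0.5,
) -> tuple[float, bool]:
    """Relative deuteration of one peptide observation, percent.

    With an FD control the peptide mass increase is normalized to the FD
    mass increase (back-exchange cancels); without one it is normalized to
    the theoretical maximum ``N_ex * d_frac * m_D``. Values are clipped to
    [-5, 110]; the second return flags observations outside that range.
    """
    if m_t < m0 - mass_tolerance:
        raise ValueError("centroid mass below undeuterated reference")
    if m_fd is not None:
        if m_fd <= m0:
            raise ValueError("FD control mass must exceed undeuterated mass")
        pct = 100.0 * (m_t - m0) / (m_fd - m0)
    else:
        n_ex = count_exchangeable_amides(sequence)
        pct = 100.0 * (m_t - m0) / (n_ex * d_frac * DEUTERIUM_MASS)
    out_of_range = pct < -5.0 or pct > 110.0
    return float(np.clip(pct, -5.0, 110.0)), out_of_range


def _mean_pct_at_timepoint(
    table: PeptideUptakeTable,
    key: tuple[str, int, int],
    timepoint: float,
    use_fd: bool = True,
) -> float | None:
    """Replicate-mean %D of one peptide at one timepoint (None if absent)."""
    sel = table._select(key)
    tp = pd.to_numeric(sel["timepoint"], errors="coerce")
    rows = sel[np.isclose(tp, timepoint)]
    if rows.empty:
        return None
    m_fd = table.fd_mass(key) if use_fd else None
    vals = []
    for _, r in rows.iterrows():
        pct, flagged = percent_deuteration(
            key[0], float(r["centroid_mass"]), table.m0[key], m_fd, table.d_frac
        )
        if flagged:
            logger.warning("out-of-range %%D for peptide %s dropped", key)
            continue
        vals.append(pct)
    if not vals:
        return None
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# difference analysis


def classify(delta_pct: float, band: float = NO_CHANGE_BAND) -> str:
    """protected / deprotected / no-change, with strict band boundaries."""
    if delta_pct < -band:
        return "protected"
    if delta_pct > band:
        return "deprotected"
    return "no-change"


def difference_table(
    mut: PeptideUptakeTable,
    wt: PeptideUptakeTable,
    timepoint: float,
    band: float = NO_CHANGE_BAND,
) -> list[WoodsRow]:
    """Mutant-minus-reference %D difference per matched peptide.

    Peptides are matched by (sequence, start, end); replicates are averaged
    within each condition before differencing. Unmatched peptides are
    logged and dropped.
    """
    keys_mut = set(mut.peptides())
    keys_wt = set(wt.peptides())
    shared = sorted(keys_mut & keys_wt, key=lambda k: (k[1], k[2], k[0]))
    for k in sorted((keys_mut | keys_wt) - set(shared)):
        logger.info("peptide %s present in only one condition; dropped", k)
    rows: list[WoodsRow] = []
    for key in shared:
        pm = _mean_pct_at_timepoint(mut, key, timepoint)
        pw = _mean_pct_at_timepoint(wt, key, timepoint)
        if pm is None or pw is None:
            continue
        delta = pm - pw
        seq, start, end = key
        rows.append(
            WoodsRow(
                peptide_id=f"{start}-{end}:{seq}",
                sequence=seq,
                start=start,
                end=end,
                delta_pct=delta,
                classification=classify(delta, band),
            )
        )
    if not rows:
        raise ValueError("no peptides matched between conditions at this timepoint")
    return rows


# ---------------------------------------------------------------------------
# residue-level interpolation


def greedy_minimal_cover(rows: Sequence[WoodsRow]) -> list[WoodsRow]:
    """Greedy minimal-length set cover of the sequence span by peptides.

    Walking the covered span left to right, the shortest peptide covering
    each yet-uncovered position is selected (ties broken by smaller start).
    """
    uncovered = set()
    for r in rows:
        uncovered.update(range(r.start, r.end + 1))
    chosen: list[WoodsRow] = []
    while uncovered:
        pos = min(uncovered)
        candidates = [r for r in rows if r.start <= pos <= r.end]
        if not candidates:
            uncovered.discard(pos)
            continue
        best = min(candidates, key=lambda r: (r.end - r.start + 1, r.start))
        chosen.append(best)
        uncovered -= set(range(best.start, best.end + 1))
    chosen.sort(key=lambda r: (r.start, r.end))
    return chosen


def residue_interpolation(
    rows: Sequence[WoodsRow],
    scheme: Literal["all-peptides", "short-peptides"] = "all-peptides",
    timepoint: float = float("nan"),
    n_residues: int | None = None,
) -> ResidueHDXProfile:
    """Interpolate peptide differences to residue level.

    Each covered residue receives the weighted mean of the covering
    peptides' differences, weighted by the inverse exchangeable-amide count
    so short peptides (closer to single-residue resolution) dominate. The
    ``short-peptides`` scheme first restricts to a greedy minimal-length
    set cover of the sequence.
    """
    if not rows:
        raise ValueError("no Woods rows to interpolate")
    if scheme == "short-peptides":
        use = greedy_minimal_cover(rows)
    elif scheme == "all-peptides":
        use = list(rows)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    last = max(r.end for r in rows)
    n = n_residues if n_residues is not None else last
    res = np.arange(1, n + 1)
    num = np.zeros(n)
    den = np.zeros(n)
    cov = np.zeros(n, dtype=int)
    for r in use:
        w = 1.0 / count_exchangeable_amides(r.sequence)
        sl = slice(r.start - 1, min(r.end, n))
        num[sl] += w * r.delta_pct
        den[sl] += w
        cov[sl] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return ResidueHDXProfile(
        residue_index=res, values=vals, coverage=cov,
        timepoint=timepoint, scheme=scheme,
    )


# ---------------------------------------------------------------------------
# uptake curves


def uptake_curves(
    table: PeptideUptakeTable, key: tuple[str, int, int]
) -> pd.DataFrame:
    """Per-timepoint mean %D and replicate spread for one peptide.

    Returns a frame with columns timepoint, mean_pct, sd_pct, n; sd is NaN
    (reported as missing, not zero) for single-replicate timepoints.
    """
    if key not in table.peptides():
        raise ValueError(f"unknown peptide {key}")
    sel = table._select(key)
    tp = pd.to_numeric(sel["timepoint"], errors="coerce")
    times = sorted(set(tp.dropna()))
    if not times:
        raise ValueError("peptide has no finite timepoints")
    m_fd = table.fd_mass(key)
    out = []
    for t in times:
        rows = sel[np.isclose(tp, t)]
        vals = [
            percent_deuteration(
                key[0], float(r["centroid_mass"]), table.m0[key], m_fd, table.d_frac
            )[0]
            for _, r in rows.iterrows()
        ]
        sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")
        out.append(
            {"timepoint": t, "mean_pct": float(np.mean(vals)), "sd_pct": sd,
             "n": len(vals)}
        )
    return pd.DataFrame(out)
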