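"""Integration of absolute difference density above threshold (IADDAT).

Every grid point of a difference map whose |density| exceeds a noise
threshold is assigned to the nearest protein heavy atom within a capture
radius (periodic minimum-image distances); per-residue scores are the
accumulated |density| divided by the residue's heavy-atom count, so
small and large residues are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from allomap.diffmap import RealSpaceMap
from allomap.structure import StructureModel

logger = logging.getLogger(__name__)

#: defaults: |density| threshold (e-/A^3), capture radius (A), display cap
DEFAULT_THRESHOLD = 0.04
DEFAULT_RADIUS = 1.5
DEFAULT_CAP = 0.3


@dataclass
class IADDATProfile:
    """Per-residue integrated absolute difference density.

    ``scores`` are the raw values; a display copy capped for
    visualization lives in ``display_scores`` and never replaces the raw
    profile.
    """

    residue_index: np.ndarray
    chain_id: np.ndarray
    scores: np.ndarray
    threshold: float
    radius: float
    cap: float | None = None
    display_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(self.scores < 0):
            raise ValueError("scores must be non-negative")
        if len(np.unique(self.residue_index)) != len(self.residue_index):
            raise ValueError("each residue must appear exactly once")

    def __len__(self) -> int:
        return len(self.residue_index)

    def score_of(self, residue: int) -> float:
        idx = np.where(self.residue_index == residue)[0]
        if len(idx) == 0:
            raise KeyError(f"residue {residue} not in profile")
        return float(self.scores[idx[0]])

    def for_display(self) -> np.ndarray:
        return self.display_scores if self.display_scores is not None else self.scores

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue_index": self.residue_index, "iaddat": self.scores}
        )


# ---------------------------------------------------------------------------


def _sorted_heavy_atoms(model: StructureModel, include_het: bool):
    atoms = [
        a
        for a in model.atoms
        if not a.is_hydrogen
        and not a.is_water
        and (include_het or a.residue_name not in ())  # ligand flag hook
    ]
    atoms.sort(key=lambda a: (a.chain_id, a.residue_index, a.atom_id))
    return atoms


def compute_iaddat(
    density_map: RealSpaceMap,
    model: StructureModel,
    threshold: float = DEFAULT_THRESHOLD,
    radius: float = DEFAULT_RADIUS,
    per_atom_average: bool = True,
    chunk: int = 4096,
) -> IADDATProfile:
    """Score each residue by nearby above-threshold difference density.

    Grid points with |density| strictly above ``threshold`` are assigned
    to the single nearest heavy atom within ``radius`` (minimum-image
    convention in fractional space; exact distance ties resolve to the
    lowest (chain, residue, atom name)). The residue score divides the
    accumulated |density| by the residue's heavy-atom count; with
    ``per_atom_average=False`` it divides by the number of contributing
    grid points instead.
    """
    if threshold <= 0 or radius <= 0:
        raise ValueError("threshold and radius must be positive")
    if not np.allclose(np.array(density_map.cell), np.array(model.cell), rtol=0.01):
        raise ValueError("map and model cells do not match")
    atoms = _sorted_heavy_atoms(model, include_het=False)
    if not atoms:
        raise ValueError("model has no protein heavy atoms")

    orth = model.orth_matrix
    inv = np.linalg.inv(orth)
    atom_frac = np.array([inv @ a.xyz for a in atoms])
    atom_frac -= np.floor(atom_frac)
    atom_residue = np.array([a.residue_index for a in atoms])

    residues = model.residue_indices()
    res_pos = {r: i for i, r in enumerate(residues)}
    chain_of = {}
    n_heavy = np.zeros(len(residues))
    for a in atoms:
        n_heavy[res_pos[a.residue_index]] += 1
        chain_of.setdefault(a.residue_index, a.chain_id)
    atom_res_slot = np.array([res_pos[r] for r in atom_residue])

    vals = density_map.values
    shape = np.array(vals.shape, dtype=float)
    pts_idx = np.argwhere(np.abs(vals) > threshold)  # C-order scan
    sums = np.zeros(len(residues))
    counts = np.zeros(len(residues))
    r2 = radius * radius
    for lo in range(0, len(pts_idx), chunk):
        block = pts_idx[lo : lo + chunk]
        frac_pts = block / shape
        absv = np.abs(vals[block[:, 0], block[:, 1], block[:, 2]])
        delta = atom_frac[None, :, :] - frac_pts[:, None, :]
        delta -= np.round(delta)
        cart = delta @ orth.T
        d2 = (cart**2).sum(axis=-1)
        nearest = np.argmin(d2, axis=1)  # first minimum = sorted-atom tie-break
        dmin2 = d2[np.arange(len(block)), nearest]
        hit = dmin2 <= r2
        slots = atom_res_slot[nearest[hit]]
        np.add.at(sums, slots, absv[hit])
        np.add.at(counts, slots, 1.0)

    if per_atom_average:
        scores = sums / n_heavy
    else:
        scores = np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), 0.0)
    return IADDATProfile(
        residue_index=np.array(residues),
        chain_id=np.array([chain_of[r] for r in residues]),
        scores=scores,
        threshold=threshold,
        radius=radius,
    )


def cap_for_display(profile: IADDATProfile, cap: float = DEFAULT_CAP) -> IADDATProfile:
    """Attach a display copy with scores capped at ``cap``; raw scores untouched."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return replace(
        profile,
        cap=cap,
        display_scores=np.minimum(profile.scores, cap),
    )


def write_residue_scores(
    profile: IADDATProfile,
    model: StructureModel,
    pdb_path,
    csv_path,
) -> None:
    """Write scores onto the model's B-factor column (PDB) and as CSV.

    The PDB copy carries each residue's display score in the B column
    (fixed 2-decimal PDB format) for structure coloring; the CSV is the
    per-residue trace (residue_index, score).
    """
    prof_res = set(int(r) for r in profile.residue_index)
    model_res = set(model.residue_indices())
    if not prof_res <= model_res:
        raise ValueError("profile contains residues absent from the model")
    display = profile.for_display()
    b_override = {
        int(r): float(s) for r, s in zip(profile.residue_index, display)
    }
    st = model.to_gemmi(b_override=b_override)
    st.write_pdb(str(pdb_path))
    pd.DataFrame(
        {"residue_index": profile.residue_index, "score": display}
    ).to_csv(csv_path, index=False)
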