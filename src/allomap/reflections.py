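"""Reflection data: indexed amplitudes with uncertainties on a crystal lattice."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from allomap.scattering import s_squared

logger = logging.getLogger(__name__)


@dataclass
class ReflectionSet:
    """Structure-factor amplitudes F with uncertainties sigF on one lattice.

    Phases (degrees) are retained only for synthetic/calculated data;
    measured sets carry ``phase=None``.
    """

    hkl: np.ndarray  # (n, 3) int
    f: np.ndarray  # amplitudes, arbitrary experimental scale until scaled
    sigf: np.ndarray
    cell: tuple[float, float, float, float, float, float]
    space_group: str = "P1"
    phase: np.ndarray | None = None  # degrees

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.f = np.asarray(self.f, dtype=float)
        self.sigf = np.asarray(self.sigf, dtype=float)
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
        n = len(self.hkl)
        if len(self.f) != n or len(self.sigf) != n:
            raise ValueError("hkl, f and sigf must have equal length")
        if np.any(self.f < 0) or np.any(self.sigf < 0):
            raise ValueError("amplitudes and sigmas must be non-negative")
        self.cell = tuple(float(x) for x in self.cell)

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    @property
    def orth_matrix(self) -> np.ndarray:
        return np.array(self.gemmi_cell.orth.mat.tolist(), dtype=float)

    def d_spacings(self) -> np.ndarray:
        """Resolution d (A) per reflection; inf for (0,0,0)."""
        s2 = s_squared(self.hkl, self.orth_matrix)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(s2)

    def d_min(self) -> float:
        d = self.d_spacings()
        return float(np.min(d[np.isfinite(d)]))

    # -- asymmetric unit handling -----------------------------------------

    def to_asu(self) -> "ReflectionSet":
        """Map indices to the reciprocal-space asymmetric unit and merge duplicates.

        Duplicates are combined by inverse-variance weighted mean (plain
        mean when any sigma is zero); the merged count is logged.
        """
        sg = gemmi.SpaceGroup(self.space_group)
        asu = gemmi.ReciprocalAsu(sg)
        ops = sg.operations()
        mapped = np.array(
            [asu.to_asu(tuple(int(x) for x in h), ops)[0] for h in self.hkl],
            dtype=int,
        )
        order = np.lexsort((mapped[:, 2], mapped[:, 1], mapped[:, 0]))
        mapped = mapped[order]
        f = self.f[order]
        sigf = self.sigf[order]
        keys, inverse, counts = np.unique(
            mapped, axis=0, return_inverse=True, return_counts=True
        )
        if np.all(counts == 1):
            return ReflectionSet(
                hkl=mapped, f=f, sigf=sigf, cell=self.cell,
                space_group=self.space_group,
            )
        n_dup = int(np.sum(counts > 1))
        logger.info("merging duplicates on %d asu indices", n_dup)
        out_f = np.zeros(len(keys))
        out_s = np.zeros(len(keys))
        for i in range(len(keys)):
            sel = inverse == i
            fi, si = f[sel], sigf[sel]
            if np.any(si <= 0):
                w = np.ones_like(fi)
            else:
                w = 1.0 / si**2
            out_f[i] = np.sum(w * fi) / np.sum(w)
            out_s[i] = np.sqrt(1.0 / np.sum(w)) if np.all(si > 0) else 0.0
        return ReflectionSet(
            hkl=keys, f=out_f, sigf=out_s, cell=self.cell,
            space_group=self.space_group,
        )

    def index_lookup(self) -> dict[tuple[int, int, int], int]:
        return {tuple(h): i for i, h in enumerate(map(tuple, self.hkl))}

    def cells_compatible(self, other: "ReflectionSet", rtol: float = 0.01) -> bool:
        a = np.array(self.cell)
        b = np.array(other.cell)
        return bool(
            np.allclose(a, b, rtol=rtol)
            and gemmi.SpaceGroup(self.space_group).number
            == gemmi.SpaceGroup(other.space_group).number
        )


def common_reflections(
    a: ReflectionSet, b: ReflectionSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices common to both sets after ASU mapping.

    Returns (hkl, idx_a, idx_b) such that a.f[idx_a] and b.f[idx_b] refer
    to the same reflections. Reflections present in only one set are
    dropped, never imputed.
    """
    la = a.index_lookup()
    lb = b.index_lookup()
    shared = sorted(set(la) & set(lb))
    hkl = np.array(shared, dtype=int).reshape(-1, 3)
    ia = np.array([la[h] for h in shared], dtype=int)
    ib = np.array([lb[h] for h in shared], dtype=int)
    return hkl, ia, ib
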