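"""Direct-summation structure factors with single-Gaussian atomic form factors.

Each element scatters as f(s) = Z_eff * exp(-b_elem * s^2 / 4) with
s = 1/d (A^-1).  Z_eff is the electron count and b_elem (A^2) a fixed
per-element Gaussian width that loosely tracks atomic size.  This is a
deliberately minimal model: adequate for synthesizing difference signals
and reference phases on toy crystals, not for refinement against data.
"""

from __future__ import annotations

import numpy as np

from allomap.structure import StructureModel

# element -> (effective electron count, Gaussian width b in A^2)
ELEMENT_GAUSSIANS: dict[str, tuple[float, float]] = {
    "H": (1.0, 8.0),
    "C": (6.0, 13.0),
    "N": (7.0, 11.0),
    "O": (8.0, 9.0),
    "P": (15.0, 13.0),
    "S": (16.0, 12.0),
}
_DEFAULT_GAUSSIAN = (6.0, 13.0)


def form_factor(element: str, s2: np.ndarray) -> np.ndarray:
    """f(s) for one element at squared scattering vector lengths s2 = 1/d^2."""
    z, b = ELEMENT_GAUSSIANS.get(element.upper(), _DEFAULT_GAUSSIAN)
    return z * np.exp(-b * s2 / 4.0)


def reciprocal_metric(orth_matrix: np.ndarray) -> np.ndarray:
    """Reciprocal metric tensor G* such that s^2 = h . G* . h (h integer)."""
    inv = np.linalg.inv(orth_matrix)
    return inv @ inv.T


def s_squared(hkl: np.ndarray, orth_matrix: np.ndarray) -> np.ndarray:
    """|s|^2 = 1/d^2 for integer index rows of hkl."""
    gstar = reciprocal_metric(orth_matrix)
    h = np.asarray(hkl, dtype=float)
    return np.einsum("ij,jk,ik->i", h, gstar, h)


def direct_summation(
    model: StructureModel,
    hkl: np.ndarray,
    include_waters: bool = False,
) -> np.ndarray:
    """Complex structure factors F(h) by direct summation over atoms.

    F(h) = sum_j occ_j * f_j(s) * exp(-B_j s^2/4) * exp(2 pi i h.x_j)
    with x_j fractional coordinates.  Hydrogens are included with their
    (small) electron count; waters are excluded by default to mirror the
    protein-only synthetic generator.
    """
    atoms = [
        a
        for a in model.atoms
        if include_waters or not a.is_water
    ]
    if not atoms:
        raise ValueError("model has no atoms to scatter")
    hkl = np.asarray(hkl, dtype=int)
    s2 = s_squared(hkl, model.orth_matrix)

    inv = np.linalg.inv(model.orth_matrix)
    frac = np.array([inv @ a.xyz for a in atoms])  # (n_atoms, 3)
    occ = np.array([a.occupancy for a in atoms])
    biso = np.array([a.b_factor for a in atoms])
    zb = np.array(
        [ELEMENT_GAUSSIANS.get(a.element.upper(), _DEFAULT_GAUSSIAN) for a in atoms]
    )
    z, b_elem = zb[:, 0], zb[:, 1]

    # (n_refl, n_atoms) pieces, chunked over reflections to bound memory
    out = np.empty(len(hkl), dtype=complex)
    chunk = 2048
    for lo in range(0, len(hkl), chunk):
        hh = hkl[lo : lo + chunk]
        ss = s2[lo : lo + chunk][:, None]
        amp = occ[None, :] * z[None, :] * np.exp(-(b_elem[None, :] + biso[None, :]) * ss / 4.0)
        phase = np.exp(2j * np.pi * (hh.astype(float) @ frac.T))
        out[lo : lo + hh.shape[0]] = (amp * phase).sum(axis=1)
    return out
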