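"""Ground-truth synthetic inputs for every pipeline stage.

The generators emulate the study conditions of a point-mutant
perturbation series: toy P1 crystals with a localized side-chain
rearrangement and Gaussian amplitude noise, peptide-level deuterium
uptake from per-residue protection factors with back-exchange,
Michaelis-Menten initial velocities, and residue sets with controlled
overlap. Every generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from allomap.hdx import DEUTERIUM_MASS, FD, PeptideUptakeTable, count_exchangeable_amides
from allomap.kinetics import KineticsDataset
from allomap.network import ResidueSet
from allomap.reflections import ReflectionSet
from allomap.scattering import direct_summation, s_squared
from allomap.structure import Atom, StructureModel

#: default assay optics used by the kinetics generator (pNP product at
#: 405 nm; AU per mM per cm, and the path of a 100 uL well)
DEFAULT_EPSILON = 18.0
DEFAULT_PATH_CM = 0.575

#: the study's labeling timepoints, seconds
HDX_TIMEPOINTS = (30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0)


@dataclass
class ProtectionProfile:
    """Ground-truth per-residue protection factors and intrinsic rates.

    PF_i >= 1 is the fold-slowdown of exchange at residue i relative to
    the intrinsic rate k_int,i (s^-1). Intrinsic rates default to a single
    configurable constant rather than sequence-dependent chemistry: the
    recovery tests need controllable rates, not chemically exact ones.
    """

    pf: np.ndarray
    k_int: np.ndarray

    def __post_init__(self) -> None:
        self.pf = np.asarray(self.pf, dtype=float)
        self.k_int = np.asarray(self.k_int, dtype=float)
        if self.pf.shape != self.k_int.shape:
            raise ValueError("pf and k_int must have equal length")
        if np.any(self.pf < 1.0):
            raise ValueError("protection factors must be >= 1")
        if np.any(self.k_int <= 0.0):
            raise ValueError("intrinsic rates must be positive")

    def __len__(self) -> int:
        return len(self.pf)

    @classmethod
    def uniform(
        cls,
        n_residues: int,
        pf: float = 1.0,
        k_int: float = 1.0,
        protected: set[int] | None = None,
        protected_pf: float = 10.0,
    ) -> "ProtectionProfile":
        """Flat profile with an optional block of extra-protected residues."""
        pfs = np.full(n_residues, pf)
        if protected:
            for r in protected:
                if not 1 <= r <= n_residues:
                    raise ValueError(f"protected residue {r} outside sequence")
                pfs[r - 1] = protected_pf
        return cls(pf=pfs, k_int=np.full(n_residues, k_int))


@dataclass
class GroundTruth:
    """What the generators planted, for downstream recovery checks."""

    perturbed_residues: set[int] = field(default_factory=set)
    displacement: float = 0.0
    protected_residues: set[int] = field(default_factory=set)
    k_cat: float = 0.0
    k_m: float = 0.0
    e0_nm: float = 0.0
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "perturbed_residues": sorted(self.perturbed_residues),
                    "displacement_A": self.displacement,
                    "protected_residues": sorted(self.protected_residues),
                    "k_cat_per_s": self.k_cat,
                    "K_m_mM": self.k_m,
                    "E0_nM": self.e0_nm,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# crystals


def make_toy_structure(n_residues: int, seed: int) -> StructureModel:
    """Poly-alanine-like helix (N, CA, C, O, CB per residue) in a P1 cell.

    Residues follow an idealized alpha-helical path (1.5 A rise, 100 deg
    twist, 2.3 A CA radius); a small seeded jitter (0.05 A) makes distinct
    seeds distinct while keeping the fold. The cell is orthorhombic P1
    sized to leave at least a 5 A solvent margin around the chain.
    """
    if not 5 <= n_residues <= 100:
        raise ValueError("n_residues must be in [5, 100]")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    coords = []
    for i in range(n_residues):
        theta = np.deg2rad(100.0) * i
        ca = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        n_pos = ca - 0.9 * radial - 1.1 * tangent + np.array([0, 0, -0.6])
        c_pos = ca - 0.6 * radial + 1.2 * tangent + np.array([0, 0, 0.7])
        o_pos = c_pos + 0.8 * radial + np.array([0, 0, 0.9])
        cb_pos = ca + 1.5 * radial + np.array([0, 0, -0.3])
        for name, elem, pos in (
            ("N", "N", n_pos),
            ("CA", "C", ca),
            ("C", "C", c_pos),
            ("O", "O", o_pos),
            ("CB", "C", cb_pos),
        ):
            coords.append(pos + rng.normal(0.0, 0.05, size=3))
            atoms.append(
                Atom(
                    atom_id=name,
                    element=elem,
                    residue_index=i + 1,
                    residue_name="ALA",
                    chain_id="A",
                    xyz=coords[-1],
                    occupancy=1.0,
                    b_factor=float(15.0 + rng.uniform(-2.0, 2.0)),
                )
            )
    xyz = np.array(coords)
    margin = 5.0
    span = xyz.max(axis=0) - xyz.min(axis=0)
    cell_lengths = span + 2 * margin
    shift = margin - xyz.min(axis=0)
    for a in atoms:
        a.xyz = a.xyz + shift
    return StructureModel(
        atoms=atoms,
        cell=(cell_lengths[0], cell_lengths[1], cell_lengths[2], 90.0, 90.0, 90.0),
        space_group="P1",
    )


def perturb_structure(
    model: StructureModel,
    residues: set[int],
    displacement: float,
    seed: int,
    move_backbone: bool = False,
) -> StructureModel:
    """Displace side-chain (CB) atoms of listed residues by a random direction.

    Emulates a point mutation's local rearrangement with a single knob:
    each listed residue's CB (and, optionally, its backbone atoms) moves
    by ``displacement`` angstroms along a seeded random unit vector. All
    other atoms are bit-identical to the input.
    """
    if displacement < 0:
        raise ValueError("displacement must be >= 0")
    known = set(model.residue_indices())
    unknown = set(residues) - known
    if unknown:
        raise ValueError(f"unknown residue indices: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = model.copy()
    targets = {"CB"} | ({"N", "CA", "C", "O"} if move_backbone else set())
    for res in sorted(residues):
        vec = rng.normal(size=3)
        vec /= np.linalg.norm(vec)
        for a in out.atoms:
            if a.residue_index == res and a.atom_id in targets:
                a.xyz = a.xyz + displacement * vec
    return out


def hkl_sphere(model: StructureModel, d_min: float) -> np.ndarray:
    """All P1 asymmetric-unit indices (plus (0,0,0)) complete to d_min."""
    a, b, c = model.cell[:3]
    hmax = int(np.ceil(a / d_min))
    kmax = int(np.ceil(b / d_min))
    lmax = int(np.ceil(c / d_min))
    grid = np.mgrid[-hmax : hmax + 1, -kmax : kmax + 1, -lmax : lmax + 1]
    hkl = grid.reshape(3, -1).T
    s2 = s_squared(hkl, model.orth_matrix)
    hkl = hkl[s2 <= 1.0 / d_min**2 + 1e-12]
    # P1 reciprocal ASU: keep one Friedel mate (l>0, or l=0 & k>0, or k=l=0 & h>=0)
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    keep = (l > 0) | ((l == 0) & (k > 0)) | ((l == 0) & (k == 0) & (h >= 0))
    hkl = hkl[keep]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def simulate_structure_factors(model: StructureModel, d_min: float) -> ReflectionSet:
    """Direct-summation amplitudes (and internal phases) complete to d_min.

    F(h) = sum_j occ_j f_j(s) exp(-B_j s^2/4) exp(2 pi i h.x_j) over all
    non-water atoms, with single-Gaussian per-element form factors. Sigmas
    are initialized to zero; use :func:`add_measurement_noise` to emulate
    measurement error.
    """
    if d_min <= 0.8:
        raise ValueError("d_min must exceed 0.8 A")
    if not model.atoms:
        raise ValueError("empty model")
    hkl = hkl_sphere(model, d_min)
    fc = direct_summation(model, hkl)
    return ReflectionSet(
        hkl=hkl,
        f=np.abs(fc),
        sigf=np.zeros(len(hkl)),
        cell=model.cell,
        space_group=model.space_group,
        phase=np.degrees(np.angle(fc)),
    )


def add_measurement_noise(
    refl: ReflectionSet, rel_sigma: float, seed: int
) -> ReflectionSet:
    """Gaussian amplitude noise F' = F + N(0, (rel_sigma F)^2), sigma recorded.

    Phases are dropped: measured amplitudes carry no phase information.
    Amplitudes are floored at zero to respect F >= 0.
    """
    if rel_sigma < 0:
        raise ValueError("rel_sigma must be >= 0")
    if rel_sigma == 0:
        return ReflectionSet(
            hkl=refl.hkl.copy(), f=refl.f.copy(), sigf=np.zeros(len(refl)),
            cell=refl.cell, space_group=refl.space_group,
        )
    rng = np.random.default_rng(seed)
    sig = rel_sigma * refl.f
    f = np.maximum(refl.f + rng.normal(0.0, 1.0, len(refl)) * sig, 0.0)
    return ReflectionSet(
        hkl=refl.hkl.copy(), f=f, sigf=sig,
        cell=refl.cell, space_group=refl.space_group,
    )


# ---------------------------------------------------------------------------
# HDX


def simulate_hdx_peptides(
    sequence: str,
    profile: ProtectionProfile,
    peptides: list[tuple[int, int]],
    timepoints: Sequence[float] = HDX_TIMEPOINTS,
    d_frac: float = 0.90,
    backexchange: float = 0.10,
    noise_da: float = 0.0,
    seed: int = 0,
    n_reps: int = 2,
) -> PeptideUptakeTable:
    """Peptide centroid masses from per-residue exchange kinetics.

    Residue uptake follows D_i(t) = d_frac (1 - exp(-(k_int,i/PF_i) t))
    for the peptide's exchange-reporting amides (positions 3..L excluding
    prolines, the same bookkeeping as the amide-counting rule). The
    peptide mass increase is (1 - backexchange) * sum_i D_i(t) * m_D; a
    fully deuterated control row per peptide carries
    (1 - backexchange) * d_frac * N_ex * m_D. Gaussian noise of scale
    ``noise_da`` perturbs every centroid.
    """
    if not 0 < d_frac <= 1:
        raise ValueError("d_frac must be in (0, 1]")
    if not 0 <= backexchange < 1:
        raise ValueError("backexchange must be in [0, 1)")
    if len(profile) != len(sequence):
        raise ValueError("profile length must equal sequence length")
    rng = np.random.default_rng(seed)
    rows = []
    m0 = {}
    for start, end in peptides:
        if start < 1 or end > len(sequence) or end < start:
            raise ValueError(f"peptide {start}-{end} outside sequence")
        pep = sequence[start - 1 : end]
        n_ex = count_exchangeable_amides(pep)
        base_mass = 110.0 * len(pep)  # synthetic reference mass; only shifts matter
        key = (pep, start, end)
        m0[key] = base_mass
        # exchange-reporting residues: peptide positions 3..L, excluding prolines
        positions = [
            start - 1 + j for j in range(2, len(pep)) if pep[j] != "P"
        ]
        assert len(positions) == n_ex
        rates = profile.k_int[positions] / profile.pf[positions]
        for t in timepoints:
            uptake = d_frac * (1.0 - np.exp(-rates * t))
            dm = (1.0 - backexchange) * uptake.sum() * DEUTERIUM_MASS
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sequence": pep, "start": start, "end": end,
                        "timepoint": float(t), "replicate": rep,
                        "centroid_mass": base_mass + dm + rng.normal(0.0, noise_da)
                        if noise_da > 0 else base_mass + dm,
                    }
                )
        dm_fd = (1.0 - backexchange) * d_frac * n_ex * DEUTERIUM_MASS
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "sequence": pep, "start": start, "end": end,
                    "timepoint": FD, "replicate": rep,
                    "centroid_mass": base_mass + dm_fd + rng.normal(0.0, noise_da)
                    if noise_da > 0 else base_mass + dm_fd,
                }
            )
    return PeptideUptakeTable(data=pd.DataFrame(rows), m0=m0, d_frac=d_frac)


def ladder_peptides(
    n_residues: int, length: int = 8, step: int = 3
) -> list[tuple[int, int]]:
    """Overlapping peptide ladder covering residues 1..n_residues."""
    peps = []
    start = 1
    while start + length - 1 <= n_residues:
        peps.append((start, start + length - 1))
        start += step
    if not peps or peps[-1][1] < n_residues:
        peps.append((max(1, n_residues - length + 1), n_residues))
    return peps


# ---------------------------------------------------------------------------
# kinetics


def pnpp_dilution_series(
    top_mM: float = 40.0, bottom_mM: float = 0.0039, n: int = 12
) -> list[float]:
    """Serial-dilution substrate series, 40 mM down to 3.9 uM by default.

    A 12-point geometric series between the assay's top and bottom
    concentrations (step ~2.3-fold), spanning well above and below a
    millimolar-range K_m.
    """
    return list(np.geomspace(top_mM, bottom_mM, n))


def simulate_kinetics(
    k_cat: float,
    K_m: float,
    E0: float,
    substrate: list[float],
    n_reps: int = 4,
    rel_noise: float = 0.0,
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
    path_cm: float = DEFAULT_PATH_CM,
) -> KineticsDataset:
    """Initial-velocity dataset from Michaelis-Menten ground truth.

    v(S) = k_cat E0 S / (K_m + S) in mM/s is converted to an absorbance
    slope (mAU/min) through the configured molar absorptivity and path
    length; replicates are perturbed multiplicatively by N(1, rel_noise).

    Parameters are k_cat (s^-1), K_m (mM), E0 (nM), substrate (mM).
    """
    if min(k_cat, K_m, E0) <= 0:
        raise ValueError("kinetic parameters must be positive")
    if not substrate:
        raise ValueError("empty substrate list")
    if rel_noise < 0:
        raise ValueError("rel_noise must be >= 0")
    rng = np.random.default_rng(seed)
    e0_mM = E0 * 1e-6
    rows = []
    for s in substrate:
        v_mM_s = k_cat * e0_mM * s / (K_m + s)
        slope = v_mM_s * epsilon * path_cm * 1000.0 * 60.0  # mAU/min
        for rep in range(1, n_reps + 1):
            fac = rng.normal(1.0, rel_noise) if rel_noise > 0 else 1.0
            rows.append(
                {"substrate_mM": s, "replicate": rep, "slope_mau_min": slope * fac}
            )
    return KineticsDataset(
        data=pd.DataFrame(rows), e0_nm=E0, epsilon=epsilon, path_cm=path_cm
    )


# ---------------------------------------------------------------------------
# residue sets


def make_residue_sets(
    universe_size: int,
    size_a: int,
    size_b: int,
    overlap: int,
    seed: int,
) -> tuple[ResidueSet, ResidueSet]:
    """Two residue sets with exactly the requested sizes and intersection."""
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed the smaller set size")
    if size_a + size_b - overlap > universe_size:
        raise ValueError("sets do not fit in the universe")
    rng = np.random.default_rng(seed)
    universe = np.arange(1, universe_size + 1)
    picked = rng.choice(universe, size=size_a + size_b - overlap, replace=False)
    shared = picked[:overlap]
    a_only = picked[overlap : size_a]
    b_only = picked[size_a :]
    uni = frozenset(int(x) for x in universe)
    set_a = ResidueSet(
        "A", frozenset(int(x) for x in np.concatenate([shared, a_only])), uni
    )
    set_b = ResidueSet(
        "B", frozenset(int(x) for x in np.concatenate([shared, b_only])), uni
    )
    return set_a, set_b
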