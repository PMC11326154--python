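"""Weighted isomorphous difference maps (F_state1 - F_state2).

A perturbed-state reflection set is scaled onto a reference set by an
isotropic (k, B) model, error/outlier-weighted difference coefficients
are formed, phases are taken from a reference coordinate model, and a
real-space difference density map is synthesized by inverse FFT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from allomap.reflections import ReflectionSet, common_reflections
from allomap.scattering import direct_summation, s_squared
from allomap.structure import StructureModel

logger = logging.getLogger(__name__)

#: default outlier-weighting strength
DEFAULT_ALPHA = 0.05


@dataclass
class ScaleResult:
    """Mutant reflections on the reference scale, with the (k, B) applied."""

    reflections: ReflectionSet
    k: float
    b_iso: float


@dataclass
class DifferenceCoefficients:
    """Per-reflection weighted difference structure factors.

    Defined only on reflections common to both inputs. ``phase_deg`` is
    None until :func:`phase_from_model` supplies reference-model phases.
    """

    hkl: np.ndarray
    delta_f: np.ndarray
    sig_delta: np.ndarray
    weight: np.ndarray
    alpha: float
    cell: tuple[float, float, float, float, float, float]
    space_group: str = "P1"
    phase_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        self.sig_delta = np.asarray(self.sig_delta, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if np.any(self.weight <= 0) or np.any(self.weight > 1):
            raise ValueError("weights must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def orth_matrix(self) -> np.ndarray:
        import gemmi

        return np.array(gemmi.UnitCell(*self.cell).orth.mat.tolist(), dtype=float)

    def d_min(self) -> float:
        s2 = s_squared(self.hkl, self.orth_matrix)
        return float(1.0 / np.sqrt(np.max(s2)))

    def complex_coefficients(self) -> np.ndarray:
        """w * dF * exp(i phi) for map synthesis."""
        if self.phase_deg is None:
            raise RuntimeError("coefficients are unphased; run phase_from_model first")
        return self.weight * self.delta_f * np.exp(1j * np.deg2rad(self.phase_deg))


@dataclass
class RealSpaceMap:
    """Density on a 3D grid covering exactly one unit cell (e-/A^3)."""

    values: np.ndarray  # (nx, ny, nz), axis i along cell axis i
    cell: tuple[float, float, float, float, float, float]
    grid_spacing_target: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def volume(self) -> float:
        import gemmi

        return gemmi.UnitCell(*self.cell).volume

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.values**2)))


# ---------------------------------------------------------------------------
# scaling


def scale_to_reference(mut: ReflectionSet, ref: ReflectionSet) -> ScaleResult:
    """Least-squares isotropic scaling of mut onto ref.

    Minimizes sum over common reflections of
    (k exp(B s^2/4) F_mut - F_ref)^2, so the reported B is the mutant
    data's excess isotropic smearing relative to the reference (a mutant
    measured with B 5 A^2 larger than the reference recovers B = +5).
    The returned set carries all of mut's reflections with F and sigF
    multiplied by the per-reflection factor k exp(B s^2/4).
    """
    if not mut.cells_compatible(ref):
        raise ValueError("cell/space-group mismatch between datasets")
    mut_asu = mut.to_asu()
    ref_asu = ref.to_asu()
    hkl, im, ir = common_reflections(mut_asu, ref_asu)
    if len(hkl) < 50:
        raise ValueError(f"only {len(hkl)} common reflections; need >= 50")
    s2 = s_squared(hkl, ref.orth_matrix)
    fm, fr = mut_asu.f[im], ref_asu.f[ir]

    # log-linear start (robust to the overall scale), then exact refinement
    pos = (fm > 0) & (fr > 0)
    coef = np.polyfit(s2[pos], np.log(fr[pos] / fm[pos]), 1)
    x0 = np.array([np.exp(coef[1]), 4.0 * coef[0]])

    def residuals(p):
        k, b = p
        return k * np.exp(b * s2 / 4.0) * fm - fr

    sol = optimize.least_squares(residuals, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    k, b = (float(x) for x in sol.x)
    logger.info("scale_to_reference: k=%.6g B=%.6g A^2 over %d reflections", k, b, len(hkl))

    factor = k * np.exp(b * s_squared(mut_asu.hkl, mut_asu.orth_matrix) / 4.0)
    scaled = ReflectionSet(
        hkl=mut_asu.hkl,
        f=mut_asu.f * factor,
        sigf=mut_asu.sigf * factor,
        cell=mut_asu.cell,
        space_group=mut_asu.space_group,
    )
    return ScaleResult(reflections=scaled, k=k, b_iso=b)


# ---------------------------------------------------------------------------
# weighting


def difference_weights(
    delta_f: np.ndarray,
    sig_delta: np.ndarray,
    alpha: float,
    s2: np.ndarray | None = None,
    n_bins: int = 0,
) -> np.ndarray:
    """Error/outlier weights w = [1 + sig^2/<sig^2> + alpha dF^2/<dF^2>]^-1.

    The normalizing means are global by default; with ``n_bins`` > 0 they
    are taken within equal-population resolution bins (requires ``s2``).
    Kept as one small function so alternative weighting schemes remain
    swappable.
    """
    delta_f = np.asarray(delta_f, dtype=float)
    sig_delta = np.asarray(sig_delta, dtype=float)

    def _w(df, sd):
        mean_s = np.mean(sd**2)
        mean_d = np.mean(df**2)
        t_sig = sd**2 / mean_s if mean_s > 0 else np.zeros_like(sd)
        t_out = alpha * df**2 / mean_d if mean_d > 0 else np.zeros_like(df)
        return 1.0 / (1.0 + t_sig + t_out)

    if n_bins and s2 is not None:
        w = np.empty_like(delta_f)
        edges = np.quantile(s2, np.linspace(0, 1, n_bins + 1))
        idx = np.clip(np.searchsorted(edges, s2, side="right") - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = idx == b
            if np.any(sel):
                w[sel] = _w(delta_f[sel], sig_delta[sel])
        return w
    return _w(delta_f, sig_delta)


def weighted_differences(
    mut_scaled: ReflectionSet,
    ref: ReflectionSet,
    alpha: float = DEFAULT_ALPHA,
    n_bins: int = 0,
) -> DifferenceCoefficients:
    """Form weighted difference coefficients on the common reflections.

    dF = F_mut,scaled - F_ref, sig_dF = sqrt(sig_mut^2 + sig_ref^2); the
    weight down-weights reflections with large measurement error or
    outlier difference magnitude (strength ``alpha``).
    """
    ref_asu = ref.to_asu()
    mut_asu = mut_scaled.to_asu()
    hkl, im, ir = common_reflections(mut_asu, ref_asu)
    if len(hkl) == 0:
        raise ValueError("no common reflections")
    delta = mut_asu.f[im] - ref_asu.f[ir]
    sig = np.sqrt(mut_asu.sigf[im] ** 2 + ref_asu.sigf[ir] ** 2)
    s2 = s_squared(hkl, ref.orth_matrix)
    w = difference_weights(delta, sig, alpha, s2=s2, n_bins=n_bins)
    return DifferenceCoefficients(
        hkl=hkl, delta_f=delta, sig_delta=sig, weight=w, alpha=alpha,
        cell=ref.cell, space_group=ref.space_group,
    )


# ---------------------------------------------------------------------------
# phasing and synthesis


def phase_from_model(
    coeffs: DifferenceCoefficients, model: StructureModel
) -> DifferenceCoefficients:
    """Attach calculated reference-model phases to the difference coefficients."""
    if model is None or not model.atoms:
        raise ValueError("missing reference model")
    if not np.allclose(np.array(model.cell), np.array(coeffs.cell), rtol=0.01):
        raise ValueError("model cell inconsistent with reflection cell")
    fc = direct_summation(model, coeffs.hkl)
    return DifferenceCoefficients(
        hkl=coeffs.hkl,
        delta_f=coeffs.delta_f,
        sig_delta=coeffs.sig_delta,
        weight=coeffs.weight,
        alpha=coeffs.alpha,
        cell=coeffs.cell,
        space_group=coeffs.space_group,
        phase_deg=np.degrees(np.angle(fc)),
    )


def _fft_grid_shape(
    cell: tuple, grid_spacing: float, hkl: np.ndarray
) -> tuple[int, int, int]:
    dims = []
    for axis in range(3):
        n = int(np.ceil(cell[axis] / grid_spacing))
        n = max(n, 2 * int(np.max(np.abs(hkl[:, axis]))) + 2)
        dims.append(n)
    return tuple(dims)


def synthesize_map(
    coeffs: DifferenceCoefficients, grid_spacing: float = 0.5
) -> RealSpaceMap:
    """Inverse-FFT difference density on a grid covering one unit cell.

    rho(x) = (1/V) sum_h w dF exp(i phi) exp(-2 pi i h.x); the Friedel
    mate of every coefficient is added explicitly so the map is real, and
    (0,0,0) is excluded so an Fobs-Fobs difference map has zero mean.
    """
    if coeffs.phase_deg is None:
        raise RuntimeError("coefficients are unphased; run phase_from_model first")
    d_min = coeffs.d_min()
    if grid_spacing > d_min / 2.0 + 1e-9:
        raise ValueError(
            f"grid spacing {grid_spacing} A too coarse for d_min {d_min:.3f} A "
            "(need <= d_min/2)"
        )
    shape = _fft_grid_shape(coeffs.cell, grid_spacing, coeffs.hkl)
    grid = np.zeros(shape, dtype=complex)
    cvals = coeffs.complex_coefficients()
    for h, c in zip(coeffs.hkl, cvals):
        if h[0] == 0 and h[1] == 0 and h[2] == 0:
            continue  # no F000 in a difference map
        idx = tuple(int(h[i]) % shape[i] for i in range(3))
        conj_idx = tuple((-int(h[i])) % shape[i] for i in range(3))
        grid[idx] += c
        grid[conj_idx] += np.conj(c)
    import gemmi

    volume = gemmi.UnitCell(*coeffs.cell).volume
    density = np.fft.fftn(grid).real / volume
    return RealSpaceMap(
        values=density, cell=coeffs.cell, grid_spacing_target=grid_spacing
    )


def density_at_points(
    coeffs: DifferenceCoefficients, frac_points: np.ndarray
) -> np.ndarray:
    """Direct-summation density at fractional coordinates (cross-check route).

    Evaluates the same Fourier sum as :func:`synthesize_map` without the
    FFT, at arbitrary fractional positions.
    """
    if coeffs.phase_deg is None:
        raise RuntimeError("coefficients are unphased")
    import gemmi

    volume = gemmi.UnitCell(*coeffs.cell).volume
    pts = np.asarray(frac_points, dtype=float).reshape(-1, 3)
    cvals = coeffs.complex_coefficients()
    keep = ~np.all(coeffs.hkl == 0, axis=1)
    hkl = coeffs.hkl[keep].astype(float)
    cvals = cvals[keep]
    phases = np.exp(-2j * np.pi * (pts @ hkl.T))  # (npts, nrefl)
    vals = (phases * cvals).sum(axis=1) + (np.conj(phases) * np.conj(cvals)).sum(axis=1)
    return vals.real / volume
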