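"""Michaelis-Menten kinetics from chromogenic plate-reader assays.

Initial velocities (absorbance slopes, mAU/min) at a dilution series of
substrate concentrations are fit to v = Vmax * S / (Km + S) by nonlinear
least squares on replicate-level points. The turnover number follows as
k_cat = Vmax / (epsilon * path * E0) once the product's molar
absorptivity and the optical path length are known.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Nonlinear fit failed or produced unphysical parameters."""


@dataclass
class KineticsDataset:
    """Initial-velocity data: (substrate_mM, replicate, slope_mau_min) rows.

    ``epsilon`` is the product molar absorptivity in AU mM^-1 cm^-1 and
    ``path_cm`` the optical path; both are required to convert Vmax to
    k_cat and are deliberately explicit configuration, not constants.
    """

    data: pd.DataFrame
    e0_nm: float
    epsilon: float | None = None  # AU / mM / cm
    path_cm: float | None = None

    def __post_init__(self) -> None:
        req = {"substrate_mM", "replicate", "slope_mau_min"}
        missing = req - set(self.data.columns)
        if missing:
            raise ValueError(f"kinetics table missing columns: {sorted(missing)}")
        if (self.data["substrate_mM"] <= 0).any():
            raise ValueError("substrate concentrations must be positive")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class MMFit:
    """Michaelis-Menten fit result with covariance-based 95% intervals."""

    vmax_mau_min: float
    km_mM: float
    vmax_ci: tuple[float, float]
    km_ci: tuple[float, float]
    kcat_s: float | None
    kcat_ci: tuple[float, float] | None
    residual_rms: float
    n_points: int
    n_replicates: int
    replicate_kcat: np.ndarray | None = None  # per-replicate estimates, kcat or Vmax/E0 units
    units: str = "mAU/min"

    def to_dict(self) -> dict:
        d = {
            "vmax_mau_min": self.vmax_mau_min,
            "km_mM": self.km_mM,
            "vmax_ci95": list(self.vmax_ci),
            "km_ci95": list(self.km_ci),
            "kcat_per_s": self.kcat_s,
            "kcat_ci95": list(self.kcat_ci) if self.kcat_ci else None,
            "residual_rms": self.residual_rms,
            "n_points": self.n_points,
            "n_replicates": self.n_replicates,
            "units": self.units,
        }
        if self.replicate_kcat is not None:
            d["replicate_kcat"] = [float(x) for x in self.replicate_kcat]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------


def slopes_from_traces(
    time_s: np.ndarray,
    absorbance_au: np.ndarray,
    window_s: tuple[float, float] | None = None,
) -> float:
    """OLS slope of an absorbance trace, converted to mAU/min.

    The default window is the full trace (the assay's 6-minute read).
    """
    t = np.asarray(time_s, dtype=float)
    a = np.asarray(absorbance_au, dtype=float)
    if window_s is not None:
        sel = (t >= window_s[0]) & (t <= window_s[1])
        t, a = t[sel], a[sel]
    if len(t) < 5:
        raise ValueError("need >= 5 time points in the fitting window")
    slope_au_s = np.polyfit(t, a, 1)[0]
    return float(slope_au_s * 1000.0 * 60.0)


def michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def _kcat_factor(data: KineticsDataset) -> float | None:
    """mAU/min -> s^-1 conversion factor, None when epsilon/path unknown."""
    if data.epsilon is None or data.path_cm is None:
        return None
    e0_mM = data.e0_nm * 1e-6
    # mAU/min -> AU/s -> mM/s -> per-enzyme s^-1
    return 1.0 / (1000.0 * 60.0 * data.epsilon * data.path_cm * e0_mM)


def fit_michaelis_menten(data: KineticsDataset) -> MMFit:
    """Fit v = Vmax S/(Km+S) to replicate-level velocities.

    Replicates are pooled (fit jointly), preserving degrees of freedom for
    the covariance-based t intervals. Initial guesses are Vmax = max(v)
    and Km = S at half-maximal velocity.
    """
    df = data.data
    if df["substrate_mM"].nunique() < 3:
        raise ValueError("need >= 3 distinct substrate concentrations to fit")
    s = df["substrate_mM"].to_numpy(dtype=float)
    v = df["slope_mau_min"].to_numpy(dtype=float)
    smin, smax = s.min(), s.max()
    vmax0 = float(v.max())
    half = np.abs(v - vmax0 / 2.0)
    km0 = float(s[np.argmin(half)])
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten, s, v, p0=[vmax0, max(km0, smin)],
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = (float(x) for x in popt)
    if vmax <= 0 or km <= 0:
        raise FitError(f"unphysical fit: Vmax={vmax:.4g}, Km={km:.4g}")
    if not (smin < km < smax):
        warnings.warn(
            "substrate series does not bracket the fitted Km; "
            "estimates may be poorly constrained",
            stacklevel=2,
        )
    n = len(s)
    dof = max(n - 2, 1)
    tq = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.diag(pcov))
    resid = v - michaelis_menten(s, vmax, km)
    rms = float(np.sqrt(np.mean(resid**2)))

    factor = _kcat_factor(data)
    kcat = kcat_ci = None
    if factor is not None:
        kcat = vmax * factor
        kcat_ci = (float((vmax - tq * se[0]) * factor), float((vmax + tq * se[0]) * factor))

    # per-replicate fits feed the mutant-vs-reference t-test
    reps = sorted(df["replicate"].unique())
    rep_kcat = []
    for r in reps:
        sub = df[df["replicate"] == r]
        if sub["substrate_mM"].nunique() < 3:
            continue
        try:
            p, _ = optimize.curve_fit(
                michaelis_menten,
                sub["substrate_mM"].to_numpy(dtype=float),
                sub["slope_mau_min"].to_numpy(dtype=float),
                p0=[vmax, km], maxfev=20000,
            )
        except RuntimeError:
            continue
        rep_kcat.append(p[0] * (factor if factor is not None else 1.0 / data.e0_nm))
    return MMFit(
        vmax_mau_min=vmax,
        km_mM=km,
        vmax_ci=(float(vmax - tq * se[0]), float(vmax + tq * se[0])),
        km_ci=(float(km - tq * se[1]), float(km + tq * se[1])),
        kcat_s=kcat,
        kcat_ci=kcat_ci,
        residual_rms=rms,
        n_points=n,
        n_replicates=len(reps),
        replicate_kcat=np.array(rep_kcat) if rep_kcat else None,
        units="mAU/min" if factor is None else "s^-1",
    )


def _ratio_ci(
    num: float, num_ci: tuple[float, float], den: float, den_ci: tuple[float, float]
) -> tuple[float, float]:
    """Delta-method 95% CI of num/den on the log scale."""
    # half-width -> standard error (95% t ~ treated as normal for propagation)
    se_num = (num_ci[1] - num_ci[0]) / (2 * 1.96)
    se_den = (den_ci[1] - den_ci[0]) / (2 * 1.96)
    ratio = num / den
    se_log = np.sqrt((se_num / num) ** 2 + (se_den / den) ** 2)
    return (float(ratio * np.exp(-1.96 * se_log)), float(ratio * np.exp(1.96 * se_log)))


def compare_fits(mutant_fits: dict[str, MMFit], wt_fit: MMFit) -> pd.DataFrame:
    """Compare each mutant fit to the reference fit.

    Per parameter (k_cat when available, else Vmax; and Km) the table
    carries the mutant/reference ratio with a propagated 95% interval and
    an "unchanged" flag when that interval contains 1. A two-tailed
    one-sample t-test compares the mutant's replicate-level k_cat
    estimates against the reference point estimate.
    """
    rows = []
    wt_has_kcat = wt_fit.kcat_s is not None
    for name, fit in mutant_fits.items():
        if (fit.kcat_s is not None) != wt_has_kcat:
            raise ValueError("mutant and reference fits carry different units")
        if wt_has_kcat:
            num, num_ci = fit.kcat_s, fit.kcat_ci
            den, den_ci = wt_fit.kcat_s, wt_fit.kcat_ci
            rate_label = "kcat"
        else:
            num, num_ci = fit.vmax_mau_min, fit.vmax_ci
            den, den_ci = wt_fit.vmax_mau_min, wt_fit.vmax_ci
            rate_label = "vmax"
        r_ci = _ratio_ci(num, num_ci, den, den_ci)
        km_ratio = fit.km_mM / wt_fit.km_mM
        km_ci = _ratio_ci(fit.km_mM, fit.km_ci, wt_fit.km_mM, wt_fit.km_ci)
        if fit.replicate_kcat is not None and len(fit.replicate_kcat) >= 2:
            wt_ref = wt_fit.kcat_s if wt_has_kcat else wt_fit.vmax_mau_min
            tstat, pval = stats.ttest_1samp(fit.replicate_kcat, wt_ref)
            pval = float(pval)
        else:
            pval = float("nan")
        rows.append(
            {
                "variant": name,
                "rate_parameter": rate_label,
                "rate_ratio": num / den,
                "rate_ratio_ci_low": r_ci[0],
                "rate_ratio_ci_high": r_ci[1],
                "rate_unchanged": r_ci[0] <= 1.0 <= r_ci[1],
                "km_ratio": km_ratio,
                "km_ratio_ci_low": km_ci[0],
                "km_ratio_ci_high": km_ci[1],
                "km_unchanged": km_ci[0] <= 1.0 <= km_ci[1],
                "t_test_p": pval,
            }
        )
    return pd.DataFrame(rows)
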