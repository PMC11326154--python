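# Methods

`allomap` implements the computational route from point-mutant
perturbation data to an allosteric residue network: weighted isomorphous
difference electron density scored per residue, residue-level HDX-MS
difference profiles, Michaelis–Menten kinetics, and thresholded network
pooling with sector-overlap statistics. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## Difference maps (`diffmap`)

Two isomorphous reflection sets — a perturbed state ("mutant") and a
reference ("wild type") — are compared as amplitudes only.

**Scaling.** The mutant set is brought onto the reference scale by an
isotropic two-parameter model, minimizing
Σ (k·exp(B·s²/4)·F_mut − F_ref)² over common reflections (s = 1/d).
B is reported as the mutant data's *excess* smearing: a mutant measured
with an isotropic B 5 Å² larger than the reference recovers B = +5. A
log-linear fit supplies the starting point; `scipy.optimize.least_squares`
refines at tight tolerances. Anisotropic scaling is out of scope; for the
synthetic acceptance surface, isotropic is exact by construction.
Reflections present in only one set are dropped, never imputed —
imputation would inject phantom difference signal. Common-reflection
matching happens after both sets are mapped to the reciprocal-space
asymmetric unit; duplicates merge by inverse-variance weighted mean.

**Weighting.** Difference amplitudes ΔF = F_mut,scaled − F_WT with
σΔ = √(σ_mut² + σ_WT²) are down-weighted when noisy or outlying:

    w = [ 1 + σΔ²/⟨σΔ²⟩ + α·ΔF²/⟨ΔF²⟩ ]⁻¹ ,   α = 0.05 by default.

This is the standard error/outlier weighting for Fobs−Fobs difference
maps. The normalizing means are global by default; equal-population
resolution-binned means are available (`n_bins`), since published
analyses do not always state which convention they use. The formula is
isolated in `difference_weights` so alternatives are swappable. Closed
forms used as checks: α = 0 with every σΔ² at the mean gives w = ½; a
single reflection with ΔF² = 100·⟨ΔF²⟩ and negligible σ gives w = 1/6.

**Phasing and synthesis.** Phases come from the reference coordinate
model by direct summation. The map

    Δρ(x) = (1/V) Σ_h w·ΔF·exp(iφ_WT)·exp(−2πi h·x)

is evaluated by FFT on a grid with spacing ≤ d_min/2 (default target
0.5 Å) and at least 2·|h|_max + 2 points per axis, with each Friedel mate
added explicitly so the map is real. (0,0,0) is excluded, so the map has
zero mean. `density_at_points` evaluates the same sum directly at
arbitrary fractional coordinates and is used as the independent route in
tests (agreement to better than 1e-6 relative; Parseval identity holds to
the same tolerance).

## Residue scoring (`iaddat`)

Grid points with |Δρ| strictly greater than the threshold (default
0.04 e⁻/Å³) are assigned to the nearest protein heavy atom within the
capture radius (default 1.5 Å, inclusive); waters and hydrogens are never
assignment targets. Distances use the minimum-image convention in
fractional space, so points near cell edges see atoms across the
boundary. Exact distance ties resolve to the lowest
(chain, residue index, atom name) — deterministic output. The residue
score is the accumulated |Δρ| divided by the residue's heavy-atom count;
this normalizes residue size so glycine and tryptophan are comparable. A
per-contributing-grid-point mean is available via
`per_atom_average=False`. The boundary semantics (strict `>` on the
threshold, inclusive `≤` on the radius) are fixed and tested.

The optimized vectorized scorer is verified bit-for-bit (same
floating-point sums, same order) against an exhaustive grid-scan oracle
in the test suite. Score magnitudes on synthetic maps are on the absolute
e⁻/Å³ scale implied by the direct-summation amplitudes; on real data the
threshold can equivalently be given in map-RMS units.

Scores are written back as a per-residue CSV and as a PDB copy with the
(display) score in the B-factor column for structure coloring; display
scores may be capped (default 0.3) without ever touching the raw values.

## HDX-MS differences (`hdx`)

**Amide counting.** A peptide of length L has L−1 backbone amides in the
fragment; prolines carry no amide NH, and the amide adjacent to the
N-terminal residue back-exchanges too fast to measure. Both bookkeeping
routes collapse to N_ex = L − 2 − (# prolines at positions 3..L), and the
implementation asserts the two formulations against each other on every
call.

**Deuteration percentages.** With a fully deuterated (FD) control,
%D = 100·(m_t − m₀)/(m_FD − m₀), which cancels back-exchange; without
one, the denominator is the theoretical maximum N_ex·d_frac·m_D with
m_D = 1.00628 Da and d_frac the labeling D₂O fraction (default 0.90).
Values are clipped to [−5, 110] and flagged outside that range; values
below −5 are treated as unusable rather than noise.

**Differences.** Replicates are averaged within condition before
differencing; peptides are matched by (sequence, start, end) and
unmatched peptides dropped with a log line. The no-change band is ±5
percentage points with strict boundaries (Δ%D = −5.0 exactly is
no-change). The band (5) and the network threshold (7) are distinct,
separately configurable constants.

**Residue interpolation.** The proprietary residue-level smoothing used
by HDX acquisition software is unpublished; this package substitutes a
transparent rule and labels outputs with it. Each covered residue takes
the mean of its covering peptides' Δ%D weighted by 1/N_ex, so shorter
peptides (closer to single-residue resolution) dominate. The
`short-peptides` scheme first restricts to a greedy minimal-length set
cover: walking left to right, the shortest peptide covering the first
still-uncovered position is selected (ties to the smaller start). Greedy
is not globally optimal in general; it is the documented, deterministic
rule. Residues with no covering peptide are flagged no-data, never
imputed as 0. A peptide's value is spread over its full start..end range.

## Kinetics (`kinetics`)

Initial velocities are OLS slopes of absorbance traces (mAU/min over the
full read window by default). Michaelis–Menten parameters are fit by
nonlinear least squares on replicate-level velocities (pooled residuals —
replicates are not averaged first, preserving degrees of freedom), with
starting values V_max = max(v) and K_m = S at half-max. 95% intervals are
covariance-based t intervals (n−2 df); profile-likelihood intervals are
out of scope. k_cat = V_max/(ε·ℓ·E₀) is reported only when the product
molar absorptivity ε and path length ℓ are supplied (they are buffer- and
plate-dependent); otherwise V_max is reported in absorbance units with an
explicit unit tag. Fitting is on velocities directly, not a
Lineweaver–Burk linearization, which would bias estimates under additive
noise. Mutant-vs-reference comparison reports per-parameter ratios with
delta-method (log-scale) intervals, an "unchanged" flag when the ratio
interval contains 1, and a two-tailed one-sample t-test of the mutant's
per-replicate k_cat estimates against the reference point estimate.

## Network pooling and overlap (`network`)

Residues whose density score exceeds 0.3 (arbitrary units) or whose
|Δ%D| exceeds 7 points are thresholded (strict `>`), pooled by union
across variants and techniques, and compared to externally supplied
residue sectors by the Jaccard ratio J = |X∩Y|/|X∪Y| (defined as 0 for
two empty sets) and the upper-tail hypergeometric probability P(X ≥ k),
inclusive of the observed overlap k. The membership universe materially
changes p-values; it defaults to the residues present in the supplied
model and is echoed in every report. An intersection pooling mode exists
for sensitivity analysis. The hypergeometric tail is evaluated with
`scipy.stats.hypergeom` (stable log-space internals) and is checked
against exact integer enumeration in the tests. Because the statistic is
discrete, null p-values are super-uniform rather than uniform; the
calibration test uses (N=100, K=20, n=15), where the attained level of
the p < 0.05 call is 0.046.

## Synthetic data (`synthetic_data`)

The generators define the study conditions for all recovery tests.

* **Crystals.** Poly-alanine-like chains (N, CA, C, O, CB per residue) on
  an idealized α-helical path with 0.05 Å seeded jitter, in an
  orthorhombic P1 cell with a ≥5 Å solvent margin. Structure factors by
  direct summation with single-Gaussian per-element form factors
  (f(s) = Z·exp(−b·s²/4)) and isotropic B smearing — adequate for
  difference signals, not refinement. A "mutation" displaces a residue's
  CB (optionally its backbone) by a seeded random direction times a
  displacement, default 1.5 Å, emulating a side-chain rearrangement with
  one knob. Measurement noise is Gaussian and relative
  (F′ = F + N(0, (0.05·F)²) at the default 5%), with σF recorded.
  Space-group symmetry beyond P1 is delegated to the I/O layer's ASU
  mapping; keeping generation in P1 keeps the direct-summation oracle
  exact and small.
* **HDX.** Per-residue uptake D_i(t) = d_frac·(1 − exp(−(k_int/PF)·t))
  over each peptide's exchange-reporting positions; peptide mass increase
  (1 − backexchange)·Σ D_i·m_D; FD controls at
  (1 − backexchange)·d_frac·N_ex·m_D; Gaussian centroid noise (0.02 Da in
  the bundled runs). Intrinsic rates default to a single constant
  (1 s⁻¹), with a hook for user-supplied per-residue rates — recovery
  tests need controllable rates, not sequence-dependent chemistry. The
  block-recovery experiments use k_int = 0.0015 s⁻¹ so that a ×10
  protection block produces a ≈ −30 point difference at the 300 s
  timepoint; at much faster rates both states saturate and protection of
  that size is invisible, which is itself a property of the model worth
  knowing.
* **Kinetics.** v(S) = k_cat·E₀·S/(K_m+S) converted to absorbance slopes
  through ε = 18 AU·mM⁻¹·cm⁻¹ and ℓ = 0.575 cm (a 100 µL well);
  multiplicative N(1, 5%) replicate noise; a 12-point geometric dilution
  series from 40 mM to 3.9 µM (step ≈ 2.3-fold). Defaults: k_cat 20 s⁻¹,
  K_m 5 mM, E₀ 125 nM, quadruplicates.
* **Residue sets.** Uniform draws with exactly requested sizes and
  intersection, for calibrating the overlap statistics.

What the synthetic data do *not* emulate: real lattice packing and
solvent, anomalous scattering, sequence-dependent intrinsic exchange
rates, EX1 kinetics, peptide ionization efficiency, or substrate
depletion. Passing recovery tests therefore demonstrates the correctness
and calibration of the analysis chain, not instrument-level realism.

## Problem sizes and determinism

The bundled end-to-end run uses a 40-residue toy crystal at d_min 2.0 Å
(≈ 4500 reflections), three variants, a 9–13-peptide ladder, and the
12-point kinetics series; it completes in a few seconds on one CPU.
Replicate studies (localization, parameter recovery, null calibration)
use 20 seeds; the type-I calibration uses 1000 draws. All randomness
flows through `numpy.random.default_rng` with explicit seeds; reruns with
the same configuration are byte-identical, which the suite checks by
hashing every CSV output.

## Known limitations

* Isotropic scaling only; strongly anisotropic inter-dataset differences
  would leak into ΔF.
* The greedy peptide cover is a heuristic; adversarial peptide maps can
  make it select more total length than the optimum.
* Covariance-based confidence intervals understate uncertainty when K_m
  sits near the edge of the substrate series.
* Minimum-image distances are computed in fractional space, which is
  exact for the orthorhombic synthetic cells but approximate for very
  oblique cells with capture radii approaching half a cell edge.
* The hypergeometric test treats residues as exchangeable; spatial
  correlation along the chain (peptide-length smearing feeding the HDX
  set) makes the nominal p-values optimistic for contiguous networks.
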