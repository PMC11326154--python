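# allomap

Mapping allosteric residue networks from mutant-perturbation experiments.

Point mutations distant from an enzyme's active site can alter catalysis
by rewiring a network of coupled residues. Two complementary experiments
see this wiring: room-temperature crystallography of mutant vs. wild-type
crystals, compared through **weighted isomorphous difference electron
density maps** (F_mut − F_WT with reference-model phases), and
**hydrogen-deuterium exchange mass spectrometry** (HDX-MS), where
backbone amide exchange reports on solvent accessibility and hydrogen
bonding in solution. `allomap` implements the full analysis chain from
raw inputs to a combined residue network, for structural biologists
analyzing a perturbation series of an enzyme such as a protein tyrosine
phosphatase:

1. **diffmap** — scale a mutant reflection set onto a reference
   (isotropic k, B least squares), form error/outlier-weighted difference
   coefficients w·ΔF with
   w = [1 + σΔ²/⟨σΔ²⟩ + α·ΔF²/⟨ΔF²⟩]⁻¹ (α = 0.05), phase with a
   reference model, and synthesize the real-space difference map by FFT.
2. **iaddat** — integrate absolute difference density above a noise
   threshold (|Δρ| > 0.04 e⁻/Å³, within 1.5 Å of a protein heavy atom,
   waters excluded), summed and averaged per residue; scores map onto
   Cα positions via the B-factor column for structure coloring.
3. **hdx** — back-exchange-corrected deuteration percentages from
   peptide centroid masses with fully-deuterated controls, mutant−WT
   Woods-plot differences with a ±5 percentage-point no-change band, and
   inverse-amide-count weighted interpolation to residue level
   (optionally over a greedy shortest-peptide cover of the sequence).
4. **kinetics** — Michaelis–Menten fits (v = V_max·S/(K_m+S), nonlinear
   least squares on replicate-level initial velocities) with
   k_cat = V_max/(ε·ℓ·E₀) and mutant/WT comparisons.
5. **network** — pool residues with density score > 0.3 and/or
   |Δ%deuteration| > 7 into a combined network; quantify overlap with
   coevolving-sector residue sets by the Jaccard ratio
   J(X,Y) = |X∩Y|/|X∪Y| and an exact upper-tail hypergeometric test.

A first-class `synthetic_data` module generates ground-truth inputs for
every stage — toy P1 crystals with planted side-chain displacements,
uptake curves from per-residue protection factors, initial-velocity
datasets, residue sets with controlled overlap — so the whole chain is
testable against known answers. See `docs/methods.md` for models,
defaults and limitations.

## Worked example

Simulate a 10-residue toy crystal whose residue 4 side chain is displaced
by 1.5 Å, then run the difference-map branch:

```sh
allomap simulate crystal --n-residues 10 --perturb 4 --seed 1 --out-dir demo
allomap diffmap --mut demo/mut.mtz --ref demo/wt.mtz --model demo/wt.pdb \
        --out demo/diff.ccp4
allomap iaddat --map demo/diff.ccp4 --model demo/mut.pdb --out-prefix demo/scored
```

which prints

```
{"scale_k": 0.9959642674922338, "scale_b": -0.26434299553989465, "map_rms": 0.012755035753126674, "out": "demo/diff.ccp4"}
{"top_residue": 4, "out": "demo/scored.csv"}
```

The scale factor k ≈ 1 and small B confirm the two simulated datasets are
already on a common scale (5% amplitude noise produces the small apparent
B); the map RMS of ≈ 0.013 e⁻/Å³ sits well below the 0.04 e⁻/Å³
integration threshold, and the planted perturbation at residue 4 is the
top-ranked residue. `demo/scored.csv` holds the per-residue trace (zeros
everywhere except residue 4) and `demo/scored.pdb` the same scores in the
B column.

Fitting simulated kinetics (true k_cat = 20 s⁻¹, K_m = 5 mM, E₀ = 125 nM,
quadruplicates at 5% noise over a 40 mM → 3.9 µM dilution series):

```sh
allomap simulate kinetics --rel-noise 0.05 --seed 2 --out-dir demo
allomap kinetics --data demo/kinetics.csv --e0-nm 125 --epsilon 18 \
        --path-cm 0.575 --out demo/fit.json
```

reports `kcat_per_s: 19.68` with 95% CI [19.14, 20.21] and
`km_mM: 4.75` with CI [4.33, 5.16] — both truths inside the intervals.

The whole pipeline (three variants, all four data types, network and
sector overlap) runs with `allomap run --seed 1 --out-dir run1`, writing
per-stage CSV/JSON outputs, a combined `report.json`, and the fully
resolved configuration.

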