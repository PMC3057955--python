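# thermoflex

Analysis toolkit for a classic question in enzyme temperature adaptation:
why are thermophilic enzymes sluggish at low temperatures?  One mechanism
is a rigidifying interaction at the active site — in acylphosphatases, a
salt bridge between the catalytic arginine and the C-terminal carboxylate
that is present in thermophilic homologues (PhAcP from *Pyrococcus
horikoshii*) and absent in mesophilic ones (human AcP).  Pinning the
arginine costs nothing at the transition state (which requires one specific
rotamer anyway) but removes ground-state conformational entropy, raising
ΔS# and, through enthalpy–entropy compensation, ΔH# — a steeper Arrhenius
slope that favors activity at high temperature and penalizes it at low
temperature.

`thermoflex` implements every quantitative stage of such a study as a
reusable, tested pipeline:

- **Transition-state decomposition** (`thermoflex.thermo`): from a turnover
  number and Arrhenius activation energy,
  ΔG# = RT·(ln(k_B·T/h) − ln k_cat), ΔH# = E_a − RT, TΔS# = ΔH# − ΔG#,
  with first-order uncertainty propagation; paired ΔΔ comparisons between
  variants, compensation curves ΔΔG#(T) and the implied fold change in
  k_cat from an entropic shift.
- **Kinetics fitting** (`thermoflex.kinetics`): Michaelis–Menten
  (v = k_cat·E₀·S/(K_m+S)) and Arrhenius (ln k_cat vs 1/T) regressions as
  scikit-learn estimators (`MichaelisMentenRegressor`,
  `ArrheniusRegressor`), extrapolation with prediction SEs, and the
  crossover temperature of two Arrhenius lines.
- **Titration calorimetry** (`thermoflex.itc`): the closed-form single-site
  (Wiseman) injection-heat model with displacement dilution, a
  `SingleSiteBindingRegressor` recovering (K_a, ΔH_b, n), and the
  decomposition ΔG_b = −RT·ln K_a, TΔS_b = ΔH_b − ΔG_b.
- **Stability** (`thermoflex.stability`): six-parameter two-state
  linear-extrapolation fits of chemical denaturation curves
  (ΔG(D) = ΔG_u − m·D, sloped baselines, C_m = ΔG_u/m).
- **Flexibility** (`thermoflex.flexibility`): rotamer classification in the
  p/t/m convention (e.g. the native arginine rotamer `mtm180`), occupancy /
  transition / dwell statistics from χ1–χ4 time series, salt-bridge
  occupancy from distance traces (d < 4 Å), and Kabsch superposition with
  RMSD/RMSF for coordinate ensembles.
- **Synthetic data** (`thermoflex.simulate`): seeded generators for every
  input above with known ground truth, including presets for the five
  studied variants (PhWT, PhG91A, HuG99, HuA99, HuWT).

## Worked example

Decompose the thermophilic wild type's measured kinetics (k_cat = 228 ± 15
s⁻¹, E_a = 49.1 ± 1.4 kJ mol⁻¹ at 298 K):

```sh
$ thermoflex tst --kcat 228 --kcat-se 15 --ea 49.1 --ea-se 1.4
{
  "dG": 59.53373280505596,
  "dH": 46.622290139836004,
  "TdS": -12.911442665219958,
  "dS": -43.32698880946295,
  ...
}
```

ΔG# ≈ 59.5 kJ mol⁻¹ sets the absolute rate; the negative TΔS# (−12.9
kJ mol⁻¹) is the entropic price of organizing the transition state.
Comparing the bridge-free mutant against the wild type:

```sh
$ thermoflex compare --variant-a PhG91A --variant-b PhWT
{
  "pair": "PhG91A-PhWT",
  "ddG": 0.19199153158617577,
  "ddH": -17.000000000000004,
  "TddS": -17.19199153158618,
  ...
}
```

Removing the salt bridge drops both ΔΔH# and TΔΔS# by ~17 kJ mol⁻¹ while
ΔΔG# changes by only 0.2 kJ mol⁻¹ at 298 K — near-perfect
enthalpy–entropy compensation.  The whole derived table for all five
variants, diffed cell-by-cell against the published values:

```sh
$ thermoflex reproduce-tables
53/53 cells within rounding tolerance (46 exact)
```

The full pipeline (synthetic assays → MM fits → Arrhenius → ΔΔ tables →
ITC → trajectory summaries) runs with
`thermoflex run --outdir out --seed 0`, and each stage also accepts CSV
inputs in the dialects documented in its module.

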