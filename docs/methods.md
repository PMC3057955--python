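# Methods

## Transition-state analysis

Turnover numbers are converted to activation free energies with the Eyring
relation at unit transmission coefficient,
ΔG# = R·T·(ln(k_B·T/h) − ln k_cat), and split into
ΔH# = E_a − RT and TΔS# = ΔH# − ΔG#.  Assumptions: a single rate-limiting
chemical step, no tunneling corrections, and temperature-independent ΔH#
and ΔS# over the assay window (283–318 K) — justified by the linearity of
the measured Arrhenius plots.  Constants are CODATA 2018
(R = 8.314462618 J mol⁻¹ K⁻¹, k_B = 1.380649·10⁻²³ J K⁻¹,
h = 6.62607015·10⁻³⁴ J s); the reference temperature is 298.00 K exactly.
Using 298.15 K would shift ΔG# by <0.05 kJ mol⁻¹ but produce worse
agreement with the published one-decimal rounding.

Uncertainties are propagated to first order assuming uncorrelated inputs:
se(ΔG#) = RT·se(k_cat)/k_cat, se(ΔH#) = se(E_a), and quadrature for
differences.  This reproduces the published ΔΔH# errors (e.g.
√(1.4² + 1.7²) = 2.2).  The published ΔG# uncertainties (±0.02–0.04
kJ mol⁻¹) are much smaller than this propagation implies (±0.16 for the
thermophilic wild type); their origin is unstated upstream, so the package
reports the propagated value rather than matching the printed error bars.

ΔΔ comparisons use the convention (variant without the salt bridge) −
(variant with it).  Compensation curves ΔΔG#(T) = ΔΔH# − T·ΔΔS# assume
temperature-independent ΔΔH#, ΔΔS# and report the compensation temperature
T_c = ΔΔH#/ΔΔS# (absent when ΔΔS# = 0).  `entropic_fold_change` is the
rate ratio exp(TΔΔS#/RT) implied by an entropic shift at constant ΔH#.

### Rounding and table regeneration

Report tables round kJ quantities to one decimal and entropies
(J mol⁻¹ K⁻¹) to integers, matching the published layout.
`reproduce_tables` diffs every derived cell against the published digits
with a tolerance of one unit in the last printed digit, because the
published rounding is internally inconsistent at that level in a handful
of cells (e.g. the mesophilic wild type's TΔS# prints −20.2 where the
recomputed value −20.27 rounds to −20.3, and the thermophilic ΔS_b prints
50 where the recomputation gives 50.6).  46 of 53 cells match exactly;
all 53 pass at the one-digit tolerance.

## Kinetics fitting

Michaelis–Menten fits use unweighted nonlinear least squares of
v = k_cat·E₀·S/(K_m + S) (enzyme concentration converted nM → mM so k_cat
is in s⁻¹), initialized from max(v)/E₀ and the substrate level nearest
half-max; SEs come from the Jacobian.  The fit requires ≥4 distinct
substrate levels; the default synthetic design is 8 levels from 0.05 to
2.0 mM in triplicate, bracketing K_m = 0.10 mM.

Arrhenius regression is ordinary least squares of ln k_cat on 1/T
(E_a = −slope·R), unweighted by default because per-point rate SEs are
typically only available at the reference temperature; inverse-variance
weighting is available via `sample_weight`.  ≥3 temperatures are required
(a two-point closed form is exposed separately as
`activation_energy_two_point` for cross-checks).  Extrapolation SEs use
the full (slope, intercept) covariance.  The crossover temperature of two
lines is T* = (E_a,1 − E_a,2)·1000/(R·(lnA₁ − lnA₂)), reported absent for
parallel lines or an unphysical (T* ≤ 0) crossing.

Whether a per-temperature k_cat should come from a full MM fit or a
saturating-substrate rate is left open upstream; the pipeline defaults to
the full fit and accepts precomputed (T, k_cat) series for the other
convention.

## Titration calorimetry

The forward model is the closed-form single-site (Wiseman) cumulative
heat.  Injection i dilutes both cell species multiplicatively by
(1 − dV_i/V₀) before adding titrant; the cumulative heat is

Q_i = n·M_i·ΔH_b·V₀/2 · [b − √(b² − 4·X_i/(n·M_i))],
b = 1 + X_i/(n·M_i) + 1/(n·K_a·M_i),

and the reported per-injection heat corrects for displaced volume,
q_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2.  Heats are in µJ;
the default protocol is 25 × 4 µl of 30 mM titrant into 1.5 mM protein in
a 1 ml cell at 298 K.  No first-injection anomaly is modelled; a
`drop_first` option discards injection 1 when real data require it.

Fitting is least squares in (ln K_a, ΔH_b, n) for conditioning, n floated
by default (`fix_n=True` pins it at 1 — the upstream instrument software's
choice is unknown).  A warning is raised when the c-value n·K_a·M₀ leaves
[1, 1000], where the isotherm shape no longer determines K_a well.  The
tests verify the closed form against an independent per-injection
bisection solve of the binding polynomial to 1e-8.

Binding thermodynamics: ΔG_b = −RT·ln K_a with se RT·se(K_a)/K_a,
TΔS_b = ΔH_b − ΔG_b, quadrature SEs.  Where prose and table disagree in
the source values at the 0.1 kJ level, the table value is used.

## Stability

Chemical denaturation is modelled as two-state with a linear denaturant
dependence, ΔG(D) = ΔG_u − m·D, unfolded fraction
f_U = 1/(1 + exp(ΔG/RT)), and sloped native/unfolded baselines (six
parameters total; baselines are standard practice even though the source
analysis does not describe its baselines).  T is fixed at 298 K.  C_m is
reported as ΔG_u/m with an SE from the (ΔG_u, m) covariance block.  The
observable is arbitrary: fitted ΔG_u and m are invariant under affine
transforms of the signal.  Thermal unfolding is irreversible for these
proteins, so no DSC model is included; apparent T_m values are carried as
metadata only (`presets.APPARENT_TM_C`).

## Flexibility

Rotamer names bin χ1–χ3 into p/t/m wells with half-open boundaries at
0/120/240° (modal values 60/180/300°) and χ4 into {85, 180, −85}; only
modal values are specified upstream, so symmetric ±60° bins are the
natural choice.  Statistics: per-frame labels, occupancy fractions
(summing to 1), transition counts, and dwell-length distributions.
Salt-bridge occupancy is the fraction of frames with donor–acceptor
distance below 4.0 Å (configurable).  Frames are assumed uniformly spaced
(1 ps default); inputs are pre-extracted scalar tables, so no periodic
imaging corrections apply.

Superposition uses the Kabsch SVD algorithm with determinant correction
(proper rotations only); collinear point sets are rejected.  RMSD series
are computed against a reference frame and flagged "stable" when all
values are below 1.5 Å.  RMSF uses a two-pass alignment to the running
mean structure, then the per-atom root of the time-averaged squared
deviation.  The single-oscillating-atom closed form (rmsf = amplitude)
holds only in the large-body limit, since mean-structure superposition
absorbs an O(1/N) share of any localized motion; the tests use a 100-atom
body accordingly.

## Synthetic data

Generators are pure functions of (parameters, seed), with presets keyed by
the five variant names carrying the published (k_cat, E_a), (K_a, ΔH_b)
and (ΔG_u, m) values.  Design choices mirroring the study conditions:

- assays: 8 substrate levels 0.05–2.0 mM, triplicate, K_m = 0.10 mM,
  E₀ = 1 nM; temperature grids 283–303 K (5 K steps) for mesophilic and
  283–318 K for thermophilic variants; multiplicative Gaussian rate noise
  at CV 3% by default (the ~7% k_cat SEs of the measured table correspond
  to the scatter after the MM fit);
- ITC: the default protocol above with additive Gaussian heat noise;
- denaturation: 0–7.5 M in 0.25 M steps with additive signal noise;
- trajectories: a hidden Markov chain over the four observed rotamers
  (mtm180 native; ptt180, ttp180, mtt180 excursions) with von Mises
  angular noise (κ = 50 ≈ 8° sd); the bridged preset dwells ~99% in the
  native well, the bridge-free preset transitions freely (~25%
  occupancy each).  Distance traces are Gaussian around 3.2 Å (bridged)
  or 6.0 Å (broken), with a +0.3 Å offset in non-native frames to
  correlate the two observables.

What the generators do *not* emulate: raw absorbance or power traces,
baseline drift, substrate depletion, correlated residuals, or real MD
force-field behaviour.  Passing recovery tests therefore demonstrates
estimator correctness and statistical calibration under the stated noise
models, not robustness to every artefact of real instruments or
simulations.  In particular the trajectory generator is a desk-scale
stand-in for MD: it reproduces the *ordering* of rotamer occupancies and
salt-bridge persistence between regimes, not any specific simulation's
numbers.

## Problem sizes and numerics

Stochastic test ensembles use 100–500 seeds (chosen so that Monte-Carlo
SEs are well below the tested tolerances) and trajectory lengths of
1e4–1e5 frames; the acceptance script uses 100 seeds and 5·10⁴ frames.
Nonlinear fits use Levenberg–Marquardt with analytic-free Jacobians and
documented initializations; the logistic in the LEM model is evaluated via
`expit` for stability; ties at rotamer bin boundaries go to the upper bin
by the half-open convention.  Degenerate inputs (nonpositive rates,
concentrations or temperatures, parallel Arrhenius lines, zero ΔΔS#,
collinear geometries) raise errors or report absent values rather than
NaNs.

## Known limitations

- Quantities assume transmission coefficient 1; absolute ΔG# values
  inherit that convention.
- The unweighted Arrhenius OLS treats all temperatures equally; strongly
  heteroscedastic series should use the weighted option.
- The ITC model covers 1:1 binding only; no sequential or multi-site
  schemes.
- The LEM fit is strictly two-state; intermediates bias ΔG_u upward
  undetectably if baselines absorb them.
- Rotamer classification is table-driven binning, not density-based
  clustering; angles near bin edges flip labels with noise.
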