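# Methods

This note documents the models implemented in `nerkinetics`, their
assumptions, the parameter choices that matter, and what the synthetic
data used by the test suite can and cannot establish.

## 1. Assembly theory (`nerkinetics.assembly`)

A locally damaged DNA site is a continuous-time Markov chain over the
occupancy configurations of `N` repair-protein components with common
pseudo-first-order association rate `k_on`, dissociation rate `k_off`, and
a catalytic rate `rho` that converts the fully assembled state to an
absorbing `repaired` state.

* Sequential mechanism: components bind in fixed order; states are the
  assembly depths `0..N` (a birth–death chain with birth rate `k_on` and
  death rate `k_off`).
* Random mechanism: states are the subsets of bound components (bit-set
  enumeration, capped at `N ≤ 16`). With common rates this chain is
  lumpable onto the number of bound components; the test suite uses the
  occupancy-count birth–death reduction as an independent oracle.

The mean repair time is computed exactly from the transient generator
`Q_T` via `-Q_T t = 1` (no closed-form coefficients are needed),
completion curves by matrix exponentials of `Q_T`, and stochastic repair
times by Gillespie simulation vectorised across walkers.

At the reference conditions (`N = 9`, random order, `k_on = k_off =
1 min⁻¹`, `rho = 600 min⁻¹`) the mean repair time is ≈ 68 min even though
every elementary rate is ≥ 1 min⁻¹: slow, hour-scale repair emerges from
fast, reversible binding. The reversible completion curve is
near-perfectly mono-exponential (fit rmse < 1% of plateau), whereas
irreversible assembly (`k_off = 0`) produces a sigmoid with zero initial
slope.

### Matching the irreversible on-rate

A sigmoid has no unique time constant, so "the irreversible scheme with
the same time constant" is ambiguous. Three criteria are implemented:

* `mean` (default) — equal mean repair times. The reversible curve is
  essentially exponential, so its mean *is* its time constant; this is the
  cleanest reading and gives `k_irr ≈ 0.041 min⁻¹` for the `N = 9`
  reference.
* `fitted_tau` — equal best-fit mono-exponential time constants on a
  common grid `[0, 8·mean]`; gives ≈ 0.045 min⁻¹ (the sigmoid's plateau
  approach biases the fitted tau upward for any grid).
* `max_slope` — the sigmoid's maximal slope equals `1/mean_ref`, the
  maximal (initial) slope of the matched exponential; gives ≈ 0.038 min⁻¹.

The mean-time criterion is the package default; the others are options.

## 2. The NER pathway model (`nerkinetics.model`)

Five DNA intermediates (damaged I, unwound II, incised III, resynthesized
IV, rechromatinized V) are interconverted by catalytic steps `alpha`
(unwinding, I→II), `beta` (dual incision, II→III), `gamma` (repair
synthesis, III→IV), `delta` (re-chromatinization, IV→V) and `epsilon`
(re-annealing, II→I). Seven factors (XPC, TFIIH, XPG, XPF, XPA, RPA,
PCNA) bind reversibly and independently (mean-field, no explicit
protein–protein cooperativity) to the intermediates allowed by the binding
mask; dissociation constants follow the published reference table.

Catalytic fluxes are proportional to the product of the occupancies
`theta[f,s] = B[f,s]/D_s` of the factors required for each step:
unwinding needs XPC and TFIIH on damaged DNA; incision needs TFIIH, XPG,
XPF, XPA and RPA on unwound DNA; synthesis needs RPA and PCNA on incised
DNA; re-annealing applies only to unwound DNA lacking TFIIH (weight
`1 − theta[TFIIH, II]`), reflecting maintenance of the open complex by the
helicase. On each state conversion, bound factors are carried along with
probability `theta[f, source]`; a factor not permitted on the target state
returns to the free pool. This is the simplest mass-conserving
bookkeeping consistent with the binding mask.

Volume bookkeeping: intermediates and bound factors are local
concentrations in the damaged region; free pools are nucleus-wide, coupled
through the damage volume fraction `phi = 0.1` (`free = total −
phi·Σ bound`). Integration uses stiff LSODA at `rtol 1e-8`, `atol 1e-10`;
`theta` is defined as 0 where `D_s` vanishes. Mass conservation holds to
`1e-6` relative and factor conservation exactly by construction. The
balance equations are compiled with numba when available (a pure-numpy
fallback gives bit-identical trajectories); fitting objectives integrate
at `rtol 1e-7` for speed, well below the optimiser's resolution.

Observables: factor accumulation `Σ_s B[f,s]`; cumulative repair synthesis
`edu(t) = ∫ J_gamma` (an auxiliary ODE state, so labeling windows are
exact integrals); incised fraction `D_III/lesions0`; and FLIP curves, in
which every bound molecule at the bleach start is labeled, dissociates
normally, is carried across state conversions, but cannot rebind. The
full DNA dynamics keep running during a FLIP measurement.

### Parameter defaults and calibration

Dissociation rates default to `k_off = 1 min⁻¹` for every permitted
factor–state pair (dwell times of order a minute), with `k_on = k_off /
K_D`. Catalytic rates default to `alpha = beta = gamma = 60 min⁻¹`
(order 1 s⁻¹), `epsilon = 1 min⁻¹`, and the one slow step `delta =
0.05 min⁻¹`. The initial local lesion concentration defaults to 0.5 µM.

The nucleus-wide factor concentrations are not part of the published
parameter table, and the per-pair binding-rate table they were fitted with
is not available; they are therefore calibration constants of this
package. They were chosen (by a Nelder–Mead scan over log-concentrations)
to reproduce the model's central predictions simultaneously:

* distributed rate control — all seven response coefficients of the
  30-min repair-synthesis rate uniformly small (maximum ≈ 0.28, no
  dominant factor);
* a propagated repair-rate CV of ≈ 0.34 for factor CVs 0.25 and a
  lesion-dose CV 0.32, with lesion response `R_L` just below 1;
* sub-saturated damage sites (accumulation approximately linear in
  expression level);
* near-exponential repair synthesis with completion within ~4 h and only
  transient (< 5% of lesions) accumulation of the incised intermediate.

The resulting reference concentrations (µM) are XPC 0.0152, TFIIH 2.93,
XPG 0.0554, XPF 0.339, XPA 0.0263, RPA 1.88, PCNA 0.0109, giving response
coefficients of 0.29 (XPC), 0.18 (TFIIH), 0.29 (XPG), 0.29 (XPF),
0.29 (XPA), 0.13 (RPA) and −0.02 (PCNA), a lesion response of 0.93, a
propagated rate CV of 0.33, and an effective repair-synthesis rate of
1.49 h⁻¹ with a mono-exponential residual of 3.8% of plateau.

**Known limitation.** Under the uniform `k_off = 1 min⁻¹` simplification
these properties pin the effective first-order rate of the reference set
at ≈ 1.5 h⁻¹, faster than the measured 0.58 h⁻¹ (half-time 1.2 h).
Slowing the reference set to 0.58 h⁻¹ by lowering concentrations
necessarily concentrates control in the least-saturated factors (maximum
response coefficient ≥ ~0.5): with a single shared dissociation rate, the
rate and the control distribution cannot be matched at once. The
published model resolved this with per-factor, per-state binding rates;
reproducing that requires the full rate table, which is unavailable. The
measured 0.58 h⁻¹ enters the package instead as the generative truth of
the first-order EdU analysis (`inference.fit_first_order` and the
synthetic EdU generator), which is independent of the mechanistic
calibration.

## 3. Inference (`nerkinetics.inference`)

The error model is independent Gaussian noise with the per-point SD from
the data table (unit weights where SDs are absent), matching
mean-±-SD reporting; the objective is the weighted half-sum of squares.
Fitting operates in log10 parameter space (positivity, scale freedom) with
L-BFGS-B inside ±4-decade box bounds, from latin-hypercube multi-starts
around the supplied centre (default spread ×/÷3, seed mandatory).

Profile likelihoods fix one parameter on a grid, re-optimise the rest
(warm-started outward from the MLE), and report the 95% CI where
`2·(nll − nll_min) ≤ 3.84` (pointwise, one degree of freedom), with
verdicts `identifiable` / `lower bound only` / `upper bound only` /
`unidentifiable`. Prediction profiles use the penalty formulation on the
predicted scalar. The test suite verifies Wald equivalence of the profile
CI on a locally quadratic problem.

## 4. Control analysis (`nerkinetics.control`)

Response coefficients are central finite differences of `ln(rate)` with
respect to `ln(concentration)` (relative step 1%, convergence checked by
step halving to < 1%). The rate `v` defaults to the instantaneous
repair-synthesis flux `J_gamma` at `t_eval = 30 min`, matching the 30-min
single-cell EdU readout; the incision flux `J_beta`, a time-averaged rate
and an effective exponential rate are exposed as options because the
choice is not uniquely determined by the source analysis. The lesion
response `R_L` is computed identically through the initial lesion
concentration. CV propagation is the first-order quadrature law
`CV_v² = Σ R_i² CV_i² + R_L² CV_L²`.

A caveat on finite perturbation scans: a flux readout at a fixed time is
non-monotone in concentration — beyond roughly two-fold increases the
30-min flux *falls* again, because faster repair has depleted the lesions
by the readout time. The effective rate constant
(`definition="exp_rate"`) increases monotonically and stays within ~10%
of its log-linear approximation over two-fold changes; the
perturbation-scan tests therefore probe monotonicity and linearity
through that readout, while response coefficients and the CV budget keep
the flux definition.

## 5. Population variability (`nerkinetics.population`)

Per-cell factor concentrations are lognormal with the reference means
preserved exactly (mean–CV parameterisation, default CV 0.25); the lesion
dose is lognormal (default CV 0.32) or resampled from an empirical dose
vector. Factors are drawn independently (no expression correlation).
Each cell is one deterministic ODE solve; default 300 cells per condition.
Correlations use Pearson r with percentile-bootstrap 95% CIs.

The error-ellipse estimator log-transforms both measurement channels and
decomposes their covariance into principal axes; the minor-axis variance
is attributed as measurement noise split equally between channels (the
single-channel attribution is an option), and converted to a relative
error via `sqrt(exp(sigma²) − 1)`.

## 6. Synthetic data (`nerkinetics.datasets`)

Generators emulate the statistical structure of the quantitative imaging
assays: bulk accumulation/EdU curves on 0–240 min (10-min steps) and FLIP
curves on 0–5 min (5-s steps) with Gaussian replicate noise (default
relative 5%, 150 replicates — within the 50–250 cells per point of the
assays); first-order EdU replicate curves; and paired two-channel tables
with lognormal signal (CV 0.3) and independent lognormal channel noise.
All generators are bit-reproducible under a fixed seed and round-trip
losslessly through the CSV reader/writer.

What the synthetic data do **not** emulate: image-level effects
(background, thresholding, bleed-through), S-phase contamination,
correlated factor expression, and CPD lesions. Passing round-trip tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to the full complexity of microscopy data.

## 7. Problem sizes used by the test suite

The suite favours exactness over size: MFPT oracles run at `N ≤ 9`;
Gillespie consistency uses 10⁴ walkers; the K_D-recovery fit uses 7
accumulation curves + EdU on a 20-min grid with two free parameters and
10 multi-starts; population checks use 500 cells (120 for the 9-run
variance decomposition); bootstrap/coverage checks use 20 replicates with
binomial slack.
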