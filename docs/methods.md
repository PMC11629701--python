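# Methods

This note documents the models, conventions and numerical choices behind
the package, and what its synthetic data can and cannot show about real
measurements.

## Food-web model

The model couples free viruses (V, ml⁻¹), heterotrophic bacteria
(B, ml⁻¹) and a phagotrophic protist grazer (G, ml⁻¹):

    dV/dt = S_v − φ_gv·G·V − φ_bv·B·V − δ_v·V
    dB/dt = μ_b·B + ε_bv·φ_bv·B·V − φ_gb·G·B − δ_b·B²
    dG/dt = ε_gb·φ_gb·G·B + ε_gv·φ_gv·G·V − δ_g·G²

Consumption is mass-action (encounter-rate) kinetics; bacterial and
grazer mortality use quadratic closures standing in for unresolved
predators. Viruses are supplied at a constant rate S_v, representing
in-situ production by hosts outside the modelled compartments. Transfer
efficiencies ε convert consumed prey into consumer biomass; they are
deliberately small for virovory (a virion is a small meal).

Default parameters (`FoodwebParameters.table1_defaults()`): S_v = 5e7
virus ml⁻¹ d⁻¹, φ_gv = 1e-3 and φ_gb = 1e-3 ml grazer⁻¹ d⁻¹,
φ_bv = 1e-6 ml bacteria⁻¹ d⁻¹, μ_b = 0.8 d⁻¹, δ_v = 0.1 d⁻¹,
δ_b = 1e-6 ml bacteria⁻¹ d⁻¹, δ_g = 0.1 ml grazer⁻¹ d⁻¹, ε_gb = 0.1,
ε_gv = 1e-6, ε_bv = 1e-3. These are illustrative values chosen to
reproduce the qualitative dynamics of size-fractionation incubations,
not fitted constants. δ_g carries the units of a quadratic closure
(ml grazer⁻¹ d⁻¹), which is what dimensional consistency of δ_g·G²
requires. The bacteria-by-grazer consumption coefficient is a single
parameter (`phi_gb`): only one such term appears in the equations.

Time is in days throughout. The default output grid (0, 0.5, 1, 2, 4,
8 d) mirrors the experimental sampling times of an 8-day bottle
incubation.

### Simulated filtration treatments

`simulate_treatment` reproduces a dark bottle experiment in four steps:
(1) spin the full model up to equilibrium, so that the simulated
dynamics reflect the model's internal feedbacks and not the arbitrary
starting point; (2) apply the filtration cut instantaneously — `lt100`
keeps all compartments, `lt1p2` zeroes G, `lt0p1` zeroes B and G (an
optional `retention` fraction models imperfect filtration, default 0);
(3) set S_v = 0, since a closed bottle receives no new virions; (4)
integrate forward. Removal at time t is 1 − V(t)/V(0⁺).

With Table-1-style defaults the 8-day removal obeys
removal(lt100) > removal(lt1p2) > removal(lt0p1) — filtration that
removes more consumers removes less virus — and the `lt0p1` treatment
collapses to the closed form 1 − e^(−δ_v·t), which the tests check to
1e-6 relative.

### Numerics

Integration uses `scipy.integrate.solve_ivp` with LSODA (adaptive,
stiff-capable), rtol = 1e-10 and atol = 1e-12 × (initial state scale).
States are clipped to zero only for transient negative excursions
smaller than 1e-12 of scale; anything larger aborts with an error
rather than silently propagating. A fixed-step RK4 oracle at dt = 1e-3 d
bounds the solver error below 1e-4 relative over 8 days in the tests.

Equilibrium spin-up integrates in 250-day chunks until
max_i |dy_i/dt| / max(y_i, 1) < 1e-9 (the max(·,1) guards near-empty
compartments), with a 5000-day cap; non-convergence raises an error
carrying the last state. The default spin-up state is (V, B, G) =
(1e6, 1e5, 1e2) ml⁻¹; the equilibrium requirement makes results
independent of this choice, which a test verifies from two decades
apart. The full-system equilibrium, checked against an independent
algebraic solve (steady-state substitution plus bracketing root-find),
is (V*, B*, G*) ≈ (5.249e7, 4.260e5, 4.265e2) ml⁻¹.

## Isotope bookkeeping

Carbon is measured as the diatomic ion ratio ¹³C¹²C⁻/¹²C₂⁻. Under
independent binomial assembly of two-carbon ions from a pool with ¹³C
atom fraction f, P(¹²C₂) = (1−f)² and P(¹³C¹²C) = 2f(1−f), so the dimer
ratio equals 2f/(1−f) — exactly twice the atomic ¹³C/¹²C ratio at every
enrichment — and f = R/(R+2). Nitrogen is measured on the CN⁻ ion,
which carries one nitrogen: f = R/(1+R).

Atom percent excess is APE = 100·(f_meas − f_nat). Negative APE
(measurement noise below natural abundance) is preserved in data files;
flooring at zero is a plotting choice only. X_net — the percent of a
cell's carbon or nitrogen derived from the labelled substrate — is
linear two-end-member mixing of atom fractions:
X_net = 100·(f_meas − f_nat)/(f_source − f_nat). Mixing in atom
fractions rather than isotope ratios is a deliberate choice; at these
enrichments the difference is negligible, and the atom-fraction form is
exactly consistent with the division anchors below.

Under exponential growth in which every new atom comes from the
substrate, d divisions give X_net = 100·(1 − 2^(−d)): 50% marks one
division, 75% two, and d = −log₂(1 − X_net/100) inverts it.

Defaults: natural abundances f¹³C = 0.0111 (VPDB convention) and
f¹⁵N = 0.003676 (atmospheric N₂); substrate enrichment 0.40/0.80
(¹³C/¹⁵N), the nominal labelling of the virus stock. All four are
per-experiment configuration (`IsotopeConstants`) because labelling
varies batch to batch; every derived record carries the constants used.

## Ion-image processing

Stacks are 4 masses × n_cycles × 256 × 256 rasters (masses ¹²C₂,
¹³C¹²C, ¹²C¹⁴N, ¹²C¹⁵N), default geometry 20 × 20 μm (78.125 nm
pixels), 1 ms dwell, 20–30 cycles.

* **Alignment** estimates each cycle's drift against cycle 0 by
  FFT cross-correlation of a reference mass (default ¹²C¹⁴N), searched
  within ±10 px, and applies the negated drift as a whole-pixel
  translation to all masses. Integer shifts only: sub-pixel
  interpolation would redistribute integer counts and bias low-count
  ratios. Pixels rolled in from outside the frame are invalidated;
  all-zero reference cycles keep shift (0, 0).
* **Dead-time correction** is the non-paralyzable form
  n_true = n/(1 − n·τ/dwell), per pixel per cycle; τ defaults to 44 ns
  but the correction is off by default (τ = 0) for synthetic data,
  whose generator draws ideal Poisson counts. Saturated pixels are
  invalidated, never extrapolated.
* **Segmentation** thresholds the cycle-summed CN channel (biomass
  carries nitrogen; the filter substrate does not) at background
  median + k·MAD (k = 5), takes 4-connected components, and keeps
  components with equivalent diameter in [0.3 μm, ∞). The `CN_total`
  channel (¹²C¹⁴N + ¹²C¹⁵N) exists because extremely ¹⁵N-enriched
  particles are dim in ¹²C¹⁴N alone and would otherwise be missed.
  Hotspot finding is the same pipeline restricted to 4–50 μm with
  k = 10, for protist-scale features in shallow large-area scans.
  The threshold rule, connectivity and minimum size are this package's
  documented defaults, not reconstructions of any proprietary tool.
* **ROI statistics** compute, per cycle, the ratio of count *sums* over
  the ROI (the standard low-count-unbiased estimator), then mean and
  SEM across cycles; cycles with a zero denominator are excluded and
  counted. Atom fractions, APE and X_net derive from the mean ratio.

## Synthetic data

The generators are pure functions of spec + seed (bit-reproducible) and
define the study conditions the tests run under.

* **Abundance series**: three filtration treatments in biological
  triplicate, sampled at 0, 0.5, 1, 2, 4, 8 d. The latent trajectory
  comes from `simulate_treatment`, with the virus compartment rescaled
  so V(0) equals the added spike (default 3e7 ml⁻¹, the nominal
  inoculum of the 8-day experiments; the long-incubation preset would
  be 2.5e7) — the added labelled virions dominate the countable pool at
  t = 0 while the model's relative removal dynamics are kept. Observed
  counts multiply the latent value by independent lognormal factors
  with CV = 0.1 (μ = 0, σ = √ln(1+CV²)). The CV is a free parameter:
  real flow-cytometry counting error is not published for these
  experiments, and 10% is a realistic bench value for replicate
  virus-like-particle counts.
* **Ion stacks**: per pixel/cycle/mass, expected counts are
  density × yield × isotopologue probability (binomial pairing for the
  carbon dimer, single-atom probabilities for CN), optionally blurred
  by a Gaussian of FWHM 150 nm (the primary beam diameter) before
  Poisson draws; a guard rejects λ > 1e6 per pixel-cycle. Exact planted
  masks and a truth table accompany each stack, so segmentation and
  ratio statistics can be scored against ground truth. In acceptance
  tests, isotope means are measured on masks eroded by 3 px to stay
  clear of beam-spread edge mixing.
* **Protist tables**: n_net drawn from a mixture (default 80%
  U(0, 10)% + 20% U(10, 85)%, emulating a weakly labelled majority and
  an intensely grazing subset), c_net = 0.9·n_net + N(0, 3²), clipped
  to [0, 100)%. The positive C–N correlation mimics direct incorporation
  of viral biomass rather than cross-feeding of remineralised N.

What the synthetic data does *not* emulate: aggregation of virions with
detritus, filament formation in long incubations, wall losses, detector
dead time (unless enabled), instrument mass fractionation, or any
community-composition dynamics. Passing tests therefore demonstrate
correctness of the computational machinery under controlled conditions,
not field realism.

## Removal statistics

Percent reduction is computed per replicate against that replicate's
own t = 0 count, then summarised as mean ± SD across replicates — the
only normalisation under which the replicate SD is well defined.
Replicates with zero starting counts are excluded and counted. Daily
removal rates assume linear removal (reduction/elapsed days); reporting
rounds rates to one decimal and rate increases to the nearest integer,
both half-away-from-zero, with unrounded rates always used as inputs to
downstream arithmetic.

`reproduce_printed_numbers` re-derives the worked rate arithmetic of
the three incubation experiments from printed inputs and flags what
does not reproduce: the long-incubation experiment's printed 1.7 and
3.3 % d⁻¹ are not exactly its printed reductions divided by 27 days
(42/27 → 1.6, 82/27 → 3.0); the table reports both and sets
match = false rather than forcing agreement (the printed rates
presumably come from unrounded internal means).

Welch's t-test is implemented from the textbook formula
(Welch–Satterthwaite df, two-sided p from the t survival function).
Note a known small-sample property: with n = 3 vs 3 the test is
conservative (empirical type-I error ≈ 0.035 at α = 0.05 under a
normal null), because the df estimate is itself random; this is a
property of Welch's approximation, not an implementation artifact, and
the test suite documents it. The Wilcoxon signed-rank test drops zero
differences, assigns mid-ranks to ties, and uses the exact null
distribution (dynamic programming over sign assignments, doubling
mid-ranks to an integer grid) for n ≤ 25, switching to a normal
approximation with continuity and tie corrections above; two-sided
p-values fold the symmetric null distribution around its mean.

## Problem sizes

Tests and the acceptance suite run planted-scene recovery at
256 × 256 × 25 cycles (three seeds, six particles each), the Welch null
calibration at 10 000 replicates, Wilcoxon enumeration exhaustively to
n = 10, and the seed-robustness check of the treatment ordering over
40 seeds — sizes chosen so the whole suite completes in well under a
minute while keeping Monte-Carlo standard errors small relative to the
tolerances tested.

## Known limitations

Single virus type, no temperature or light forcing, no explicit
microzooplankton; filtration is idealised as instantaneous and
complete; model parameters are illustrative rather than fitted; the
dimer-ion identity assumes independent binomial pairing of carbons;
amplicon-based community analysis is out of scope.
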