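# virovory

Quantitative machinery for studying **virovory** — the consumption of
virus particles by phagotrophic protists — and bacterial degradation of
virions in coastal marine microbial communities.

Free virions are the most abundant biological particles in the ocean,
and their carbon and nitrogen can be routed back into the microbial
loop when protists ingest them or bacteria degrade them. Experiments
that quantify this flux typically combine (i) dark bottle incubations
of size-fractionated seawater spiked with isotopically labelled
(¹³C/¹⁵N) virions, counted over time by flow cytometry, and (ii)
single-cell isotope imaging by nanoSIMS of the material collected on
filters. This package implements the full analysis chain for such
experiments:

* **`virovory.foodweb`** — a three-compartment virus (V) – bacteria
  (B) – grazer (G) ODE model with mass-action consumption and
  quadratic mortality closures:

  ```
  dV/dt = S_v − φ_gv·G·V − φ_bv·B·V − δ_v·V
  dB/dt = μ_b·B + ε_bv·φ_bv·B·V − φ_gb·G·B − δ_b·B²
  dG/dt = ε_gb·φ_gb·G·B + ε_gv·φ_gv·G·V − δ_g·G²
  ```

  with equilibrium spin-up and simulated filtration treatments
  (< 100 μm keeps everything, < 1.2 μm removes grazers, < 0.1 μm
  removes all cells; the virus supply S_v is cut at t = 0 inside a
  closed bottle).
* **`virovory.isotope`** — secondary-ion ratio → atom fraction
  conversions (the carbon dimer identity ¹³C¹²C⁻/¹²C₂⁻ = 2·¹³C/¹²C,
  the CN identity ¹²C¹⁵N⁻/¹²C¹⁴N⁻ = ¹⁵N/¹⁴N), atom percent excess,
  X_net two-end-member mixing, and implied cell divisions
  (X_net = 100·(1 − 2^(−d))).
* **`virovory.simsroi`** — nanoSIMS-style ion-image stack processing:
  cycle alignment, dead-time correction, automatic particle
  thresholding on the CN channel, 4–50 μm hotspot finding, and
  ratio-by-cycle mean ± SEM per region of interest.
* **`virovory.removalstats`** — percent reductions (per-replicate
  normalisation, mean ± SD), linear daily removal rates, rate-increase
  percentages, Welch's t-test and the exact Wilcoxon signed-rank test.
* **`virovory.synthetic_data`** — seeded generators for
  flow-cytometry-like abundance series (food-web dynamics + lognormal
  noise), Poisson ion-image stacks with planted particles and exact
  ground truth, and correlated single-cell (C_net, N_net) tables.
* **`virovory.pipeline`** / the `virovory` CLI — end-to-end synthetic
  studies and recomputation of the published worked arithmetic.

## Worked example

Simulate the three filtration treatments of an 8-day bottle experiment
and summarise virus removal:

```python
from virovory.foodweb import TreatmentSpec, removal_fraction, simulate_treatment
from virovory.removalstats import daily_removal_rate, rate_increase, round_half_away

rates = {}
for treatment in ("lt0p1", "lt1p2", "lt100"):
    traj = simulate_treatment(TreatmentSpec(filtration=treatment))
    removal = 100 * removal_fraction(traj)[-1]
    rates[treatment] = daily_removal_rate(removal, 8.0)
    print(f"{treatment}: 8-day removal {removal:.1f}%, "
          f"daily rate {round_half_away(rates[treatment], 1)} %/d")
print(f"biotic rate increase over abiotic: "
      f"{round_half_away(rate_increase(rates['lt100'], rates['lt0p1']))}%")
```

prints

```
lt0p1: 8-day removal 55.1%, daily rate 6.9 %/d
lt1p2: 8-day removal 99.9%, daily rate 12.5 %/d
lt100: 8-day removal 99.9%, daily rate 12.5 %/d
biotic rate increase over abiotic: 81.0%
```

The cell-free (`lt0p1`) bottle decays abiotically — 55.1% is exactly
1 − e^(−0.1·8), first-order decay at δ_v = 0.1 d⁻¹ — while consumers
in the coarser fractions drive removal far higher; removing more of
the community always removes less virus. (With default parameters the
grazer dominates consumption, so `lt1p2` and `lt100` differ only in
the fourth decimal here; the ordering lt100 ≥ lt1p2 ≥ lt0p1 holds at
every time point, which the tests check.)

The same arithmetic applied to the published 8-day reductions
(45%, 60%, 83%) gives daily rates 5.6, 7.5 and 10.4 % d⁻¹ and rate
increases of 33% (bacteria) and 84% (bacteria + protists) —
see `virovory paper-numbers`, which prints every printed/recomputed
pair with a match flag (and deliberately flags the long-incubation
rates, which do not reproduce from their printed inputs).

Everything is also reachable from the shell, e.g.:

```sh
virovory foodweb simulate --treatment lt0p1 --duration 8 --out traj.csv
virovory --seed 5 synth abundances --out counts.csv
virovory removal --counts counts.csv --at 8 --out summary.csv
virovory --seed 2 study --out run/
```

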