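# Methods

## Measurement model

A tooth is powdered, incinerated, and its Sr chemically separated from Ca
(fuming nitric acid route) and from the ⁹⁰Y daughter; the chemistry is
represented here only by its gravimetric chemical yield, a scalar in
(0, 1]. The SrCO₃ precipitate is counted repeatedly on a low-background
gas-flow counter while ⁹⁰Y grows back toward secular equilibrium. The
expected gross rate in cpm at time t hours after separation is

    r(t) = b + 60 ε f(x) A e^(−λ_Sr t) (1 + g(t)),   g(t) = 1 − e^(−λ_Y t)

- **b** — background rate, default 0.155 cpm (measured over 12 h runs; its
  Poisson σ is 0.0147 cpm, so the 3σ decision level is 0.044 cpm).
- **ε** — counting efficiency, default 0.339, defined against an 88.4 Bq
  standard of 24 mg cm⁻² areal thickness. Because that calibration already
  embeds the standard's own self-absorption, the self-absorption factor
  f(x) = e^(−μ(x − 24)) is normalized to 1 at 24 mg cm⁻² and corrects only
  thickness deviations; μ (cm² mg⁻¹) is fitted by log-linear least squares
  from thickness/relative-response calibration pairs.
- **λ_Sr, λ_Y** — decay constants from T½(⁹⁰Sr) = 28.8 y and T½(⁹⁰Y) =
  64.05 h. The ⁹⁰Y half-life is standard nuclear data (the study constants
  do not fix it) and is configurable. The parent-decay factor over a
  fortnight is ~0.1 % and is kept for exactness.
- The bracket (1 + g) counts parent and in-grown daughter; at equilibrium it
  is the equilibrium count multiplier, default 2 (both β's counted with
  equal efficiency; configurable since true efficiencies differ with β
  energy).

**Fit.** The model is linear in A, so the estimate is closed-form weighted
least squares with Poisson weights var(rate) = rate/duration, iteratively
reweighted on the fitted expectation (3 passes; the noiseless fit is exact
to machine precision). Goodness of fit is the χ² of rate residuals with
n−1 degrees of freedom; p < 0.05 flags departure from the ingrowth curve
(e.g. a β contaminant that survived the chemistry) — flagged, never
dropped. Negative fitted activities are clamped to 0 and flagged below
detection rather than reported negative. A single-point equilibrium
estimator (net rate / (60 m ε f y)) is provided for the post-equilibrium
total count.

**Decay correction.** Activities are corrected from the separation date
back to the accident reference date (2011-03-11) by A_ref = A e^{+λ_Sr Δt},
with Δt in 365.25-day years from calendar dates; forward projection
(measurement before reference) is refused.

**Detection limit.** Rate limit 3σ_b(T); activity limit through the
multiplier, efficiency and yield; normalized per gram of Ca. With the
default constants (0.044 cpm, ε = 0.339, yield 0.70, multiplier 2, 1 g ash)
the per-sample limit is 1.55 mBq; per gram of Ca it spans 3.9–5.2 mBq over
the physically plausible ash Ca fraction range 0.30–0.40. The ash Ca mass
fraction is taken from the per-sample ICP value when available, else a
hydroxyapatite-ash default of 0.37 with a warning.

## Composition

Stable Sr by standard addition (OLS line through intensity vs added
concentration; native solution concentration = intercept/slope), Ca by
inverse prediction from an external standard line, both converted to
per-g-ash units through the dissolution geometry (default: 1 g ash in
10 mL, 10,000-fold dilution; the aliquot volume is not independently known,
so the full dissolution volume is the basis). Each assay is run in
triplicate and summarized as mean ± sample SD. The two normalized metrics
satisfy the identity

    specific activity [Bq/g Sr] = activity conc [mBq/g Ca] · f_Ca · 10⁶ / (1000 · c_Sr)

which is asserted as a property test. Fallen-out teeth and failed
separations are distinct NA categories carried in a `status` column and
excluded from statistics, never imputed.

## Chronology

Mineralization windows in months relative to birth. Only the P1 window
(12–24 months) is authoritative; DM1–3 (−8→1), M1 (−1→12), M2 (6→18),
M3 (12→30), P2 (14–26) and P3 (15–27) are placeholder defaults consistent
with radiographic staging of an 8-month-old animal (DM complete, M active,
P early or not started) and are configurable. Mineralization rate is
uniform within a window; a weight-function hook exists because real crown
deposition is nonuniform. Under a step exposure the predicted specific
activity is linear in the post-step window fraction φ, so the pre/post
levels (times the transfer factor) are recovered by least squares; the
inversion needs at least two distinct φ and raises on an adult-only
dentition (all φ = 0). Post-accident environmental decline (washout,
weathering) is deliberately not modeled — the exposure is one post-accident
regime.

Uptake into already-formed teeth (surface adsorption, dental calculus,
secondary-dentine ion exchange) is an additive baseline term, default 0 in
the prediction function.

## Statistics

Kruskal-Wallis with midranks and the standard tie correction
1 − Σ(t³−t)/(N³−N); p from the χ² upper tail with k−1 df (the statistic's
only tail, matching the study's one-tailed convention), or from full
permutation enumeration (`method="exact"`) for small N. Singleton groups
are allowed, as the adult table structure requires. Spearman ρ is the
Pearson correlation of midranks; the two-sided t-approximation p is the
default and the one-tailed value is reported alongside. p-values are
formatted to 4 decimals in stage outputs. No post-hoc pairwise comparisons
or multiplicity corrections are performed.

## Synthetic studies

The generator's defaults are the study conditions: three areas with soil
⁹⁰Sr means 738/195/96 Bq m⁻²; the eight published animals (ids, areas,
birth dates, ages at accident and sampling); counter efficiency 0.339,
background 0.155 cpm; chemical yield uniform on [0.50, 0.96] (the reported
range; the reported mean is 70 %); 5–6 counts of 3–12 h within a fortnight
of separation; precipitate thickness N(24, 3²) mg cm⁻² clipped to 15–35;
ICP intensities linear in concentration with 1 % multiplicative noise,
in triplicate; 5 % of separations fail at random.

Choices where the study conditions leave the value open, fixed a priori
from the published summary ranges and not revisited:

- **Environmental levels.** Post-accident bioavailable levels of 900 (H)
  and 280 (L) Bq (g Sr)⁻¹ over a uniform 29 Bq (g Sr)⁻¹ pre-accident
  baseline (legacy weapons-test fallout; the control area stays at
  baseline). These reproduce the reported per-area specific-activity ranges
  and put the control mean activity concentration near the reported
  14 mBq (g Ca)⁻¹.
- **Adsorption baseline.** The default scenario adds post-hoc uptake of
  0.25 × post-level × (1−φ) in contaminated areas, because the study's own
  data show pre-formed teeth (deciduous molars, adult dentition) in
  contaminated areas sitting well above control level; without it the
  simulated H/L deciduous molars would contradict the reported ranges.
  Control area: 0.
- **Biological noise** is lognormal with CV 30 % (keeps activities positive;
  consistent with the reported within-area spread of 6–831 mBq (g Ca)⁻¹).
- **Stable Sr** is lognormal (CV 15 %) around 140 µg g⁻¹ in the
  contaminated areas and 180 µg g⁻¹ in the control area, with a
  post-accident dietary uplift of 45 % × φ in contaminated areas — the
  published stable-Sr table shows exactly this pre/post contrast and those
  levels. Ash Ca fraction N(0.37, 0.015²).
- **Windows are truncated at the sampling age** (a tooth cannot record
  exposure after the animal was sampled); teeth whose window has not begun
  are omitted, and deciduous molars of animals sampled at ≥ 30 months are
  marked fallen out, mirroring the adult rows of the published table.
- The transfer factor is a single free scalar (default 1): absolute intake
  is not calibrated, only relative structure.

What the simulator does **not** emulate: feed-intake and gut-absorption
biokinetics, soil-to-plant transfer, nonuniform crown deposition,
within-tooth enamel/dentine differences, Ra/Pb interferents (assumed
chemically removed), and post-accident environmental decline. Passing
tests therefore demonstrate that the reduction and inference chain is
correct and well calibrated under the stated generative assumptions — not
that those assumptions capture every feature of real herds.

## Problem sizes and numerical choices

The default study is 8 animals × up to 9 teeth (≈ 60–65 usable samples);
an end-to-end run takes well under a second. Monte-Carlo checks use 1000
count-series replicates (fit unbiasedness), 2000 null replicates at group
sizes 16/24/21 (type-I error 0.05 ± 0.02), 500 blank series (false-positive
rate under the 3σ limit ≤ 1 %), 200 noisy dentitions (step recovery, median
relative error < 15 %), and 100 study replicates (area ordering H > L > C
in ≥ 95 %). Seeds are explicit everywhere; identical scenario + seed gives
byte-identical output files.

Degenerate inputs: all-tied data return H = 0, p = 1; zero-variance vectors
are rejected for rank correlation; empty count tables produce an empty
reduction with a warning; per-row failures (bad yield, missing series) are
recorded in an `error` column and never abort a run.

## Known limitations

- The non-P1 mineralization windows are approximations; conclusions that
  depend on their exact endpoints (e.g. the absolute recovered pre-level,
  which is also confounded with the adsorption baseline) should be treated
  as qualitative. The recovered post-level is robust.
- The χ² approximation to Kruskal-Wallis is rough below N ≈ 10; the exact
  mode exists for that regime.
- Efficiency uncertainty (±0.001) is not propagated into reported activity
  uncertainties by default; the standard error reflects counting statistics
  only.
- The equilibrium count multiplier 2 assumes equal β counting efficiency
  for ⁹⁰Sr and ⁹⁰Y; the true value depends on β energy spectra and the
  counter, and the per-g-Ca detection limit scales inversely with it.
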