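# toothsr

Radiochemical analysis of ⁹⁰Sr in teeth as a recorder of environmental
contamination, built around the cattle abandoned in the Fukushima-Daiichi
evacuation zone.

Because tooth enamel and dentine are metabolically inert once mineralized,
the strontium a tooth contains was fixed during its mineralization window.
Cattle dentition mineralizes on a staggered schedule — deciduous molars
prenatally, molars around birth to ~2 years, premolars last — so a single
animal's teeth sample the environmental ⁹⁰Sr level at a sequence of past
times. `toothsr` implements the full measurement and inference chain for
this kind of study:

- **radiometrics** — reduction of low-background gas-flow-counter β-count
  time series to ⁹⁰Sr activities. After chemical separation of Sr from its
  daughter ⁹⁰Y (T½ = 64.05 h), the gross rate follows the ingrowth curve

  r(t) = b + 60 · ε · f(x) · A · e^(−λ_Sr t) · (1 + (1 − e^(−λ_Y t)))  [cpm]

  with background b, counting efficiency ε, self-absorption factor
  f(x) = e^(−μ(x − x_ref)) for precipitate thickness x, and ⁹⁰Sr activity A.
  A is fitted by Poisson-weighted least squares with a χ² goodness-of-fit
  check (a flat series flags a surviving contaminant), corrected for
  chemical yield, and decay-corrected to the accident date
  (A_ref = A e^{+λ_Sr Δt}, T½(⁹⁰Sr) = 28.8 y). 3σ Poisson detection limits
  are propagated through efficiency, yield and Ca normalization.
- **composition** — stable Sr by ICP standard addition and Ca by external
  calibration curve (triplicates, mean ± SD), then normalization of each
  activity to an *activity concentration* in mBq (g Ca)⁻¹ and a *specific
  activity* in Bq (g Sr)⁻¹.
- **chronology** — mineralization windows per tooth class; the predicted
  specific activity under a step change in environmental ⁹⁰Sr at the
  accident date is transfer · (L_pre (1−φ) + L_post φ), where φ is the
  fraction of the window after the step. The inversion (recovering the
  pre/post levels from an observed dentition) is linear least squares in φ.
- **stats** — tie-corrected Kruskal-Wallis H (χ² upper tail, plus an exact
  full-enumeration mode for small N) and Spearman rank correlation with
  midranks, over teeth grouped by class (DM/M/P) or residence area.
- **synthetic** — a herd/laboratory simulator generating complete studies
  (soil gradient across three areas, an eight-animal herd, per-tooth true
  activities, Poisson-noised count series, ICP intensities) so the whole
  chain is testable without external data.
- **pipeline / CLI** — `toothsr simulate | reduce | normalize | chronology
  | stats | report` over plain CSV schemas, with run manifests.

## Worked example

```python
import toothsr as t

study = t.run_study(t.default_scenario(), seed=1)
report = study["report"]
print(report["per_area"]["activity_conc"].round(1))
rho = report["spearman_soil_activity_conc"]
print(f"Spearman rho (soil vs activity conc): {rho.statistic:.4f}, p = {rho.p:.2g}")
```

prints

```
       mean    std  count
area
C      15.4    7.5     17
H     286.1  184.5     18
L      81.2   52.9     28
Spearman rho (soil vs activity conc): 0.8486, p = 1.6e-18
```

Reading this: the default scenario simulates the study's three areas (soil
⁹⁰Sr means 738, 195 and 96 Bq m⁻² for H, L and C), runs every simulated
precipitate's count series through the ingrowth fit and every ICP assay
through its calibration fit, and normalizes per gram of calcium. The
per-area means reproduce the strong contamination gradient (high area ≫ low
area ≫ control, control teeth near 14 mBq (g Ca)⁻¹), and per-tooth activity
concentrations correlate strongly with the soil levels the animals lived
on. Within young animals the developmental gradient DM < M < P emerges
because premolars mineralized almost entirely after the accident.

The same chain is available stage by stage from the shell:

```
toothsr simulate --seed 5 --outdir run/
toothsr normalize --assays run/assays.csv --samples run/samples.csv --outdir run/
toothsr reduce --counts run/counts.csv --samples run/samples.csv \
    --composition run/composition.csv --outdir run/
toothsr normalize --assays run/assays.csv --samples run/samples.csv \
    --reduced run/reduced.csv --outdir run/
toothsr stats --teeth run/normalized.csv --factor area --response activity_conc
```

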