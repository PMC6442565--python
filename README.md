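# grazemulti

Quantitative analysis of livestock-diversification grazing experiments:
does grazing a grassland with *two* livestock species (sheep and cattle
together) rather than one change the biodiversity of the whole community —
plants, insects, soil microbes, nematodes — and with it the ecosystem's
ability to deliver many functions at once?

The package implements, as a tested library plus a set of analysis drivers,
the complete statistical pipeline for a randomized-complete-block grazing
experiment (6 blocks × 4 treatments: no grazing NG, sheep SG, cattle CG,
mixed MG): composite biodiversity and multifunctionality indices, blocked
treatment tests, diversity–function regressions, random-forest predictor
screening and path-model effect decomposition. It is written for community
ecologists who have plot-level tables (functions, richness counts, design)
and want every reported number to be reproducible from a config and a seed.

## The indices and models

**Min-max standardization.** Every raw ecosystem function and richness
count is rescaled over the experiment: EF = (rawEF − min) / (max − min),
so each variable spans [0, 1].

**Ecosystem multifunctionality (EMF)** is the per-plot mean of the 12
standardized functions; **multidiversity** is the same construction over
the 6 organism groups (plants, herbivorous and predatory insects, soil
bacteria, fungi, nematodes), with above-/below-ground aggregates over the
respective triplets. A **weighted EMF** down-weights redundant functions:
average-linkage clustering on the distance 1 − |ρ| (Spearman, cut at 0.5)
gives k clusters, and each function gets weight 1/(k·m) for cluster size m.
The **multithreshold** profile counts, per plot, the functions whose
standardized value reaches t ∈ {25, 50, 75, 90}%.

**Treatment tests** use the additive RCBD ANOVA y = μ + block + treatment + ε
(F with (t−1, (t−1)(b−1)) df — identical to the random-block model in a
balanced design) with Tukey studentized-range post hoc comparisons at
P < 0.1 and compact letter displays.

**Path analysis** fits recursive observed-variable models (livestock
diversification → diversity → EMF, plus a direct path) by per-equation
least squares — exact ML for recursive models with uncorrelated
disturbances. Fit is the Wishart discrepancy χ² = (n−1)·F_ML with
df = p(p+1)/2 − free parameters, RMSEA with its close-fit test, and a
Bollen–Stine bootstrap (data rotated by S^(−1/2)Σ̂^(1/2) so the fitted model
holds exactly, then resampled). Standardized total effects are
(I − B)⁻¹ − I, the sum over all directed paths of coefficient products.

A **synthetic-data generator** emulates the full design with an explicit
causal chain (standardized coefficients a, b, c′), correlated function
clusters, block effects and integer richness counts, so every stage is
exercisable — and calibratable against known truth — without any field data.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
experiment and write their tables under `results/`:

```sh
python analysis/01_simulate.py        # 24 plots, 6 blocks x 4 treatments
python analysis/02_indices.py
python analysis/03_treatment_effects.py
python analysis/04_diversity_function.py
```

which prints, for the shipped seed:

```
multidiversity   F(3,15) =  0.45, p = 0.7217 | NG=0.491a, SG=0.491a, CG=0.496a, MG=0.607a
above_diversity  F(3,15) =  1.75, p = 0.1991 | NG=0.371a, SG=0.390a, CG=0.390a, MG=0.632a
...
multidiversity ~ EMF: R = 0.404, p = 0.0501, n = 24
  threshold 0.25: slope =  7.15, R = 0.376, p = 0.0702
  threshold 0.50: slope =  9.05, R = 0.361, p = 0.0832
```

Reading this: mixed grazing (MG) has the highest mean multidiversity and
above-ground diversity, but in this particular draw the blocked F-test does
not reach P < 0.1 (the design is deliberately moderate-powered, so both
significant and null outcomes occur across seeds); treatments sharing the
letter "a" are not separated by Tukey's test. The
diversity–multifunctionality regression is positive (R = 0.404 across 24
plots), and the positive slope persists across the 25–90% multithreshold
counts, weakening at the strictest threshold — the signature pattern of a
diversity–function relationship that is not an averaging artifact.
`05_rf_screen.py` and `06_path_models.py` continue with the random-forest
predictor screen and the path-model effect decomposition.

The same pipeline runs from a single config via the CLI:

```sh
grazemulti run-all --seed 9 --out results/run9    # writes manifest.yaml
grazemulti simulate --seed 5 --out sim/
grazemulti anova indices.csv design.csv --response EMF_avg --out anova.csv
```

Rerunning `run-all` with the same config reproduces every output
byte-for-byte (the manifest records seeds, config hash and SHA-256 digests).

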