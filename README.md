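# frailtycompare

Head-to-head comparison of two ways of measuring frailty in older adults —
the **deficit-accumulation frailty index (FI)** and the **phenotypic
frailty (PF)** construct — as predictors of falls, fractures and death in a
questionnaire-based cohort.

## The scientific problem

Frailty can be quantified in two quite different ways:

* the **frailty index** counts accumulated health deficits. Each of 34
  items (symptoms and signs, comorbidities, activities of daily living,
  healthcare utilisation) is coded into [0, 1] by severity or frequency,
  and the FI is the sum divided by 34. A participant with 5 deficits coded
  1, 25 coded 0 and 4 coded 0.25 has FI = 6/34 = 0.18.
* the **phenotypic frailty** model scores five physical criteria —
  slowness and weakness (SF-36 physical-functioning scale, double-weighted),
  poor endurance/exhaustion (SF-36 vitality scale), low physical activity
  (days with a ≥ 20-minute walk in the past month) and unintentional weight
  loss (≥ 10 lb in a year) — awarding points to participants in the lowest
  quartile of each continuous criterion. The 0–5 total classifies
  robust (0), pre-frail (1–2) and frail (3–5).

The two instruments live on different scales, so comparing their predictive
accuracy requires putting them on a common footing. The package implements
three stratification strategies:

1. **per-one-fifth increments** — the FI is binned at multiples of one
   fifth of its observed range (e.g. range 0–0.72 → increment 0.144,
   reported 0.14, cutpoints 0.14/0.28/0.42/0.56), so both measures become
   six ordered levels;
2. **density-overlap trichotomisation** — kernel densities of the FI within
   the three PF categories are intersected to give FI-based
   robust/pre-frail/frail cutpoints;
3. **predicted-fall-probability grouping** — a multivariable logistic model
   of falls on the FI assigns low/medium/high risk at predicted
   probabilities 0.27 and 0.50.

For each strategy the package fits logistic models (falls in follow-up
year 3, death) and Cox proportional-hazards models (time to incident
fracture, Efron ties) for both instruments, with outcome-specific
adjustment sets, and compares:

* effect sizes — OR/HR per instrument increment, Wald 95% CIs;
* discrimination — AUC with DeLong variance and the paired DeLong z-test
  for correlated AUCs; Harrell's c-index with a paired bootstrap contrast
  for the survival outcome;
* calibration / fit — Hosmer–Lemeshow chi-square, partial-likelihood AIC,
  Grambsch–Therneau proportional-hazards checks from Schoenfeld residuals;
* agreement — tie-corrected Spearman correlation between the two
  instruments' group assignments.

Because no participant-level cohort is distributable, the package ships a
seeded synthetic-cohort generator: a single latent frailty trait (standard
normal plus an age slope, two age strata with two thirds aged ≥ 65) drives
the 34 deficits, the four PF components and the outcome risks, with
intercepts calibrated by bisection to marginal rates of 0.32 (falls), 0.064
(fractures) and 0.027 (death). See `docs/methods.md` for the full model.

## Worked example

The public surface follows the model/results pattern: build a
`FrailtyComparison`, call `fit()`, read the report off the results object.

```python
from frailtycompare import FrailtyComparison, RunConfig, GeneratorConfig

model = FrailtyComparison.simulate(
    GeneratorConfig(n=2000, seed=42),
    config=RunConfig(seed=42, n_boot=200),
)
results = model.fit()
print(results.summary())
```

Output (abridged; the full report also tabulates group frequencies,
all effect estimates and the calibration statistics):

```text
Frailty instrument comparison
============================================================
participants: 2000   subgroup: all
FI increment (1/5 of range): 0.1853 (reported 0.19); strategy-1 cutpoints: 0.19, 0.38, 0.57, 0.76
strategy-2 density-overlap cutpoints: 0.190, 0.306

PF-FI agreement (Spearman)
          spearman_rho  ci_lo  ci_hi     p
strategy
1                0.662  0.636  0.686 0.000
2                0.659  0.633  0.683 0.000
3                0.536  0.504  0.567 0.000

Effect estimates (per increment / vs reference group)
 strategy  outcome instrument    adjustment         term scale  estimate       95% CI
        1 falls_y3         PF      age_only     pf_score    OR      1.29  (1.21-1.38)
        1 falls_y3         PF multivariable     pf_score    OR      1.16  (1.07-1.24)
        1 falls_y3         FI      age_only           fi    OR      1.90  (1.65-2.19)
        1 falls_y3         FI multivariable           fi    OR      1.50  (1.28-1.76)
        ...

Discrimination (AUC for falls/death, c-index for fractures)
 strategy  outcome    adjustment  metric  stat_pf  pf_ci_lo  pf_ci_hi  stat_fi  fi_ci_lo  fi_ci_hi  p_contrast
        1 falls_y3      age_only     AUC    0.634     0.607     0.661    0.653     0.628     0.679       0.016
        1 falls_y3 multivariable     AUC    0.687     0.662     0.713    0.693     0.668     0.719       0.106
        1 fracture multivariable c-index    0.664     0.618     0.705    0.666     0.619     0.706       0.695
        1    death multivariable     AUC    0.754     0.681     0.826    0.780     0.717     0.844       0.086
        ...
```

Scoring the worked FI example directly:

```python
from frailtycompare import compute_fi
fi = compute_fi([1.0] * 5 + [0.0] * 25 + [0.25] * 4)
print(round(fi.fi, 2))   # 0.18
```

### Command line

```bash
frailtycompare simulate --n 4000 --seed 0 --out out/sim     # cohort.csv + truth.json
frailtycompare score out/sim/cohort.csv --out out/scored    # PF points, FI, quartile cuts
frailtycompare stratify out/scored/scored_cohort.csv --out out/strata
frailtycompare run --n 4000 --seed 0 --out out/run          # full pipeline + report
frailtycompare run --input my_cohort.csv --subgroup ">=65" --out out/old
```

`run` writes `scored_cohort.csv`, `strategy_assignments.csv`,
`pf_quartile_cuts.json`, `report.json` and `report.txt` under `--out`.

## Layout

| Module | Contents |
| --- | --- |
| `frailtycompare.deficits` | 34-item deficit codebook, FI computation |
| `frailtycompare.phenotype` | SF-36/vitality scoring, quartile cuts, PF categories |
| `frailtycompare.cohort` | schema validation, CSV I/O, missing-data policy |
| `frailtycompare.strata` | the three common-footing strategies |
| `frailtycompare.models` | logistic/Cox fits, effects per increment, PH checks |
| `frailtycompare.discrimination` | AUC/DeLong, Harrell's c, Hosmer–Lemeshow, Spearman (from scratch) |
| `frailtycompare.simulate` | seeded latent-trait cohort generator |
| `frailtycompare.pipeline` / `cli` | `FrailtyComparison` model/results objects, `frailtycompare` CLI |
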