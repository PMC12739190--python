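# ddrs — the Dental Diet Risk Score

`ddrs` implements a composite dietary risk score for oral health and the
in-silico study used to evaluate it. Established dietary-quality indices —
the Mediterranean Diet Adherence Screener (MEDAS, 0–14), the Dietary
Phytochemical Index (DPI, 0–100) and the Healthy Eating Index (HEI, 0–100) —
were not designed to capture dental risk. The Dental Diet Risk Score (DDRS)
combines the four dietary pathways most relevant to caries and erosion into
a single 0–100 score:

```
DDRS = 0.40·S + 0.20·A + 0.25·(100 − K) + 0.15·(100 − Q)
```

where S is free-sugar exposure, A acidic-beverage exposure, K
protective-food intake and Q overall diet quality (all 0–100). Higher DDRS
means higher theoretical dental risk; the weights reflect the relative
epidemiologic contribution of each pathway, with sugar dominant.

Because no individual-level dataset pairs these exposures with the three
indices, the package evaluates the score on simulated cohorts: 10,000
dietary profiles drawn from beta distributions (shape parameters α ∈ [2, 5],
β ∈ [3, 6], approximating the skewness of NHANES-style intake data), with a
latent diet-quality factor inducing realistic correlation between components
and indices. The pipeline computes Pearson correlations (Fisher-z CIs)
between DDRS and each index, a covariance-based variance decomposition of
the score, healthy / unhealthy / mixed scenario contrasts (Welch t,
Cohen's d), one-at-a-time ±20 % weight-sensitivity (tornado) analysis, and a
Monte Carlo convergence trace. It is aimed at nutrition-epidemiology and
dental-public-health researchers prototyping diet-based risk screening.

## Worked example

```python
from ddrs import DDRSModel

model = DDRSModel.from_simulation(n_profiles=10_000, seed=42)  # frozen calibrated generator
results = model.fit()
print(results.summary())
```

```
Dental Diet Risk Score — study summary
======================================================
profiles: 10000    weights: S=0.40 A=0.20 K=0.25 Q=0.15
DDRS mean 49.2  sd 14.9  median 49.3

Correlations with dietary indices (Pearson, Fisher-z 95% CI)
------------------------------------------------------
  MEDAS  r = -0.62  [-0.63, -0.61]  p <0.001
  DPI    r = -0.68  [-0.69, -0.67]  p <0.001
  HEI    r = -0.55  [-0.57, -0.54]  p <0.001

Variance decomposition of DDRS (covariance shares)
------------------------------------------------------
  sugar               42.2 %
  acidic beverages    18.0 %
  protective foods    27.7 %
  overall quality     12.1 %

Scenario groups (healthy >= 70, unhealthy <= 30)
------------------------------------------------------
  healthy    n=190    median DDRS  25.0  IQR (20.7, 30.2)
  unhealthy  n=351    median DDRS  71.4  IQR (65.8, 76.1)
  mixed      n=9459   median DDRS  48.9  IQR (38.2, 59.7)
  healthy vs unhealthy: t = -68.5, p <0.001, Cohen's d = -6.10

Weight sensitivity (one-at-a-time ±20%)
------------------------------------------------------
  S: mean DDRS 45.5 → 53.0  (range 7.5)
  K: mean DDRS 46.6 → 51.9  (range 5.3)
  A: mean DDRS 47.4 → 51.1  (range 3.7)
  Q: mean DDRS 47.6 → 50.9  (range 3.3)
  sugar weight 0.30 → 0.50: +20.9 % change in mean DDRS
```

Reading the output: all three indices correlate inversely with DDRS —
healthier diets score lower dental risk — with DPI strongest (phytochemical
intake aligns most closely with the score's protective component). Sugar
explains ~42 % of score variance and tops the tornado; shifting its weight
from 0.30 to 0.50 raises mean DDRS by ~21 %. The threshold-classified
groups in this pooled cohort are sparse at the extremes; the dedicated
scenario presets (below) reproduce the full healthy / unhealthy / mixed
contrast with medians ≈ 28 / 76 / 49.

Scenario-preset cohorts and the full artifact-writing pipeline:

```python
from ddrs import generate_scenario_cohort, score_cohort
ddrs_healthy = score_cohort(generate_scenario_cohort("healthy", 2000, seed=42))
print(round(ddrs_healthy.median(), 1))   # 27.8
```

The same is available from the shell:

```bash
ddrs simulate --n 10000 --seed 42 --out cohort.csv
ddrs score cohort.csv --out scored.csv
ddrs analyze cohort.csv
ddrs run-all --seed 42 --out study_out/   # all CSV/JSON artifacts + manifest
ddrs converge --seed 42                   # stabilization of r / shares vs n
```

`examples/study_config.yaml` is a committed `RunConfig` reproducing the
full study (`ddrs run-all --config examples/study_config.yaml`).

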