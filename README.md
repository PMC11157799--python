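# syndromic

Syndromic (symptom-based) case definitions are a front-line tool for
detecting lower respiratory tract infection (LRTI), but older adults often
present atypically — with confusion, falls and general deterioration
instead of cough, fever and pleurisy — so symptom-based screening can miss
exactly the patients at highest risk. This package implements, as a tested
and reusable pipeline, the statistical analysis of age-dependent syndromic
LRTI case ascertainment in hospitalised adults: who meets a symptom-based
case definition, how that probability varies with age after adjustment,
and how symptom profiles themselves change across the age span. It is
aimed at epidemiologists and biostatisticians working on surveillance case
definitions.

Because the motivating hospital cohort's patient-level data are
confidential, the package ships a calibrated synthetic cohort generator
whose expected margins reproduce the published summary tables, so every
analysis stage is runnable and testable end to end.

## What it computes

* **Case definition** — a patient meets the syndromic LRTI definition iff
  *cough AND fever*, or at least 3 of the 9 symptoms {cough, fever,
  breathlessness, wheeze, pleurisy, abnormal sputum, myalgia, headache,
  general deterioration}. Fever is composed as reported fever/chills or
  temperature > 38.0 °C or < 35.0 °C. Confusion and falls are recorded but
  never count toward the definition.
* **Clinical scores** — CRB severity score (one point each for AMTS ≤ 7,
  respiratory rate ≥ 30, SBP < 90 or DBP ≤ 60 mmHg; no age point),
  modified Charlson comorbidity categories (0 / 1–2 / 3–4 / >4, excluding
  age and dementia points), Rockwood frailty flag (scale > 4).
* **Contingency statistics** — Wald odds ratios
  OR = ad/bc with CI = exp(log OR ± z<sub>0.975</sub>·√(1/a+1/b+1/c+1/d)),
  two-sided Fisher exact tests (hypergeometric enumeration in log-gamma
  arithmetic), Wilcoxon rank-sum (exact for small samples, tie- and
  continuity-corrected normal approximation otherwise) and two-sample
  Kolmogorov–Smirnov tests — all implemented in-package.
* **Logistic regression** — from-scratch Newton/IRLS maximum likelihood
  with step-halving, Wald intervals, complete-case handling; model 1a
  (age ≥ 65, sex, dementia, CCI > 4) and model 1b (age ≥ 65, sex), plus a
  radiologically-confirmed-CAP sensitivity subgroup filter.
* **Weighted log-odds symptom contrast** — empirical-Bayes comparison of
  symptom expression in adults ≥ 65y vs < 65y with an informative
  Dirichlet prior α<sub>w</sub> proportional to pooled symptom frequencies:

  δ<sub>w</sub> = log[(y<sub>iw</sub>+α<sub>w</sub>)/(n<sub>i</sub>+α<sub>0</sub>−y<sub>iw</sub>−α<sub>w</sub>)] −
  log[(y<sub>jw</sub>+α<sub>w</sub>)/(n<sub>j</sub>+α<sub>0</sub>−y<sub>jw</sub>−α<sub>w</sub>)],
  &nbsp; σ²<sub>w</sub> = 1/(y<sub>iw</sub>+α<sub>w</sub>) + 1/(y<sub>jw</sub>+α<sub>w</sub>),
  &nbsp; z<sub>w</sub> = δ<sub>w</sub>/σ<sub>w</sub>.

* **Age-band profiles** — 8-band × 11-symptom prevalence matrix, row
  z-scored heatmap values, agglomerative hierarchical clustering
  (Euclidean; complete linkage by default), PCA by SVD, and k-means
  (k-means++ seeding, restarts) on the leading PC scores with the number
  of clusters chosen by mean silhouette.

Estimator-shaped components follow scikit-learn conventions
(`fit`/`predict`/`transform`, `get_params`, trailing-underscore fitted
attributes): `SyndromicCaseClassifier`, `IRLSLogisticRegression`,
`DirichletLogOddsContrast`, `PrincipalComponents`, `KMeansSilhouette`.

## Worked example

```python
from syndromic import (
    DirichletLogOddsContrast, MODEL_1A, band_frequency_matrix,
    classify_cohort, default_calibration, fit_logistic,
    generate_cohort_frame, kmeans_with_silhouette, pca,
)

cfg = default_calibration(n_patients=17620, seed=20200801)
cohort = classify_cohort(generate_cohort_frame(cfg))
print(len(cohort), int(cohort.meets_definition.sum()))

fit = fit_logistic(cohort, MODEL_1A)
age = fit.aor["age_ge_65"]
print(f"aOR {age['odds_ratio']:.2f} ({age['ci_low']:.2f}, {age['ci_high']:.2f})")

contrast = DirichletLogOddsContrast().fit(cohort)
prof = band_frequency_matrix(cohort)
res = pca(prof)
km = kmeans_with_silhouette(res.scores[:, :2], seed=1)
print(contrast.ranking_[:3], f"{100*res.explained_variance_ratio[:2].sum():.1f}%", km.k)
```

prints

```
17620 8478
aOR 0.54 (0.50, 0.57)
['confusion', 'general_deterioration', 'falls'] 98.8% 2
```

meaning: 8,478 of 17,620 synthetic admissions (48.1%) meet the syndromic
definition; after adjusting for sex, dementia and comorbidity, being ≥ 65
roughly halves the odds of meeting it on this synthetic cohort; confusion,
general deterioration and falls are the symptoms most enriched in older
patients (z = +24.3, +20.9, +19.1, with cough −11.5 and pleurisy −17.8 at
the other end); two principal components carry 98.8% of the between-band
variance; and the silhouette-chosen k-means clustering splits the eight
age bands into two clusters, below and above 65.

The same stages are exposed as a CLI:

```bash
syndromic simulate --n 17620 --seed 20200801 --out cohort.csv
syndromic classify --cohort cohort.csv --out classified.csv
syndromic regress  --cohort classified.csv --model 1a --out fit.json
syndromic logodds  --cohort classified.csv --out logodds.csv
syndromic profiles --cohort classified.csv --out-prefix prof
syndromic pipeline --out results/ --seed 20200801   # all of the above + manifest
syndromic check-reference                            # printed-count worked examples
```

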