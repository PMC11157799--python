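# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices and the limitations of the package. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## The scientific setting

Hospitalised adults with clinically confirmed LRTI do not all present with
"classical" respiratory symptoms. The analysis asks three questions:

1. What fraction of confirmed cases would a syndromic (symptom-only) case
   definition capture, and how does age change that probability?
2. Which individual symptoms are over- or under-expressed in adults ≥ 65y
   relative to younger adults?
3. How do whole symptom *profiles* evolve across the age span, and which
   age bands resemble each other?

The motivating cohort (two UK acute-care hospitals, August 2020 – July
2022, n = 17,620 confirmed LRTI admissions) is confidential; only summary
tables were published. The package therefore pairs each analysis stage
with a synthetic cohort generator calibrated to those published margins.

## Case definition and clinical scores

A patient meets the definition iff (cough AND fever) OR at least 3 of the
9 symptoms {cough, fever, breathlessness, wheeze, pleurisy, sputum,
myalgia, headache, general deterioration}. Two presenting symptoms that
are recorded but never contribute: confusion and falls.

* Fever composition: reported fever/chills OR temperature > 38.0 °C OR
  < 35.0 °C, strict inequalities at both bounds. When raw temperature
  exists the composed indicator takes precedence over the stored binary in
  the sense that either source suffices (`compose_fever` flag on the
  classifier); the default uses the stored binary so that files without
  vitals behave identically.
* "General deterioration (weakness/fatigue/anorexia)" is a single
  pre-aggregated indicator; OR-composition from the three raw fields is
  provided as a helper.
* CRB severity score: one point each for AMTS ≤ 7, respiratory rate ≥ 30,
  SBP < 90 mmHg or DBP ≤ 60 mmHg. There is deliberately no age-65 point
  (age is the exposure under study). Missing any component makes the score
  missing (complete-case rule).
* CRB acute confusion (AMTS ≤ 7) and the presenting symptom "confusion"
  are distinct fields throughout and are generated separately; the
  motivating study does not say whether they shared a data field, so they
  are never conflated here.
* Modified Charlson index: categories 0 / 1–2 / 3–4 / >4 on a score that
  excludes age and dementia points (dementia is its own covariate).
* Frailty: Rockwood clinical frailty scale > 4.

## Contingency statistics

All tests are implemented in the package (scipy/statsmodels appear only as
independent oracles in the test suite):

* Odds ratios: OR = ad/bc, SE(log OR) = √(1/a+1/b+1/c+1/d), Wald CI on the
  log scale with the exact normal quantile z = 1.959963984540054 (the
  2-dp-rounded 1.96 can flip a printed boundary digit). Zero cells:
  Haldane–Anscombe +0.5 on all cells with a `corrected` flag (default), or
  refusal, selectable per call. The CI method is not named in the source
  tables; Wald reproduces the printed 0.58–0.66 interval for the age
  contrast, which is the basis for adopting it.
* Fisher exact (two-sided): sum of the probabilities of all tables with
  the observed margins whose probability is ≤ the observed table's — the
  common two-sided convention; alternatives (doubling, mid-p) exist, so
  the choice is stated. Probabilities are computed from log-gamma sums and
  renormalised over the support, stable for cell counts well past 10⁴.
  Ties in table probability are compared with a 1e-7 relative tolerance.
* Wilcoxon rank-sum: exact enumeration of all C(n, n_x) rank assignments
  when n ≤ 20 (two-sided p = 2·min(P(W≤w), P(W≥w)), capped at 1);
  otherwise the normal approximation with the standard tie correction and
  a 0.5 continuity correction toward the null.
* Two-sample KS: D = sup|ECDF difference|; p from the asymptotic
  Kolmogorov distribution Q(λ) = 2Σ(−1)^{k−1}e^{−2k²λ²} at
  λ = √(n_x n_y/(n_x+n_y))·D (no small-sample λ correction, so p can
  differ in the third decimal from implementations that apply one).
* Table-1-style summary: test mapping is an assumption because the source
  table footnote lists tests without row-level mapping — continuous and
  ordinal score variables (age, CRB, CCI score) use the rank-sum test on
  the underlying values; dichotomous characteristics use Fisher. Unknown
  levels are reported as rows with whole-group percentages but are
  excluded from non-missing denominators and from all test statistics;
  this reproduces the published 65%/55% (vaccination/frailty among known)
  and 7.5%/23% (unknown rows) simultaneously.

## Logistic regression

Newton/IRLS on the Bernoulli log-likelihood. Convergence when the largest
absolute score component < `tol` (default 1e-10, max 50 iterations).
Step-halving (up to 50 halvings) guarantees the log-likelihood never
decreases. Diverging coefficients (max |β| > 15) with perfectly predicted
outcomes raise a separation error with a diagnostic; a singular
information matrix raises a rank error. Covariates are binary 0/1, with
age dichotomised at ≥ 65 as the primary exposure; model 1a adds sex,
dementia and CCI > 4, model 1b only sex. Complete-case analysis (no
imputation); the number of rows used is reported.

The published *adjusted* odds ratios (0.67 for model 1a; 0.53 in the CAP
subgroup) depend on the joint covariate distribution of the confidential
microdata and cannot be recomputed from printed counts. They are therefore
validated indirectly: the saturated single-predictor model reproduces the
closed-form 2×2 OR to 1e-8; a 200-replicate parameter-recovery simulation
at n = 17,620 checks unbiasedness (within 3 Monte-Carlo SEs) and ~95% Wald
coverage; and on synthetic cohorts where dementia/CCI are age-correlated
and symptom-suppressing, dropping them (1b vs 1a) moves the age aOR
downward, the direction the published 0.62-vs-0.67 contrast shows.
Coverage is assessed pooled over the five coefficients (1,000 intervals),
since per-coefficient coverage from 200 replicates has a Monte-Carlo SD of
~1.5 percentage points.

## Weighted log-odds with an informative Dirichlet prior

For symptom w with count y_gw in group g of size n_g and prior
pseudo-counts α_w (Σα_w = α_0):

    δ_w = log[(y_iw+α_w)/(n_i+α_0−y_iw−α_w)] − log[(y_jw+α_w)/(n_j+α_0−y_jw−α_w)]
    σ²_w = 1/(y_iw+α_w) + 1/(y_jw+α_w)
    z_w = δ_w/σ_w

α is estimated from the data: pooled symptom frequencies × a strength
parameter (default: mean group total / number of symptoms; exposed as
config). Pooled-zero symptoms get a 0.5 pseudo-count floor before
normalisation so every α_w > 0. The variance weighting down-weights rare
symptoms, and results are ranked by z (ties alphabetical).

Two group-total conventions are supported because "a multinomial model of
symptom expression" can count either unit: `multinomial` (n_g = total
symptom occurrences in group g; each symptom vs all other symptom
mentions; the default) and `bernoulli` (n_g = patients; each symptom vs
its own absence). Neither is asserted to be the original study's — the
published figure cannot disambiguate — and the direction checks pass under
both.

A note on shrinkage: with the informative pooled-frequency prior, both
groups' posterior odds are pulled toward the *common* pooled odds, so
|δ| never exceeds the raw log-odds-ratio magnitude (property-tested over
random draws). This is a property of the pooled prior specifically: an
arbitrary pseudo-count added to the symptom cell alone can *increase*
|δ|, so the shrinkage guarantee is stated and tested for the prior the
package actually estimates.

## Age-band profiles

Bands follow the published table layout — 18–24, then decades, with ≥ 85
open-ended (truncated at 100 in the generator) — rather than strict
10-year bands, because that is the stratification the cohort itself used.
The 8×11 prevalence matrix is row-standardised (mean 0, SD 1 with ddof=1,
matching R's `scale`), expressing each symptom's frequency relative to
other symptoms within the band; empty bands and constant rows are flagged
and excluded from clustering.

* Hierarchical clustering: naive agglomerative merging on Euclidean
  distances between standardised rows; complete linkage by default with
  single/average/ward selectable (the source does not name its linkage).
  Ties break toward the lowest-index pair, making the tree deterministic.
* PCA: SVD of the centred matrix; scores = UΣ, explained-variance ratios
  from squared singular values; component signs fixed so each loading's
  largest-magnitude entry is positive. The PCA input is the z-scored
  matrix by default (`use_z` flag for raw prevalences): the heatmap
  semantics are relative-within-band frequencies, and the original
  analysis's choice is not stated.
* k-means: Lloyd's algorithm with k-means++ seeding, best of 50 restarts
  by inertia, empty clusters re-seeded with the farthest point; k chosen
  from 2..6 by mean silhouette ((b−a)/max(a,b); singleton clusters score
  0; k = n is excluded as undefined), ties toward smaller k. Deterministic
  given the seed.

## Synthetic cohort generator

The generator defines the study conditions for every synthetic check.

* Age: band drawn from the published band totals (443, 998, 1240, 1639,
  2378, 3127, 4152, 3643 out of 17,620), uniform integer ages within the
  band. Only banded counts were published, hence the uniform fill.
* Symptoms: Bernoulli with log-odds = intercept + slope × (age−18)/10,
  conditionally independent given age. Slopes are fixed domain choices
  with the reported gradient signs (negative: pleurisy −0.28, headache
  −0.30, myalgia −0.25, fever −0.15, cough −0.20, sputum −0.12, wheeze
  −0.05; positive: confusion +0.40, falls +0.35, general deterioration
  +0.22, breathlessness +0.02); magnitudes were chosen once as plausible
  per-decade clinical gradients that also keep cough and breathlessness
  the two most frequent symptoms below 85y. Base prevalences (cough 0.64,
  breathlessness 0.62, fever 0.28, sputum 0.30, wheeze 0.22, pleurisy
  0.15, myalgia 0.11, headache 0.10, general deterioration 0.35,
  confusion 0.14, falls 0.12) are realistic admission-symptom rates for a
  hospitalised LRTI population.
* Calibration is deterministic, not Monte-Carlo: every intercept is solved
  by 1-D root finding so the *exact expectation over the age grid* equals
  its published margin (dementia 1,953/17,620; care home 1,392/17,620;
  SARS-CoV-2 7,310/17,620; vaccination 10,389/16,429 among known with
  6.76% unknown; frailty 6,645/14,146 among recorded with 19.7% missing;
  CCI category margins over 17,609 known via a cumulative-logit model).
  Finally a common offset on the nine definition symptoms is solved (exact
  2⁹ enumeration per age year) so the expected meeting fraction equals
  8,487/17,620. Frailty and vaccination are calibrated on non-missing
  denominators because the published percentages are computed that way;
  whole-group rates then follow from the independent missingness.
* Vitals are generated consistently with the drawn indicators so CRB can
  be recomputed from raw fields: AMTS uniform 0–7 vs 8–10 given the
  confusion component (whose probability rises with age and dementia,
  log-OR +1.5), respiratory rate 30–44 vs 12–29, blood pressure in the
  hypotensive vs normal ranges, temperature ranges chosen so 1-dp rounding
  cannot cross the 35.0/38.0 fever boundaries. CRB/CCI components are
  missing completely at random at 0.06% each, mirroring the published
  missingness.
* Dependence: an optional shared "severity" latent factor (one
  logistic-scale Gaussian per patient added to every symptom's log-odds,
  `severity_sd`) is available for robustness checks; the default is off.
* Determinism: one `numpy` Generator seeded from the config; identical
  config + seed gives identical cohorts. Default seed 20200801 (the study
  start date) for reproducible documentation.

What the generator does **not** emulate — and hence what passing synthetic
checks cannot show about real data: calendar-time structure (variant eras,
vaccination rollout), symptom dependence beyond the optional single latent
factor, correlation between recruitment route and symptom profile, the
joint covariate distribution behind the published *adjusted* odds ratios
(the synthetic cohort's own aORs are reported as its own quantities, not
as reproductions), pregnancy structure, and pathogen-specific symptom
differences.

## Problem sizes and determinism of the checks

The margin-calibration check uses 100 seeds at n = 17,620 (each margin
within 3 Monte-Carlo SEs in ≥ 95 of them); parameter recovery uses 200
replicates at n = 17,620; the Fisher implementation is compared with an
exact integer-arithmetic enumeration over all 316,250 tables with N ≤ 50;
the k-means optimum is compared with exhaustive bipartition search on
8-point instances. These sizes make the full suite run in well under a
minute while keeping Monte-Carlo bands tight. All stochastic tests are
seeded; hypothesis runs derandomised.

## Known limitations

* The published 48.1% meeting fraction is inconsistent at the last digit
  with the published group totals (8,487/17,620 = 48.17%); the package
  computes from the totals and compares at the printed 0.1 precision.
* The synthetic cohort reproduces margins and gradient directions, not the
  joint distribution; its adjusted odds ratios are internally consistent
  quantities, not estimates of the published ones.
* The Wilcoxon exact path enumerates combinations and is exponential; it
  is gated at pooled n ≤ 20 by default.
* The two-sided Fisher convention and the asymptotic KS p-value can differ
  from other software in edge cases (probability ties; small samples).
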