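# Methods

`pedsep` re-implements, as a tested pipeline, the derivation of four
computable 24-hour pediatric sepsis phenotypes (PedSep-A, B, C, D) from
bedside clinical variables, together with the rule-based multiple-organ-
failure (MOF) phenotypes used to characterize them and an exploratory
treatment-interaction screen. Because the underlying individual-level
cohort is not publicly deposited, the package ships a synthetic-cohort
generator calibrated to the published summary tables; every downstream
stage is exercised against that generator.

## The synthetic cohort

The generator draws each patient from a four-component mixture with
weights 136/404, 102/404, 110/404 and 56/404 and then samples the 25 day-1
clustering variables from phenotype-conditional distributions:

* Variables with published mean/SD (age, heart rate, systolic BP,
  temperatures, hemoglobin, platelets, GCS) are truncated normals on
  physiologic bounds. The location is solved numerically so the mean of
  the *truncated* distribution equals the published mean — without this,
  truncation shifts heavily dispersed variables (platelets in PedSep-D)
  by tens of units.
* Right-skewed variables with published median/IQR (ferritin, ALC,
  creatinine) are log-normal with `mu = log(median)` and
  `sigma = log(q3/q1) / (2 z_0.75)`; CRP, published as mean/SD but
  clearly skewed, is log-normal by moment matching. A two-parameter
  log-normal reproduces the median exactly and the quartile *ratio*; it
  cannot also absorb the asymmetry of the printed IQR around the median.
* Binary demographics and therapies are Bernoulli at the published rates.
* GCS is rounded to the integer grid 3–15.

### Organ-failure flags and the two extraction windows

PRISM-type variables are defined as the most abnormal value in the first
6 h; organ-failure flags and inflammation markers use the full first 24 h.
The generator therefore emits two day-1 records per patient: a `first_6h`
record holding the calibrated PRISM draws, and a full-day record. Day-1
organ-failure flags are drawn directly at the published 24-h prevalences;
when a flag fires but the 6-h value has not crossed the rule threshold,
the full-day record deteriorates past the threshold (creatinine rises,
platelets fall, GCS drops). This is how the published flag rates and the
published 6-h continuous summaries can hold simultaneously, and it keeps
both calibrated at once. The PedSep-D hematologic flag rate is taken from
the printed count (31/56 = 55.4%); see the data file comment.

Within a phenotype the six flags are coupled through a Gaussian copula.
A common latent correlation per phenotype is solved (bivariate-normal
orthant probabilities, Brent's method) so that the SD of the total organ
failure index matches the published within-phenotype SDs (0.5/0.6/0.6/1.0)
— independent flags would give 0.65–1.12, so the published SDs imply
negative coupling: each phenotype has a characteristic failure pattern.
The renal × hematologic pair inside PedSep-D additionally carries a
configured joint prevalence (default 0.25, slightly below the independence
value 0.30). The published marginals leave this joint free; the bound
comes from the fact that the source screening retained both variables,
which caps their cohort-level association below the 0.6 screen. An
optional `lab_coupling` parameter can instead tie each lab-linked flag to
its defining lab's within-phenotype percentile; the default is 0 so that
each flag contributes its own information to the phenotype signature.

### Longitudinal structure

The published analysis uses only day-1 data for clustering; later days
exist to exercise the MOF rules and the organ-failure/mortality curves.
Day-to-day evolution is a first-order autoregressive walk toward the
phenotype mean (persistence 0.7 on the modeling scale) with flag
persistence (daily resolution probability 0.25) and no spontaneous new
organ failures. No within-patient longitudinal correlation structure is
published; this walk is a stand-in and nothing downstream depends on its
details beyond rule firing.

### MOF-rule prevalences: classify-then-top-up

Baseline trajectories keep the rule-specific biomarkers in rule-safe
ranges (ADAMTS13 ≥ 58% of control, TNF response ≥ 210 pg/mL, sFasL ≤ 195
pg/mL), so TAMOF/IPMOF/SMOF cannot fire spontaneously while MAS can fire
naturally from day-1 co-occurrence of hyperferritinemia with DIC-liver
failure. For each rule and phenotype, the generator counts natural
positives with the same logic the rule engine applies, draws a
Binomial(n, rate) target at the published prevalence, and injects
qualifying biomarker windows (on days ≥ 2, never touching day-1 records)
into additional patients until the target is met. Injection candidates
are preferred when their day-1 failure pattern is compatible (e.g. TAMOF
into patients already in renal failure), which limits collateral
new-organ-failure events; NPMOF is topped up last against the realized
trajectory. Realized rates therefore converge to the configured ones, and
mortality, length of stay and therapy exposures follow the published
per-phenotype rates. Methylprednisolone and IVIG are drawn jointly so the
published combination prevalence holds; an optional odds multiplier on
mortality for a therapy pair within one phenotype (default 1.0 = null)
lets interaction-recovery power be studied without asserting efficacy.

### What the generator does not emulate

No site effects, no informative missingness (masking is MCAR at the
patient × variable level, emulating a lab never sent), no real
physiologic coupling between continuous labs beyond the configured flag
copula, and no admission/readmission structure. Passing tests show the
*pipeline* behaves correctly under the published summary structure; they
are not evidence about real patients.

## Screening and standardization

Candidate variables are screened to < 20% missingness and < 60% pairwise
correlation. Correlation is Spearman's rank correlation uniformly, with
binaries coded 0/1 — on two binaries this equals the phi coefficient, and
on mixed pairs it is a rank point-biserial, which is properly scaled by
flag prevalence (a full-separation rank-biserial of a 7%-prevalence flag
against its defining lab is ~0.9 and would eliminate variable pairs the
source screening demonstrably retained). Correlated pairs are eliminated
greedily in descending |r|, dropping the member with more missingness
(ties: later in schema order), which makes the retained set independent
of column order. Imputation is column median (mode for binaries) — the
source publication is silent on imputation; this is a documented
stand-in. Skewed columns are log(x+1)-transformed (an offset admits
zeros, e.g. lymphocyte counts) and every column is z-scored; the
transform parameters are stored with the model so a new patient can be
mapped into the training space exactly.

## Consensus k-means and model selection

For each k in 2..6, `n_iterations` (default 1000) k-means fits
(k-means++ seeding, 10 restarts, 300 sweeps, per-iteration seeds derived
from the master seed) run on random 80% patient subsamples. The consensus
matrix M(k) is the fraction of runs co-clustering each pair among runs
co-sampling it. A(k) is the area under the empirical CDF of the
upper-triangle consensus values, integrated over [0, 1]; Δ(k) is the
relative gain A(k)−A(k−1) over A(k−1), with Δ(k_min) = A(k_min).

The selection rule takes the largest k with Δ(k) ≥ threshold. The default
threshold is 0.08, chosen from the two bounds the design itself implies.
In the noiseless limit, the gain of moving from k−1 to the true k equals
the pair share of the two clusters merged at k−1 relative to A(k−1):
Δ(k*) = 2 w_i w_j / (1 − Σw² − 2 w_i w_j) ≈ 0.106 at the calibrated
mixture weights (w_D = 0.139, w_B = 0.25 merge first). The spurious gain
of splitting a true cluster beyond k* is bounded by roughly half that
cluster's squared weight over A(k), ≈ 0.04–0.075 here. A threshold of 0.1
sits above the ideal true gain once resampling noise is accounted for and
rejects k = 4 even for near-perfect consensus; 0.08 sits inside the
window. The threshold is config-exposed.

The ambiguity flag fires when the Δ profile is flat beyond k_min, when it
declines smoothly with no consecutive drop ratio ≥ 2 (no elbow — the
signature of resampling-stable but hierarchy-free structure, e.g. the
discrete cells formed by binary variables when phenotype separation is
removed), or when the PAC (proportion of consensus entries strictly
between 0.1 and 0.9) at the chosen k exceeds 0.3 (unstable membership,
e.g. subsample-induced splits of a single Gaussian cloud).

Final labels cut an average-linkage tree of the consensus distance 1−M at
the chosen k, using the consensus evidence itself rather than one more
k-means on raw data; clusters are renumbered by decreasing size and, at
k = 4, mapped to the PedSep letters by maximizing total agreement between
standardized centroids and sign templates of the published phenotype
signatures (Hungarian assignment, so ties still yield a bijection). The
t-SNE embedding is a delegated visualization utility and feeds no
inference.

Measured on the calibrated default cohort, consensus k-means recovers the
latent phenotype with ARI ≈ 0.75–0.82; the Bayes-optimal classifier under
the generator's own model reaches ≈ 0.91, so roughly 15% of patients are
genuinely ambiguous at the published effect sizes and a further slice is
lost to the Euclidean spherical geometry of k-means relative to the true
likelihood. Median imputation of the configured missingness costs a
further ~0.01–0.02 ARI and is reported separately from the module's
recovery properties, which are therefore assessed on complete feature
tables.

## Bedside assignment

A new patient's raw features pass through the stored log/z transform;
missing inputs (allowed up to 40%) are imputed at the training median
(0 in z-space) and counted; the nearest centroid by Euclidean distance
wins, ties going to the lower letter with a flag. Softmax membership
weights (temperature 1) are descriptive only. The published web tool's
internals are not public; nearest-centroid is the simplest rule consistent
with a k-means-derived model, and the divergence between it and the
hierarchical-cut training labels is measured (≥ 95% agreement on
well-separated cohorts).

## Association statistics

Across-phenotype comparisons use Kruskal–Wallis for continuous variables
and chi-square for categorical ones, switching to Fisher's exact test for
2×2 tables with an expected cell below 5 and to a seeded permutation
chi-square for larger sparse tables (an exact r×c network algorithm is
out of scope). Multiplicity adjustment is Benjamini–Hochberg per table
family (config-switchable). Unadjusted odds ratios are cross-products
with Woolf CIs and Haldane–Anscombe correction for zero cells (flagged);
adjusted odds ratios come from maximum-likelihood logistic fits with Wald
CIs, and (quasi-)separation raises an error rather than silently
degrading. Organ-failure curves are non-nested daily means (patients
leave the risk set on PICU exit; no carry-forward) with normal-theory
CIs and at-risk counts; mortality curves are cumulative fractions.
Chord-diagram links require the group mean to differ from the cohort mean
in the category's canonical direction (lower for low temperature,
systolic BP, hemoglobin, platelets, GCS; higher otherwise) and, by
default, a significant BH-adjusted group-vs-rest contrast; a
direction-only mode is available. Biomarker heatmap inputs are natural-log
ratios of phenotype medians to the cohort median, ordered by
average-linkage hierarchical clustering.

## Treatment-interaction screening

Therapies univariably associated with survival (p < 0.05 overall or
within any phenotype; chi-square/Fisher by the expected-cell rule) enter
an elastic-net logistic model of mortality over all main effects and
pairwise products (14 therapies → 105 terms). Hyperparameters are not
published; defaults are l1 ratio 0.5 with the penalty strength chosen by
seed-fixed stratified cross-validated deviance (10 folds, 10 candidate
strengths), indicator columns unstandardized. Grid cells are
exponentiated coefficients (unadjusted, no CIs by construction); blank
cells mark combinations no patient received; strata with fewer than five
deaths are refused, mirroring the exclusion of the lowest-mortality
phenotype from the published analysis. Cells with OR < 0.1 are re-examined
by covariate-adjusted (age, sex, ethnicity, race, PRISM) maximum-
likelihood logistic regression of the product term.

## Problem sizes and numerical choices

Default analyses run at the published cohort size (n = 404). Simulation-
based checks use 200 resampling iterations per k for model-selection
studies and the module default of 1000 for recovery studies; calibration
checks run at n = 4,000–20,000, where binomial 3-SD bands are decisive.
Tolerances: standardization to 1e-9; odds-ratio oracle agreement to 1e-6;
strict inequalities throughout the rule engine, so boundary values never
fire a rule. Degenerate inputs (zero-variance columns, single-class
outcomes, empty clusters, all-missing columns) raise errors naming the
offending object.

## Known limitations

The generator reproduces published *marginal* structure plus a minimal
coupling model; real covariance between labs is not represented, so
cluster-recovery numbers here do not predict performance on real data.
The day numbering convention ("beyond three days" = day index > 3, day 1
= first severe-sepsis PICU day) and same-day conjunction readings of the
TAMOF/MAS rules follow the published wording literally and are
config-exposed. The 28- vs 30-day PICU-free-days inconsistency in the
source is preserved as a configurable default of 30 with death scoring 0.
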