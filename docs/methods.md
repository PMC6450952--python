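# Methods

## Data model

The unit of analysis is the drug × organ-system pair. All phenotypes —
drug indications, clinical-trial side effects, Mendelian syndrome phenotypes
and GWAS trait associations of target genes — are assumed pre-mapped to a
fixed vocabulary of 21 MedDRA system-organ-class (SOC) categories; ontology
mapping itself (UMLS/MetaMap, SOC exclusions such as "Social circumstances")
is upstream of this package and out of scope. Catalogs are plain TSV: one
gene table (phenotype SOC sets per source, constraint flag, expression
breadth), one drug table (target genes, modality, routes, indication and
side-effect SOC sets), or a pre-flattened drug × SOC observation table.

Genetic support is derived per (drug, SOC, source): MATCH if any target
gene carries the SOC, otherwise MISMATCH if any target gene is informative
for the source, otherwise NO_INFO. Two deliberate choices here, since both
readings exist in practice:

* MISMATCH requires only one informative target. The stricter condition —
  *every* target informative — is carried separately per observation
  (`all_targets_informative`) because the de-risk split is defined on it.
* "No genetic information" means *no* target has any phenotype for the
  source. The alternative (any target uninformative) is representable via
  `all_targets_informative` but is not the regression baseline.

A gene is "informative" for a source iff its SOC set for that source is
nonempty; no separate flag is stored. Multi-SOC phenotype terms contribute
to every mapped SOC. Routes are non-exclusive binary flags.

## Enrichment statistics

2×2 tables (support × side effect) are summarized by the sample odds ratio
ad/bc with a Woolf (log-scale normal) 95% CI and Fisher's exact test.
The two-tailed *P* follows the probability-mass convention (sum of
hypergeometric point masses not exceeding the observed one, with a ~1e-7
relative tolerance), delegated to `scipy.stats.fisher_exact` and verified in
the test suite against exact rational enumeration of all margin-preserving
tables. Degenerate margins return *P* = 1. Zero cells leave the OR at 0/∞
with an undefined CI; a Haldane–Anscombe (+0.5) CI is available behind a
flag for display only, keeping the raw estimator primary. Report rounding
follows the published table: rates at one decimal percent, OR at two
decimals.

Diagnostic metrics treat support as a screening test: sensitivity a/(a+c),
specificity d/(b+d), LR+ = sens/(1−spec), and iLR− = spec/(1−sens) (the
inverse negative likelihood ratio, so "LR > 1 = predictive" reads uniformly
for positive and negative findings).

The treatment-vs-placebo arm filter uses the one-tailed (greater) Fisher
test and keeps an adverse event iff *P* < α **and** the treatment-arm rate
exceeds the placebo rate. No multiple-testing correction is applied across
organ systems in enrichment (raw per-category *P* values are reported); the
conservative 0.05/18 Bonferroni threshold lives in regression reporting.

## Permutation nulls

Two structured randomizations: gene → phenotype-set reassignment by uniform
permutation (empty sets travel like any other, so the uninformative fraction
is preserved; under `source="both"` the Mendelian/GWAS pair moves as a unit,
preserving cross-source co-occurrence — permuting the sources jointly is the
default, independent permutation is available), and drug → side-effect
profile reassignment (targets, indications, covariates untouched). The
permutation runs over the genes that actually appear as drug targets, not
the whole catalog. The default statistic is the pooled any-support OR; any
scalar statistic of the observation set is pluggable. Empirical *P* uses the
add-one convention (r+1)/(n+1) and therefore never reports zero; replicates
on which the statistic fails are dropped and logged, with >10% failures an
error. Replicate RNG streams are spawned independently from the master seed,
so results do not depend on replicate order.

## Regression models

Eligibility: organ systems with ≥100 drugs eliciting the side effect (18 of
21 on the published counts). The design has one row per drug: 20 indication
indicators (Neoplasm excluded — oncology trials are excluded upstream),
modality (small molecule baseline), four non-exclusive route indicators (no
reference level is dropped; collinearity is tolerated by the penalized fit
and surfaced as a separation/instability warning in the unpenalized one),
three expression-breadth indicators (baseline `none_detected`), a constraint
indicator, and the four genetic-support indicators (MATCH/MISMATCH per
source against the NO_INFO baseline). For multi-target drugs, breadth and
constraint indicators are "any target" aggregations. An optional continuous
variant replaces the breadth indicators with per-tissue means of log2 TPM
over the drug's targets.

Unpenalized fits use statsmodels GLM (Binomial) with Wald inference;
suspected perfect separation is reported via `converged=False` with
coefficients still returned. The lasso minimizes mean negative
log-likelihood + λ‖β‖₁ (intercept unpenalized, predictors unstandardized —
the design is all indicators on a common scale), via scikit-learn's saga
solver; an independent proximal-gradient oracle in the tests confirms the
optimum. Penalty selection mirrors the glmnet recipe: per repeat, stratified
k-fold CV traces test AUC over a descending log grid of 100 λ values from
λ_max (the smallest penalty zeroing all coefficients) down to 1e-4·λ_max;
λ.min maximizes the across-fold mean AUC and λ.1se is the largest λ within
one across-fold standard error of that maximum (the SE is taken across folds
within each repeat); λ\* averages the two means over repeats. Degenerate
(single-class) folds are refolded from a fresh substream. The reference
procedure is 100 repeats of 10-fold CV; the bundled analysis script defaults
to 2 repeats of 5-fold over 25 λ values, which selects indistinguishable λ\*
on the default cohort at a fraction of the cost.

## Leave-one-target-set-out cross-validation

Each unique target set is one fold: test = all drugs with exactly that set,
training = all drugs sharing none of its genes. A leakage assertion
(test-fold target genes ∩ training-drug targets = ∅) runs on every fold of
every call. Folds with empty training sets, or single-class training
responses for the modeled organ, are skipped and counted; their drugs
contribute no predictions. Per-fold models are the full unpenalized
logistic fit; for speed the inner loop uses a Newton (IRLS) solver with
step halving, warm-started from the full-data solution, falling back to
scikit-learn's LBFGS if it fails. AUC is computed on the pooled out-of-fold
predictions with the Mann–Whitney tie convention (ties count ½). The
permuted-genetics null reuses the fold partition (which depends only on
target sets, not genetics) and permutes phenotype assignments within the
drug-target genes.

## Synthetic cohort generator

Side effects are drawn from a single logistic model, with no
overdispersion — deliberately identical in form to the analysis model so
that parameter recovery is a clean end-to-end check:

    logit P(SE_is) = α_s + β_gen·[any-source MATCH] + β_ind·[s ∈ indications_i]
                   + covariate terms

Defaults emulate the study's scale and conditions:

| parameter | default | rationale |
|---|---|---|
| n_drugs / n_genes | 1819 / 1046 | cohort size of the study |
| α_s | logit of published per-SOC no-support SE rates | realistic marginal rates spanning ~2–40% |
| β_gen | ln 1.55 | the off-indication (less confounded) published enrichment |
| β_ind | ln 2 | exaggerated-pharmacology effect in the organ of action |
| confounding | 0.25 | indications seeded from target phenotype SOCs with this probability |
| frac_no_mendelian / frac_no_gwas | 0.50 / 0.55 | reproduces ~3/4 of drugs having some informative target |
| targets_per_drug / target_sharing | 1–3 / 0.4 | many shared target sets, so grouped CV is non-trivial |
| covariate effects | small log-ORs (±0.1–0.2) | confounder stand-ins, not simulation targets |

The random stream is consumed in a fixed order (gene annotations → per-drug
structure → side-effect draws); the same seed yields byte-identical
catalogs. Confounding is implemented in the indication-assignment direction
(a drug's indications are seeded from its targets' phenotype organ systems),
which induces the intended indication–genetics correlation while keeping
that stream order intact. Phenotype set sizes are 1+Poisson(1.5) SOCs.

What the generator does **not** emulate: per-SOC marginal side-effect
frequencies of the real data beyond the baseline intercepts, drug chemistry,
trial-size reporting bias, correlated side effects within a drug beyond the
shared covariates, or any dose dependence. Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
assumed generative model — not that the real-data effect sizes are
reproduced, which requires the study's full per-drug dataset.

## Problem sizes in the test suite and acceptance script

Simulation-based checks use cohorts of 150–3000 drugs: permutation
calibration runs 500 null cohorts of 150 drugs at 99 permutations;
parameter recovery uses 50 (tests) or 10 (acceptance script) cohorts of
2000 drugs; CV contribution uses 20 cohorts of 800 drugs plus 99-permutation
AUC nulls. These sizes give stable pass/fail behavior for the stated
tolerances while keeping full runs in the minutes range.

## Known limitations

* The vocabulary is hard-coded to the 21 categories; other MedDRA levels or
  custom vocabularies are unsupported.
* Zero-cell ORs are reported as 0/∞ rather than corrected; downstream
  consumers must handle the undefined CI marker.
* The lasso path uses a first-order solver; at extremely small penalties it
  is slower and slightly less exact than a dedicated coordinate-descent
  implementation (tests pin accuracy to ~1e-4 in coefficients).
* `select_lambda` at the full reference setting (100×10-fold×100 λ) is
  expensive on a single core; use the reduced defaults for exploration.
* The de-risk split requires both strata to be populated and errors
  otherwise rather than returning a degenerate OR.
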