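# Methods

This note documents the models and procedures implemented in `s3score`,
the parameters that matter, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Similarity scoring

Each tumor profile is correlated against eight nephron-region reference
profiles over the genes shared between tumor matrix and reference
matrix. Spearman rank correlation is the default: the workflow spans
RNA-seq, microarray and qRT-PCR measurements, and rank correlation is
invariant to the monotone scale differences between those platforms.
Pearson is available by flag and every result records the method used.

Two aggregations of the eight correlations are provided:

- `origin` (default) — the correlation with the designated cell-of-origin
  region (the S3 proximal-tubule segment);
- `origin_margin` — origin correlation minus the maximum over the other
  regions, which rewards *specific* resemblance.

Both are recorded in outputs so externally published coefficients or
aggregation rules can be substituted. Samples with missing values fall
back to pairwise-complete genes with a hard floor of three genes;
constant profiles are an error (the correlation is undefined), not a
silent NaN.

Risk classification uses the convention *score > cutoff ⇒ S3-high*; a
score exactly at the cut-off is S3-low. Ties are measure-zero for
continuous scores; the convention simply makes classification
deterministic and documentable.

## Survival machinery

Kaplan–Meier estimation, the k-sample log-rank test, Cox fits with
Efron tie handling (with optional strata) and Harrell's concordance
index are delegated to lifelines. A small in-package Newton solver on
the Breslow partial likelihood (standard errors from the inverse
observed information, strata by summing per-stratum score and
information) provides the Breslow tie option, since no installed
library exposes Breslow ties together with standard errors and strata.
Efron and Breslow agree to ≈1e-5 on tie-free data (tested). Analysis of
deviance for nested Cox models is the likelihood-ratio statistic
2·(ℓ_full − ℓ_reduced) against χ² with the parameter-count difference
as degrees of freedom.

Confidence intervals are Wald-type, exp(β̂ ± 1.96·SE); significance is
two-sided at α = 0.05 throughout, with no multiplicity adjustment
across cohorts or endpoints — the permutation adjustment applies only
inside cut-off selection, where it belongs.

### Cut-off discovery

The prognostic cut-off is found by a depth-1 conditional-inference
split: candidate cutpoints are the observed score values inside a
quantile window (default 10–90%) whose induced groups both meet a
minimum size (default 10); the candidate maximizing the absolute
standardized two-group log-rank statistic is selected. Because the
maximum over many candidates inflates the naive p-value, the selection
p is estimated by permuting scores against outcomes B times (default
1000) and counting permutations whose own maximal statistic reaches the
observed one, with the add-one estimator (r+1)/(B+1) so finite B never
yields p = 0. The reported threshold is the midpoint of the empirical
gap above the selected observed value: every threshold in that gap
induces the same split, and the midpoint is the natural representative.
The statistic matrix over candidates (and over permutation blocks) is
computed vectorized from cumulative risk-set counts, so B = 1000 on a
few hundred samples takes seconds.

### Clinical covariate recoding

For multivariate models, T/N/M/G are expanded to reference-coded
indicators (reference levels T1, N0, M0, G1). Grades "2–3" and "4" are
folded into G3; records with missing or X grade, or metastasis status
MX, are excluded and itemized in a report rather than raising errors —
cohort filtering is an auditable analysis step, not a failure.

## Signature refinement

The reduction from the full signature to a qRT-PCR panel runs in three
stages on two cohorts (a development cohort with genome-wide data and a
qRT-PCR-measured cohort):

1. **Assay-failure filter** — a gene is kept only with zero missing Ct
   values across all samples ("failed at least once" ⇒ excluded). The
   report carries per-gene failure counts; an empty retained set is a
   reportable outcome, not an exception.
2. **Comparability filter** — both matrices are per-sample
   median-centered, which removes platform location offsets without
   flattening per-gene variance (full z-scoring would make the mean
   criterion vacuous). A gene is kept iff its between-platform mean
   difference is ≤ 0.5 pooled SDs and its SD ratio (larger/smaller) is
   ≤ 2.0. Both thresholds are config; the criterion is inherently
   qualitative and these defaults encode "same location, same order of
   variability". Genes with zero SD on both platforms are retained but
   flagged degenerate.
3. **Sparse linear reconstruction** — on the development cohort, the
   correlation-based score itself is the response and the filtered
   candidates are predictors. Default selection is bidirectional
   stepwise from the empty model under an information criterion:
   - `aic` (default) — the classical choice for predictive
     reconstruction; it will admit occasional spurious terms when many
     pure-noise candidates are offered (each noise candidate clears the
     AIC penalty with probability ≈ 0.16);
   - `bic`, `ebic` — consistent support recovery; `ebic` (γ = 1) adds
     2·k·log(p) and is the configuration to use when the goal is
     recovering a sparse true support from a large candidate pool.
   A `max_terms` cap stops growth at a target panel size. The
   alternative `lasso_path` method takes the least-angle lasso path,
   picks the largest support within `max_terms` (or the AIC-best point),
   and refits unpenalized on the support. Candidates exactly collinear
   with the current support are excluded from moves and reported on the
   returned model, never silently dropped; a rank-deficient *selected*
   design raises.

The fitted model is a plain intercept + coefficient map, serialized to
JSON (exact round-trip), and applied to any matrix containing the model
genes — typically delta-Ct normalized qRT-PCR, where expression is
mean(reference-gene Ct) − Ct(gene). The arithmetic mean of Ct equals the
log-scale geometric mean of the linear quantities, the standard ΔCt
convention. Held-out concordance between the reduced and the full score
is summarized by Spearman's ρ.

## Comparator classifiers

The SSIGN point table (stage, size, grade, necrosis) ships as editable
JSON config with a provenance note; points are summed per patient and
binned into configurable risk strata. Any missing or X feature is an
error listing the offending features, since a silently partial sum
would be a wrong score. The two-class centroid classifier assigns each
sample the class of its best-correlated centroid with confidence equal
to the correlation difference; exact ties are "unclassified". The
packaged centroid file contains synthetic values and demonstrates the
schema only — published centroid tables are user input. Per-patient
concordance (primary vs metastases, multi-region metastases included)
asks whether all samples of a patient share one class and reports the
within-patient score range.

## Synthetic cohorts

The generator produces structurally realistic inputs with returned
ground truth; every recovery test reads truth from the generator rather
than re-deriving it. One top-level seed fixes everything; each
operation draws from its own child stream so artifacts do not depend on
call order.

- **Reference profiles** — per-gene baseline N(8, 2²) on log2 scale plus
  region-specific contrasts. Fifteen "informative" signature genes get
  contrast SD 16; the remaining signature genes SD 0.2; non-signature
  genes SD 1. With purity Beta(5, 2) and expression noise SD 0.3, the
  informative genes then carry ≈94% of between-sample signature
  variance — the regime in which a ~15-gene linear model can stand in
  for the full signature; the 82 low-contrast genes contribute an
  irreducible 82 × 0.3² noise floor, which is why the informative
  contrast must be this large for the share to clear 90%. Any two
  regions correlate < 0.8 over signature genes.
- **Tumors** — expr = w·origin + (1−w)·background + ε, with purity
  w ~ Beta(5, 2) (skewed high, as tumors largely resemble their origin)
  and background a per-sample Dirichlet mixture of the non-origin
  regions, so all eight correlations are informative, as in tissue.
- **Survival** — event times Exponential with hazard h₀·exp(−β·w)
  (defaults h₀ = 0.25/yr, β = 2), censoring Uniform(0, 10 yr); at the
  defaults ≈26% of subjects have events, matching a cancer-specific
  endpoint over a decade of follow-up.
- **qRT-PCR** — Ct = intercept − slope·expr + noise (defaults 30, 1.0,
  SD 0.25), clipped to the instrument dynamic range [0.5, 44.5]. Slope 1
  encodes ~100% amplification efficiency (one cycle per doubling);
  slope ≠ 1 is available and induces platform non-comparability
  proportional to a gene's offset from the sample median — useful for
  stress-testing the comparability filter, deliberately not the
  default. Wells fail i.i.d. at rate 0.002; normalization genes are
  generated failure-free with SD 0.05, reflecting reference genes
  chosen for reliability (and the ΔCt contract requires them complete).
- **Metastases** — per-gene N(0, 0.1²) perturbations of the primary,
  optionally several regions of one metastasis.

What the generator does **not** emulate: real count distributions,
batch or FFPE effects, correlated assay dropout (failures are
independent per well, whereas real failures cluster by assay),
non-proportional hazards, or any actual ccRCC biology beyond the
mixture structure the scoring method relies on. Passing tests therefore
demonstrate correctness and calibration of the *method* under its
stated assumptions, not clinical performance.

## Problem sizes

Simulation-based checks use a development cohort of 400 and a
validation cohort of 150 samples on 300 genes (97 signature), 100–1000
replicates for calibration and coverage suites, and B = 200–1000
permutations for cut-off p-values — sizes at which every quantity of
interest is stable to well under the tolerances asserted, while the
full suite runs in a few minutes on one core.

## Known limitations

- The published gene identities, reference-profile values, score
  cut-offs and centroid tables of the original signature are not
  bundled; they are user-supplied config, and the package validates
  machinery, not those constants.
- Breslow fits use an unregularized Newton solver; near-separated data
  raise a divergence error rather than being shrunk.
- `find_cutoff` permutes scores against (time, event) pairs, which
  assumes exchangeability under the null; covariate-conditional nulls
  are out of scope.
- The stepwise selector refits by dense least squares and is intended
  for candidate pools of up to a few hundred genes, not genome-wide
  selection.
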