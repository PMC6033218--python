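# s3score

Cell-of-origin similarity scoring for prognosis in clear cell renal cell
carcinoma (ccRCC), with the full survival-validation and
signature-refinement toolchain around it.

## The problem and the method

ccRCC arises from the S3 segment of the nephron's proximal tubule, and
tumors that still resemble their cell of origin behave less
aggressively. The S3 score turns that observation into a prognostic
statistic: over a panel of signature genes, each tumor's expression
profile *x* is correlated against reference expression profiles
*r₁ … r₈* of eight nephron regions,

&nbsp;&nbsp;&nbsp;&nbsp;ρₛ(x, rⱼ) = Spearman rank correlation over the shared signature genes,

and the score is the correlation with the designated origin region
(optionally the margin over the best other region). Patients are split
into S3-high (origin-like, better prognosis) and S3-low strata at a
cut-off discovered by the maximally-selected log-rank statistic with a
permutation-adjusted selection p-value (a depth-1 conditional-inference
split). Strata are validated with Kaplan–Meier curves, log-rank tests,
uni-/multivariate Cox proportional-hazards models (HR, 95% CI, Wald p),
Harrell's c-index, and analysis-of-deviance comparisons of nested Cox
models — including whether the molecular score adds prognostic
information to the clinicopathological SSIGN score.

Because a genome-wide assay is impractical clinically, the package also
refines the signature to a small qRT-PCR panel: assays that failed at
least once are dropped, genes whose mean/variance are not comparable
between RNA-seq and normalized qRT-PCR are dropped, and a sparse linear
model (stepwise information-criterion selection, or an L1 path) is
fitted on a development cohort to reconstruct the correlation-based
score from the surviving candidates. The resulting model is a plain
intercept + weighted sum over ~15 genes, applicable to delta-Ct
normalized qRT-PCR measurements.

A seeded synthetic-cohort generator produces every input the pipeline
needs (reference profiles, tumors as noisy convex mixtures of the origin
profile, survival with hazard decreasing in the latent similarity, qPCR
re-measurements with sporadic well failures, matched metastases), with
its ground truth returned alongside the data.

## Worked example

```python
from s3score import (GeneratorConfig, make_reference_profiles,
                     simulate_tumors, simulate_survival, run_score97)

cfg = GeneratorConfig(seed=11, n_samples=150)
refs = make_reference_profiles(cfg)
tumors, w = simulate_tumors(cfg, refs)
clinical = simulate_survival(cfg, w)

report = run_score97(tumors, refs, clinical, learn_cutoff=True,
                     seed=11, n_permutations=500)
print(report.summary())
```

```
Risk-group survival validation
==============================
samples: 150  S3_high: 109  S3_low: 41  cutoff: 0.9582
log-rank: chi2 = 10.499 (df 1), p = 0.00119
univariate Cox (S3_low vs S3_high): HR = 2.72 (95% CI 1.45-5.11), Wald p = 0.00183
Harrell's c-index: 0.606
```

Read: the learned cut-off (0.958, permutation-adjusted selection
p = 0.026) splits the cohort 109/41; the S3-low stratum has a 2.7-fold
higher cancer-specific hazard, the survival curves differ (log-rank
p ≈ 1.2 × 10⁻³), and the continuous score orders event times better than
chance (c = 0.61). The direction is by construction: the generator gives
low-similarity tumors higher hazard.

The same workflows are available from the shell:

```sh
s3score simulate --seed 11 --out runs/sim
s3score score97 --expression runs/sim/tumors.tsv \
    --refs runs/sim/reference_profiles.tsv \
    --refs-meta runs/sim/reference_profiles.json \
    --clinical runs/sim/clinical.csv --learn-cutoff --seed 11 --out runs/score
s3score refine --dev runs/sim/tumors.tsv --refs runs/sim/reference_profiles.tsv \
    --refs-meta runs/sim/reference_profiles.json --qpcr runs/sim/qpcr_ct.tsv \
    --panel runs/sim/panel.json --max-terms 15 --out runs/refine
```

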