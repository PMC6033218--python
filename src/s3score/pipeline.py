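"""End-to-end workflows: score a cohort and validate it against survival,
refine the signature to a sparse qRT-PCR model, and test whether a
molecular classification adds prognostic information to SSIGN.

Each workflow returns a results object; the CLI writes these plus a
machine-readable run manifest sufficient to re-run the command exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .refinement import (
    ComparabilityCriteria,
    LinearScoreModel,
    apply_linear_model,
    comparability_filter,
    filter_failed_assays,
    score_concordance,
    select_linear_model,
)
from .scoring import (
    HIGH,
    LOW,
    ReferenceProfiles,
    RiskClassification,
    S3ScoreModel,
    classify_risk,
)
from .survival import (
    CoxFit,
    CutoffModel,
    KMCurve,
    LogrankResult,
    LRTResult,
    cox_fit,
    find_cutoff,
    harrell_c,
    km_estimate,
    logrank_test,
    lr_test,
    validate_survival,
)

__all__ = ["ValidationReport", "run_score97", "RefinementResults",
           "ScoreRefinement", "run_refine", "run_improvement_test"]


@dataclass
class ValidationReport:
    """Survival validation of a risk classification (Table-2-style)."""

    scores: pd.Series
    classification: RiskClassification
    km_by_group: dict[str, KMCurve]
    logrank: LogrankResult
    cox_univariate: CoxFit
    c_index: float
    cutoff_model: CutoffModel | None = None
    cox_multivariate: CoxFit | None = None

    def summary(self) -> str:
        counts = self.classification.counts
        hr_row = self.cox_univariate.table.iloc[0]
        lines = [
            "Risk-group survival validation",
            "==============================",
            f"samples: {len(self.scores)}  "
            f"{HIGH}: {counts[HIGH]}  {LOW}: {counts[LOW]}  "
            f"cutoff: {self.classification.cutoff_used:.4f}",
            f"log-rank: chi2 = {self.logrank.statistic:.3f} "
            f"(df {self.logrank.df}), p = {self.logrank.p_value:.3g}",
            f"univariate Cox ({LOW} vs {HIGH}): HR = {hr_row['hr']:.2f} "
            f"(95% CI {hr_row['ci_lower']:.2f}-{hr_row['ci_upper']:.2f}), "
            f"Wald p = {hr_row['p']:.3g}",
            f"Harrell's c-index: {self.c_index:.3f}",
        ]
        if self.cox_multivariate is not None:
            lines += ["", "multivariate Cox:", self.cox_multivariate.summary()]
        return "\n".join(lines)


def validate_classification(
    scores: pd.Series,
    classification: RiskClassification,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    cutoff_model: CutoffModel | None = None,
) -> ValidationReport:
    """KM / log-rank / Cox / c-index for an S3-high vs S3-low split."""
    records = validate_survival(clinical.loc[scores.index])
    labels = classification.labels
    km = {
        lab: km_estimate(records.loc[labels == lab])
        for lab in (HIGH, LOW)
        if (labels == lab).any()
    }
    lr = logrank_test(records, labels)
    # risk covariate: 1 for the low-similarity (worse prognosis) group,
    # so HR > 1 matches "low score, higher hazard"
    xlow = pd.DataFrame({"s3_low": (labels == LOW).astype(int)}, index=labels.index)
    cox = cox_fit(records, xlow)
    cidx = harrell_c(records, -scores.to_numpy())
    multiv = None
    if covariates is not None and len(covariates) > 0:
        cov = covariates.reindex(records.index).dropna()
        recs = records.loc[cov.index]
        multiv = cox_fit(recs, xlow.loc[cov.index].join(cov))
    return ValidationReport(
        scores=scores,
        classification=classification,
        km_by_group=km,
        logrank=lr,
        cox_univariate=cox,
        c_index=cidx,
        cutoff_model=cutoff_model,
        cox_multivariate=multiv,
    )


def run_score97(
    tumors: ExpressionMatrix,
    refs: ReferenceProfiles,
    clinical: pd.DataFrame,
    cutoff: float | None = None,
    learn_cutoff: bool = False,
    method: str = "spearman",
    aggregation: str = "origin",
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    n_permutations: int = 1000,
) -> ValidationReport:
    """Full-signature workflow: correlation score -> strata -> validation.

    Either a fixed ``cutoff`` is supplied or one is learned from the data
    by maximally-selected log-rank (``learn_cutoff=True``).
    """
    results = S3ScoreModel(tumors, refs, method=method, aggregation=aggregation).fit()
    cutoff_model = None
    if learn_cutoff:
        cutoff_model = find_cutoff(
            results.score,
            clinical.loc[results.score.index],
            seed=seed,
            n_permutations=n_permutations,
        )
        cutoff = cutoff_model.threshold
    if cutoff is None:
        raise ValueError("supply a cutoff or set learn_cutoff=True")
    classification = results.classify(cutoff)
    return validate_classification(
        results.score, classification, clinical, covariates, cutoff_model
    )


# ---------------------------------------------------------------------------
# Signature refinement workflow
# ---------------------------------------------------------------------------

@dataclass
class RefinementResults:
    """Outcome of the 97-gene -> sparse-panel refinement pipeline."""

    model: LinearScoreModel
    failed_assay_report: pd.DataFrame
    comparability_report: pd.DataFrame
    n_signature: int
    n_after_failure_filter: int
    n_candidates: int
    n_selected: int
    holdout_concordance: float | None
    holdout_n: int

    def summary(self) -> str:
        lines = [
            "Signature refinement",
            "====================",
            f"signature genes: {self.n_signature}",
            f"after assay-failure filter: {self.n_after_failure_filter}",
            f"candidates after comparability filter: {self.n_candidates}",
            f"selected model terms: {self.n_selected} "
            f"(method {self.model.training_method}, in-sample R^2 = "
            f"{self.model.training_fit:.3f})",
        ]
        if self.holdout_concordance is not None:
            lines.append(
                f"held-out Spearman concordance with the full score: "
                f"{self.holdout_concordance:.3f} (n = {self.holdout_n})"
            )
        return "\n".join(lines)


class ScoreRefinement:
    """Model-style wrapper for the refinement pipeline.

    Fits on a development cohort (RNA-seq-scale matrix + reference
    profiles); the qRT-PCR cohort supplies the assay-failure and
    comparability filters. ``fit`` holds out a fraction of development
    samples to report concordance between the reduced linear score and
    the full correlation-based score.
    """

    def __init__(
        self,
        dev: ExpressionMatrix,
        refs: ReferenceProfiles,
        qpcr_ct: ExpressionMatrix,
        panel,
        criteria: ComparabilityCriteria | None = None,
        method: str = "stepwise_aic",
        max_terms: int | None = None,
        score_method: str = "spearman",
        aggregation: str = "origin",
    ) -> None:
        self.dev = dev
        self.refs = refs
        self.qpcr_ct = qpcr_ct
        self.panel = panel
        self.criteria = criteria or ComparabilityCriteria()
        self.method = method
        self.max_terms = max_terms
        self.score_method = score_method
        self.aggregation = aggregation

    def fit(
        self,
        holdout_fraction: float = 0.25,
        seed: int = 0,
        validation: ExpressionMatrix | None = None,
    ) -> RefinementResults:
        from .expression import align_genes, normalize_qpcr

        signature = [
            g for g in self.panel.signature_genes if g in self.qpcr_ct.values.index
        ]
        qpcr_sig = align_genes(self.qpcr_ct, signature + [
            g for g in self.panel.normalization_genes
            if g in self.qpcr_ct.values.index
        ])
        sig_only = align_genes(self.qpcr_ct, signature)
        retained, fail_report = filter_failed_assays(sig_only)
        if not retained:
            raise ValueError("assay-failure filter retained no genes")
        qnorm = normalize_qpcr(qpcr_sig, self.panel)
        keep = [g for g in retained if g in qnorm.values.index]
        qnorm_kept = align_genes(qnorm, keep)
        dev_kept = align_genes(self.dev, keep)
        candidates, comp_report = comparability_filter(
            dev_kept, qnorm_kept, self.criteria
        )
        if not candidates:
            raise ValueError("comparability filter retained no genes")

        full_scores = S3ScoreModel(
            self.dev, self.refs, self.score_method, self.aggregation
        ).fit().score

        samples = list(self.dev.sample_ids)
        if validation is not None:
            train_ids, hold = samples, None
        else:
            rng = np.random.default_rng(seed)
            n_hold = int(round(holdout_fraction * len(samples)))
            perm = rng.permutation(len(samples))
            hold = [samples[i] for i in perm[:n_hold]]
            train_ids = [samples[i] for i in perm[n_hold:]]

        X_train = align_genes(self.dev.subset_samples(train_ids), candidates)
        model = select_linear_model(
            X_train, full_scores.loc[train_ids], self.method, self.max_terms
        )
        model.normalization_genes = list(self.panel.normalization_genes)

        conc, n_hold_used = None, 0
        if validation is not None:
            val_scores = S3ScoreModel(
                validation, self.refs, self.score_method, self.aggregation
            ).fit().score
            pred = apply_linear_model(model, validation)
            conc = score_concordance(pred, val_scores).rho
            n_hold_used = len(val_scores)
        elif hold:
            pred = apply_linear_model(model, self.dev.subset_samples(hold))
            conc = score_concordance(pred, full_scores.loc[hold]).rho
            n_hold_used = len(hold)

        return RefinementResults(
            model=model,
            failed_assay_report=fail_report,
            comparability_report=comp_report,
            n_signature=len(signature),
            n_after_failure_filter=len(retained),
            n_candidates=len(candidates),
            n_selected=len(model.coefficients),
            holdout_concordance=conc,
            holdout_n=n_hold_used,
        )


def run_refine(
    dev: ExpressionMatrix,
    refs: ReferenceProfiles,
    qpcr_ct: ExpressionMatrix,
    panel,
    criteria: ComparabilityCriteria | None = None,
    method: str = "stepwise_aic",
    max_terms: int | None = None,
    holdout_fraction: float = 0.25,
    seed: int = 0,
    validation: ExpressionMatrix | None = None,
) -> RefinementResults:
    """Functional entry point for the refinement pipeline."""
    return ScoreRefinement(
        dev, refs, qpcr_ct, panel, criteria, method, max_terms
    ).fit(holdout_fraction=holdout_fraction, seed=seed, validation=validation)


# ---------------------------------------------------------------------------
# Added-value (analysis of deviance) workflow
# ---------------------------------------------------------------------------

def run_improvement_test(
    predictor: pd.Series,
    ssign: pd.Series,
    clinical: pd.DataFrame,
) -> dict[str, LRTResult]:
    """Does the molecular classification add to SSIGN, and vice versa?

    Fits Cox(SSIGN), Cox(predictor), Cox(SSIGN + predictor) on the
    common samples and reports both nested likelihood-ratio comparisons:
    ``predictor_added_to_ssign`` and ``ssign_added_to_predictor``.
    ``predictor`` may be a numeric score or a 0/1 risk-class indicator.
    """
    common = predictor.index.intersection(ssign.index).intersection(clinical.index)
    if len(common) == 0:
        raise ValueError("no common samples between predictors and clinical table")
    records = validate_survival(clinical.loc[common])
    pred = pd.to_numeric(predictor.loc[common])
    ss = pd.to_numeric(ssign.loc[common])
    x_ss = pd.DataFrame({"ssign": ss})
    x_pred = pd.DataFrame({"predictor": pred})
    x_both = pd.DataFrame({"ssign": ss, "predictor": pred})
    fit_ss = cox_fit(records, x_ss)
    fit_pred = cox_fit(records, x_pred)
    fit_both = cox_fit(records, x_both)
    return {
        "predictor_added_to_ssign": lr_test(fit_ss, fit_both),
        "ssign_added_to_predictor": lr_test(fit_pred, fit_both),
    }


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    run_dir: str | Path, command: str, inputs: dict[str, str | Path], config: dict
) -> Path:
    """Write a machine-readable manifest (inputs hashed, config, seed)."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "inputs": {
            k: {"path": str(v), "sha256": _sha256(Path(v))}
            for k, v in inputs.items()
            if v is not None and Path(v).exists()
        },
        "config": config,
    }
    out = run_dir / "manifest.json"
    with open(out, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
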