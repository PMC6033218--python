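"""Cross-platform signature refinement.

Reduces the full correlation-based signature to a small qRT-PCR panel in
three stages, mirroring how a genome-wide score is transferred to a
clinical assay:

1. drop every assay that failed at least once in the qRT-PCR cohort
   (:func:`filter_failed_assays`);
2. keep only genes whose mean and variance of expression are comparable
   between the development platform (RNA-seq) and normalized qRT-PCR
   after per-sample median centering (:func:`comparability_filter`);
3. fit a sparse linear model on the development cohort that reconstructs
   the correlation-based score from the surviving candidate genes
   (:func:`select_linear_model`), by bidirectional stepwise selection
   minimizing AIC (default) or an L1 path sized to a target support.

The selected :class:`LinearScoreModel` is the 15-gene-score analogue: a
plain intercept + weighted sum that can be evaluated on normalized
qRT-PCR measurements of the model genes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, ExpressionError

__all__ = [
    "ComparabilityCriteria",
    "LinearScoreModel",
    "filter_failed_assays",
    "comparability_filter",
    "select_linear_model",
    "apply_linear_model",
    "score_concordance",
]


class RefinementError(ValueError):
    pass


@dataclass
class ComparabilityCriteria:
    """Thresholds for cross-platform comparability of a gene.

    max_mean_shift is in pooled-SD units; max_sd_ratio is the allowed
    larger/smaller SD ratio between platforms.
    """

    max_mean_shift: float = 0.5
    max_sd_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.max_mean_shift <= 0:
            raise RefinementError("max_mean_shift must be positive")
        if self.max_sd_ratio < 1:
            raise RefinementError("max_sd_ratio must be >= 1")


def filter_failed_assays(
    qpcr: ExpressionMatrix,
) -> tuple[list[str], pd.DataFrame]:
    """Retain genes with zero missing values across all samples.

    Returns (retained gene list, report). The report lists every gene
    with its failure count; an empty retained list is valid.
    """
    failures = qpcr.values.isna().sum(axis=1)
    report = pd.DataFrame(
        {"gene": failures.index, "n_failures": failures.to_numpy(dtype=int)}
    ).reset_index(drop=True)
    report["retained"] = report["n_failures"] == 0
    retained = report.loc[report["retained"], "gene"].tolist()
    return retained, report


def _median_center(values: pd.DataFrame) -> pd.DataFrame:
    return values - values.median(axis=0)


def comparability_filter(
    dev: ExpressionMatrix,
    qpcr: ExpressionMatrix,
    criteria: ComparabilityCriteria | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Keep genes comparable in mean and variance across platforms.

    Both matrices are restricted to their shared genes and per-sample
    median-centered (removing platform location offsets). A gene is
    retained iff |mean_dev - mean_qpcr| <= max_mean_shift x pooled SD and
    the SD ratio (larger/smaller) <= max_sd_ratio. Genes with zero SD on
    both platforms are retained and flagged degenerate.
    """
    criteria = criteria or ComparabilityCriteria()
    if dev.n_samples < 3 or qpcr.n_samples < 3:
        raise RefinementError("each platform needs at least 3 samples")
    shared = [g for g in dev.gene_ids if g in qpcr.values.index]
    if not shared:
        raise RefinementError("no shared genes between platforms")
    a = _median_center(dev.values.loc[shared])
    b = _median_center(qpcr.values.loc[shared])

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = a.std(axis=1, ddof=1)
    sd_b = b.std(axis=1, ddof=1)
    n_a, n_b = a.shape[1], b.shape[1]
    pooled = np.sqrt(
        ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    )
    degenerate = (sd_a == 0) & (sd_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.maximum(sd_a, sd_b) / np.minimum(sd_a, sd_b)
        shift_units = (mean_a - mean_b).abs() / pooled
    mean_ok = shift_units <= criteria.max_mean_shift
    sd_ok = ratio <= criteria.max_sd_ratio
    retain = (mean_ok & sd_ok) | degenerate

    report = pd.DataFrame(
        {
            "gene": shared,
            "mean_dev": mean_a,
            "mean_qpcr": mean_b,
            "sd_dev": sd_a,
            "sd_qpcr": sd_b,
            "pooled_sd": pooled,
            "mean_shift_units": shift_units,
            "sd_ratio": ratio,
            "mean_ok": mean_ok | degenerate,
            "sd_ok": sd_ok | degenerate,
            "degenerate": degenerate,
            "retained": retain,
        }
    ).reset_index(drop=True)
    return report.loc[report["retained"], "gene"].tolist(), report


@dataclass
class LinearScoreModel:
    """Sparse linear reconstruction of the correlation-based score.

    score(sample) = intercept + sum_g coefficients[g] * expression(g, sample)
    """

    intercept: float
    coefficients: dict[str, float]
    training_method: str
    training_fit: float  # in-sample R^2
    normalization_genes: list[str] = field(default_factory=list)
    collinear_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise RefinementError("coefficient map must be non-empty")

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "coefficients": self.coefficients,
                    "method": self.training_method,
                    "r2": self.training_fit,
                    "normalization_genes": self.normalization_genes,
                    "collinear_genes": self.collinear_genes,
                },
                fh,
                indent=1,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearScoreModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            intercept=d["intercept"],
            coefficients=dict(d["coefficients"]),
            training_method=d.get("method", "unknown"),
            training_fit=d.get("r2", float("nan")),
            normalization_genes=list(d.get("normalization_genes", [])),
            collinear_genes=list(d.get("collinear_genes", [])),
        )


def _design(X: ExpressionMatrix, genes: Sequence[str]) -> np.ndarray:
    """Samples x (1 + genes) design matrix with intercept column."""
    block = X.values.loc[list(genes)].to_numpy(dtype=float).T
    return np.column_stack([np.ones(block.shape[0]), block])


def _rss(design: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, int]:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef, int(rank)


def _aic(rss: float, n: int, k_params: int, criterion: str = "aic", p: int = 1) -> float:
    # Gaussian profile log-likelihood form; constant terms omitted
    # (only differences matter for selection). "ebic" adds the extended-BIC
    # term 2*k*log(p) (gamma = 1), which is selection-consistent when the
    # candidate pool is large relative to the true support.
    ll = n * np.log(max(rss, 1e-300) / n)
    if criterion == "aic":
        return ll + 2 * k_params
    if criterion == "bic":
        return ll + k_params * np.log(n)
    if criterion == "ebic":
        return ll + k_params * np.log(n) + 2 * k_params * np.log(max(p, 1))
    raise RefinementError(f"unknown selection criterion {criterion!r}")


def select_linear_model(
    X: ExpressionMatrix,
    y: pd.Series,
    method: str = "stepwise_aic",
    max_terms: int | None = None,
    criterion: str = "aic",
) -> LinearScoreModel:
    """Select a sparse linear model of ``y`` on the genes of ``X``.

    ``stepwise_aic`` (default): bidirectional stepwise selection starting
    from the empty (intercept-only) model, minimizing the chosen
    information criterion (``criterion``: "aic" default, "bic", or
    "ebic"); if ``max_terms`` is set, the support never exceeds it. Plain
    AIC favours predictive fit and will admit occasional spurious terms
    when many pure-noise candidates are offered; "ebic" trades a little
    fit for consistent support recovery in that regime. ``lasso_path``:
    least-angle lasso path, taking the largest support of size
    <= max_terms (or the AIC-best point on the path when max_terms is
    None), followed by an unpenalized refit on the support.

    Genes exactly collinear with the current support are reported on the
    returned model (``collinear_genes``), never silently dropped.
    """
    genes = X.gene_ids
    if len(genes) < 1:
        raise RefinementError("no candidate genes")
    y = y.reindex(X.sample_ids)
    if y.isna().any():
        raise RefinementError("response missing for some samples of X")
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    if method == "stepwise_aic" and n <= len(genes) and max_terms is None:
        raise RefinementError(
            "stepwise selection needs more samples than candidate genes "
            "(or a max_terms bound)"
        )
    if X.values.isna().any().any():
        raise RefinementError("candidate matrix contains missing values")

    collinear: set[str] = set()
    if method == "stepwise_aic":
        support: list[str] = []
        n_cand = len(genes)
        rss0, _, _ = _rss(np.ones((n, 1)), yv)
        best_aic = _aic(rss0, n, 1, criterion, n_cand)
        while True:
            moves: list[tuple[float, str, str]] = []
            if max_terms is None or len(support) < max_terms:
                for g in genes:
                    if g in support:
                        continue
                    d = _design(X, support + [g])
                    rss, _, rank = _rss(d, yv)
                    if rank < d.shape[1]:
                        collinear.add(g)
                        continue
                    moves.append((_aic(rss, n, d.shape[1], criterion, n_cand), "add", g))
            for g in support:
                rest = [s for s in support if s != g]
                d = _design(X, rest)
                rss, _, _ = _rss(d, yv)
                moves.append((_aic(rss, n, d.shape[1], criterion, n_cand), "drop", g))
            if not moves:
                break
            aic_new, action, gene = min(moves, key=lambda m: m[0])
            if aic_new < best_aic - 1e-10:
                best_aic = aic_new
                if action == "add":
                    support.append(gene)
                else:
                    support.remove(gene)
            else:
                break
        if not support:
            raise RefinementError("stepwise selection retained no genes")
    elif method == "lasso_path":
        from sklearn.linear_model import lars_path

        block = X.values.to_numpy(dtype=float).T
        mu, sd = block.mean(axis=0), block.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (block - mu) / sd
        yc = yv - yv.mean()
        alphas, _, coefs = lars_path(Xs, yc, method="lasso")
        supports = [np.flatnonzero(coefs[:, j]) for j in range(coefs.shape[1])]
        if max_terms is not None:
            sizes = np.array([len(s) for s in supports])
            ok = np.flatnonzero(sizes <= max_terms)
            j = ok[np.argmax(sizes[ok])]
        else:
            aics = []
            for sup in supports:
                if len(sup) == 0:
                    rss, _, _ = _rss(np.ones((n, 1)), yv)
                    aics.append(_aic(rss, n, 1))
                else:
                    d = _design(X, [genes[i] for i in sup])
                    rss, _, _ = _rss(d, yv)
                    aics.append(_aic(rss, n, d.shape[1]))
            j = int(np.argmin(aics))
        support = [genes[i] for i in supports[j]]
        if not support:
            raise RefinementError("lasso path retained no genes")
    else:
        raise RefinementError(f"unknown selection method {method!r}")

    d = _design(X, support)
    rss, coef, rank = _rss(d, yv)
    if rank < d.shape[1]:
        raise RefinementError(
            f"selected design is rank-deficient (support {support})"
        )
    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    if collinear:
        warnings.warn(
            f"candidates collinear with the selected support were excluded "
            f"from moves and are reported on the model: {sorted(collinear)}",
            stacklevel=2,
        )
    return LinearScoreModel(
        intercept=float(coef[0]),
        coefficients={g: float(c) for g, c in zip(support, coef[1:])},
        training_method=(method if method != "stepwise_aic" else f"stepwise_{criterion}"),
        training_fit=float(r2),
        collinear_genes=sorted(collinear),
    )


def apply_linear_model(model: LinearScoreModel, m: ExpressionMatrix) -> pd.Series:
    """Evaluate the linear score on a matrix (all model genes required)."""
    absent = [g for g in model.genes if g not in m.values.index]
    if absent:
        raise RefinementError(f"model genes absent from matrix: {absent}")
    block = m.values.loc[model.genes]
    if block.isna().any().any():
        bad = block.index[block.isna().any(axis=1)].tolist()
        raise RefinementError(f"model genes with missing values: {bad}")
    w = np.array([model.coefficients[g] for g in model.genes])
    scores = model.intercept + block.to_numpy(dtype=float).T @ w
    return pd.Series(scores, index=m.sample_ids, name="linear_score")


@dataclass
class ConcordanceResult:
    rho: float
    n: int
    mean_abs_diff: float

    def __iter__(self):  # allow tuple-unpacking (rho, n)
        yield self.rho
        yield self.n


def score_concordance(a: pd.Series, b: pd.Series) -> ConcordanceResult:
    """Spearman rank concordance between two scorings of the same samples."""
    if set(a.index) != set(b.index):
        raise RefinementError("mismatched sample sets")
    if len(a) < 3:
        raise RefinementError("need at least 3 samples")
    b = b.reindex(a.index)
    rho, _ = stats.spearmanr(a.to_numpy(), b.to_numpy())
    return ConcordanceResult(
        rho=float(rho), n=len(a), mean_abs_diff=float((a - b).abs().mean())
    )
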