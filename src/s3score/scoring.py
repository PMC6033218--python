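"""Cell-of-origin similarity scoring.

The S3 score quantifies how closely a ccRCC tumor's expression profile
resembles the expression profile of its proposed cell of origin, the S3
segment of the proximal tubule. Each tumor is correlated, over a panel
of signature genes, against reference expression profiles of the eight
nephron regions; the score aggregates these interprofile correlations
(by default, the correlation with the designated origin region). Tumors
are then split into S3-high (more origin-like, better prognosis) and
S3-low strata at a score cut-off.

The class :class:`S3ScoreModel` presents this as a fit/results pair;
the module-level functions are the underlying operations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, ExpressionError

__all__ = [
    "ReferenceProfiles",
    "S3ScoreResults",
    "RiskClassification",
    "S3ScoreModel",
    "interprofile_correlations",
    "s3_score",
    "classify_risk",
]

CORRELATION_METHODS = ("spearman", "pearson")
AGGREGATIONS = ("origin", "origin_margin")
MIN_SHARED_GENES = 3

HIGH, LOW = "S3_high", "S3_low"


class ScoringError(ValueError):
    pass


@dataclass
class ReferenceProfiles:
    """Gene-by-region reference expression profiles of the nephron.

    ``values`` is a genes x regions DataFrame (log2 scale, no missing
    values); ``origin_region`` names the column taken as the tumor's
    cell of origin.
    """

    values: pd.DataFrame
    origin_region: str

    def __post_init__(self) -> None:
        if self.origin_region not in self.values.columns:
            raise ScoringError(
                f"origin region {self.origin_region!r} not among regions "
                f"{list(self.values.columns)}"
            )
        if self.values.isna().any().any():
            raise ScoringError("reference profiles contain missing values")
        if self.values.shape[0] < MIN_SHARED_GENES:
            raise ScoringError("reference profiles need at least 3 genes")
        if self.values.index.duplicated().any():
            raise ScoringError("duplicate gene identifiers in reference profiles")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_labels(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_files(cls, table: str | Path, sidecar: str | Path) -> "ReferenceProfiles":
        """Load from a gene x region TSV plus a JSON naming origin_region."""
        df = pd.read_csv(table, sep="\t", index_col=0)
        with open(sidecar) as fh:
            meta = json.load(fh)
        return cls(df, meta["origin_region"])

    def to_files(self, table: str | Path, sidecar: str | Path) -> None:
        self.values.to_csv(table, sep="\t", float_format="%.12g")
        with open(sidecar, "w") as fh:
            json.dump({"origin_region": self.origin_region}, fh)
            fh.write("\n")


def _rank_or_raw(a: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        return np.apply_along_axis(stats.rankdata, 0, a)
    return a


def _standardize_cols(a: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=0, keepdims=True)
    sd = a.std(axis=0, keepdims=True, ddof=0)
    if np.any(sd == 0):
        raise ScoringError("constant profile: correlation undefined")
    return a / sd


def interprofile_correlations(
    tumors: ExpressionMatrix,
    refs: ReferenceProfiles,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate every tumor against every nephron-region profile.

    Returns a samples x regions DataFrame of correlation coefficients
    computed over the genes shared between ``tumors`` and ``refs``.
    Samples with missing values fall back to pairwise-complete genes
    (error if fewer than 3 remain).
    """
    if method not in CORRELATION_METHODS:
        raise ScoringError(f"unknown correlation method {method!r}")
    shared = [g for g in refs.gene_ids if g in tumors.values.index]
    if len(shared) < MIN_SHARED_GENES:
        raise ScoringError(
            f"only {len(shared)} genes shared between tumors and references; need >=3"
        )
    t = tumors.values.loc[shared]
    r = refs.values.loc[shared].to_numpy()
    out = np.empty((t.shape[1], r.shape[1]))

    tv = t.to_numpy()
    complete = ~np.isnan(tv).any(axis=0)
    r_std = _standardize_cols(_rank_or_raw(r, method))

    for j, sample in enumerate(t.columns):
        col = tv[:, j]
        if complete.all() or not np.isnan(col).any():
            x, rr = col, r_std
            n = len(x)
        else:
            keep = ~np.isnan(col)
            if keep.sum() < MIN_SHARED_GENES:
                raise ScoringError(
                    f"sample {sample!r}: fewer than 3 non-missing shared genes"
                )
            x = col[keep]
            rr = _standardize_cols(_rank_or_raw(r[keep], method))
            n = keep.sum()
        if np.all(x == x[0]):
            raise ScoringError(f"sample {sample!r}: constant profile on shared genes")
        xs = _standardize_cols(_rank_or_raw(x[:, None], method))[:, 0]
        out[j] = xs @ rr / n

    return pd.DataFrame(
        np.clip(out, -1.0, 1.0), index=list(t.columns), columns=refs.region_labels
    )


def s3_score(
    correlations: pd.DataFrame,
    refs: ReferenceProfiles,
    aggregation: str = "origin",
) -> pd.Series:
    """Aggregate region correlations to one score per sample.

    ``origin``: the correlation with the designated cell-of-origin region.
    ``origin_margin``: correlation with the origin minus the maximum
    correlation over the other regions.
    """
    if aggregation not in AGGREGATIONS:
        raise ScoringError(f"unknown aggregation {aggregation!r}")
    if refs.origin_region not in correlations.columns:
        raise ScoringError(
            f"origin region {refs.origin_region!r} missing from correlation matrix"
        )
    origin = correlations[refs.origin_region]
    if aggregation == "origin":
        score = origin.copy()
    else:
        others = correlations.drop(columns=[refs.origin_region])
        score = origin - others.max(axis=1)
    score.name = "s3_score"
    return score


@dataclass
class RiskClassification:
    """S3-high / S3-low strata at a score cut-off (high iff score > cutoff)."""

    labels: pd.Series
    cutoff_used: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def counts(self) -> dict[str, int]:
        c = self.labels.value_counts()
        return {HIGH: int(c.get(HIGH, 0)), LOW: int(c.get(LOW, 0))}


def classify_risk(scores: pd.Series, cutoff: float) -> RiskClassification:
    """Split samples at ``cutoff``: score > cutoff -> S3_high, else S3_low."""
    if not np.isfinite(cutoff):
        raise ScoringError("cutoff must be finite")
    if scores.isna().any():
        bad = scores.index[scores.isna()].tolist()
        raise ScoringError(f"missing score for samples: {bad}")
    labels = pd.Series(
        np.where(scores > cutoff, HIGH, LOW), index=scores.index, name="risk_group"
    )
    return RiskClassification(labels, float(cutoff))


@dataclass
class S3ScoreResults:
    """Fitted interprofile correlations and scores for a cohort."""

    correlations: pd.DataFrame
    score: pd.Series
    method: str
    aggregation: str
    origin_region: str

    @property
    def sample_ids(self) -> list[str]:
        return list(self.score.index)

    def classify(self, cutoff: float) -> RiskClassification:
        return classify_risk(self.score, cutoff)

    def summary(self) -> str:
        s = self.score
        lines = [
            "S3 score results",
            "================",
            f"samples: {len(s)}   correlation: {self.method}   "
            f"aggregation: {self.aggregation}   origin: {self.origin_region}",
            f"score: min {s.min():.3f}  median {s.median():.3f}  max {s.max():.3f}",
        ]
        return "\n".join(lines)

    def to_files(self, table: str | Path, meta: str | Path) -> None:
        out = self.correlations.copy()
        out["s3_score"] = self.score
        out.index.name = "sample_id"
        out.to_csv(table, sep="\t", float_format="%.10g")
        with open(meta, "w") as fh:
            json.dump(
                {
                    "method": self.method,
                    "aggregation": self.aggregation,
                    "origin_region": self.origin_region,
                },
                fh,
            )
            fh.write("\n")


class S3ScoreModel:
    """Similarity-scoring model: tumors vs nephron reference profiles.

    Parameters
    ----------
    tumors
        Expression matrix of the cohort (any log-scale platform or
        normalized qPCR).
    refs
        Nephron-region reference profiles with a designated origin region.
    method
        Correlation method, ``spearman`` (default; robust to
        cross-platform scale differences) or ``pearson``.
    aggregation
        ``origin`` (default) or ``origin_margin``.
    """

    def __init__(
        self,
        tumors: ExpressionMatrix,
        refs: ReferenceProfiles,
        method: str = "spearman",
        aggregation: str = "origin",
    ) -> None:
        self.tumors = tumors
        self.refs = refs
        self.method = method
        self.aggregation = aggregation

    def fit(self) -> S3ScoreResults:
        corr = interprofile_correlations(self.tumors, self.refs, self.method)
        score = s3_score(corr, self.refs, self.aggregation)
        return S3ScoreResults(
            correlations=corr,
            score=score,
            method=self.method,
            aggregation=self.aggregation,
            origin_region=self.refs.origin_region,
        )
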