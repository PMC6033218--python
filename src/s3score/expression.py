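"""Expression-matrix containers and I/O.

Everything downstream of this module works on an :class:`ExpressionMatrix`,
a genes-by-samples numeric matrix tagged with the measurement platform.
Three input platforms are supported:

``rnaseq_log``
    log2-scale RNA-seq expression (e.g. log2(count + 1)).
``microarray_log``
    log2-scale microarray intensities.
``qpcr_ct``
    raw qRT-PCR threshold-cycle (Ct) values; *lower* Ct means *more*
    transcript. :func:`normalize_qpcr` converts these to log2-scale
    relative expression (platform ``qpcr_norm``) by the standard delta-Ct
    rule against a panel of reference ("housekeeping") genes.

The internal orientation is fixed: genes in rows, samples in columns.
Missing measurements are carried explicitly as NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PLATFORMS",
    "ExpressionMatrix",
    "GenePanel",
    "read_expression_table",
    "write_expression_table",
    "normalize_qpcr",
    "log_transform_counts",
    "align_genes",
]

#: Recognised platform tags. ``qpcr_norm`` is produced by
#: :func:`normalize_qpcr`, never read directly from an instrument export.
PLATFORMS = ("rnaseq_log", "microarray_log", "qpcr_ct", "qpcr_norm")

#: Plausible instrument range for raw Ct values.
CT_RANGE = (0.0, 45.0)

#: Missing-value tokens accepted on input (case-insensitive), in addition
#: to empty cells.
NA_TOKENS = ("NA", "NaN", "nan", "na", "N/A", "n/a", "")


class ExpressionError(ValueError):
    """Raised for malformed expression inputs."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    seen: set = set()
    dupes = sorted({i for i in ids if i in seen or seen.add(i)})
    if dupes:
        raise ExpressionError(f"duplicate {what} identifiers: {dupes}")


@dataclass
class ExpressionMatrix:
    """Genes-by-samples expression matrix with a platform tag.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as index and sample identifiers
        as columns. NaN marks a missing measurement.
    platform
        One of :data:`PLATFORMS`.
    """

    values: pd.DataFrame
    platform: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ExpressionError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        if self.platform == "qpcr_ct":
            vals = self.values.to_numpy()
            finite = vals[np.isfinite(vals)]
            lo, hi = CT_RANGE
            if finite.size and (finite.min() < lo or finite.max() > hi):
                raise ExpressionError(
                    f"Ct values outside the plausible range [{lo}, {hi}]: "
                    f"min={finite.min():.3g}, max={finite.max():.3g}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.platform)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ExpressionError(f"samples not present: {missing}")
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.platform)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"platform={self.platform!r})"
        )


@dataclass
class GenePanel:
    """Signature and normalization gene lists for a qRT-PCR panel."""

    signature_genes: list[str] = field(default_factory=list)
    normalization_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.signature_genes) & set(self.normalization_genes)
        if overlap:
            raise ExpressionError(
                f"signature and normalization gene lists overlap: {sorted(overlap)}"
            )
        _check_unique(self.signature_genes, "signature gene")
        _check_unique(self.normalization_genes, "normalization gene")

    @classmethod
    def from_json(cls, path: str | Path) -> "GenePanel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            signature_genes=list(d.get("signature_genes", [])),
            normalization_genes=list(d.get("normalization_genes", [])),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "signature_genes": self.signature_genes,
                    "normalization_genes": self.normalization_genes,
                },
                fh,
                indent=1,
            )
            fh.write("\n")


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    platform: str,
    sep: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a delimited gene-by-sample table.

    The first column holds gene identifiers and the header row sample
    identifiers. Unparseable cells (and the tokens in :data:`NA_TOKENS`)
    become missing values. Duplicate gene or sample identifiers are an
    error, as is a header that looks entirely numeric (a sign the file
    has no header row).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path, sep),
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    if df.shape[1] == 0:
        raise ExpressionError(f"{path}: no sample columns found")

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if all(_numeric(str(c)) for c in df.columns):
        raise ExpressionError(
            f"{path}: header row is entirely numeric; expected sample identifiers"
        )
    _check_unique(df.index.astype(str), "gene")
    _check_unique(df.columns.astype(str), "sample")
    na = {t.lower() for t in NA_TOKENS}
    cleaned = df.apply(
        lambda col: pd.to_numeric(
            col.map(lambda x: np.nan if str(x).strip().lower() in na else x),
            errors="coerce",
        )
    )
    if transpose:
        cleaned = cleaned.T
    return ExpressionMatrix(cleaned, platform)


def write_expression_table(
    m: ExpressionMatrix, path: str | Path, sep: str | None = None
) -> None:
    """Write a matrix as a delimited table (round-trips values to 1e-9)."""
    path = Path(path)
    m.values.to_csv(path, sep=_sep_for(path, sep), na_rep="NA", float_format="%.12g")


def normalize_qpcr(ct: ExpressionMatrix, panel: GenePanel) -> ExpressionMatrix:
    """Delta-Ct normalization of raw Ct values against reference genes.

    Per sample, ``expression(g) = mean(Ct of normalization genes) - Ct(g)``,
    so the result is log2-scale relative expression with higher values
    meaning more transcript. The arithmetic mean of Ct values equals the
    geometric mean of the linear quantities, the standard delta-Ct
    convention. Normalization genes are dropped from the output; missing
    target Ct values stay missing.
    """
    if ct.platform != "qpcr_ct":
        raise ExpressionError(f"normalize_qpcr expects platform qpcr_ct, got {ct.platform}")
    norm = panel.normalization_genes
    if not norm:
        raise ExpressionError("normalization gene list is empty")
    absent = [g for g in norm if g not in ct.values.index]
    if absent:
        raise ExpressionError(f"normalization genes absent from matrix: {absent}")
    ref_block = ct.values.loc[norm]
    if ref_block.isna().any().any():
        bad = ref_block.columns[ref_block.isna().any(axis=0)].tolist()
        raise ExpressionError(
            f"normalization genes have missing Ct in samples: {bad}"
        )
    ref = ref_block.mean(axis=0)  # per-sample mean of reference Ct
    out = ct.values.drop(index=[g for g in norm if g in ct.values.index])
    normalized = ref - out  # broadcast over rows
    return ExpressionMatrix(normalized, "qpcr_norm")


def log_transform_counts(
    raw: ExpressionMatrix, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Map non-negative values to log2(value + pseudocount)."""
    if pseudocount <= 0:
        raise ExpressionError("pseudocount must be positive")
    vals = raw.values.to_numpy()
    if np.nanmin(vals) < 0:
        raise ExpressionError("negative values cannot be log-transformed")
    return ExpressionMatrix(np.log2(raw.values + pseudocount), "rnaseq_log")


def align_genes(m: ExpressionMatrix, genes: Sequence[str]) -> ExpressionMatrix:
    """Subset and order rows to ``genes``; error naming any absent gene."""
    genes = list(genes)
    absent = [g for g in genes if g not in m.values.index]
    if absent:
        raise ExpressionError(f"requested genes absent from matrix: {absent}")
    return ExpressionMatrix(m.values.loc[genes], m.platform)
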