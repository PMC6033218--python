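"""Comparator classifiers: SSIGN, centroid subtyping, and
primary/metastasis concordance.

SSIGN (Stage, Size, Grade and Necrosis) is a clinicopathological point
score for ccRCC outcome; the point table ships as editable JSON config
with a provenance note (see ``data/ssign_table.json``). The centroid
classifier is the two-class (ccA/ccB-style) nearest-centroid scheme:
each sample is assigned the class whose centroid it correlates with
best. Concordance analysis asks whether all samples of a patient
(primary tumor, metastases, multi-region metastasis samples) fall in the
same risk class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = [
    "SSIGNTable",
    "load_default_ssign",
    "ssign_score",
    "ssign_scores",
    "CentroidModel",
    "load_example_centroids",
    "centroid_classify",
    "ConcordancePair",
    "concordance_analysis",
]


class ComparatorError(ValueError):
    pass


@dataclass
class SSIGNTable:
    """Point assignments for the SSIGN score components.

    Keys of the category maps are strings ("1", "2", ...); tumor size is
    scored by a threshold in cm. ``bins`` maps risk-stratum labels to
    inclusive (lo, hi) score ranges.
    """

    t_points: dict[str, int]
    n_points: dict[str, int]
    m_points: dict[str, int]
    grade_points: dict[str, int]
    necrosis_points: dict[str, int]
    size_threshold_cm: float
    size_points_below: int
    size_points_at_or_above: int
    bins: dict[str, tuple[int, int]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for m in (
            self.t_points,
            self.n_points,
            self.m_points,
            self.grade_points,
            self.necrosis_points,
        ):
            if any(v < 0 for v in m.values()):
                raise ComparatorError("SSIGN points must be non-negative")
        if min(self.size_points_below, self.size_points_at_or_above) < 0:
            raise ComparatorError("SSIGN points must be non-negative")

    @classmethod
    def from_json(cls, path: str | Path) -> "SSIGNTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            t_points={str(k): int(v) for k, v in d["t_points"].items()},
            n_points={str(k): int(v) for k, v in d["n_points"].items()},
            m_points={str(k): int(v) for k, v in d["m_points"].items()},
            grade_points={str(k): int(v) for k, v in d["grade_points"].items()},
            necrosis_points={str(k): int(v) for k, v in d["necrosis_points"].items()},
            size_threshold_cm=float(d["size_threshold_cm"]),
            size_points_below=int(d["size_points_below"]),
            size_points_at_or_above=int(d["size_points_at_or_above"]),
            bins={k: tuple(v) for k, v in d["bins"].items()},
            provenance=d.get("provenance", ""),
        )


def load_default_ssign() -> SSIGNTable:
    """The packaged default SSIGN point table (editable JSON config)."""
    ref = resources.files("s3score").joinpath("data/ssign_table.json")
    with resources.as_file(ref) as path:
        return SSIGNTable.from_json(path)


def _norm_level(value, prefix: str) -> str:
    if pd.isna(value):
        return ""
    s = str(value).strip().upper()
    if s.startswith(prefix.upper()):
        s = s[len(prefix):]
    return s


def ssign_score(
    T, N, M, grade, necrosis, size_cm, table: SSIGNTable
) -> tuple[int, str]:
    """Score one tumor: sum of table points, plus the risk stratum.

    Every feature must be present and not "X"; violations raise with the
    offending feature names.
    """
    missing = []
    t = _norm_level(T, "T")
    n = _norm_level(N, "N")
    m = _norm_level(M, "M")
    g = _norm_level(grade, "G")
    nec = "" if pd.isna(necrosis) else str(necrosis).strip().lower()
    if t not in table.t_points:
        missing.append(f"T={T!r}")
    if n not in table.n_points:
        missing.append(f"N={N!r}")
    if m not in table.m_points:
        missing.append(f"M={M!r}")
    if g not in table.grade_points:
        missing.append(f"G={grade!r}")
    if nec not in table.necrosis_points:
        missing.append(f"necrosis={necrosis!r}")
    if size_cm is None or (isinstance(size_cm, float) and np.isnan(size_cm)):
        missing.append("size_cm missing")
    if missing:
        raise ComparatorError(f"SSIGN features missing or unscorable: {missing}")
    score = (
        table.t_points[t]
        + table.n_points[n]
        + table.m_points[m]
        + table.grade_points[g]
        + table.necrosis_points[nec]
        + (
            table.size_points_at_or_above
            if float(size_cm) >= table.size_threshold_cm
            else table.size_points_below
        )
    )
    stratum = "unbinned"
    for label, (lo, hi) in table.bins.items():
        if lo <= score <= hi:
            stratum = label
            break
    return int(score), stratum


def ssign_scores(
    clinical: pd.DataFrame, table: SSIGNTable | None = None
) -> pd.DataFrame:
    """Vectorized convenience: SSIGN score + stratum per clinical row."""
    table = table or load_default_ssign()
    rows = {}
    for sid, row in clinical.iterrows():
        score, stratum = ssign_score(
            row.get("T"),
            row.get("N"),
            row.get("M"),
            row.get("G"),
            row.get("necrosis"),
            row.get("size_cm"),
            table,
        )
        rows[sid] = {"ssign": score, "stratum": stratum}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Centroid classifier
# ---------------------------------------------------------------------------

@dataclass
class CentroidModel:
    """Two-class nearest-centroid classifier on a fixed gene list."""

    centroids: pd.DataFrame  # genes x 2 classes
    method: str = "pearson"

    def __post_init__(self) -> None:
        if self.centroids.shape[1] != 2:
            raise ComparatorError("centroid model needs exactly two class centroids")
        if self.centroids.isna().any().any():
            raise ComparatorError("centroids contain missing values")

    @property
    def genes(self) -> list[str]:
        return list(self.centroids.index)

    @property
    def class_labels(self) -> list[str]:
        return list(self.centroids.columns)

    @classmethod
    def from_json(cls, path: str | Path) -> "CentroidModel":
        with open(path) as fh:
            d = json.load(fh)
        df = pd.DataFrame(d["centroids"])
        return cls(centroids=df, method=d.get("method", "pearson"))


def load_example_centroids() -> CentroidModel:
    """A synthetic example centroid config (schema demonstration only).

    The published two-class ccA/ccB centroid values live in the cited
    classifier's supplement and are user-supplied config; this packaged
    file carries synthetic values for testing the machinery.
    """
    ref = resources.files("s3score").joinpath("data/centroids_synthetic_example.json")
    with resources.as_file(ref) as path:
        return CentroidModel.from_json(path)


def centroid_classify(
    m: ExpressionMatrix, model: CentroidModel, tie_tol: float = 1e-12
) -> pd.DataFrame:
    """Assign each sample the class of its best-correlated centroid.

    Returns a DataFrame (sample x [class, confidence, corr_<label>...]);
    confidence is the correlation difference, and an exact tie (within
    ``tie_tol``) yields class "unclassified".
    """
    absent = [g for g in model.genes if g not in m.values.index]
    if absent:
        raise ComparatorError(f"centroid genes absent from matrix: {absent}")
    block = m.values.loc[model.genes]
    if block.isna().any().any():
        raise ComparatorError("centroid genes contain missing values")
    labels = model.class_labels
    corrs = np.empty((block.shape[1], 2))
    for j, lab in enumerate(labels):
        c = model.centroids[lab].to_numpy(dtype=float)
        for i, sid in enumerate(block.columns):
            x = block[sid].to_numpy(dtype=float)
            if model.method == "spearman":
                r, _ = stats.spearmanr(x, c)
            else:
                r, _ = stats.pearsonr(x, c)
            corrs[i, j] = r
    diff = corrs[:, 0] - corrs[:, 1]
    cls = np.where(diff > 0, labels[0], labels[1])
    cls = np.where(np.abs(diff) <= tie_tol, "unclassified", cls)
    out = pd.DataFrame(
        {
            "class": cls,
            "confidence": np.abs(diff),
            f"corr_{labels[0]}": corrs[:, 0],
            f"corr_{labels[1]}": corrs[:, 1],
        },
        index=list(block.columns),
    )
    out.loc[out["class"] == "unclassified", "confidence"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Primary / metastasis concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordancePair:
    patient_id: str
    sample_ids: list[str]
    roles: list[str]
    classes: list[str]
    scores: list[float]
    concordant: bool

    @property
    def score_range(self) -> float:
        return float(max(self.scores) - min(self.scores))


def concordance_analysis(
    table: pd.DataFrame,
) -> tuple[list[ConcordancePair], pd.DataFrame, dict]:
    """Per-patient class concordance across tissue roles.

    ``table`` needs columns patient_id, sample_id, role, score, class.
    A patient is concordant iff all their samples share one class.
    Patients with a single sample are skipped and reported.

    Returns (pairs, skipped-patient report, summary dict with n_patients,
    n_concordant, concordance_fraction).
    """
    required = {"patient_id", "sample_id", "role", "score", "class"}
    if not required <= set(table.columns):
        raise ComparatorError(f"concordance table needs columns {sorted(required)}")
    pairs: list[ConcordancePair] = []
    skipped = []
    for pid, grp in table.groupby("patient_id", sort=True):
        if len(grp) < 2:
            skipped.append((pid, "single sample"))
            continue
        classes = grp["class"].tolist()
        pairs.append(
            ConcordancePair(
                patient_id=str(pid),
                sample_ids=grp["sample_id"].tolist(),
                roles=grp["role"].tolist(),
                classes=classes,
                scores=[float(s) for s in grp["score"]],
                concordant=len(set(classes)) == 1,
            )
        )
    summary = {
        "n_patients": len(pairs),
        "n_concordant": sum(p.concordant for p in pairs),
        "concordance_fraction": (
            sum(p.concordant for p in pairs) / len(pairs) if pairs else float("nan")
        ),
        "max_within_patient_range": (
            max((p.score_range for p in pairs), default=float("nan"))
        ),
    }
    report = pd.DataFrame(skipped, columns=["patient_id", "reason"])
    return pairs, report, summary
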