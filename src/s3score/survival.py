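"""Survival machinery for score validation.

Kaplan-Meier estimation, the log-rank test, Cox proportional-hazards
fits (Efron ties via lifelines; Breslow ties via an in-package Newton
solver on the Breslow partial likelihood), Harrell's concordance index,
analysis of deviance for nested Cox models, clinical covariate
recoding/filtering, and survival-driven cut-off discovery by a
maximally-selected log-rank statistic with a permutation-adjusted
selection p-value (a depth-1 conditional-inference split).

Survival data are carried as a pandas DataFrame with columns ``time``
(years, > 0) and ``event`` (1 = event, 0 = censored), indexed by sample
identifier; an optional ``endpoint`` column records CSS, PFS or OS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats

__all__ = [
    "validate_survival",
    "read_clinical_table",
    "KMCurve",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "CoxFit",
    "cox_fit",
    "harrell_c",
    "LRTResult",
    "lr_test",
    "CutoffModel",
    "find_cutoff",
    "CutoffSearch",
    "recode_covariates",
]

ENDPOINTS = ("CSS", "PFS", "OS")


class SurvivalError(ValueError):
    pass


def validate_survival(records: pd.DataFrame) -> pd.DataFrame:
    """Check a survival table: time > 0, event in {0, 1}."""
    if len(records) == 0:
        raise SurvivalError("empty survival table")
    for col in ("time", "event"):
        if col not in records.columns:
            raise SurvivalError(f"survival table lacks column {col!r}")
    if (records["time"] <= 0).any() or records["time"].isna().any():
        raise SurvivalError("survival times must be positive and non-missing")
    if not records["event"].isin([0, 1]).all():
        raise SurvivalError("event indicator must be 0 (censored) or 1 (event)")
    return records


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical CSV (sample_id, time_years, event, endpoint, T, N,
    M, G, necrosis, size_cm) into a validated survival/covariate table."""
    df = pd.read_csv(path, dtype={"T": str, "N": str, "M": str, "G": str})
    if "sample_id" not in df.columns:
        raise SurvivalError("clinical table lacks sample_id column")
    df = df.set_index("sample_id")
    df = df.rename(columns={"time_years": "time"})
    validate_survival(df)
    return df


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve: step function with at-risk counts."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.timeline, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    records = validate_survival(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(timeline).ffill().to_numpy(dtype=float)
    )
    return KMCurve(
        timeline=timeline,
        survival=surv,
        at_risk=at_risk.astype(int),
        n=len(records),
        n_events=int(records["event"].sum()),
    )


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    group_sizes: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)
            fh.write("\n")


def logrank_test(records: pd.DataFrame, groups: Sequence) -> LogrankResult:
    """K-sample log-rank test (chi-square with k-1 df)."""
    records = validate_survival(records)
    groups = pd.Series(np.asarray(groups), index=records.index)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise SurvivalError("log-rank test needs at least two non-empty groups")
    if (sizes == 0).any():
        raise SurvivalError("log-rank test: empty group")
    res = multivariate_logrank_test(records["time"], groups, records["event"])
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=int(len(sizes) - 1),
        p_value=float(res.p_value),
        group_sizes={str(k): int(v) for k, v in sizes.items()},
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Cox model fit: per-covariate estimates plus model-level quantities.

    ``table`` has one row per covariate with columns coef, se, hr,
    ci_lower, ci_upper, p (Wald).
    """

    table: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    ties: str
    strata: list[str] | None = None
    covariates: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Cox proportional hazards fit",
            "============================",
            f"n = {self.n}   events = {self.n_events}   ties = {self.ties}"
            + (f"   strata = {self.strata}" if self.strata else ""),
            f"partial log-likelihood = {self.log_likelihood:.4f}",
            "",
            self.table.to_string(float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "table": self.table.to_dict(orient="index"),
                    "log_likelihood": self.log_likelihood,
                    "n": self.n,
                    "n_events": self.n_events,
                    "ties": self.ties,
                    "strata": self.strata,
                },
                fh,
                indent=1,
            )
            fh.write("\n")


def _breslow_newton(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton-Raphson on the Breslow partial likelihood (single stratum).

    Returns (beta, inverse Hessian, log partial likelihood).
    """
    n, p = X.shape
    order = np.argsort(-time, kind="mergesort")  # decreasing time
    X = X[order]
    time = time[order]
    event = event[order]
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        w = np.exp(eta)
        cum_w = np.cumsum(w)
        cum_wx = np.cumsum(w[:, None] * X, axis=0)
        cum_wxx = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)
        # risk set of subject i (sorted by decreasing time) = first k(i) rows
        # with time >= time_i; ties share the full tied risk set
        idx = np.searchsorted(-time, -time, side="right") - 1
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        ev = np.flatnonzero(event == 1)
        for i in ev:
            k = idx[i]
            s0 = cum_w[k]
            s1 = cum_wx[k]
            s2 = cum_wxx[k]
            ll += eta[i] - np.log(s0)
            grad += X[i] - s1 / s0
            hess += s2 / s0 - np.outer(s1, s1) / s0**2
        if not np.all(np.isfinite(hess)):
            raise SurvivalError("Cox fit (breslow): non-finite Hessian")
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SurvivalError(f"Cox fit (breslow): singular Hessian ({exc})")
        beta_new = beta + step
        if np.max(np.abs(step)) < 1e-9:
            beta = beta_new
            break
        beta = beta_new
        if np.max(np.abs(beta)) > 50:
            raise SurvivalError(
                "Cox fit (breslow): coefficients diverging; possible complete separation"
            )
    cov = np.linalg.inv(hess)
    return beta, cov, float(ll)


def cox_fit(
    records: pd.DataFrame,
    covariates: pd.DataFrame,
    strata: pd.Series | None = None,
    ties: str = "efron",
) -> CoxFit:
    """Fit a Cox proportional-hazards model by partial likelihood.

    Efron tie handling (default) is delegated to lifelines; Breslow uses
    the in-package Newton solver. With ``strata``, risk sets form within
    stratum. Constant covariates and non-convergence are reported as
    errors with diagnostics.
    """
    records = validate_survival(records)
    if not records.index.equals(covariates.index):
        covariates = covariates.reindex(records.index)
        if covariates.isna().any().any():
            raise SurvivalError("covariate matrix does not cover all samples")
    if len(records) <= covariates.shape[1]:
        raise SurvivalError("need more subjects than covariates")
    const = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if const:
        raise SurvivalError(f"constant covariates cannot be estimated: {const}")

    names = list(covariates.columns)
    if ties == "efron":
        df = covariates.copy()
        df["time"] = records["time"].to_numpy()
        df["event"] = records["event"].to_numpy()
        strata_cols = None
        if strata is not None:
            df["_stratum"] = np.asarray(strata)
            strata_cols = ["_stratum"]
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(
                    df,
                    duration_col="time",
                    event_col="event",
                    strata=strata_cols,
                    show_progress=False,
                )
        except Exception as exc:
            raise SurvivalError(f"Cox fit failed to converge: {exc}") from exc
        summ = cph.summary
        table = pd.DataFrame(
            {
                "coef": summ["coef"],
                "se": summ["se(coef)"],
                "hr": np.exp(summ["coef"]),
                "ci_lower": np.exp(summ["coef"] - 1.959963984540054 * summ["se(coef)"]),
                "ci_upper": np.exp(summ["coef"] + 1.959963984540054 * summ["se(coef)"]),
                "p": summ["p"],
            }
        ).loc[names]
        ll = float(cph.log_likelihood_)
    elif ties == "breslow":
        X = covariates.to_numpy(dtype=float)
        t = records["time"].to_numpy(dtype=float)
        e = records["event"].to_numpy(dtype=int)
        if strata is None:
            beta, cov, ll = _breslow_newton(X, t, e)
        else:
            # stratified fit: sum score/information over strata with shared beta
            svals = np.asarray(strata)
            beta, cov, ll = _breslow_newton_stratified(X, t, e, svals)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        table = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_lower": np.exp(beta - 1.959963984540054 * se),
                "ci_upper": np.exp(beta + 1.959963984540054 * se),
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=names,
        )
    else:
        raise SurvivalError(f"unknown ties method {ties!r}")

    strata_desc = None
    if strata is not None:
        strata_desc = sorted({str(v) for v in np.asarray(strata)})
    return CoxFit(
        table=table,
        log_likelihood=ll,
        n=len(records),
        n_events=int(records["event"].sum()),
        ties=ties,
        strata=strata_desc,
        covariates=names,
    )


def _breslow_newton_stratified(X, time, event, strata):
    """Shared-beta Breslow fit with within-stratum risk sets."""
    levels = np.unique(strata)
    for lev in levels:
        if event[strata == lev].sum() < 1:
            raise SurvivalError(f"stratum {lev!r} has no events")
    p = X.shape[1]
    beta = np.zeros(p)
    ll = 0.0
    hess_total = np.eye(p)
    for _ in range(100):
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        ll = 0.0
        for lev in levels:
            m = strata == lev
            g_, h_, ll_ = _breslow_derivs(X[m], time[m], event[m], beta)
            grad += g_
            hess += h_
            ll += ll_
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        hess_total = hess
        if np.max(np.abs(step)) < 1e-9:
            break
        if np.max(np.abs(beta)) > 50:
            raise SurvivalError("Cox fit (breslow, stratified): diverging")
    return beta, np.linalg.inv(hess_total), float(ll)


def _breslow_derivs(X, time, event, beta):
    order = np.argsort(-time, kind="mergesort")
    X = X[order]
    time = time[order]
    event = event[order]
    eta = X @ beta
    w = np.exp(eta)
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w[:, None] * X, axis=0)
    cum_wxx = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)
    idx = np.searchsorted(-time, -time, side="right") - 1
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for i in np.flatnonzero(event == 1):
        k = idx[i]
        s0 = cum_w[k]
        s1 = cum_wx[k]
        s2 = cum_wxx[k]
        ll += eta[i] - np.log(s0)
        grad += X[i] - s1 / s0
        hess += s2 / s0 - np.outer(s1, s1) / s0**2
    return grad, hess, ll


# ---------------------------------------------------------------------------
# Harrell's c-index
# ---------------------------------------------------------------------------

def harrell_c(records: pd.DataFrame, risk: pd.Series | np.ndarray) -> float:
    """Harrell's concordance index for a risk score.

    Higher ``risk`` is expected to mean earlier events. Pairs rendered
    incomparable by censoring are excluded; score ties count 0.5.
    """
    records = validate_survival(records)
    risk = np.asarray(risk, dtype=float)
    if len(risk) != len(records):
        raise SurvivalError("risk score length does not match records")
    if len(records) < 2:
        raise SurvivalError("need at least two subjects")
    try:
        # lifelines treats higher predictions as longer survival
        return float(
            concordance_index(records["time"], -risk, records["event"])
        )
    except ZeroDivisionError as exc:
        raise SurvivalError("no comparable pairs") from exc


# ---------------------------------------------------------------------------
# Analysis of deviance (likelihood-ratio test for nested Cox models)
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    chi2: float
    df: int
    p_value: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)
            fh.write("\n")


def lr_test(reduced: CoxFit, full: CoxFit) -> LRTResult:
    """Likelihood-ratio (analysis of deviance) comparison of nested Cox fits."""
    if not set(reduced.covariates) <= set(full.covariates):
        raise SurvivalError(
            "models are not nested: reduced covariates must be a subset of full's"
        )
    if reduced.n != full.n or reduced.n_events != full.n_events:
        raise SurvivalError("models were fitted on different samples")
    if reduced.strata != full.strata:
        raise SurvivalError("models use different strata")
    df = len(full.covariates) - len(reduced.covariates)
    chi2 = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=chi2, df=df, p_value=p)


# ---------------------------------------------------------------------------
# Survival-driven cut-off discovery
# ---------------------------------------------------------------------------

@dataclass
class CutoffModel:
    """A score threshold selected by the maximally-selected log-rank
    statistic, with a permutation-adjusted selection p-value."""

    threshold: float
    max_statistic: float
    p_adjusted: float
    candidate_range: tuple[float, float]
    min_group_size: int
    n_permutations: int
    seed: int
    n_candidates: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
            fh.write("\n")


def _logrank_z_matrix(
    group_high: np.ndarray, time: np.ndarray, event: np.ndarray
) -> np.ndarray:
    """Standardized two-group log-rank statistics for many group splits.

    ``group_high`` is (n_splits, n_subjects) boolean. Returns |z| per split.
    """
    ev_times = np.unique(time[event == 1])
    at_risk = time[:, None] >= ev_times[None, :]  # n x T
    ev_mat = (time[:, None] == ev_times[None, :]) & (event[:, None] == 1)
    d = ev_mat.sum(axis=0).astype(float)
    n_at = at_risk.sum(axis=0).astype(float)

    G = group_high.astype(float)
    n1 = G @ at_risk
    o1 = G @ ev_mat
    frac = n1 / n_at
    e1 = d * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * frac * (1 - frac) * (n_at - d) / (n_at - 1)
    v[:, n_at <= 1] = 0.0
    U = (o1 - e1).sum(axis=1)
    V = v.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(U) / np.sqrt(V)
    z[V <= 0] = 0.0
    return z


def find_cutoff(
    scores: pd.Series,
    records: pd.DataFrame,
    quantile_range: tuple[float, float] = (0.10, 0.90),
    min_group_size: int = 10,
    n_permutations: int = 1000,
    seed: int = 0,
) -> CutoffModel:
    """Discover a prognostic score cut-off by maximally-selected log-rank.

    Candidate cutpoints are the observed score values inside the quantile
    range whose induced groups both satisfy ``min_group_size``. The
    cutpoint maximizing the absolute standardized two-group log-rank
    statistic is selected. The selection-adjusted p-value is the add-one
    permutation estimate (r+1)/(B+1), where r counts score permutations
    whose own maximal statistic reaches the observed maximum.
    """
    records = validate_survival(records)
    scores = scores.reindex(records.index)
    if scores.isna().any():
        raise SurvivalError("scores missing for some samples")
    s = scores.to_numpy(dtype=float)
    if len(s) < 2 * min_group_size:
        raise SurvivalError("too few samples for the requested minimum group size")
    if np.all(s == s[0]):
        raise SurvivalError("scores are constant; no cutpoint exists")

    lo, hi = np.quantile(s, quantile_range)
    cand = np.unique(s[(s >= lo) & (s <= hi)])
    n_high = (s[None, :] > cand[:, None]).sum(axis=1)
    ok = (n_high >= min_group_size) & (len(s) - n_high >= min_group_size)
    cand = cand[ok]
    if cand.size == 0:
        raise SurvivalError("no admissible candidate cutpoint")

    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    G = s[None, :] > cand[:, None]
    z_obs = _logrank_z_matrix(G, time, event)
    best = int(np.argmax(z_obs))
    max_stat = float(z_obs[best])
    # report the midpoint of the empirical gap above the selected observed
    # value: the induced split is identical, and the midpoint is the natural
    # representative of the interval of equivalent thresholds
    uniq = np.unique(s)
    pos = np.searchsorted(uniq, cand[best])
    if pos + 1 < len(uniq):
        threshold = 0.5 * (uniq[pos] + uniq[pos + 1])
    else:
        threshold = float(cand[best])

    rng = np.random.default_rng(seed)
    B = int(n_permutations)
    r = 0
    chunk = max(1, min(B, int(5e6 // max(1, cand.size * len(s)))))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        perms = np.array([rng.permutation(len(s)) for _ in range(b)])
        Gp = G[:, perms]  # (C, b, n)
        Gp = np.moveaxis(Gp, 1, 0).reshape(b * cand.size, len(s))
        zp = _logrank_z_matrix(Gp, time, event).reshape(b, cand.size)
        r += int((zp.max(axis=1) >= max_stat - 1e-12).sum())
        done += b
    p_adj = (r + 1) / (B + 1)

    return CutoffModel(
        threshold=float(threshold),
        max_statistic=max_stat,
        p_adjusted=float(p_adj),
        candidate_range=(float(lo), float(hi)),
        min_group_size=int(min_group_size),
        n_permutations=B,
        seed=int(seed),
        n_candidates=int(cand.size),
    )


class CutoffSearch:
    """Model-style wrapper around :func:`find_cutoff`."""

    def __init__(
        self,
        scores: pd.Series,
        records: pd.DataFrame,
        quantile_range: tuple[float, float] = (0.10, 0.90),
        min_group_size: int = 10,
        n_permutations: int = 1000,
    ) -> None:
        self.scores = scores
        self.records = records
        self.quantile_range = quantile_range
        self.min_group_size = min_group_size
        self.n_permutations = n_permutations

    def fit(self, seed: int = 0) -> CutoffModel:
        return find_cutoff(
            self.scores,
            self.records,
            quantile_range=self.quantile_range,
            min_group_size=self.min_group_size,
            n_permutations=self.n_permutations,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Clinical covariate recoding
# ---------------------------------------------------------------------------

_G_TO_G3 = {"2-3", "2–3", "4"}  # grades folded into G3
_G_MISSING = {"X", "GX", "NA", ""}


def recode_covariates(
    clinical: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recode T/N/M/G into reference-coded indicators for Cox models.

    Grades "2-3" and "4" are folded into G3. Records with missing/X grade
    or metastasis status MX are excluded and listed in the report (not
    errors). Reference levels: T1, N0, M0, G1. Necrosis becomes a 0/1
    indicator and tumor size passes through when present.

    Returns (model-ready covariate table, exclusion report with columns
    sample_id, reason).
    """
    df = clinical.copy()
    excl: list[tuple[str, str]] = []

    def _norm(v) -> str:
        return "" if pd.isna(v) else str(v).strip()

    keep_rows = []
    g_final = {}
    for sid, row in df.iterrows():
        m = _norm(row.get("M")).upper().lstrip("M")
        g = _norm(row.get("G")).upper().lstrip("G")
        if m == "X":
            excl.append((sid, "MX"))
            continue
        if g in _G_MISSING or g == "":
            excl.append((sid, "missing_grade"))
            continue
        g_final[sid] = "3" if g in _G_TO_G3 else g
        keep_rows.append(sid)

    kept = df.loc[keep_rows]
    out = pd.DataFrame(index=kept.index)
    for level in ("2", "3", "4"):
        out[f"T{level}"] = (
            kept["T"].map(lambda v: _norm(v).lstrip("T")) == level
        ).astype(int)
    for level in ("1", "2"):
        out[f"N{level}"] = (
            kept["N"].map(lambda v: _norm(v).upper().lstrip("N")) == level
        ).astype(int)
    out["M1"] = (kept["M"].map(lambda v: _norm(v).upper().lstrip("M")) == "1").astype(int)
    for level in ("2", "3"):
        out[f"G{level}"] = pd.Series(g_final).reindex(out.index).eq(level).astype(int)
    if "necrosis" in kept.columns:
        out["necrosis"] = (
            kept["necrosis"].map(lambda v: _norm(v).lower()) == "present"
        ).astype(int)
    if "size_cm" in kept.columns:
        out["size_cm"] = pd.to_numeric(kept["size_cm"], errors="coerce")
    report = pd.DataFrame(excl, columns=["sample_id", "reason"])
    return out, report
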