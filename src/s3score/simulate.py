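"""Seeded synthetic cohorts for the full scoring-and-validation pipeline.

The generator emulates the structural features the scoring method relies
on, with the ground truth returned alongside the data:

- nephron-region reference profiles with per-gene baselines and
  region-specific contrasts; a configurable subset of "informative"
  signature genes carries large inter-region contrast, the rest little;
- tumors as noisy convex mixtures of the cell-of-origin profile (weight
  ``w``, the latent purity/origin-similarity) and a per-sample random
  convex mixture of the other regions (so every region correlation is
  informative);
- survival with hazard decreasing in ``w`` (exponential event times,
  uniform censoring);
- a qRT-PCR re-measurement as an affine map from log2 expression to Ct
  with i.i.d. sporadic well failures and low-variance normalization
  genes;
- matched metastases as small per-gene perturbations of their primaries,
  optionally multi-region.

All randomness derives from one seed; each operation draws from its own
child stream so artifacts are reproducible independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GenePanel
from .scoring import ReferenceProfiles

__all__ = [
    "GeneratorConfig",
    "make_reference_profiles",
    "simulate_tumors",
    "simulate_survival",
    "to_qpcr",
    "make_metastases",
    "simulate_cohort",
]


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohorts."""

    seed: int
    n_genes: int = 300
    n_signature: int = 97
    n_regions: int = 8
    origin_region_index: int = 2  # "S3" position among region labels
    n_samples: int = 200
    # purity (latent origin-similarity) distribution; skews high
    purity_a: float = 5.0
    purity_b: float = 2.0
    # expression model
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_informative: int = 15
    informative_contrast_sd: float = 16.0
    uninformative_contrast_sd: float = 0.2
    nonsignature_contrast_sd: float = 1.0
    # survival model: hazard = h0 * exp(-beta * w)
    baseline_hazard: float = 0.25
    beta: float = 2.0
    censoring_horizon: float = 10.0
    # qRT-PCR model: Ct = intercept - slope * expr + noise, clipped to
    # the instrument dynamic range
    qpcr_slope: float = 1.0
    qpcr_intercept: float = 30.0
    ct_noise_sd: float = 0.25
    assay_failure_rate: float = 0.002
    n_normalization_genes: int = 5
    ct_clip: tuple[float, float] = (0.5, 44.5)
    # metastasis model
    metastasis_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.assay_failure_rate < 1):
            raise ValueError("assay failure rate must be in [0, 1)")
        for sd in (
            self.noise_sd,
            self.ct_noise_sd,
            self.metastasis_sd,
            self.informative_contrast_sd,
            self.uninformative_contrast_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if self.n_signature > self.n_genes:
            raise ValueError("n_signature cannot exceed n_genes")
        if self.n_informative > self.n_signature:
            raise ValueError("n_informative cannot exceed n_signature")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def signature_genes(self) -> list[str]:
        return self.gene_ids[: self.n_signature]

    @property
    def informative_genes(self) -> list[str]:
        return self.gene_ids[: self.n_informative]

    @property
    def normalization_genes(self) -> list[str]:
        return [f"NORM{i}" for i in range(1, self.n_normalization_genes + 1)]

    @property
    def region_labels(self) -> list[str]:
        return [f"region{i}" for i in range(1, self.n_regions + 1)]

    @property
    def origin_region(self) -> str:
        return self.region_labels[self.origin_region_index]

    def panel(self) -> GenePanel:
        return GenePanel(
            signature_genes=self.signature_genes,
            normalization_genes=self.normalization_genes,
        )


# stream ids, one per stochastic operation
_S_REFS, _S_TUMORS, _S_SURV, _S_QPCR, _S_MET, _S_VALID = 11, 22, 33, 44, 55, 66


def make_reference_profiles(cfg: GeneratorConfig) -> ReferenceProfiles:
    """Gene x region reference matrix with region-specific contrasts.

    Informative signature genes receive large i.i.d. region offsets, so
    any two regions correlate weakly over the signature genes.
    """
    rng = cfg.rng(_S_REFS)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    contrast_sd = np.full(cfg.n_genes, cfg.nonsignature_contrast_sd)
    contrast_sd[: cfg.n_signature] = cfg.uninformative_contrast_sd
    contrast_sd[: cfg.n_informative] = cfg.informative_contrast_sd
    offsets = rng.normal(0.0, 1.0, (cfg.n_genes, cfg.n_regions)) * contrast_sd[:, None]
    values = baseline[:, None] + offsets
    return ReferenceProfiles(
        values=pd.DataFrame(values, index=cfg.gene_ids, columns=cfg.region_labels),
        origin_region=cfg.origin_region,
    )


def _mix_tumors(
    cfg: GeneratorConfig, refs: ReferenceProfiles, rng: np.random.Generator, n: int,
    prefix: str,
) -> tuple[ExpressionMatrix, pd.Series]:
    w = rng.beta(cfg.purity_a, cfg.purity_b, n)
    ref_vals = refs.values.to_numpy()
    origin_col = refs.region_labels.index(refs.origin_region)
    others = np.delete(np.arange(cfg.n_regions), origin_col)
    mix = rng.dirichlet(np.ones(len(others)), size=n)  # n x (R-1)
    background = ref_vals[:, others] @ mix.T  # genes x n
    expr = (
        w[None, :] * ref_vals[:, [origin_col]]
        + (1 - w[None, :]) * background
        + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, n))
    )
    sample_ids = [f"{prefix}{i:04d}" for i in range(1, n + 1)]
    m = ExpressionMatrix(
        pd.DataFrame(expr, index=cfg.gene_ids, columns=sample_ids), "rnaseq_log"
    )
    return m, pd.Series(w, index=sample_ids, name="w")


def simulate_tumors(
    cfg: GeneratorConfig, refs: ReferenceProfiles
) -> tuple[ExpressionMatrix, pd.Series]:
    """Simulate a tumor cohort; returns (expression, latent purity ``w``)."""
    return _mix_tumors(cfg, refs, cfg.rng(_S_TUMORS), cfg.n_samples, "S")


def simulate_validation_tumors(
    cfg: GeneratorConfig, refs: ReferenceProfiles, n: int
) -> tuple[ExpressionMatrix, pd.Series]:
    """An independent cohort from the same reference profiles."""
    return _mix_tumors(cfg, refs, cfg.rng(_S_VALID), n, "V")


def simulate_survival(cfg: GeneratorConfig, w: pd.Series) -> pd.DataFrame:
    """Exponential event times with hazard h0 * exp(-beta * w), uniform
    censoring on (0, horizon]. Returns a survival table (time, event)."""
    if ((w < 0) | (w > 1)).any():
        raise ValueError("latent purity w must lie in [0, 1]")
    rng = cfg.rng(_S_SURV)
    rate = cfg.baseline_hazard * np.exp(-cfg.beta * w.to_numpy())
    t_event = rng.exponential(1.0 / rate)
    c = rng.uniform(0.0, cfg.censoring_horizon, len(w))
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame(
        {"time": time, "event": event, "endpoint": "CSS"}, index=w.index
    )


def to_qpcr(
    cfg: GeneratorConfig, m: ExpressionMatrix, genes: Sequence[str] | None = None
) -> ExpressionMatrix:
    """qRT-PCR re-measurement of ``genes`` (default: the signature panel).

    Ct = intercept - slope * expr + noise, clipped to the instrument
    dynamic range; each well fails (missing Ct) independently with the
    configured rate. Normalization genes are appended with low variance
    and never fail (they are chosen for reliability).
    """
    genes = list(genes) if genes is not None else cfg.signature_genes
    absent = [g for g in genes if g not in m.values.index]
    if absent:
        raise ValueError(f"genes absent from source matrix: {absent}")
    rng = cfg.rng(_S_QPCR)
    expr = m.values.loc[genes].to_numpy()
    ct = (
        cfg.qpcr_intercept
        - cfg.qpcr_slope * expr
        + rng.normal(0.0, cfg.ct_noise_sd, expr.shape)
    )
    ct = np.clip(ct, *cfg.ct_clip)
    if cfg.assay_failure_rate > 0:
        fail = rng.random(ct.shape) < cfg.assay_failure_rate
        ct[fail] = np.nan
    # low-variance reference genes, one stable level each
    norm_levels = rng.uniform(18.0, 26.0, cfg.n_normalization_genes)
    norm_ct = norm_levels[:, None] + rng.normal(
        0.0, 0.05, (cfg.n_normalization_genes, expr.shape[1])
    )
    values = pd.DataFrame(
        np.vstack([ct, norm_ct]),
        index=genes + cfg.normalization_genes,
        columns=m.sample_ids,
    )
    return ExpressionMatrix(values, "qpcr_ct")


def make_metastases(
    cfg: GeneratorConfig,
    tumors: ExpressionMatrix,
    patients: Sequence[str],
    multi_region: dict[str, int] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Matched metastasis profiles as perturbations of primary tumors.

    ``patients`` are sample ids of the primaries; ``multi_region`` maps a
    patient to the number of regions sampled from one metastasis (each an
    independent perturbation). Returns (metastasis expression, role table
    with columns patient_id, sample_id, role, region).
    """
    absent = [p for p in patients if p not in tumors.values.columns]
    if absent:
        raise ValueError(f"patients not in tumor matrix: {absent}")
    multi_region = multi_region or {}
    rng = cfg.rng(_S_MET)
    cols = {}
    roles = []
    for pid in patients:
        base = tumors.values[pid].to_numpy()
        k = multi_region.get(pid, 1)
        for region in range(1, k + 1):
            sid = f"{pid}_met" if k == 1 else f"{pid}_met_r{region}"
            cols[sid] = base + rng.normal(0.0, cfg.metastasis_sd, len(base))
            roles.append(
                {
                    "patient_id": pid,
                    "sample_id": sid,
                    "role": "metastasis",
                    "region": region,
                }
            )
    met = ExpressionMatrix(
        pd.DataFrame(cols, index=tumors.gene_ids), tumors.platform
    )
    return met, pd.DataFrame(roles)


def simulate_cohort(cfg: GeneratorConfig) -> dict:
    """One-call bundle: refs, tumors, truth, survival, qPCR, panel."""
    refs = make_reference_profiles(cfg)
    tumors, w = simulate_tumors(cfg, refs)
    clinical = simulate_survival(cfg, w)
    qpcr = to_qpcr(cfg, tumors)
    return {
        "config": cfg,
        "refs": refs,
        "tumors": tumors,
        "w": w,
        "clinical": clinical,
        "qpcr": qpcr,
        "panel": cfg.panel(),
    }
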