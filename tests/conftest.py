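import numpy as np
import pandas as pd
import pytest

from s3score import ExpressionMatrix, GenePanel, GeneratorConfig, ReferenceProfiles
from s3score.simulate import make_reference_profiles, simulate_survival, simulate_tumors


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    df = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(df, "rnaseq_log")


@pytest.fixture
def panel() -> GenePanel:
    return GenePanel(signature_genes=["g1", "g2"], normalization_genes=["n1", "n2"])


@pytest.fixture
def tiny_refs() -> ReferenceProfiles:
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        rng.normal(8, 2, (20, 4)),
        index=[f"g{i}" for i in range(20)],
        columns=["regA", "regB", "regC", "regD"],
    )
    return ReferenceProfiles(df, origin_region="regB")


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=123)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    refs = make_reference_profiles(default_cfg)
    tumors, w = simulate_tumors(default_cfg, refs)
    clinical = simulate_survival(default_cfg, w)
    return {"refs": refs, "tumors": tumors, "w": w, "clinical": clinical}


def make_survival_frame(times, events, prefix="s") -> pd.DataFrame:
    return pd.DataFrame(
        {"time": np.asarray(times, dtype=float), "event": np.asarray(events, dtype=int)},
        index=[f"{prefix}{i}" for i in range(len(times))],
    )
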