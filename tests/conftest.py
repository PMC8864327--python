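import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cariesdta import (
    ArmRecord,
    SamplerSettings,
    SimulationConfig,
    StudyTable,
    fit,
    simulate_study_table,
)
from cariesdta.cohort import ANALYSIS1_HETEROGENEITY, ANALYSIS1_MU

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")

#: Compact sampler settings for test fits: fast while still clearing the
#: convergence gate on these small problems.
FAST = SamplerSettings(
    chains=2, warmup_iterations=500, sampling_iterations=500, seed=0,
    pointwise_loglik=False, auto_raise=False,
)


@pytest.fixture
def toy_table_t2():
    """3 studies x 2 technologies, complete design, hand-sized counts."""
    rows = [
        ("s1", "visual", 8, 2, 2, 8),
        ("s1", "imaging", 5, 1, 5, 9),
        ("s2", "visual", 30, 5, 10, 35),
        ("s2", "imaging", 22, 3, 18, 37),
        ("s3", "visual", 14, 6, 6, 14),
        ("s3", "imaging", 10, 2, 10, 18),
    ]
    return StudyTable(
        [ArmRecord(s, t, tp=a, fp=b, fn=c, tn=d) for s, t, a, b, c, d in rows]
    )


@pytest.fixture
def toy_network():
    """5-study incomplete network over 3 technologies (every study >= 2)."""
    rows = [
        ("n1", "visual", 12, 3, 4, 11), ("n1", "imaging", 9, 2, 7, 12),
        ("n2", "visual", 20, 6, 10, 24), ("n2", "fluorescence", 24, 8, 6, 22),
        ("n3", "imaging", 7, 1, 9, 13), ("n3", "fluorescence", 11, 4, 5, 10),
        ("n4", "visual", 18, 5, 6, 19), ("n4", "imaging", 12, 2, 12, 22),
        ("n4", "fluorescence", 17, 6, 7, 18),
        ("n5", "visual", 25, 4, 9, 26), ("n5", "fluorescence", 28, 7, 6, 23),
    ]
    return StudyTable(
        [ArmRecord(s, t, tp=a, fp=b, fn=c, tn=d) for s, t, a, b, c, d in rows]
    )


def small_within_config(seed=11, n_studies=12):
    return SimulationConfig(
        n_studies=n_studies,
        technologies=("fluorescence", "visual", "imaging"),
        mu_se=ANALYSIS1_MU["se"],
        mu_sp=ANALYSIS1_MU["sp"],
        prevalence=0.66,
        site_count_range=(80, 200),
        seed=seed,
        covariance=dict(ANALYSIS1_HETEROGENEITY),
    )


@pytest.fixture(scope="session")
def small_within_table():
    table, truths = simulate_study_table(small_within_config())
    return table, truths


@pytest.fixture(scope="session")
def m3_fit(small_within_table):
    table, _ = small_within_table
    s = SamplerSettings(
        chains=2, warmup_iterations=500, sampling_iterations=500, seed=7,
        pointwise_loglik=True, auto_raise=False,
    )
    return fit("M3", table, settings=s)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210)
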