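import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pharmfc as pf

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """Full default two-genotype cohort (seed 1) with ground truth."""
    return pf.simulate_cohort(pf.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def preprocessed(default_cohort):
    ts, gt = default_cohort
    pre = pf.preprocess(ts)
    seg = pf.segment_conditions(pre)
    zstack = pf.interval_fc(pre, seg)
    return pre, seg, zstack, gt


@pytest.fixture(scope="session")
def null_cohort():
    """Stationary cohort: no drug effects, no artifacts, no nuisance."""
    cfg = pf.SimulationConfig(
        seed=7,
        drug_effect_edges=[],
        injection_artifact_spec=pf.InjectionArtifactSpec(
            edges=(), global_amplitude=0.0),
        nuisance_spec=pf.NuisanceSpec(drift_order=0, drift_amplitude=0.0,
                                      wmcsf_sd=0.0),
    )
    return pf.simulate_cohort(cfg)


def pearson_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook covariance/SD Pearson correlation (independent oracle)."""
    am, bm = a.mean(), b.mean()
    num = ((a - am) * (b - bm)).sum()
    den = np.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum())
    return num / den


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Hand Benjamini–Hochberg step-up adjusted p values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
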