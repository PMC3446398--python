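import pytest

from daehap.simulate import SimConfig


@pytest.fixture
def cfg() -> SimConfig:
    """Small default synthetic cohort configuration."""
    return SimConfig(n_samples=60, seed=11)


@pytest.fixture
def noiseless_low_cfg() -> SimConfig:
    """Noise-free cohort where every marker heterozygote has a 1/0.7 ratio."""
    c = SimConfig(n_samples=40, seed=5, meas_cv=0.0)
    c.hap_expr_level = {
        "hap1": 1.0, "hap2": 0.7, "hap3": 0.7, "hap4": 0.7, "hap5": 0.7
    }
    return c
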