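import numpy as np
import pytest

from metapower import Architecture, CGRStructure, ScalarConfig, StudyPanel

try:  # hypothesis is test-only; derandomize so CI runs are reproducible
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "default",
        derandomize=True,
        max_examples=25,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("default")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def wood_config():
    """79 equal studies totaling 253,288; the flagship equal-design benchmark."""
    return ScalarConfig(
        n_total=253_288,
        n_studies=79,
        h2=0.449,
        cgr=0.965,
        cgr_holdout=0.965,
        h2_holdout=0.449,
        s_total=250_000,
        m_causal=20_000,
    )


@pytest.fixture
def small_design():
    """A tiny valid (panel, cgr, arch) triple for unit tests."""
    panel = StudyPanel([1000, 2000, 1500], [0.3, 0.5, 0.4])
    cgr = CGRStructure.constant(3, 0.6, 0.5, 0.45)
    arch = Architecture(5000, 500, 5e-8)
    return panel, cgr, arch


def random_design(rng, c=None, alpha=5e-8):
    """Random valid design with a PSD constant+noise correlation structure."""
    c = c or int(rng.integers(1, 11))
    sizes = rng.integers(100, 50_000, size=c).astype(float)
    h2 = rng.uniform(0.05, 0.8, size=c)
    # random PSD correlation: normalized Gram matrix of random vectors
    v = rng.standard_normal((c + 1, c + 3))
    v += 2.0 * rng.standard_normal((1, c + 3))  # induce positive correlations
    gram = v @ v.T
    d = np.sqrt(np.diag(gram))
    corr = gram / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    cgr = CGRStructure(corr[:c, :c], corr[:c, c], float(rng.uniform(0.1, 0.8)))
    arch = Architecture(
        int(rng.integers(1_000, 500_000)), int(rng.integers(100, 1_000)), alpha
    )
    return StudyPanel(sizes, h2), cgr, arch
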