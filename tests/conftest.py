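import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def pooled_chisquare(counts, expected, min_expected=10.0):
    """Pearson chi-square with low-expectation bins pooled into one."""
    import scipy.stats

    counts = np.asarray(counts, dtype=float)
    expected = np.asarray(expected, dtype=float)
    low = expected < min_expected
    if low.any():
        counts = np.append(counts[~low], counts[low].sum())
        expected = np.append(expected[~low], expected[low].sum())
    return scipy.stats.chisquare(counts, expected * counts.sum() / expected.sum())


@pytest.fixture
def sr20():
    from grm import build_sr

    return build_sr(20, 1.0)


@pytest.fixture
def sr200():
    from grm import build_sr

    return build_sr(200, 1.0)


@pytest.fixture
def binding3():
    """Three hypothetical proteins on evenly spaced windows of an N=200 cycle."""
    from grm import binding_from_windows

    return binding_from_windows(
        200, {"P1": [(0, 40)], "P2": [(66, 106)], "P3": [(133, 173)]}
    )


@pytest.fixture
def random_net30():
    """A dense-ish random strongly connected 30-state network."""
    from grm import RecruitmentNetwork

    rng = np.random.default_rng(0)
    rates = rng.uniform(0, 1, (30, 30)) * (rng.random((30, 30)) < 0.2)
    np.fill_diagonal(rates, 0)
    rates[np.arange(30), (np.arange(30) + 1) % 30] += 1.0
    return RecruitmentNetwork(30, rates)
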