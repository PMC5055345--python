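import numpy as np
import pytest

from nucperiod.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests."""
    cfg = SimConfig(seed=7, n_promoters=30, amplitude=0.8,
                    fragments_per_promoter=40, tag_depth=1000)
    return simulate_cohort(cfg)


def brute_force_power(window, f):
    """Independent double-loop DFT oracle: |sum (x-xbar) e^{-2 pi i f n}|^2 / L."""
    import math

    x = [float(v) for v in window]
    mean = sum(x) / len(x)
    re = im = 0.0
    for n, v in enumerate(x):
        re += (v - mean) * math.cos(2 * math.pi * f * n)
        im -= (v - mean) * math.sin(2 * math.pi * f * n)
    return (re * re + im * im) / len(x)
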