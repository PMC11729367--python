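import numpy as np
import pandas as pd
import pytest

from specurve.synthetic import EffectConfig, assign_ground_truth, generate_cohort


@pytest.fixture(scope="session")
def freq_grid():
    """Half-Hz grid from 1 to 100 Hz (the 2 s epoch resolution)."""
    return np.arange(1.0, 100.5, 0.5)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(
        n_pain=20, n_healthy=20, diagnosis_counts={"CBP": 10, "CWP": 5, "other": 5}, seed=11
    )


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return assign_ground_truth(small_cohort, EffectConfig(), seed=12)


def aperiodic_power(freqs, offset, exponent, knee=0.0):
    """Linear power of a pure Lorentzian spectrum (test helper)."""
    return 10.0 ** (offset - np.log10(knee + freqs**exponent))
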