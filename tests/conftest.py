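import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: the six calibration concentrations of the assay design, in uM
CALIBRATION_SERIES = np.array([0.0, 25.0, 50.0, 75.0, 100.0, 125.0])


@pytest.fixture
def calibration_series():
    return CALIBRATION_SERIES.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


def make_exact_trials(coefficients, concentrations, rng, n_trials=3):
    """Trials of 3 x n log-intensities exactly satisfying C = a . ln(I).

    Green/blue log-intensities are drawn freely; the red row is solved so
    the intercept-free linear relation holds exactly, giving a full-rank
    design with a known coefficient vector.
    """
    a = np.asarray(coefficients, dtype=float)
    trials = []
    for _ in range(n_trials):
        gb = rng.normal(scale=0.5, size=(2, concentrations.size))
        r = (concentrations - a[1] * gb[0] - a[2] * gb[1]) / a[0]
        trials.append(np.vstack([r, gb]))
    return trials


def stacked_ols_coefficients(concentrations, trials):
    """Independent oracle: pooled fit via stacked ordinary least squares.

    Stacks the trials into one long design and solves the intercept-free
    regression of the repeated concentration vector on the three log-
    intensity channels with numpy's lstsq — a route entirely separate from
    the pseudo-inverse construction under test.
    """
    X = np.hstack([np.asarray(t, float) for t in trials]).T  # (k*n, 3)
    y = np.tile(np.asarray(concentrations, float), len(trials))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef
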