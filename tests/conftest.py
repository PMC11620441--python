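"""Shared fixtures and independent oracles for the greycast test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from greycast import Series

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# -- independent oracles --------------------------------------------------------------


def cramer_solve(design: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Brute-force least squares: normal equations solved by Cramer's rule.

    Deliberately naive (determinant substitution), so it shares no code path
    with the SVD-based estimation it cross-checks.
    """
    ata = design.T @ design
    atb = design.T @ rhs
    det = np.linalg.det(ata)
    theta = np.empty(len(atb))
    for j in range(len(atb)):
        modified = ata.copy()
        modified[:, j] = atb
        theta[j] = np.linalg.det(modified) / det
    return theta


def iterate_dngm_recursion(alpha: float, beta: float, gamma: float,
                           x1_init: float, length: int) -> np.ndarray:
    """Accumulated path from the recursion x1(t+1) = alpha x1(t) + beta t + gamma."""
    x1 = np.empty(length)
    x1[0] = x1_init
    for i in range(1, length):
        x1[i] = alpha * x1[i - 1] + beta * i + gamma
    return x1


def restore_original(x1: np.ndarray) -> np.ndarray:
    """First differences keeping the first element (closed-form IAGO)."""
    return np.diff(x1, prepend=0.0)


def linear_recursion_series(beta1: float, beta2: float, init: float, length: int) -> np.ndarray:
    y = np.empty(length)
    y[0] = init
    for i in range(1, length):
        y[i] = beta1 * y[i - 1] + beta2
    return y


# -- canonical fixtures ---------------------------------------------------------------


@pytest.fixture
def dngm_exact_series() -> Series:
    """The worked example: recursion (alpha, beta, gamma) = (0.5, 1, 2) from x1(1)=1,
    i.e. x0(t) = 2 + 0.5^(t-1) with x0(1) anchored at 1."""
    return Series.from_values([1.0, 2.5, 2.25, 2.125, 2.0625])


@pytest.fixture
def geometric_window() -> Series:
    return Series.from_values([2.0, 1.0, 0.5, 0.25])


@pytest.fixture
def noisy_series() -> Series:
    """A fixed, reproducible noisy declining series for rolling tests."""
    rng = np.random.default_rng(424242)
    t = np.arange(12, dtype=float)
    base = 50.0 + 40.0 * np.exp(-0.2 * t)
    return Series.from_values(base * (1.0 + rng.normal(0.0, 0.05, size=12)))
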