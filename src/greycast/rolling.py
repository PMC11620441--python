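"""Metabolic (rolling-window) grey forecasting and window-size selection.

Any static grey model becomes dynamic by "metabolism": before each one-step
forecast, append the newest observation to the modelling window, drop the
oldest, and refit — the window size n stays constant.  Rolling GM(1,1) is the
metabolic model MGM(1,1); rolling DNGM(1,1) is DNMGM(1,1).

During retrospective evaluation every window contains actual observations
only, so each recorded error is an honest one-step-ahead error; forecasts
enter windows only in :func:`roll_extrapolate`, which continues past the last
observation by feeding the window with its own predictions.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .models import MIN_WINDOW, ModelError, get_fitter, simulate_static
from .series import Series

__all__ = [
    "RollingStep",
    "RollingForecast",
    "WindowSearchResult",
    "roll",
    "optimize_window",
    "roll_extrapolate",
    "DEFAULT_CANDIDATES",
]

logger = logging.getLogger(__name__)

#: window sizes swept by default when selecting n.
DEFAULT_CANDIDATES = tuple(range(4, 11))

#: two candidate MAPEs closer than this (percentage points) count as tied;
#: ties resolve to the smallest window.
TIE_TOL = 1e-9


@dataclass(frozen=True)
class RollingStep:
    """One metabolic step: the fit on window t-n..t-1 and the forecast at t."""

    position: int                    # 1-based target index t
    period: int
    window_periods: tuple[int, ...]
    actual: float
    forecast: float | None           # None when the window fit was ill-posed
    relative_error: float | None     # |forecast - actual| / actual, a fraction
    params: object | None = None
    note: str = ""


@dataclass
class RollingForecast:
    """One-step-ahead forecast track of a metabolic model.

    ``overall_mape`` is 100 x the mean of the defined per-step relative
    errors, evaluated over t = n+1 .. n_obs (the first n points are
    in-window, not forecast).
    """

    model_name: str
    window_size: int
    steps: list[RollingStep]
    overall_mape: float

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [s.position for s in self.steps],
                "period": [s.period for s in self.steps],
                "actual": [s.actual for s in self.steps],
                "forecast": [s.forecast for s in self.steps],
                "relative_error_pct": [
                    None if s.relative_error is None else 100.0 * s.relative_error
                    for s in self.steps
                ],
                "note": [s.note for s in self.steps],
            }
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "window_size": self.window_size,
            "evaluation_positions": f"t={self.window_size + 1}..{self.window_size + len(self.steps)}",
            "overall_mape": self.overall_mape,
            "steps": [
                {
                    **{k: v for k, v in asdict(s).items() if k != "params"},
                    "params": asdict(s.params) if s.params is not None else None,
                }
                for s in self.steps
            ],
        }


@dataclass
class WindowSearchResult:
    """MAPE per candidate window size and the selected optimum.

    Infeasible candidates are recorded with MAPE ``None``.  Ties within
    ``TIE_TOL`` percentage points resolve to the smallest size and set
    ``ties_broken``.
    """

    model_name: str
    candidate_sizes: tuple[int, ...]
    mape_by_size: dict[int, float | None]
    best_size: int
    ties_broken: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_size": list(self.mape_by_size),
                "mape_pct": [self.mape_by_size[s] for s in self.mape_by_size],
                "selected": [s == self.best_size for s in self.mape_by_size],
            }
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "candidate_sizes": list(self.candidate_sizes),
            "mape_by_size": {str(k): v for k, v in self.mape_by_size.items()},
            "best_size": self.best_size,
            "ties_broken": self.ties_broken,
        }


def _check_roll_args(series: Series, model_name: str, n: int) -> None:
    need = MIN_WINDOW.get(model_name)
    if need is None:
        get_fitter(model_name)  # raises with the canonical message
    if n < need:
        raise ModelError(f"{model_name} needs a window of at least {need}, got n={n}")
    if len(series) < n + 1:
        raise ModelError(
            f"series too short for rolling {model_name} with n={n}: "
            f"needs at least {n + 1} observations, got {len(series)}"
        )


def roll(series: Series, model_name: str, n: int) -> RollingForecast:
    """One-step-ahead metabolic evaluation of ``model_name`` with window size n.

    For each t = n+1 .. n_obs the model is refitted on the actual observations
    at t-n .. t-1 and forecasts x0(t); the window never contains forecasts.
    Ill-posed window fits are recorded as undefined steps, excluded from the
    overall MAPE, and logged.
    """
    _check_roll_args(series, model_name, n)
    fitter = get_fitter(model_name)
    steps: list[RollingStep] = []
    for t in range(n + 1, len(series) + 1):
        window = series.slice(t - 1 - n, t - 1)
        actual = float(series.values[t - 1])
        period = int(series.periods[t - 1])
        fit = fitter(window)
        if not fit.well_posed:
            note = f"ill-posed window fit: {'; '.join(fit.diagnostics)}"
            logger.warning("t=%d (period %d): %s; step excluded from MAPE", t, period, note)
            steps.append(RollingStep(t, period, tuple(window.periods.tolist()),
                                     actual, None, None, fit.params, note))
            continue
        forecast = float(simulate_static(fit, horizon=1).values[-1])
        rel = abs(forecast - actual) / actual
        steps.append(RollingStep(t, period, tuple(window.periods.tolist()),
                                 actual, forecast, rel, fit.params))
    defined = [s.relative_error for s in steps if s.relative_error is not None]
    if defined:
        overall = float(100.0 * np.mean(defined))
    else:
        overall = float("nan")
        logger.warning("rolling %s n=%d: no well-posed step; MAPE undefined", model_name, n)
    return RollingForecast(model_name, n, steps, overall)


def optimize_window(series: Series, model_name: str,
                    candidates=DEFAULT_CANDIDATES) -> WindowSearchResult:
    """Sweep candidate window sizes and select the one with minimal rolling MAPE.

    Infeasible candidates (below the model minimum, or leaving no forecast
    step) are skipped with a logged warning and recorded as undefined rather
    than aborting the sweep.
    """
    candidates = tuple(int(c) for c in candidates)
    if not candidates:
        raise ModelError("candidate list must not be empty")
    mape_by_size: dict[int, float | None] = {}
    for c in candidates:
        try:
            mape_by_size[c] = roll(series, model_name, c).overall_mape
        except ModelError as exc:
            logger.warning("window candidate n=%d skipped: %s", c, exc)
            mape_by_size[c] = None
    defined = {s: m for s, m in mape_by_size.items() if m is not None and np.isfinite(m)}
    if not defined:
        raise ModelError(
            f"no feasible window candidate among {candidates} for a "
            f"length-{len(series)} series and model {model_name}"
        )
    best_mape = min(defined.values())
    tied = sorted(s for s, m in defined.items() if m - best_mape <= TIE_TOL)
    return WindowSearchResult(
        model_name=model_name,
        candidate_sizes=candidates,
        mape_by_size=mape_by_size,
        best_size=tied[0],
        ties_broken=len(tied) > 1,
    )


def roll_extrapolate(series: Series, model_name: str, n: int, horizon: int) -> Series:
    """Metabolic forecasting beyond the last observation.

    The first step fits the last n actual observations; each subsequent step
    appends its own forecast to the window and drops the oldest value —
    beyond-sample metabolism feeds on predictions, so errors can compound.
    """
    if horizon < 1:
        raise ModelError("horizon must be >= 1")
    need = MIN_WINDOW.get(model_name)
    if need is None:
        get_fitter(model_name)
    if n < need:
        raise ModelError(f"{model_name} needs a window of at least {need}, got n={n}")
    if len(series) < n:
        raise ModelError(
            f"series too short to extrapolate with n={n}: needs at least {n} observations"
        )
    fitter = get_fitter(model_name)
    step = series.step
    buf_periods = list(series.periods[-n:])
    buf_values = list(series.values[-n:])
    out_periods: list[int] = []
    out_values: list[float] = []
    for _ in range(horizon):
        window = Series(np.array(buf_periods), np.array(buf_values))
        fit = fitter(window)
        if not fit.well_posed:
            raise ModelError(
                f"ill-posed {model_name} fit while extrapolating: {'; '.join(fit.diagnostics)}"
            )
        forecast = float(simulate_static(fit, horizon=1).values[-1])
        if forecast <= 0.0:
            raise ModelError(
                f"extrapolated forecast became nonpositive ({forecast:.6g}); "
                "metabolic continuation cannot proceed"
            )
        next_period = buf_periods[-1] + step
        out_periods.append(next_period)
        out_values.append(forecast)
        buf_periods = buf_periods[1:] + [next_period]
        buf_values = buf_values[1:] + [forecast]
    return Series(np.array(out_periods), np.array(out_values))
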