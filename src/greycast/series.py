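"""Positive, equally spaced series and the accumulation operators (AGO/IAGO).

Grey models never work on the raw observations directly: they model the
first-order accumulated generating operation (1-AGO) of the series,
``x1(k) = sum_{i<=k} x0(i)``, which smooths short noisy count data into a
near-monotone sequence that a first-order difference/differential equation
can describe.  The inverse operation (IAGO) restores the original scale by
first differencing, keeping the first element.

All model mathematics uses the 1-based position ``t = 1..n``.  Period labels
(typically years) are metadata carried through for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Series",
    "AccumulatedSeries",
    "SeriesValidationError",
    "ago",
    "iago",
    "read_series_csv",
    "write_series_csv",
]


class SeriesValidationError(ValueError):
    """An input series violates the grey-modelling contract."""


@dataclass
class Series:
    """A univariate, strictly positive, equally spaced series.

    Parameters
    ----------
    periods
        Strictly increasing integer labels (e.g. years) with a constant step.
    values
        Observations, one per period.  Strictly positive: both the models'
        accumulated scale and MAPE are undefined at zero, so zeros are
        rejected rather than epsilon-adjusted — rescale the data instead.
    require_positive
        Predicted series produced by a model may dip to or below zero for a
        badly conditioned fit; such outputs are constructed with
        ``require_positive=False``.  Observed input data always keeps the
        default ``True``.
    """

    periods: np.ndarray
    values: np.ndarray
    require_positive: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        periods = np.atleast_1d(np.asarray(self.periods))
        if not np.issubdtype(periods.dtype, np.integer):
            cast = periods.astype(np.int64, copy=True)
            if not np.array_equal(cast, periods):
                raise SeriesValidationError("period labels must be integers")
            periods = cast
        else:
            periods = periods.astype(np.int64, copy=False)
        values = np.atleast_1d(np.asarray(self.values, dtype=np.float64))

        if periods.ndim != 1 or values.ndim != 1:
            raise SeriesValidationError("periods and values must be one-dimensional")
        if len(periods) != len(values):
            raise SeriesValidationError(
                f"length mismatch: {len(periods)} periods vs {len(values)} values"
            )
        if len(values) == 0:
            raise SeriesValidationError("series must contain at least one observation")
        if not np.all(np.isfinite(values)):
            bad = periods[~np.isfinite(values)][0]
            raise SeriesValidationError(f"non-finite value at period {bad}")
        if self.require_positive and np.any(values <= 0.0):
            bad = periods[values <= 0.0][0]
            raise SeriesValidationError(
                f"nonpositive value at period {bad}: grey models and MAPE require "
                "strictly positive data"
            )
        if len(periods) >= 2:
            steps = np.diff(periods)
            if steps[0] <= 0 or np.any(steps != steps[0]):
                raise SeriesValidationError(
                    "periods must be strictly increasing with a constant step"
                )
        self.periods = periods
        self.values = values

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_obs(self) -> int:
        return len(self.values)

    @property
    def step(self) -> int:
        return int(self.periods[1] - self.periods[0]) if len(self) >= 2 else 1

    @classmethod
    def from_values(cls, values, first_period: int = 1) -> "Series":
        values = np.atleast_1d(np.asarray(values, dtype=np.float64))
        periods = first_period + np.arange(len(values), dtype=np.int64)
        return cls(periods, values)

    def slice(self, start: int, stop: int) -> "Series":
        """Contiguous sub-series by 0-based half-open index range."""
        if not (0 <= start < stop <= len(self)):
            raise SeriesValidationError(f"invalid slice [{start}:{stop}] of length-{len(self)} series")
        return Series(self.periods[start:stop], self.values[start:stop],
                      require_positive=self.require_positive)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"period": self.periods, "value": self.values})


@dataclass
class AccumulatedSeries:
    """The 1-AGO sequence x1 of a series, with a reference to its origin."""

    values: np.ndarray
    origin: Series

    def __post_init__(self) -> None:
        values = np.atleast_1d(np.asarray(self.values, dtype=np.float64))
        if len(values) == 0:
            raise SeriesValidationError("accumulated series must be nonempty")
        if len(values) != len(self.origin):
            raise SeriesValidationError("accumulated series length differs from origin")
        self.values = values

    def __len__(self) -> int:
        return len(self.values)


def ago(series: Series) -> AccumulatedSeries:
    """First-order accumulated generating operation: x1(k) = Σ_{i<=k} x0(i)."""
    return AccumulatedSeries(np.cumsum(series.values), series)


def iago(acc: AccumulatedSeries) -> Series:
    """Inverse AGO: first differences with the first element kept.

    ``iago(ago(s))`` reproduces ``s`` (exactly up to the float summation path).
    """
    if len(acc) == 0:  # defensive; AccumulatedSeries already rejects empties
        raise SeriesValidationError("cannot restore an empty accumulated series")
    restored = np.diff(acc.values, prepend=0.0)
    return Series(acc.origin.periods, restored,
                  require_positive=acc.origin.require_positive)


# -- CSV contract -----------------------------------------------------------------
# Two columns with header `period,value`, UTF-8, '.' decimal separator; periods
# must parse as integers.

def read_series_csv(path) -> Series:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface parser detail to the caller
        raise SeriesValidationError(f"cannot parse CSV {path}: {exc}") from exc
    missing = [c for c in ("period", "value") if c not in frame.columns]
    if missing:
        raise SeriesValidationError(
            f"{path}: missing column(s) {missing}; expected header 'period,value'"
        )
    periods_raw = pd.to_numeric(frame["period"], errors="coerce")
    values_raw = pd.to_numeric(frame["value"], errors="coerce")
    for col, parsed in (("period", periods_raw), ("value", values_raw)):
        if parsed.isna().any():
            line = int(parsed.index[parsed.isna()][0]) + 2  # +1 header, +1 one-based
            raise SeriesValidationError(f"{path}: unparseable {col} on line {line}")
    if not np.array_equal(periods_raw, periods_raw.astype(np.int64)):
        line = int(np.nonzero(periods_raw != periods_raw.astype(np.int64))[0][0]) + 2
        raise SeriesValidationError(f"{path}: non-integer period on line {line}")
    return Series(periods_raw.astype(np.int64).to_numpy(), values_raw.to_numpy())


def write_series_csv(series: Series, path) -> None:
    series.to_frame().to_csv(path, index=False)
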