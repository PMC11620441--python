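"""Error metrics and the static-vs-dynamic model comparison workflow.

MAPE — 100 x mean(|predicted - actual| / actual) — is the core suitability
index throughout: it is scale free, so models and window sizes can be
compared across series of very different magnitude, at the price of being
undefined at zero actuals (hence the strict-positivity input contract).

Index-set conventions, the main source of irreproducibility in grey-model
comparisons, are made explicit in every report: static fits are scored over
t = 2..n (t = 1 is anchored exactly by construction and would deflate the
average); dynamic fits over t = n+1..n_obs (the first n points are in-window,
not forecast).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import MODEL_NAMES, ModelError, get_fitter
from .rolling import DEFAULT_CANDIDATES, optimize_window, roll
from .series import Series

__all__ = [
    "mape",
    "relative_error_series",
    "ModelResult",
    "ComparisonReport",
    "compare_models",
    "DYNAMIC_LABELS",
]

#: field names of the metabolic variants of each static model
DYNAMIC_LABELS = {"gm": "MGM", "dngm": "DNMGM", "dgm": "MDGM",
                  "idgm": "MIDGM", "ddgm": "MDDGM"}


def _check_pair(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.atleast_1d(np.asarray(actual, dtype=np.float64))
    p = np.atleast_1d(np.asarray(predicted, dtype=np.float64))
    if a.size == 0:
        raise ValueError("empty input: MAPE needs at least one point")
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.size} actual vs {p.size} predicted")
    if np.any(a <= 0.0) or not np.all(np.isfinite(a)):
        raise ValueError("actual values must be finite and strictly positive")
    return a, p


def relative_error_series(actual, predicted) -> np.ndarray:
    """Per-index percentage errors 100 x |predicted - actual| / actual."""
    a, p = _check_pair(actual, predicted)
    return 100.0 * np.abs((p - a) / a)


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, in percent."""
    return float(np.mean(relative_error_series(actual, predicted)))


@dataclass
class ModelResult:
    """One model's error track within a comparison."""

    label: str
    kind: str                       # "static" or "dynamic"
    model: str
    window_size: int | None
    eval_periods: tuple[int, ...]
    relative_errors: tuple[float, ...]   # percent, aligned with eval_periods
    mape: float
    note: str = ""
    failed: str | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "kind": self.kind,
            "model": self.model,
            "window_size": self.window_size,
            "eval_periods": list(self.eval_periods),
            "relative_errors_pct": list(self.relative_errors),
            "mape": self.mape,
            "note": self.note,
            "failed": self.failed,
        }


@dataclass
class ComparisonReport:
    """Per-model error tracks, MAPEs and the ascending-MAPE ranking."""

    series_periods: tuple[int, ...]
    results: list[ModelResult] = field(default_factory=list)

    @property
    def ranking(self) -> list[str]:
        ok = [r for r in self.results if r.failed is None and np.isfinite(r.mape)]
        return [r.label for r in sorted(ok, key=lambda r: r.mape)]

    def result(self, label: str) -> ModelResult:
        for r in self.results:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "series_periods": list(self.series_periods),
            "results": [r.to_dict() for r in self.results],
            "ranking": self.ranking,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            if r.failed is not None:
                continue
            for period, err in zip(r.eval_periods, r.relative_errors):
                rows.append({"label": r.label, "kind": r.kind, "model": r.model,
                             "window_size": r.window_size, "period": period,
                             "relative_error_pct": err})
        return pd.DataFrame(rows)

    def summary_table(self) -> str:
        """Plain-text model-vs-MAPE table, percentages to 2 decimals."""
        lines = [f"{'model':<14}{'kind':<9}{'MAPE %':>8}  evaluation"]
        for r in sorted(self.results, key=lambda r: (r.failed is not None, r.mape)):
            if r.failed is not None:
                lines.append(f"{r.label:<14}{r.kind:<9}{'--':>8}  failed: {r.failed}")
            else:
                span = f"{r.eval_periods[0]}..{r.eval_periods[-1]}"
                extra = f" ({r.note})" if r.note else ""
                lines.append(f"{r.label:<14}{r.kind:<9}{r.mape:>8.2f}  {span}{extra}")
        return "\n".join(lines)


def compare_models(
    series: Series,
    static: tuple[str, ...] = MODEL_NAMES,
    dynamic: tuple[tuple[str, int | None], ...] = (("gm", 6), ("dngm", 6)),
    candidates=DEFAULT_CANDIDATES,
) -> ComparisonReport:
    """Fit static models full-span and roll dynamic specs, then rank by MAPE.

    ``dynamic`` entries are (model, n) pairs; ``n=None`` triggers a window
    search over ``candidates`` first.  Infeasible specs are recorded as failed
    entries rather than aborting the comparison.
    """
    report = ComparisonReport(series_periods=tuple(series.periods.tolist()))
    for name in static:
        label = name.upper()
        try:
            fit = get_fitter(name)(series)
            errors = relative_error_series(series.values[1:], fit.simulated[1:])
            report.results.append(ModelResult(
                label=label, kind="static", model=name, window_size=None,
                eval_periods=tuple(series.periods[1:].tolist()),
                relative_errors=tuple(errors.tolist()),
                mape=fit.in_sample_mape,
                note="full-span fit, t=1 anchored/excluded",
            ))
        except (ModelError, ValueError) as exc:
            report.results.append(ModelResult(
                label=label, kind="static", model=name, window_size=None,
                eval_periods=(), relative_errors=(), mape=float("nan"),
                failed=str(exc),
            ))
    for name, n in dynamic:
        try:
            note = ""
            if n is None:
                search = optimize_window(series, name, candidates)
                n = search.best_size
                note = f"window selected by MAPE sweep over {list(search.candidate_sizes)}"
            track = roll(series, name, n)
            defined = [(s.period, 100.0 * s.relative_error)
                       for s in track.steps if s.relative_error is not None]
            label = f"{DYNAMIC_LABELS.get(name, 'M' + name.upper())}(n={n})"
            report.results.append(ModelResult(
                label=label, kind="dynamic", model=name, window_size=n,
                eval_periods=tuple(p for p, _ in defined),
                relative_errors=tuple(e for _, e in defined),
                mape=track.overall_mape,
                note=note or f"one-step-ahead over t={n + 1}..{len(series)}",
            ))
        except (ModelError, ValueError) as exc:
            label = f"{DYNAMIC_LABELS.get(name, 'M' + str(name).upper())}(n={n})"
            report.results.append(ModelResult(
                label=label, kind="dynamic", model=name, window_size=n,
                eval_periods=(), relative_errors=(), mape=float("nan"),
                failed=str(exc),
            ))
    return report
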