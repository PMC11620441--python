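"""The five static grey models: GM(1,1), DGM(1,1), DNGM(1,1), IDGM(1,1), DDGM(1,1).

The centrepiece is the discrete nonhomogeneous grey model DNGM(1,1).  Its
whitening equation is the first-order ODE with a linear drive

    dx1/dt + A x1 = B t + C ,

whose time response, anchored at the first observation x1(1), is

    x1(t) = K e^{-A(t-1)} + (B/A) t - B/A^2 + C/A ,
    K     = x1(1) - B/A + B/A^2 - C/A ,

and whose original-scale restoration (first difference of the response) is

    x0(t) = (1 - e^A) K e^{-A(t-1)} + B/A            for t >= 2.

The response satisfies an *exact* linear recursion on the accumulated scale,

    x1(t+1) = alpha x1(t) + beta t + gamma ,

with the bijection

    alpha = e^{-A},
    beta  = (B/A) (1 - e^{-A}),
    gamma = (1 - e^{-A}) (C/A - B/A^2) + B/A .

DNGM estimates (alpha, beta, gamma) by least squares on that recursion, so the
discrete estimate is free of discretisation error.  Classical GM(1,1), by
contrast, estimates its development coefficient from a trapezoidal
("background value") difference equation that is *not* exactly consistent
with its own exponential time response — the source of its restoration bias
on exactly exponential data, demonstrated in the test suite.

IDGM(1,1) and DDGM(1,1) are only sketched in the literature this library
follows; the plain reconstructions used here are: IDGM applies the DGM(1,1)
recursion one accumulation level up (on x2 = AGO(x1)) and restores twice;
DDGM fits the linear recursion directly on the raw data with no accumulation.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .series import Series, SeriesValidationError

__all__ = [
    "ModelError",
    "RecursionParams",
    "WhiteningParams",
    "LinearRecursionParams",
    "GMParams",
    "ModelFit",
    "MODEL_NAMES",
    "MIN_WINDOW",
    "fit_gm",
    "fit_dgm",
    "fit_dngm",
    "fit_idgm",
    "fit_ddgm",
    "get_fitter",
    "simulate_static",
    "whitening_to_recursion",
    "recursion_to_whitening",
    "dngm_time_response",
    "dngm_restore",
]

#: reciprocal-condition-number threshold below which a design matrix is
#: flagged as (near-)singular and the fit marked not well posed.
RCOND_SINGULAR = 1e-12

#: |alpha - 1| below this is treated as alpha == 1 (no whitening form).
ALPHA_UNIT_TOL = 1e-12

MODEL_NAMES = ("gm", "dgm", "dngm", "idgm", "ddgm")

#: minimum window length per model: three recursion equations are needed for
#: DNGM's three unknowns; the two-parameter models need two equations but four
#: points are required for any overdetermination except DDGM, which the
#: direct-modelling literature allows from three points.
MIN_WINDOW = {"gm": 4, "dgm": 4, "dngm": 4, "idgm": 4, "ddgm": 3}


class ModelError(ValueError):
    """A model cannot be fitted or simulated under the given conditions."""


# -- parameter records --------------------------------------------------------------


@dataclass(frozen=True)
class RecursionParams:
    """Parameters of the DNGM recursion x1(t+1) = alpha x1(t) + beta t + gamma."""

    alpha: float
    beta: float
    gamma: float
    well_posed: bool = True
    rcond: float = float("nan")


@dataclass(frozen=True)
class WhiteningParams:
    """Continuous-time DNGM parameters (A, B, C) and the response coefficient K.

    A is the decay (A > 0) or growth (A < 0) rate per index step; B the slope
    and C the constant of the nonhomogeneous drive.  Defined only when the
    fitted alpha is positive and not 1, so that A = -ln(alpha) exists and is
    nonzero.
    """

    A: float
    B: float
    C: float
    K: float


@dataclass(frozen=True)
class LinearRecursionParams:
    """Parameters of a plain linear recursion y(k+1) = beta1 y(k) + beta2.

    Used by DGM(1,1) (y = x1), IDGM(1,1) (y = x2) and DDGM(1,1) (y = x0).
    """

    beta1: float
    beta2: float
    well_posed: bool = True
    rcond: float = float("nan")


@dataclass(frozen=True)
class GMParams:
    """GM(1,1) development coefficient ``a`` and grey input ``b``."""

    a: float
    b: float
    well_posed: bool = True
    rcond: float = float("nan")


@dataclass
class ModelFit:
    """One grey model fitted to one data window.

    ``simulated`` holds the restored in-sample values on the original scale;
    its first element equals the observed first value (every model anchors the
    initial condition at t = 1).  ``in_sample_mape`` is evaluated over
    t = 2..n — the anchored first point would deflate the average.
    """

    model_name: str
    params: RecursionParams | LinearRecursionParams | GMParams
    window: Series
    simulated: np.ndarray
    in_sample_mape: float
    whitening: WhiteningParams | None = None
    diagnostics: tuple[str, ...] = ()

    @property
    def well_posed(self) -> bool:
        return self.params.well_posed

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "params": asdict(self.params),
            "whitening": asdict(self.whitening) if self.whitening is not None else None,
            "window_periods": self.window.periods.tolist(),
            "window_values": self.window.values.tolist(),
            "simulated": self.simulated.tolist(),
            "in_sample_mape": self.in_sample_mape,
            "evaluation_positions": f"t=2..{len(self.window)} (t=1 anchored)",
            "diagnostics": list(self.diagnostics),
        }


# -- whitening <-> recursion mapping -------------------------------------------------


def whitening_to_recursion(params: WhiteningParams) -> RecursionParams:
    """Map continuous (A, B, C) to the exact discrete recursion (alpha, beta, gamma)."""
    A, B, C = params.A, params.B, params.C
    if A == 0.0:
        raise ModelError("whitening parameters require A != 0")
    alpha = math.exp(-A)
    beta = (B / A) * (1.0 - alpha)
    gamma = (1.0 - alpha) * (C / A - B / A**2) + B / A
    return RecursionParams(alpha, beta, gamma)


def recursion_to_whitening(params: RecursionParams, x1_initial: float) -> WhiteningParams:
    """Invert the discrete->continuous mapping; defined for alpha > 0, alpha != 1."""
    alpha, beta, gamma = params.alpha, params.beta, params.gamma
    if alpha <= 0.0 or abs(alpha - 1.0) < ALPHA_UNIT_TOL:
        raise ModelError(
            f"whitening form undefined for alpha={alpha!r}: requires alpha > 0 and "
            "alpha != 1; forecast by iterating the recursion instead"
        )
    A = -math.log(alpha)
    B = A * beta / (1.0 - alpha)
    C = A * ((gamma - B / A) / (1.0 - alpha) + B / A**2)
    K = x1_initial - B / A + B / A**2 - C / A
    return WhiteningParams(A=A, B=B, C=C, K=K)


def dngm_time_response(params: WhiteningParams, x1_initial: float, t):
    """Closed-form accumulated response x1(t); t may be a scalar or array, t >= 1.

    The response coefficient is recomputed from ``x1_initial`` so that
    ``t = 1`` returns ``x1_initial`` exactly.
    """
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 1):
        raise ModelError("time response defined for t >= 1")
    A, B, C = params.A, params.B, params.C
    K = x1_initial - B / A + B / A**2 - C / A
    out = K * np.exp(-A * (t_arr - 1.0)) + (B / A) * t_arr - B / A**2 + C / A
    return out if out.ndim else float(out)


def dngm_restore(params: WhiteningParams, x1_initial: float, t):
    """Original-scale restored value x0(t) = x1(t) - x1(t-1); defined for t >= 2."""
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 2):
        raise ModelError("restoration defined for t >= 2; t = 1 is anchored to the observation")
    A, B = params.A, params.B
    K = x1_initial - B / A + B / params.A**2 - params.C / A
    out = (1.0 - math.exp(A)) * K * np.exp(-A * (t_arr - 1.0)) + B / A
    return out if out.ndim else float(out)


# -- shared fitting machinery --------------------------------------------------------


def _lstsq(design: np.ndarray, rhs: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Least squares via SVD; returns (theta, rcond, well_posed)."""
    sv = np.linalg.svd(design, compute_uv=False)
    rcond = float(sv[-1] / sv[0]) if sv[0] > 0 else 0.0
    well_posed = rcond > RCOND_SINGULAR
    theta, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return theta, rcond, well_posed


def _require_window(window: Series, model_name: str) -> None:
    need = MIN_WINDOW[model_name]
    if len(window) < need:
        raise ModelError(
            f"{model_name} requires a window of at least {need} observations, "
            f"got {len(window)}"
        )


def _restore_from_accumulated(x1_path: np.ndarray, anchor: float) -> np.ndarray:
    restored = np.diff(x1_path, prepend=0.0)
    restored[0] = anchor
    return restored


def _simulate_values(model_name: str, params, anchor: float, total: int) -> np.ndarray:
    """Restored original-scale path of length ``total`` for a fitted model.

    ``anchor`` is the observed first value x0(1) (= x1(1) = x2(1)); every
    model starts its own recursion there.
    """
    if model_name == "dngm":
        x1 = np.empty(total)
        x1[0] = anchor
        for i in range(1, total):
            x1[i] = params.alpha * x1[i - 1] + params.beta * i + params.gamma
        return _restore_from_accumulated(x1, anchor)
    if model_name == "dgm":
        x1 = np.empty(total)
        x1[0] = anchor
        for i in range(1, total):
            x1[i] = params.beta1 * x1[i - 1] + params.beta2
        return _restore_from_accumulated(x1, anchor)
    if model_name == "idgm":
        x2 = np.empty(total)
        x2[0] = anchor
        for i in range(1, total):
            x2[i] = params.beta1 * x2[i - 1] + params.beta2
        x1 = _restore_from_accumulated(x2, anchor)
        return _restore_from_accumulated(x1, anchor)
    if model_name == "ddgm":
        x0 = np.empty(total)
        x0[0] = anchor
        for i in range(1, total):
            x0[i] = params.beta1 * x0[i - 1] + params.beta2
        return x0
    if model_name == "gm":
        a, b = params.a, params.b
        k = np.arange(total, dtype=np.float64)
        if abs(a) < 1e-12:  # degenerate: whitening ODE collapses to dx1/dt = b
            x1 = anchor + b * k
        else:
            x1 = (anchor - b / a) * np.exp(-a * k) + b / a
        return _restore_from_accumulated(x1, anchor)
    raise ModelError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")


def _in_sample_mape(actual: np.ndarray, simulated: np.ndarray) -> float:
    # evaluated over t = 2..n: t = 1 is anchored by construction
    rel = np.abs((simulated[1:] - actual[1:]) / actual[1:])
    return float(100.0 * np.mean(rel))


def _finish_fit(model_name: str, params, window: Series,
                diagnostics: list[str], whitening=None) -> ModelFit:
    simulated = _simulate_values(model_name, params, window.values[0], len(window))
    return ModelFit(
        model_name=model_name,
        params=params,
        window=window,
        simulated=simulated,
        in_sample_mape=_in_sample_mape(window.values, simulated),
        whitening=whitening,
        diagnostics=tuple(diagnostics),
    )


# -- the five fitters ----------------------------------------------------------------


def fit_dngm(window: Series) -> ModelFit:
    """Fit DNGM(1,1): least squares on x1(t+1) = alpha x1(t) + beta t + gamma.

    The drift regressor is the *source* index t (the position of x1(t)).
    When alpha > 0 and alpha != 1 the continuous whitening parameters are
    attached; otherwise forecasting proceeds by the recursion alone, which is
    always sufficient.
    """
    _require_window(window, "dngm")
    x1 = np.cumsum(window.values)
    n = len(x1)
    t_src = np.arange(1, n, dtype=np.float64)
    design = np.column_stack([x1[:-1], t_src, np.ones(n - 1)])
    theta, rcond, well_posed = _lstsq(design, x1[1:])
    params = RecursionParams(float(theta[0]), float(theta[1]), float(theta[2]),
                             well_posed=well_posed, rcond=rcond)
    diagnostics: list[str] = []
    if not well_posed:
        diagnostics.append(
            f"near-singular design (rcond={rcond:.2e}): parameters unreliable"
        )
    whitening = None
    if params.alpha > 0.0 and abs(params.alpha - 1.0) >= ALPHA_UNIT_TOL:
        whitening = recursion_to_whitening(params, float(x1[0]))
    else:
        diagnostics.append(
            f"alpha={params.alpha:.6g}: whitening form undefined; "
            "forecasting by the fitted recursion"
        )
    return _finish_fit("dngm", params, window, diagnostics, whitening)


def fit_gm(window: Series) -> ModelFit:
    """Fit classical GM(1,1) with background values z1(k) = (x1(k)+x1(k-1))/2.

    Least squares on x0(k) = -a z1(k) + b for k = 2..n; simulation uses the
    whitening time response x1(k) = (x0(1) - b/a) e^{-a(k-1)} + b/a restored
    by differencing.  |a| ~ 0 degenerates to a linear accumulated path, i.e. a
    flat forecast at level b.
    """
    _require_window(window, "gm")
    x0 = window.values
    x1 = np.cumsum(x0)
    z = 0.5 * (x1[1:] + x1[:-1])
    design = np.column_stack([-z, np.ones(len(z))])
    theta, rcond, well_posed = _lstsq(design, x0[1:])
    params = GMParams(float(theta[0]), float(theta[1]), well_posed=well_posed, rcond=rcond)
    diagnostics: list[str] = []
    if not well_posed:
        diagnostics.append(f"near-singular design (rcond={rcond:.2e}): parameters unreliable")
    if abs(params.a) < 1e-12:
        diagnostics.append("development coefficient a ~ 0: degenerate flat forecast at level b")
    return _finish_fit("gm", params, window, diagnostics)


def fit_dgm(window: Series) -> ModelFit:
    """Fit DGM(1,1): least squares on x1(k+1) = beta1 x1(k) + beta2."""
    _require_window(window, "dgm")
    x1 = np.cumsum(window.values)
    design = np.column_stack([x1[:-1], np.ones(len(x1) - 1)])
    theta, rcond, well_posed = _lstsq(design, x1[1:])
    params = LinearRecursionParams(float(theta[0]), float(theta[1]),
                                   well_posed=well_posed, rcond=rcond)
    diagnostics = [] if well_posed else [
        f"near-singular design (rcond={rcond:.2e}): parameters unreliable"
    ]
    return _finish_fit("dgm", params, window, diagnostics)


def fit_idgm(window: Series) -> ModelFit:
    """Fit IDGM(1,1): the DGM recursion one accumulation level up.

    Treats y0 = x1 as the raw sequence, accumulates again to y1 = x2, fits
    y1(k+1) = beta1 y1(k) + beta2, and restores twice (each difference
    anchored at its first observed element).
    """
    _require_window(window, "idgm")
    x2 = np.cumsum(np.cumsum(window.values))
    design = np.column_stack([x2[:-1], np.ones(len(x2) - 1)])
    theta, rcond, well_posed = _lstsq(design, x2[1:])
    params = LinearRecursionParams(float(theta[0]), float(theta[1]),
                                   well_posed=well_posed, rcond=rcond)
    diagnostics = [] if well_posed else [
        f"near-singular design (rcond={rcond:.2e}): parameters unreliable"
    ]
    return _finish_fit("idgm", params, window, diagnostics)


def fit_ddgm(window: Series) -> ModelFit:
    """Fit DDGM(1,1): direct modelling, x0(k+1) = beta1 x0(k) + beta2.

    No accumulation anywhere — appropriate when the raw series itself is
    already approximately (non)homogeneous exponential.
    """
    _require_window(window, "ddgm")
    x0 = window.values
    design = np.column_stack([x0[:-1], np.ones(len(x0) - 1)])
    theta, rcond, well_posed = _lstsq(design, x0[1:])
    params = LinearRecursionParams(float(theta[0]), float(theta[1]),
                                   well_posed=well_posed, rcond=rcond)
    diagnostics = [] if well_posed else [
        f"near-singular design (rcond={rcond:.2e}): parameters unreliable"
    ]
    return _finish_fit("ddgm", params, window, diagnostics)


_FITTERS = {
    "gm": fit_gm,
    "dgm": fit_dgm,
    "dngm": fit_dngm,
    "idgm": fit_idgm,
    "ddgm": fit_ddgm,
}


def get_fitter(model_name: str):
    try:
        return _FITTERS[model_name]
    except KeyError:
        raise ModelError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}") from None


def simulate_static(fit: ModelFit, horizon: int = 0) -> Series:
    """In-sample simulated values followed by ``horizon`` extrapolated steps.

    Extrapolation iterates the fitted model's own recursion past the window.
    The returned series is a prediction, so positivity is not enforced.
    """
    if horizon < 0:
        raise ModelError("horizon must be >= 0")
    if not fit.well_posed:
        raise ModelError(
            f"cannot simulate an ill-posed {fit.model_name} fit: {'; '.join(fit.diagnostics)}"
        )
    total = len(fit.window) + horizon
    values = _simulate_values(fit.model_name, fit.params, fit.window.values[0], total)
    step = fit.window.step
    periods = fit.window.periods[0] + step * np.arange(total, dtype=np.int64)
    return Series(periods, values, require_positive=False)
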