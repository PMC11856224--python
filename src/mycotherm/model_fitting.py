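"""Nonlinear least-squares fitting, fit statistics, ranking, and curve comparison.

The Ratkowsky response surface is multimodal in the cardinal temperatures
(T1, T2), so every fit runs bounded trust-region least squares
(:func:`scipy.optimize.least_squares`) from multiple deterministic starting
points drawn from a Latin hypercube over the parameter bounds, plus a
data-driven heuristic start.  The best (lowest-RSS) solution is returned;
identical input and seed give identical estimates.

Goodness of fit is summarized by R², adjusted R², the least-squares form of
Akaike's information criterion ``AIC = n·ln(RSS/n) + 2(k+1)`` (counting the
error variance as a parameter), RMSE and RSS.  Candidate models are ranked
by ascending AIC, ties broken by descending adjusted R² then ascending RSS.

Two groups' curves are compared with a likelihood-ratio chi-square under
Gaussian errors: one curve is fitted to the pooled data and one to each
group; the statistic is ``n_total · ln(RSS_pooled / RSS_separate)`` with
degrees of freedom equal to the number of parameters freed by the separate
fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2, qmc

from .thermal_models import (
    ThermalModel,
    ThermalModelParams,
    TimeCourseFamily,
    TimeCourseParams,
    eval_thermal,
    eval_time_course,
)

__all__ = [
    "ResponsePoint",
    "FitStatistics",
    "FittedModel",
    "CurveComparison",
    "FitOptions",
    "InsufficientDataError",
    "fit_model",
    "fit_statistics",
    "rank_models",
    "compare_curves",
    "read_points",
    "points_to_frame",
]

ModelId = Union[ThermalModel, TimeCourseFamily, str]


class InsufficientDataError(ValueError):
    """Fewer points than the model's free-parameter count allows."""


@dataclass(frozen=True)
class ResponsePoint:
    """One observation: predictor x (°C or day), response y, optional labels."""

    x: float
    y: float
    group: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite observation: x={self.x}, y={self.y}")


@dataclass(frozen=True)
class FitStatistics:
    r2: float
    adj_r2: float
    aic: float
    rmse: float
    rss: float
    n: int
    k: int


@dataclass(frozen=True)
class FittedModel:
    params: ThermalModelParams | TimeCourseParams
    stats: FitStatistics | None
    converged: bool
    n_starts_used: int

    def predict(self, x) -> np.ndarray:
        if isinstance(self.params, ThermalModelParams):
            return eval_thermal(x, self.params)
        return eval_time_course(x, self.params)


@dataclass(frozen=True)
class CurveComparison:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class FitOptions:
    """Fitting controls: multi-start count, RNG seed, optional bound overrides."""

    n_starts: int = 20
    seed: int = 0
    bounds: dict[str, tuple[float, float]] | None = None
    max_nfev: int = 2000


# Default box constraints.  Cardinal temperatures follow the mesophilic range
# of the organism; scale and rate parameters are positive and generously
# bounded.  Time-course location e is in days (assay horizon scale).
_THERMAL_BOUNDS = {
    "cc": (1e-6, 100.0),
    "k": (1e-6, 100.0),
    "k1": (1e-6, 100.0),
    "k2": (1e-6, 100.0),
    "T1": (0.0, 25.0),
    "T2": (25.0, 45.0),
}
_TIMECOURSE_BOUNDS = {
    "b": (1e-3, 50.0),
    "d": (0.0, 1.0),
    "e": (1e-3, 60.0),
}


def _model_spec(model_id: ModelId, options: FitOptions):
    """Return (names, lower, upper, build, predict) for a model family."""
    try:
        model_id = ThermalModel(model_id)
    except ValueError:
        model_id = TimeCourseFamily(model_id)

    if isinstance(model_id, ThermalModel):
        names = (
            ("cc", "k1", "k2", "T1", "T2")
            if model_id is ThermalModel.RATKOWSKY1
            else ("cc", "k", "T1", "T2")
        )
        base = _THERMAL_BOUNDS

        def build(theta: np.ndarray) -> ThermalModelParams:
            kw = dict(zip(names, theta))
            return ThermalModelParams(model_id=model_id, **kw)

        predict: Callable = eval_thermal
    else:
        names = ("b", "d", "e")
        base = _TIMECOURSE_BOUNDS

        def build(theta: np.ndarray) -> TimeCourseParams:
            return TimeCourseParams(family=model_id, b=theta[0], d=theta[1], e=theta[2])

        predict = eval_time_course

    overrides = options.bounds or {}
    lower = np.array([overrides.get(n, base[n])[0] for n in names])
    upper = np.array([overrides.get(n, base[n])[1] for n in names])
    return model_id, names, lower, upper, build, predict


def _heuristic_start(model_id, names, lower, upper, x, y) -> np.ndarray:
    """A data-driven initial point, clipped into the bounds."""
    start = {}
    if isinstance(model_id, ThermalModel):
        start["T1"] = float(np.min(x)) - 1.0
        start["T2"] = float(np.max(x)) + 1.0
        peak = float(np.max(y)) if np.max(y) > 0 else 1.0
        span = max(float(np.max(x) - np.min(x)), 1.0)
        if model_id is ThermalModel.RATKOWSKY1:
            start.update(cc=peak, k1=1.0 / span, k2=0.1)
        else:
            start.update(cc=math.sqrt(peak) / span, k=0.1)
    else:
        start["d"] = min(max(float(np.max(y)), 0.05), 1.0)
        start["e"] = float(np.median(x))
        start["b"] = 1.0
    theta = np.array([start[n] for n in names])
    return np.clip(theta, lower, upper)


def fit_model(
    points: Sequence[ResponsePoint],
    model_id: ModelId,
    options: FitOptions | None = None,
    extra_starts: Sequence[np.ndarray] = (),
) -> FittedModel:
    """Fit a thermal or time-course model to points by multi-start least squares.

    Non-convergence of every start is reported through the ``converged`` flag
    rather than an exception; too few distinct predictors raises
    :class:`InsufficientDataError`.
    """
    options = options or FitOptions()
    model_id, names, lower, upper, build, predict = _model_spec(model_id, options)
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    k = len(names)
    if len(np.unique(x)) < k + 1:
        raise InsufficientDataError(
            f"need at least {k + 1} distinct predictor values for {k} parameters, "
            f"got {len(np.unique(x))}"
        )

    sampler = qmc.LatinHypercube(d=k, seed=options.seed)
    unit = sampler.random(n=options.n_starts)
    starts = [qmc.scale(unit[i : i + 1], lower, upper)[0] for i in range(options.n_starts)]
    starts.append(_heuristic_start(model_id, names, lower, upper, x, y))
    starts.extend(np.clip(np.asarray(s, float), lower, upper) for s in extra_starts)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return predict(x, build(theta)) - y

    best_theta, best_rss, any_success = None, np.inf, False
    for theta0 in starts:
        # keep T1 < T2 strictly at the start
        if isinstance(model_id, ThermalModel):
            i1, i2 = names.index("T1"), names.index("T2")
            if theta0[i1] >= theta0[i2]:
                theta0 = theta0.copy()
                theta0[i1], theta0[i2] = lower[i1], upper[i2]
        try:
            res = least_squares(
                residuals, theta0, bounds=(lower, upper), method="trf",
                max_nfev=options.max_nfev,
            )
        except (ValueError, FloatingPointError):
            continue
        rss = float(np.sum(res.fun**2))
        if rss < best_rss - 1e-15 or best_theta is None:
            best_theta, best_rss = res.x, rss
        any_success = any_success or res.success

    params = build(best_theta)
    try:
        stats = fit_statistics(y, predict(x, params), k)
    except ValueError:  # zero total sum of squares (e.g. all-zero response)
        stats = None
        any_success = False
    return FittedModel(
        params=params, stats=stats, converged=bool(any_success),
        n_starts_used=len(starts),
    )


def fit_statistics(observed, predicted, k: int) -> FitStatistics:
    """Goodness-of-fit summary of predicted vs observed values.

    ``aic`` uses the least-squares convention ``n·ln(RSS/n) + 2(k+1)``; a
    perfect fit (RSS = 0) reports ``aic = -inf``.  Raises if the observed
    values have zero total sum of squares (R² undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n < k + 2:
        raise InsufficientDataError(f"need n >= k + 2 points, got n={n}, k={k}")
    rss = float(np.sum((obs - pred) ** 2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("zero total sum of squares: R^2 undefined")
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    rmse = math.sqrt(rss / n)
    aic = -math.inf if rss <= 0.0 else n * math.log(rss / n) + 2 * (k + 1)
    return FitStatistics(r2=r2, adj_r2=adj_r2, aic=aic, rmse=rmse, rss=rss, n=n, k=k)


def rank_models(fits: Sequence[FittedModel]) -> list[FittedModel]:
    """Order fits best-first: ascending AIC, then descending adjusted R²,
    then ascending RSS; non-converged fits always last."""
    if not fits:
        raise ValueError("no fits to rank")

    def key(f: FittedModel):
        if not f.converged or f.stats is None:
            return (1, math.inf, math.inf, math.inf)
        return (0, f.stats.aic, -f.stats.adj_r2, f.stats.rss)

    return sorted(fits, key=key)


def compare_curves(
    group_a: Sequence[ResponsePoint],
    group_b: Sequence[ResponsePoint],
    family: ModelId,
    options: FitOptions | None = None,
) -> CurveComparison:
    """Likelihood-ratio chi-square test that two groups share one curve.

    Fits the family once to the pooled data and once per group; under the
    null (a common curve), ``n_total·ln(RSS_pooled/RSS_separate)`` is
    asymptotically chi-square with df equal to the extra free parameters.
    """
    options = options or FitOptions()
    pooled = fit_model(list(group_a) + list(group_b), family, options)
    pooled_theta = _theta_of(pooled.params)
    fit_a = fit_model(group_a, family, options, extra_starts=[pooled_theta])
    fit_b = fit_model(group_b, family, options, extra_starts=[pooled_theta])
    rss_pooled = pooled.stats.rss if pooled.stats else float(
        np.sum((pooled.predict([p.x for p in list(group_a) + list(group_b)])
                - np.array([p.y for p in list(group_a) + list(group_b)])) ** 2))
    rss_sep = _rss_of(fit_a, group_a) + _rss_of(fit_b, group_b)
    n_total = len(group_a) + len(group_b)
    df = len(pooled_theta)
    if rss_sep <= 0.0:
        if rss_pooled <= 0.0:
            return CurveComparison(statistic=0.0, df=df, p_value=1.0)
        return CurveComparison(statistic=math.inf, df=df, p_value=0.0)
    stat = max(n_total * math.log(rss_pooled / rss_sep), 0.0)
    return CurveComparison(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


def _theta_of(params: ThermalModelParams | TimeCourseParams) -> np.ndarray:
    if isinstance(params, ThermalModelParams):
        return np.array([getattr(params, n) for n in params.free_names()])
    return np.array([params.b, params.d, params.e])


def _rss_of(fit: FittedModel, points: Sequence[ResponsePoint]) -> float:
    if fit.stats is not None:
        return fit.stats.rss
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    return float(np.sum((fit.predict(x) - y) ** 2))


# --- tabular I/O -------------------------------------------------------------

def read_points(path: str | Path, sep: str = ",") -> list[ResponsePoint]:
    """Read (x, y[, group[, replicate]]) observations from delimited text."""
    df = pd.read_csv(path, sep=sep)
    required = {"x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"input table must have columns {sorted(required)}, got {list(df.columns)}")
    return [
        ResponsePoint(
            x=float(r.x), y=float(r.y),
            group=str(getattr(r, "group", "")), replicate=str(getattr(r, "replicate", "")),
        )
        for r in df.itertuples(index=False)
    ]


def points_to_frame(points: Sequence[ResponsePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {"x": [p.x for p in points], "y": [p.y for p in points],
         "group": [p.group for p in points], "replicate": [p.replicate for p in points]}
    )
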