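"""Temperature-response and time-mortality model functions.

Thermal performance of the fungus (mycelial growth rate, nymphal mortality)
is described by Ratkowsky-type square-of-product curves with explicit
cardinal temperatures ``T1`` (lower) and ``T2`` (upper) at which the response
is zero, and an exponential decline toward the upper limit.  Two variants are
supported:

ratkowsky1
    ``r(T) = cc * [k1 * (T - T1) * (1 - exp(k2 * (T - T2)))]**2``
    with an outer scale factor ``cc``; used for proportion-scale responses
    such as 7-day nymphal mortality.

ratkowsky2
    ``r(T) = [cc * (T - T1) * (1 - exp(k * (T - T2)))]**2``
    with the scale inside the square; used for colony growth rate in
    arbitrary units.

Both curves are defined as exactly zero outside the biological range
``[T1, T2]`` (the squared expression is mathematically positive there, but
no growth or infection occurs beyond the cardinal temperatures).

Cumulative time-mortality curves ``F(t)`` are standard dose-response
families (logistic, log-logistic, log-normal, Weibull, Gompertz), each with
an upper asymptote ``d`` (the mortality plateau), steepness ``b`` and
location ``e`` in days, and each with a closed-form inverse used for median
lethal time (LT50) estimation.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "ThermalModel",
    "TimeCourseFamily",
    "ThermalModelParams",
    "TimeCourseParams",
    "eval_ratkowsky1",
    "eval_ratkowsky2",
    "eval_thermal",
    "eval_time_course",
    "thermal_optimum",
    "load_params",
    "dump_params",
    "FIG5_VIRULENCE",
    "TABLE6_EXPERIMENT1",
    "TABLE6_EXPERIMENT2",
    "TABLE6_EXPERIMENT3",
]


class InvalidParameterError(ValueError):
    """A model parameter is missing, non-finite, or violates an invariant."""


class ThermalModel(str, enum.Enum):
    RATKOWSKY1 = "ratkowsky1"
    RATKOWSKY2 = "ratkowsky2"


class TimeCourseFamily(str, enum.Enum):
    LOGISTIC = "logistic"
    LOG_LOGISTIC = "log_logistic"
    LOG_NORMAL = "log_normal"
    WEIBULL = "weibull"
    GOMPERTZ = "gompertz"


def _require_finite(name: str, value: float) -> float:
    if value is None or not math.isfinite(value):
        raise InvalidParameterError(f"parameter {name!r} is missing or non-finite: {value!r}")
    return float(value)


@dataclass(frozen=True)
class ThermalModelParams:
    """Parameters of a named temperature-response model.

    ``model_id`` selects the family; ``ratkowsky1`` uses (cc, k1, k2, T1, T2)
    and ``ratkowsky2`` uses (cc, k, T1, T2).  ``T1 < T2`` and ``cc >= 0`` are
    enforced on construction.
    """

    model_id: ThermalModel
    cc: float
    T1: float
    T2: float
    k1: float | None = None
    k2: float | None = None
    k: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_id", ThermalModel(self.model_id))
        _require_finite("cc", self.cc)
        _require_finite("T1", self.T1)
        _require_finite("T2", self.T2)
        if self.cc < 0:
            raise InvalidParameterError(f"cc must be >= 0, got {self.cc}")
        if not self.T1 < self.T2:
            raise InvalidParameterError(f"require T1 < T2, got T1={self.T1}, T2={self.T2}")
        if self.model_id is ThermalModel.RATKOWSKY1:
            _require_finite("k1", self.k1)
            _require_finite("k2", self.k2)
        else:
            _require_finite("k", self.k)

    def free_names(self) -> tuple[str, ...]:
        """Names of the free parameters of this family, in fitting order."""
        if self.model_id is ThermalModel.RATKOWSKY1:
            return ("cc", "k1", "k2", "T1", "T2")
        return ("cc", "k", "T1", "T2")

    def to_dict(self) -> dict:
        d = {"model_id": self.model_id.value, "cc": self.cc, "T1": self.T1, "T2": self.T2}
        if self.model_id is ThermalModel.RATKOWSKY1:
            d.update(k1=self.k1, k2=self.k2)
        else:
            d.update(k=self.k)
        return d


@dataclass(frozen=True)
class TimeCourseParams:
    """Parameters (family, b, d, e) of a cumulative time-mortality curve.

    ``d`` is the upper asymptote (final mortality proportion, 0-1), ``b`` the
    steepness and ``e`` the location in days (log-day scale for the
    log-logistic and log-normal families).
    """

    family: TimeCourseFamily
    b: float
    d: float
    e: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", TimeCourseFamily(self.family))
        _require_finite("b", self.b)
        _require_finite("d", self.d)
        _require_finite("e", self.e)
        if not 0.0 <= self.d <= 1.0:
            raise InvalidParameterError(f"asymptote d must lie in [0, 1], got {self.d}")
        if self.b <= 0:
            raise InvalidParameterError(f"steepness b must be > 0, got {self.b}")
        if self.e <= 0 and self.family in (
            TimeCourseFamily.LOG_LOGISTIC,
            TimeCourseFamily.LOG_NORMAL,
            TimeCourseFamily.WEIBULL,
        ):
            raise InvalidParameterError(
                f"location e must be > 0 for family {self.family.value}, got {self.e}"
            )

    def to_dict(self) -> dict:
        return {"family": self.family.value, "b": self.b, "d": self.d, "e": self.e}


ArrayLike = Union[float, np.ndarray]


def eval_ratkowsky1(T: ArrayLike, params: ThermalModelParams) -> ArrayLike:
    """Proportion-scale response of the outer-cc Ratkowsky curve at T (°C).

    Returns ``cc * [k1*(T-T1)*(1-exp(k2*(T-T2)))]**2`` inside ``[T1, T2]``
    and exactly 0 outside.
    """
    if params.model_id is not ThermalModel.RATKOWSKY1:
        raise InvalidParameterError(f"expected ratkowsky1 parameters, got {params.model_id.value}")
    T_arr = np.asarray(T, dtype=float)
    with np.errstate(over="ignore"):  # optimizer may probe extreme (k2, T) corners
        core = params.k1 * (T_arr - params.T1) * (1.0 - np.exp(params.k2 * (T_arr - params.T2)))
        out = params.cc * core**2
    out = np.where((T_arr < params.T1) | (T_arr > params.T2), 0.0, out)
    return float(out) if np.isscalar(T) else out


def eval_ratkowsky2(T: ArrayLike, params: ThermalModelParams) -> ArrayLike:
    """Growth-rate response of the classic Ratkowsky curve at T (°C).

    Returns ``[cc*(T-T1)*(1-exp(k*(T-T2)))]**2`` inside ``[T1, T2]`` and
    exactly 0 outside.
    """
    if params.model_id is not ThermalModel.RATKOWSKY2:
        raise InvalidParameterError(f"expected ratkowsky2 parameters, got {params.model_id.value}")
    T_arr = np.asarray(T, dtype=float)
    with np.errstate(over="ignore"):
        core = params.cc * (T_arr - params.T1) * (1.0 - np.exp(params.k * (T_arr - params.T2)))
        out = core**2
    out = np.where((T_arr < params.T1) | (T_arr > params.T2), 0.0, out)
    return float(out) if np.isscalar(T) else out


def eval_thermal(T: ArrayLike, params: ThermalModelParams) -> ArrayLike:
    """Dispatch to the evaluator matching ``params.model_id``."""
    if params.model_id is ThermalModel.RATKOWSKY1:
        return eval_ratkowsky1(T, params)
    return eval_ratkowsky2(T, params)


def eval_time_course(t: ArrayLike, params: TimeCourseParams) -> ArrayLike:
    """Cumulative mortality proportion F(t) at t days post-inoculation.

    Monotone non-decreasing in t and bounded in [0, d].  Raises for t < 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time t must be >= 0")
    b, d, e = params.b, params.d, params.e
    fam = params.family
    if fam is TimeCourseFamily.LOGISTIC:
        with np.errstate(over="ignore"):
            out = d / (1.0 + np.exp(-b * (t_arr - e)))
    elif fam is TimeCourseFamily.LOG_LOGISTIC:
        with np.errstate(divide="ignore"):
            out = np.where(t_arr > 0, d / (1.0 + (t_arr / e) ** (-b)), 0.0)
    elif fam is TimeCourseFamily.LOG_NORMAL:
        with np.errstate(divide="ignore"):
            out = np.where(t_arr > 0, d * norm.cdf(b * np.log(np.maximum(t_arr, 1e-300) / e)), 0.0)
    elif fam is TimeCourseFamily.WEIBULL:
        with np.errstate(over="ignore"):
            out = d * (1.0 - np.exp(-((t_arr / e) ** b)))
    else:  # gompertz
        with np.errstate(over="ignore"):
            out = d * np.exp(-np.exp(-b * (t_arr - e)))
    return float(out) if np.isscalar(t) else out


def thermal_optimum(
    params: ThermalModelParams, resolution: float = 0.01
) -> tuple[float, float]:
    """Locate the temperature maximizing the response on [T1, T2].

    Deterministic: coarse 0.1 °C grid scan followed by bounded
    golden-section refinement around the best grid point.  Returns
    ``(T_opt, r_max)`` with ``T_opt`` accurate to within ``resolution``.
    """
    if not params.T1 < params.T2:
        raise InvalidParameterError("degenerate interval: T1 >= T2")
    lo, hi = params.T1, params.T2
    grid = np.arange(lo, hi + 1e-12, 0.1)
    vals = eval_thermal(grid, params)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    if a == b:
        a, b = lo, hi
    res = minimize_scalar(
        lambda T: -eval_thermal(float(T), params),
        bounds=(float(a), float(b)),
        method="bounded",
        options={"xatol": resolution / 10.0},
    )
    T_opt = float(res.x)
    return T_opt, float(eval_thermal(T_opt, params))


# --- serialization -----------------------------------------------------------

def dump_params(params: ThermalModelParams | TimeCourseParams, path: str | Path) -> None:
    """Write a parameter set as a flat key-value JSON document."""
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def load_params(source: str | Path | dict) -> ThermalModelParams | TimeCourseParams:
    """Load a parameter set from a JSON/YAML-style mapping or a JSON file."""
    if isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text())
    else:
        doc = dict(source)
    if "family" in doc:
        return TimeCourseParams(
            family=doc["family"], b=doc["b"], d=doc["d"], e=doc["e"]
        )
    known = {"model_id", "cc", "k", "k1", "k2", "T1", "T2"}
    return ThermalModelParams(**{k: v for k, v in doc.items() if k in known})


def _bundled(name: str) -> ThermalModelParams:
    return load_params(Path(__file__).parent / "params" / name)


# Published parameter sets for the C. javanica BRM 27666 strain, loaded from
# the bundled JSON fixtures.
FIG5_VIRULENCE: ThermalModelParams
TABLE6_EXPERIMENT1: ThermalModelParams
TABLE6_EXPERIMENT2: ThermalModelParams
TABLE6_EXPERIMENT3: ThermalModelParams

FIG5_VIRULENCE = _bundled("virulence_constant_temperature.json")
TABLE6_EXPERIMENT1 = _bundled("growth_experiment1.json")
TABLE6_EXPERIMENT2 = _bundled("growth_experiment2.json")
TABLE6_EXPERIMENT3 = _bundled("growth_experiment3.json")
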