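"""Synthetic growth, mortality, and climate inputs for the analysis pipeline.

The generators emulate the statistical structure the pipeline assumes:

* colony-growth trajectories driven by a Ratkowsky-shaped temperature
  response with additive Gaussian measurement noise;
* binomial cumulative-mortality time courses whose 7-day plateau follows the
  thermal performance curve and whose median lethal time follows prescribed
  LT50 truths, with a low spontaneous control-mortality series and
  per-cadaver mycosis confirmation;
* monthly minimum/maximum temperature grids with a latitudinal gradient,
  a seasonal sinusoid, and a random diurnal range, together with the
  analytically known performance class of every cell.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spatial import (
    DEFAULT_EDGES,
    DEFAULT_MONTHS,
    ClimateGrid,
    MonthlyStack,
)
from .thermal_models import (
    FIG5_VIRULENCE,
    ThermalModelParams,
    eval_thermal,
)
from .time_mortality import MortalityDataset

__all__ = [
    "RegimeKind",
    "TemperatureRegime",
    "SimulationTruth",
    "default_truth",
    "simulate_growth",
    "simulate_mortality",
    "simulate_climate",
]

#: Probability that a fungus-killed nymph shows confirmatory sporulation.
MYCOSIS_PROB = 0.95


class RegimeKind(str, enum.Enum):
    CONSTANT = "constant"
    PULSE_THEN_AMBIENT = "pulse_then_ambient"
    DAILY_ALTERNATING = "daily_alternating"


@dataclass(frozen=True)
class TemperatureRegime:
    """An exposure schedule: constant, a single pulse, or a daily alternation.

    ``treatment_temp`` is the incubator temperature; non-constant kinds spend
    ``pulse_hours`` per day (or once, for a single pulse) at it and the rest
    at ``ambient_mean``.
    """

    kind: RegimeKind
    treatment_temp: float
    ambient_mean: float = math.nan
    pulse_hours: float = 6.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", RegimeKind(self.kind))
        if self.kind is not RegimeKind.CONSTANT:
            if not math.isfinite(self.ambient_mean):
                raise ValueError("non-constant regimes need an ambient_mean")
            if not 0.0 < self.pulse_hours <= 24.0:
                raise ValueError("pulse_hours must lie in (0, 24]")

    @property
    def label(self) -> str:
        if self.kind is RegimeKind.CONSTANT:
            return f"constant_{self.treatment_temp:g}C"
        return f"{self.kind.value}_{self.treatment_temp:g}C"


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth shared by the generators and the recovery tests.

    ``lt50_by_temp`` maps a treatment temperature (°C) to the target median
    lethal time in days; ``control_rate`` is the daily spontaneous mortality
    hazard of untreated nymphs; ``steepness`` is the logistic slope of the
    cumulative mortality curve (per day); ``noise_sd`` scales the Gaussian
    measurement noise on colony areas (mm²).
    """

    thermal: ThermalModelParams
    lt50_by_temp: dict[float, float] = field(default_factory=dict)
    control_rate: float = 0.005
    noise_sd: float = 10.0
    steepness: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.control_rate <= 1.0:
            raise ValueError("control_rate must lie in [0, 1]")
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")


def default_truth() -> SimulationTruth:
    """Published virulence curve with its reported constant-regime LT50s."""
    return SimulationTruth(
        thermal=FIG5_VIRULENCE,
        lt50_by_temp={25.0: 6.3, 30.0: 5.4},
    )


# --- growth ------------------------------------------------------------------

def simulate_growth(
    truth: SimulationTruth,
    temps: Sequence[float],
    days: Sequence[int] = (3, 4, 5, 6, 7, 10),
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Colony-area trajectories at each temperature.

    The area grows linearly at the thermal-response rate (mm²/day) with
    additive Gaussian noise of sd ``truth.noise_sd``, floored at 0.  Colony
    length and width (mm) are emitted assuming an elliptical colony,
    ``area = π·L·W/4`` with L = W.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for temp in temps:
        rate = float(eval_thermal(float(temp), truth.thermal))
        for rep in range(reps):
            for day in days:
                area = rate * day + rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 \
                    else rate * day
                area = max(area, 0.0)
                diam = math.sqrt(4.0 * area / math.pi)
                rows.append(
                    {"temperature": float(temp), "day": int(day), "replicate": f"r{rep}",
                     "length_mm": diam, "width_mm": diam, "area_mm2": area}
                )
    return pd.DataFrame(rows)


# --- mortality ---------------------------------------------------------------

def _plateau(truth: SimulationTruth, regime: TemperatureRegime) -> float:
    """7-day mortality plateau: thermal response at the effective temperature.

    Constant regimes respond to the treatment temperature; pulse and
    alternating regimes are temperature-insensitive and respond to the
    ambient mean (the fungus completes infection at ambient temperature).
    """
    temp = (
        regime.treatment_temp
        if regime.kind is RegimeKind.CONSTANT
        else regime.ambient_mean
    )
    return float(min(eval_thermal(float(temp), truth.thermal), 1.0))


def _location_for_lt50(d: float, b: float, lt50: float) -> float:
    """Logistic location e such that the absolute-50% crossing sits at lt50."""
    if d > 0.5:
        return lt50 + math.log(2.0 * d - 1.0) / b
    return lt50


def _cumulative_curve(truth: SimulationTruth, regime: TemperatureRegime,
                      days: np.ndarray) -> np.ndarray:
    d = _plateau(truth, regime)
    lt50 = truth.lt50_by_temp.get(regime.treatment_temp, float(np.median(days)))
    e = _location_for_lt50(d, truth.steepness, lt50)
    return d / (1.0 + np.exp(-truth.steepness * (days - e)))


def _binomial_timecourse(rng: np.random.Generator, F: np.ndarray, n: int):
    """Monotone cumulative dead counts with Binomial(n, F(t)) margins."""
    dead = np.zeros(len(F), dtype=int)
    prev_F, prev_dead = 0.0, 0
    new_deaths = np.zeros(len(F), dtype=int)
    for i, f in enumerate(F):
        hazard = 0.0 if prev_F >= 1.0 else (f - prev_F) / (1.0 - prev_F)
        hazard = min(max(hazard, 0.0), 1.0)
        add = rng.binomial(n - prev_dead, hazard)
        new_deaths[i] = add
        dead[i] = prev_dead + add
        prev_F, prev_dead = f, dead[i]
    return dead, new_deaths


def simulate_mortality(
    truth: SimulationTruth,
    regimes: Sequence[TemperatureRegime],
    days: Sequence[int] = (3, 4, 5, 6, 7),
    n_per_rep: int = 60,
    reps: int = 4,
    seed: int = 0,
    include_control: bool = True,
) -> MortalityDataset:
    """Binomial cumulative-mortality assay across temperature regimes.

    Each replicate holds ``n_per_rep`` nymphs; cumulative dead counts follow
    the regime's logistic curve through conditional binomial increments, so
    counts are monotone and marginally Binomial(n, F(day)).  A ``mycosed``
    column counts cadavers with confirmatory sporulation (probability
    ``MYCOSIS_PROB`` per fungus-killed nymph).  An untreated control series
    with daily hazard ``truth.control_rate`` is appended unless disabled.
    """
    rng = np.random.default_rng(seed)
    day_arr = np.asarray(sorted(days), dtype=float)
    rows = []
    for regime in regimes:
        F = _cumulative_curve(truth, regime, day_arr)
        for rep in range(reps):
            dead, new = _binomial_timecourse(rng, F, n_per_rep)
            myc_new = rng.binomial(new, MYCOSIS_PROB)
            myc = np.cumsum(myc_new)
            for i, day in enumerate(day_arr):
                rows.append(
                    {"regime": regime.label, "day": int(day), "dead": int(dead[i]),
                     "total": n_per_rep, "replicate": f"r{rep}", "mycosed": int(myc[i])}
                )
    if include_control:
        F_control = 1.0 - (1.0 - truth.control_rate) ** day_arr
        for rep in range(reps):
            dead, _ = _binomial_timecourse(rng, F_control, n_per_rep)
            for i, day in enumerate(day_arr):
                rows.append(
                    {"regime": "control", "day": int(day), "dead": int(dead[i]),
                     "total": n_per_rep, "replicate": f"r{rep}", "mycosed": 0}
                )
    return MortalityDataset(pd.DataFrame(rows))


# --- climate -----------------------------------------------------------------

def simulate_climate(
    nrows: int,
    ncols: int,
    lat_range: tuple[float, float] = (-35.0, 5.0),
    seed: int = 0,
    lon_range: tuple[float, float] = (-75.0, -30.0),
    midpoint_range: tuple[float, float] = (18.0, 28.0),
    seasonal_amp: float = 4.0,
    diurnal_range: tuple[float, float] = (6.0, 12.0),
    nodata_fraction: float = 0.0,
    params: ThermalModelParams | None = None,
    months: Iterable[int] = DEFAULT_MONTHS,
    edges: Sequence[float] = DEFAULT_EDGES,
):
    """Monthly Tmin/Tmax stack with a north-south gradient and seasonal cycle.

    The daily midpoint temperature varies linearly with latitude from
    ``midpoint_range[1]`` at the northern edge to ``midpoint_range[0]`` at
    the southern edge, plus a sinusoid of amplitude ``seasonal_amp`` peaking
    in January (austral summer).  Tmin/Tmax straddle the midpoint by a
    random per-cell-month diurnal range.  Because the range is symmetric,
    the midpoint field is deterministic, so when a thermal model ``params``
    is supplied the true performance class of every valid cell (mean
    midpoint-policy response over ``months``, classified by ``edges``) is
    returned alongside the stack.

    Returns ``(stack, truth_classes)``; ``truth_classes`` is None without
    ``params``.
    """
    if nrows <= 0 or ncols <= 0:
        raise ValueError("grid dimensions must be positive")
    rng = np.random.default_rng(seed)
    lat_lo, lat_hi = min(lat_range), max(lat_range)
    lon_lo, lon_hi = min(lon_range), max(lon_range)
    cellsize = (lat_hi - lat_lo) / nrows
    # row 0 is the northern edge; cell-center latitudes
    lats = lat_hi - (np.arange(nrows) + 0.5) * cellsize
    frac = (lats - lat_lo) / (lat_hi - lat_lo)  # 1 at north, 0 at south
    mid_lat = midpoint_range[0] + frac * (midpoint_range[1] - midpoint_range[0])
    mid_lat = np.repeat(mid_lat[:, None], ncols, axis=1)

    nodata_mask = (
        rng.random((nrows, ncols)) < nodata_fraction
        if nodata_fraction > 0
        else np.zeros((nrows, ncols), dtype=bool)
    )

    def month_mid(m: int) -> np.ndarray:
        return mid_lat + seasonal_amp * math.cos(2.0 * math.pi * (m - 1) / 12.0)

    tmin, tmax = {}, {}
    for m in range(1, 13):
        mid = month_mid(m)
        dr = rng.uniform(diurnal_range[0], diurnal_range[1], size=(nrows, ncols))
        lo = mid - dr / 2.0
        hi = mid + dr / 2.0
        lo[nodata_mask] = np.nan
        hi[nodata_mask] = np.nan
        geo = dict(cellsize=cellsize, xllcorner=lon_lo, yllcorner=lat_lo)
        tmin[m] = ClimateGrid(values=lo, **geo)
        tmax[m] = ClimateGrid(values=hi, **geo)
    stack = MonthlyStack(tmin=tmin, tmax=tmax)

    truth_classes = None
    if params is not None:
        months = tuple(months)
        resp = np.mean([eval_thermal(month_mid(m), params) for m in months], axis=0)
        percent = np.minimum(resp * 100.0, 100.0)
        truth_classes = np.searchsorted(
            np.asarray(edges, dtype=float), percent, side="right"
        ).astype(int)
        truth_classes[nodata_mask] = -1
    return stack, truth_classes
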