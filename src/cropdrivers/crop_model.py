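"""Generic daily-timestep crop simulator with switchable stress mechanisms.

A single process-based model (thermal-time phenology, light interception with
radiation-use efficiency, a soil-water bucket, threshold heat damage around
anthesis, and logarithmic CO2 response factors) stands in for an ensemble of
crop models.  Drought, heat (driven by air or simulated canopy temperature)
and CO2 effects can be enabled independently, which is what allows yield
variability to be decomposed into its climatic drivers:

* T1 -- mean-temperature effects only (full irrigation, no heat damage),
* T2 -- heat stress from air temperature, full irrigation,
* T3 -- heat stress from canopy temperature, full irrigation,
* T4 -- drought, no heat damage,
* T5 -- drought + heat stress from air temperature,
* T6 -- drought + heat stress from canopy temperature.

Two parameter presets are shipped: a C3 winter cereal ("winter_wheat",
critical heat threshold 31 degC) and a C4 summer cereal ("grain_maize",
threshold 35 degC).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, NamedTuple

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .synthetic_data import SoilProfile, WeatherSeries

CO2_AMBIENT_PPM = 360.0

__all__ = [
    "CO2_AMBIENT_PPM",
    "CropParameters",
    "TreatmentSpec",
    "SeasonResult",
    "CANONICAL_TREATMENTS",
    "saturation_vapor_pressure",
    "daily_vpd",
    "thermal_time_increment",
    "canopy_temperature",
    "heat_stress_retention",
    "co2_factors",
    "water_balance_step",
    "transpiration_demand",
    "simulate_season",
    "simulate_batch",
    "preset",
    "load_crop_parameters",
    "save_crop_parameters",
]


# --------------------------------------------------------------------------
# parameterisation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TreatmentSpec:
    """One of the six canonical stress-switch treatments."""

    id: str
    water_limited: bool
    heat_mode: str  # 'none' | 'air' | 'canopy'

    def __post_init__(self) -> None:
        if self.heat_mode not in ("none", "air", "canopy"):
            raise ValueError(f"unknown heat_mode {self.heat_mode!r}")


#: Fixed mapping of treatment ids to stress switches.
CANONICAL_TREATMENTS: dict[str, TreatmentSpec] = {
    "T1": TreatmentSpec("T1", water_limited=False, heat_mode="none"),
    "T2": TreatmentSpec("T2", water_limited=False, heat_mode="air"),
    "T3": TreatmentSpec("T3", water_limited=False, heat_mode="canopy"),
    "T4": TreatmentSpec("T4", water_limited=True, heat_mode="none"),
    "T5": TreatmentSpec("T5", water_limited=True, heat_mode="air"),
    "T6": TreatmentSpec("T6", water_limited=True, heat_mode="canopy"),
}


@dataclass(frozen=True)
class CropParameters:
    """Parameter set for one crop (or one perturbed pseudo-ensemble member).

    Units: temperatures degC, thermal times degC d, RUE g biomass per MJ
    global radiation, TE coefficient g biomass kPa m-2 mm-1 water, areas of
    leaves m2 m-2.  CO2 response factors are logarithmic in [CO2]/360; for a
    C4 crop the photosynthesis (beta_rue) and leaf-area (lambda_lai)
    responses are identically zero, only transpiration efficiency responds.
    """

    name: str = "winter_wheat"
    crop_class: str = "C3"  # 'C3' | 'C4'
    sowing_doy: int = 289
    t_base: float = 3.0
    t_opt: float = 24.0
    t_suit_span: float = 10.0  # degC of linear RUE decline above t_opt
    tt_emergence: float = 100.0
    tt_anthesis: float = 1250.0
    tt_maturity: float = 1900.0
    senescence_start_frac: float = 0.35  # of anthesis->maturity thermal time
    rue: float = 1.4
    harvest_index: float = 0.45
    max_lai: float = 6.0
    k_ext: float = 0.55
    t_crit: float = 31.0
    heat_slope: float = 0.05  # HI fraction lost per degC d above t_crit
    heat_window_before: float = 100.0  # degC d before anthesis
    heat_window_after: float = 250.0  # degC d after anthesis
    heat_senescence_threshold: float = math.inf  # degC d; inf disables
    te_c: float = 5.0
    beta_rue: float = 0.08  # C3 RUE response to ln([CO2]/360)
    gamma_te: float = 0.10  # TE response, both classes
    lambda_lai: float = 0.04  # C3 leaf-area response
    delta_heat: float = 5.0  # canopy warming over air at f_w = 0
    delta_cool: float = 2.0  # canopy cooling below air at f_w = 1
    k_r: float = 0.1  # daily extractable fraction of the bucket
    simulates_canopy: bool = True

    def __post_init__(self) -> None:
        if self.crop_class not in ("C3", "C4"):
            raise ValueError(f"crop_class must be C3 or C4, got {self.crop_class!r}")
        if not self.t_base < self.t_opt:
            raise ValueError("t_base must be below t_opt")
        if not 0 < self.tt_anthesis < self.tt_maturity:
            raise ValueError("need 0 < tt_anthesis < tt_maturity")
        for attr in ("rue", "harvest_index", "te_c", "max_lai", "k_ext"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if self.heat_slope < 0:
            raise ValueError("heat_slope must be >= 0")
        if self.delta_heat < 0 or self.delta_cool < 0:
            raise ValueError("canopy offsets must be >= 0")
        if not 0 < self.k_r <= 1:
            raise ValueError("k_r must be in (0, 1]")
        if self.crop_class == "C4" and (self.beta_rue != 0 or self.lambda_lai != 0):
            raise ValueError("C4 crops must have beta_rue = lambda_lai = 0")

    def replace(self, **kw) -> "CropParameters":
        return dataclasses.replace(self, **kw)


_PRESETS: dict[str, dict] = {
    # autumn-sown C3 cereal; low base temperature stands in for the cool
    # establishment phase of a vernalising winter crop
    "winter_wheat": {},
    # spring-sown C4 cereal: higher cardinal temperatures, higher TE, no
    # photosynthetic or leaf-area CO2 response
    "grain_maize": dict(
        name="grain_maize",
        crop_class="C4",
        sowing_doy=115,
        t_base=6.0,
        t_opt=28.0,
        tt_emergence=80.0,
        tt_anthesis=600.0,
        tt_maturity=1150.0,
        rue=1.7,
        harvest_index=0.50,
        max_lai=5.0,
        t_crit=35.0,
        heat_slope=0.05,
        te_c=9.0,
        beta_rue=0.0,
        lambda_lai=0.0,
    ),
}


def preset(name: str) -> CropParameters:
    """Return one of the shipped crop parameterisations."""
    try:
        return CropParameters(**_PRESETS[name])
    except KeyError:
        raise KeyError(f"no preset {name!r}; available: {sorted(_PRESETS)}") from None


def load_crop_parameters(path) -> CropParameters:
    with open(path) as fh:
        return CropParameters(**yaml.safe_load(fh))


def save_crop_parameters(params: CropParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=False)


# --------------------------------------------------------------------------
# elementary process functions
# --------------------------------------------------------------------------

def saturation_vapor_pressure(t):
    """Saturation vapor pressure (kPa) at air temperature ``t`` (degC).

    Tetens form, 0.6108 * exp(17.27 t / (t + 237.3)); strictly increasing
    and convex, which is what makes atmospheric water demand respond
    non-linearly to warming.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= -50):
        raise ValueError("temperature out of the valid range (> -50 degC)")
    out = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return float(out) if out.ndim == 0 else out


def daily_vpd(tmax, tmin, ea):
    """Daily vapor pressure deficit (kPa) from extreme temperatures and ea."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    ea = np.asarray(ea, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax")
    if np.any(ea < 0):
        raise ValueError("actual vapor pressure must be >= 0")
    es_mean = 0.5 * (saturation_vapor_pressure(tmax) + saturation_vapor_pressure(tmin))
    out = np.maximum(0.0, es_mean - ea)
    return float(out) if out.ndim == 0 else out


def thermal_time_increment(tavg, t_base, t_opt):
    """Daily thermal-time increment (degC d): linear between base and
    optimum, zero below base, capped at ``t_opt - t_base`` above optimum."""
    if not np.all(np.asarray(t_base) < np.asarray(t_opt)):
        raise ValueError("t_base must be below t_opt")
    out = np.clip(np.asarray(tavg, dtype=float) - t_base, 0.0, t_opt - t_base)
    return float(out) if out.ndim == 0 else out


def canopy_temperature(t_air, f_w, params: CropParameters):
    """Canopy temperature (degC) as air temperature plus a drought-driven
    warming and minus a transpirational-cooling term.

    At full transpiration (f_w = 1) the canopy sits ``delta_cool`` below the
    air; with transpiration fully shut down (f_w = 0) it sits ``delta_heat``
    above it.  Strictly decreasing in f_w.
    """
    f_w = np.asarray(f_w, dtype=float)
    if np.any((f_w < 0) | (f_w > 1)):
        raise ValueError("f_w must lie in [0, 1]")
    out = (
        np.asarray(t_air, dtype=float)
        + params.delta_heat * (1.0 - f_w)
        - params.delta_cool * f_w
    )
    return float(out) if out.ndim == 0 else out


def heat_stress_retention(driver_temps, t_crit, slope):
    """Fraction of harvest index retained after threshold heat damage.

    ``retention = max(0, 1 - slope * sum(max(0, T - t_crit)))`` over the
    daily driver temperatures inside the heat-sensitive window.
    """
    if slope < 0:
        raise ValueError("slope must be >= 0")
    exceed = np.maximum(0.0, np.asarray(driver_temps, dtype=float) - t_crit)
    return float(max(0.0, 1.0 - slope * exceed.sum()))


def co2_factors(crop_class: str, co2, params: CropParameters):
    """Multipliers (rue_mult, te_mult, lai_mult) at atmospheric [CO2] ``co2``.

    All equal 1 at the 360 ppm ambient reference.  Transpiration efficiency
    responds for both photosynthetic classes; RUE and leaf-area expansion
    respond only for C3 (a C4 canopy is CO2-saturated, so its potential
    production is exactly invariant).
    """
    co2 = float(co2)
    if co2 < CO2_AMBIENT_PPM:
        raise ValueError("co2 below the 360 ppm ambient reference")
    lnr = math.log(co2 / CO2_AMBIENT_PPM)
    te_mult = 1.0 + params.gamma_te * lnr
    if crop_class == "C4":
        return 1.0, te_mult, 1.0
    return 1.0 + params.beta_rue * lnr, te_mult, 1.0 + params.lambda_lai * lnr


class WaterStep(NamedTuple):
    new_state: float
    supply: float
    f_w: float
    irrigation_applied: float
    drainage: float


def water_balance_step(
    state: float,
    precip: float,
    demand: float,
    profile: "SoilProfile",
    irrigation: bool,
    k_r: float = 0.1,
) -> WaterStep:
    """Advance the single-layer soil-water bucket by one day.

    Supply is limited to the extractable fraction ``k_r`` of the current
    store; full automatic irrigation tops supply up to demand so the drought
    factor f_w is exactly 1.  Overflow beyond TAWC drains.  Water is
    conserved exactly: inflows - outflows = change of store.
    """
    if demand < 0 or state < 0:
        raise ValueError("state and demand must be >= 0")
    tawc = profile.tawc_mm
    soil_supply = min(demand, k_r * state)
    irrigation_applied = demand - soil_supply if irrigation else 0.0
    supply = demand if irrigation else soil_supply
    f_w = 1.0 if (irrigation or demand == 0) else soil_supply / demand
    raw_state = state + precip + irrigation_applied - supply
    drainage = max(0.0, raw_state - tawc)
    new_state = min(max(raw_state, 0.0), tawc)
    return WaterStep(new_state, supply, f_w, irrigation_applied, drainage)


def transpiration_demand(potential_growth, vpd, te_c, te_mult=1.0):
    """Water (mm) required to realise ``potential_growth`` (g m-2 d-1) at the
    day's VPD, via the transpiration-efficiency coefficient."""
    if np.any(np.asarray(te_c) == 0):
        raise ValueError("te_c must be non-zero")
    pg = np.asarray(potential_growth, dtype=float)
    if np.any(pg < 0) or np.any(np.asarray(vpd) < 0):
        raise ValueError("inputs must be >= 0")
    out = pg * np.asarray(vpd, dtype=float) / (te_c * te_mult)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# season engine
# --------------------------------------------------------------------------

_HEAT_CODES = {"none": 0, "air": 1, "canopy": 2}

#: CropParameters fields broadcast per season by the batch engine.
_PARAM_FIELDS = (
    "t_base", "t_opt", "t_suit_span", "tt_emergence", "tt_anthesis",
    "tt_maturity", "senescence_start_frac", "rue", "harvest_index",
    "max_lai", "k_ext", "t_crit", "heat_slope", "heat_window_before",
    "heat_window_after", "heat_senescence_threshold", "te_c", "beta_rue",
    "gamma_te", "lambda_lai", "delta_heat", "delta_cool", "k_r",
)


@dataclass
class SeasonResult:
    """Outcome of one simulated crop season."""

    yield_t_ha: float
    biomass_t_ha: float
    sowing_date: pd.Timestamp
    anthesis_date: pd.Timestamp
    maturity_date: pd.Timestamp
    transpiration_mm: float
    irrigation_mm: float
    mean_fw: float
    heat_exceedance_cdd: float
    retention: float
    treatment: str
    co2_ppm: float
    matured: bool

    def __post_init__(self) -> None:
        if self.yield_t_ha < 0 or self.yield_t_ha > self.biomass_t_ha + 1e-9:
            raise ValueError("yield must lie in [0, biomass]")
        if not (self.maturity_date >= self.anthesis_date >= self.sowing_date):
            raise ValueError("phenology dates out of order")
        if self.transpiration_mm < 0 or self.irrigation_mm < 0:
            raise ValueError("water amounts must be >= 0")


def simulate_batch(
    weather_arrays: dict[str, np.ndarray],
    cell_index: np.ndarray,
    sow_index: np.ndarray,
    param_arrays: dict[str, np.ndarray],
    crop_is_c4: np.ndarray,
    water_limited: np.ndarray,
    heat_mode_code: np.ndarray,
    co2_ppm: np.ndarray,
    tawc_mm: np.ndarray,
    initial_water_mm: np.ndarray,
    max_days: int = 400,
) -> dict[str, np.ndarray]:
    """Vectorised simulation of many seasons at once.

    ``weather_arrays`` maps variable name (tmin/tavg/tmax/precip/rad/ea) to a
    (n_cells, n_days) array; each of the S seasons is described by a cell row,
    a sowing-day column index, per-season parameter vectors and stress
    switches.  The daily loop carries (S,)-shaped state only, so memory stays
    flat in S.  Returns per-season aggregate arrays.
    """
    S = len(cell_index)
    n_days = weather_arrays["tavg"].shape[1]
    p = param_arrays
    lnr = np.log(np.maximum(co2_ppm, CO2_AMBIENT_PPM) / CO2_AMBIENT_PPM)
    if np.any(co2_ppm < CO2_AMBIENT_PPM):
        raise ValueError("co2 below the 360 ppm ambient reference")
    te_mult = 1.0 + p["gamma_te"] * lnr
    rue_mult = np.where(crop_is_c4, 1.0, 1.0 + p["beta_rue"] * lnr)
    lai_mult = np.where(crop_is_c4, 1.0, 1.0 + p["lambda_lai"] * lnr)

    state = initial_water_mm.astype(float).copy()
    cum_tt = np.zeros(S)
    biomass = np.zeros(S)
    transp = np.zeros(S)
    irrig = np.zeros(S)
    exceed = np.zeros(S)
    fw_sum = np.zeros(S)
    fw_days = np.zeros(S)
    anth_idx = np.full(S, -1, dtype=np.int64)
    mat_idx = np.full(S, -1, dtype=np.int64)
    lai_cap = np.full(S, np.inf)

    tt_sen_start = p["tt_anthesis"] + p["senescence_start_frac"] * (
        p["tt_maturity"] - p["tt_anthesis"]
    )
    heat_on = heat_mode_code > 0
    canopy = heat_mode_code == 2

    for t in range(max_days):
        day = sow_index + t
        active = (mat_idx < 0) & (day < n_days)
        if not active.any():
            break
        di = np.minimum(day, n_days - 1)
        tavg = weather_arrays["tavg"][cell_index, di]
        tmin = weather_arrays["tmin"][cell_index, di]
        tmax = weather_arrays["tmax"][cell_index, di]
        precip = weather_arrays["precip"][cell_index, di]
        rad = weather_arrays["rad"][cell_index, di]
        ea = weather_arrays["ea"][cell_index, di]

        inc = np.clip(tavg - p["t_base"], 0.0, p["t_opt"] - p["t_base"])
        cum_tt = cum_tt + inc * active

        np.putmask(anth_idx, active & (anth_idx < 0) & (cum_tt >= p["tt_anthesis"]), t)

        # leaf area from thermal time: linear rise emergence->anthesis,
        # linear senescence from tt_sen_start to maturity
        rise = np.clip(
            (cum_tt - p["tt_emergence"]) / (p["tt_anthesis"] - p["tt_emergence"]),
            0.0, 1.0,
        )
        green = np.clip(
            (p["tt_maturity"] - cum_tt) / (p["tt_maturity"] - tt_sen_start),
            0.0, 1.0,
        )
        lai = np.minimum(p["max_lai"] * lai_mult * rise * green, lai_cap)
        fint = 1.0 - np.exp(-p["k_ext"] * lai)

        f_t = np.where(
            tavg <= p["t_opt"],
            np.clip((tavg - p["t_base"]) / (p["t_opt"] - p["t_base"]), 0.0, 1.0),
            np.clip(1.0 - (tavg - p["t_opt"]) / p["t_suit_span"], 0.0, 1.0),
        )
        pot = p["rue"] * rue_mult * fint * rad * f_t * active

        es_mean = 0.5 * (
            0.6108 * np.exp(17.27 * tmax / (tmax + 237.3))
            + 0.6108 * np.exp(17.27 * tmin / (tmin + 237.3))
        )
        vpd = np.maximum(0.0, es_mean - ea)
        demand = pot * vpd / (p["te_c"] * te_mult)

        soil_supply = np.minimum(demand, p["k_r"] * state)
        irr_add = np.where(water_limited, 0.0, demand - soil_supply)
        # irrigated supply equals demand exactly (not soil + top-up, which
        # rounds); keeps f_w == 1 and yields bit-stable across CO2 arms
        supply = np.where(water_limited, soil_supply, demand)
        f_w = np.where(
            water_limited & (demand > 0),
            soil_supply / np.where(demand > 0, demand, 1.0),
            1.0,
        )

        new_state = state + (precip + irr_add - supply) * active
        state = np.clip(new_state, 0.0, tawc_mm)

        growth = pot * f_w
        biomass += growth
        transp += supply * active
        irrig += irr_add * active
        fw_sum += f_w * active
        fw_days += active

        driver = np.where(
            canopy,
            tmax + p["delta_heat"] * (1.0 - f_w) - p["delta_cool"] * f_w,
            tmax,
        )
        in_window = (
            (cum_tt >= p["tt_anthesis"] - p["heat_window_before"])
            & (cum_tt <= p["tt_anthesis"] + p["heat_window_after"])
        )
        exceed += (
            np.maximum(0.0, driver - p["t_crit"]) * in_window * active * heat_on
        )
        # accelerated senescence: freeze LAI once cumulative exceedance
        # passes the threshold (disabled at the default threshold of inf)
        trip = heat_on & (exceed > p["heat_senescence_threshold"]) & np.isinf(lai_cap)
        if trip.any():
            lai_cap = np.where(trip, lai, lai_cap)

        np.putmask(mat_idx, active & (cum_tt >= p["tt_maturity"]), t)

    matured = mat_idx >= 0
    last = np.minimum(n_days - 1 - sow_index, max_days - 1)
    mat_idx = np.where(matured, mat_idx, last)
    anth_idx = np.where(anth_idx >= 0, anth_idx, mat_idx)
    retention = np.where(
        heat_on, np.clip(1.0 - p["heat_slope"] * exceed, 0.0, 1.0), 1.0
    )
    yield_t_ha = biomass * p["harvest_index"] * retention * 0.01
    return {
        "yield_t_ha": yield_t_ha,
        "biomass_t_ha": biomass * 0.01,
        "anthesis_offset": anth_idx,
        "maturity_offset": mat_idx,
        "transpiration_mm": transp,
        "irrigation_mm": irrig,
        "mean_fw": np.where(fw_days > 0, fw_sum / np.maximum(fw_days, 1), 1.0),
        "heat_exceedance_cdd": exceed,
        "retention": retention,
        "matured": matured,
    }


def _param_vectors(params_list, model_of_season):
    out = {
        f: np.array([getattr(m, f) for m in params_list], dtype=float)[model_of_season]
        for f in _PARAM_FIELDS
    }
    return out


def simulate_season(
    weather: "WeatherSeries",
    soil: "SoilProfile",
    params: CropParameters,
    treatment: TreatmentSpec,
    co2: float = CO2_AMBIENT_PPM,
    raw_fraction: float = 0.5,
    sow_date: pd.Timestamp | None = None,
) -> SeasonResult:
    """Simulate one crop season on one cell.

    Sowing is the first occurrence of the crop's sowing day-of-year in the
    weather series (or ``sow_date``); the season runs until maturity thermal
    time is reached or the series ends.
    """
    from .synthetic_data import initial_soil_water

    df = weather.data
    if df[["tmin", "tavg", "tmax", "precip", "rad", "ea"]].isna().any().any():
        raise ValueError("weather contains NaN")
    dates = pd.DatetimeIndex(df["date"])
    if sow_date is None:
        hits = np.nonzero(dates.dayofyear.values == params.sowing_doy)[0]
        if len(hits) == 0:
            raise ValueError("sowing day-of-year not present in weather series")
        sow_idx = int(hits[0])
    else:
        pos = np.nonzero(dates == pd.Timestamp(sow_date))[0]
        if len(pos) == 0:
            raise ValueError("sow_date not in weather series")
        sow_idx = int(pos[0])
    if len(df) - sow_idx < 30:
        raise ValueError("weather slice too short for a season")

    arrays = {
        v: df[v].to_numpy(dtype=float)[None, :]
        for v in ("tmin", "tavg", "tmax", "precip", "rad", "ea")
    }
    res = simulate_batch(
        arrays,
        cell_index=np.zeros(1, dtype=np.int64),
        sow_index=np.array([sow_idx], dtype=np.int64),
        param_arrays=_param_vectors([params], np.zeros(1, dtype=np.int64)),
        crop_is_c4=np.array([params.crop_class == "C4"]),
        water_limited=np.array([treatment.water_limited]),
        heat_mode_code=np.array([_HEAT_CODES[treatment.heat_mode]], dtype=np.int64),
        co2_ppm=np.array([float(co2)]),
        tawc_mm=np.array([soil.tawc_mm], dtype=float),
        initial_water_mm=np.array(
            [initial_soil_water(soil, raw_fraction)], dtype=float
        ),
    )
    sow = dates[sow_idx]
    return SeasonResult(
        yield_t_ha=float(res["yield_t_ha"][0]),
        biomass_t_ha=float(res["biomass_t_ha"][0]),
        sowing_date=sow,
        anthesis_date=dates[sow_idx + int(res["anthesis_offset"][0])],
        maturity_date=dates[sow_idx + int(res["maturity_offset"][0])],
        transpiration_mm=float(res["transpiration_mm"][0]),
        irrigation_mm=float(res["irrigation_mm"][0]),
        mean_fw=float(res["mean_fw"][0]),
        heat_exceedance_cdd=float(res["heat_exceedance_cdd"][0]),
        retention=float(res["retention"][0]),
        treatment=treatment.id,
        co2_ppm=float(co2),
        matured=bool(res["matured"][0]),
    )
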