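"""Synthetic inputs: daily weather, soils, grid cells, scenario deltas and
"observed" yield statistics.

The study design needs, per grid cell, a multi-decade daily weather record
(Tmin/Tavg/Tmax, precipitation, global radiation, actual vapor pressure,
10-m wind), a soil profile (rooting depth, TAWC, wilting point, field
capacity), rainfed/irrigated crop areas, climate-scenario perturbations built
with the delta-change method, and regional observed yield series to evaluate
against.  Everything here is generated with controllable statistical
structure and explicit seeds; identical (parameters, seed) gives
bit-identical output.

The weather generator is deliberately minimal: a harmonic seasonal cycle,
AR(1) day-to-day temperature residuals, and Bernoulli-gamma rainfall.  Its
closed-form means are used by the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .crop_model import saturation_vapor_pressure

logger = logging.getLogger(__name__)

#: A day is "wet" when precipitation reaches this amount (mm).
WET_DAY_MM = 0.1

WEATHER_COLUMNS = ["date", "tmin", "tavg", "tmax", "precip", "rad", "ea", "wind10"]

__all__ = [
    "WET_DAY_MM",
    "ClimateProfile",
    "WeatherSeries",
    "SoilProfile",
    "GridCell",
    "RegionPlan",
    "ScenarioDeltas",
    "ObservedYieldSeries",
    "generate_weather",
    "apply_delta_change",
    "plan_flips",
    "wind_at_2m",
    "derive_field_capacity",
    "initial_soil_water",
    "generate_grid",
    "synthesize_observed_yields",
    "CLIMATE_PROFILES",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClimateProfile:
    """Parameters of the stochastic daily weather generator for one latitude
    band.

    The mean of daily average temperature over whole years equals
    ``tavg_mean`` (the harmonic integrates to zero), which the Monte-Carlo
    tests exploit.
    """

    name: str = "central"
    tavg_mean: float = 10.0  # degC, annual mean
    tavg_amplitude: float = 9.0  # degC, seasonal half-range
    tavg_sd: float = 2.8  # degC, stationary sd of daily residuals
    tavg_ar1: float = 0.65  # lag-1 autocorrelation of residuals
    peak_doy: int = 205  # day of year of the warm peak
    diurnal_range: float = 9.0  # degC, tmax - tmin annual mean
    diurnal_range_amplitude: float = 3.0  # larger diurnal range in summer
    wet_prob: tuple = (0.42,) * 12  # monthly wet-day probability
    rain_mean: float = 5.0  # mm per wet day
    rain_shape: float = 0.75  # gamma shape of wet-day amounts
    rad_mean: float = 12.0  # MJ m-2 d-1 annual mean
    rad_amplitude: float = 9.0  # seasonal half-range
    rad_min: float = 0.5  # floor keeping radiation positive
    wet_day_rad_factor: float = 0.8  # cloud reduction on wet days
    ea_fraction: float = 0.8  # ea as a fraction of es(tmin)
    wind_mean: float = 3.5  # m s-1 at 10 m
    wind_sd: float = 1.0

    def __post_init__(self) -> None:
        if len(self.wet_prob) != 12:
            raise ValueError("wet_prob must have 12 monthly values")
        if self.diurnal_range < 0 or self.diurnal_range_amplitude < 0:
            raise ValueError(
                "diurnal range parameters must be >= 0 (tmin above tmax otherwise)"
            )
        if not 0 <= self.tavg_ar1 < 1:
            raise ValueError("tavg_ar1 must be in [0, 1)")
        if not 0 < self.ea_fraction <= 1:
            raise ValueError("ea_fraction must be in (0, 1]")


#: Stylised latitude-band profiles: a cool maritime north, a temperate
#: centre, and a Mediterranean south with a pronounced summer dry season.
CLIMATE_PROFILES: dict[str, ClimateProfile] = {
    "north": ClimateProfile(
        name="north", tavg_mean=8.5, tavg_amplitude=7.0, tavg_sd=2.5,
        diurnal_range=7.0,
        wet_prob=(0.48, 0.45, 0.42, 0.40, 0.40, 0.42, 0.44, 0.46, 0.46, 0.48, 0.50, 0.50),
        rain_mean=4.0, rad_mean=10.0, rad_amplitude=8.5, wind_mean=4.5,
    ),
    "central": ClimateProfile(
        name="central",
        wet_prob=(0.45, 0.42, 0.40, 0.38, 0.36, 0.33, 0.31, 0.32, 0.36, 0.40, 0.44, 0.46),
    ),
    "south": ClimateProfile(
        name="south", tavg_mean=15.0, tavg_amplitude=8.5, tavg_sd=2.5,
        diurnal_range=11.0,
        wet_prob=(0.33, 0.30, 0.26, 0.22, 0.16, 0.10, 0.06, 0.07, 0.14, 0.24, 0.32, 0.34),
        rain_mean=6.5, rad_mean=15.0, rad_amplitude=9.0, ea_fraction=0.75,
        wind_mean=3.0,
    ),
}


@dataclass
class WeatherSeries:
    """Daily meteorological record for one cell over whole calendar years."""

    data: pd.DataFrame
    profile_name: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"weather missing columns {missing}")
        dates = pd.DatetimeIndex(df["date"])
        if len(dates) > 1 and not (np.diff(dates.values) == np.timedelta64(1, "D")).all():
            raise ValueError("weather series has gaps")
        first, last = dates[0], dates[-1]
        if (first.month, first.day) != (1, 1) or (last.month, last.day) != (12, 31):
            raise ValueError("weather series must cover whole calendar years")
        if not ((df["tmin"] <= df["tavg"] + 1e-9) & (df["tavg"] <= df["tmax"] + 1e-9)).all():
            raise ValueError("tmin <= tavg <= tmax violated")
        if (df["precip"] < 0).any():
            raise ValueError("negative precipitation")
        if (df["rad"] <= 0).any():
            raise ValueError("radiation must be > 0")
        if (df["ea"] < 0).any():
            raise ValueError("negative vapor pressure")

    @property
    def n_years(self) -> int:
        return int(pd.DatetimeIndex(self.data["date"]).year.nunique())

    def copy(self) -> "WeatherSeries":
        return WeatherSeries(self.data.copy(), self.profile_name, self.seed)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# cropdrivers weather v1 profile={self.profile_name} seed={self.seed}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        df = pd.read_csv(path, comment="#", parse_dates=["date"])
        return cls(df)


@dataclass(frozen=True)
class SoilProfile:
    """Rooting-zone soil description (single-bucket view of the profile)."""

    depth_cm: float
    tawc_mm: float
    wp: float  # volumetric wilting point
    fc: float  # volumetric field capacity
    saturation: float = 0.45
    texture_top: str = "loam"
    texture_sub: str = "loam"

    def __post_init__(self) -> None:
        if self.depth_cm < 40:
            raise ValueError("soils shallower than 40 cm are excluded")
        if not 0 < self.wp < self.fc <= self.saturation < 1:
            raise ValueError("need 0 < WP < FC <= saturation < 1")
        implied = (self.fc - self.wp) * 10.0 * self.depth_cm
        if abs(implied - self.tawc_mm) > 1e-6:
            raise ValueError(
                f"TAWC {self.tawc_mm} inconsistent with (FC-WP)*depth = {implied:.3f}"
            )


@dataclass(frozen=True)
class GridCell:
    """One simulation unit: soil, location band and crop areas (ha)."""

    cell_id: str
    region: str
    lat_band: str
    soil: SoilProfile
    rainfed_area: Mapping[str, float]
    irrigated_area: Mapping[str, float]

    def __post_init__(self) -> None:
        for areas in (self.rainfed_area, self.irrigated_area):
            if any(a < 0 for a in areas.values()):
                raise ValueError("areas must be >= 0")


@dataclass(frozen=True)
class RegionPlan:
    """Assignment of grid cells to regions and their generating parameters."""

    regions: tuple
    lat_band: Mapping[str, str]  # region -> climate band
    depth_mean_cm: float = 110.0
    depth_sd_cm: float = 30.0
    wp_range: tuple = (0.08, 0.16)
    tawc_mean_mm: float = 150.0
    tawc_sd_mm: float = 35.0
    saturation: float = 0.46
    area_scale_ha: float = 10_000.0
    irrigated_fraction: Mapping[str, float] = field(default_factory=dict)
    crops: tuple = ("winter_wheat", "grain_maize")

    def __post_init__(self) -> None:
        if len(self.regions) == 0:
            raise ValueError("region plan must declare at least one region")
        for r in self.regions:
            if r not in self.lat_band:
                raise ValueError(f"no latitude band for region {r!r}")


@dataclass
class ScenarioDeltas:
    """Delta-change perturbation of a baseline weather series.

    Monthly mean-temperature offsets and precipitation factors plus an
    explicit wet/dry transition plan; flipping a baseline-wet day dry zeroes
    its rain and raises radiation by 10%, the reverse flip supplies rain and
    lowers radiation by 10%.  The CO2 level rides along with the scenario.
    """

    scenario_id: str = "baseline"
    temp_offsets: Sequence[float] = (0.0,) * 12
    precip_factors: Sequence[float] = (1.0,) * 12
    wet_to_dry: Sequence = ()
    dry_to_wet: Mapping = field(default_factory=dict)  # date -> rain (mm)
    co2_ppm: float = 360.0

    def __post_init__(self) -> None:
        if len(self.temp_offsets) != 12 or len(self.precip_factors) != 12:
            raise ValueError("temp_offsets and precip_factors must have 12 entries")
        if any(f < 0 for f in self.precip_factors):
            raise ValueError("precipitation factors must be >= 0")
        if self.co2_ppm < 360.0:
            raise ValueError("scenario CO2 below the 360 ppm ambient level")

    @classmethod
    def baseline(cls) -> "ScenarioDeltas":
        return cls()

    @property
    def is_baseline(self) -> bool:
        return (
            all(o == 0 for o in self.temp_offsets)
            and all(f == 1 for f in self.precip_factors)
            and not self.wet_to_dry
            and not self.dry_to_wet
            and self.co2_ppm == 360.0
        )


@dataclass
class ObservedYieldSeries:
    """Regional yield statistics with the generating truth retained."""

    region: str
    years: np.ndarray
    yields: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.yields = np.asarray(self.yields, dtype=float)
        if len(self.years) != len(self.yields):
            raise ValueError("years and yields differ in length")
        if len(self.years) > 1 and not (np.diff(self.years) == 1).all():
            raise ValueError("years must be consecutive")
        if (self.yields <= 0).any():
            raise ValueError("yields must be > 0")

    def as_series(self) -> pd.Series:
        return pd.Series(self.yields, index=self.years)


# --------------------------------------------------------------------------
# weather generation
# --------------------------------------------------------------------------

def generate_weather(
    profile: ClimateProfile, n_years: int, seed: int, start_year: int = 1980
) -> WeatherSeries:
    """Generate a daily weather series for ``n_years`` whole calendar years.

    Temperature is a harmonic seasonal cycle plus AR(1) residuals with
    stationary standard deviation ``tavg_sd``; rainfall is Bernoulli-gamma
    with monthly wet-day probabilities; radiation follows its own harmonic,
    reduced on wet days; actual vapor pressure is a configured fraction of
    saturation at tmin (dewpoint near tmin).  Pure function of
    (profile, n_years, seed).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D"
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy()
    phase = 2.0 * math.pi * (doy - profile.peak_doy) / 365.25

    seasonal = profile.tavg_mean + profile.tavg_amplitude * np.cos(phase)
    if profile.tavg_sd > 0:
        rho = profile.tavg_ar1
        eps = rng.normal(0.0, profile.tavg_sd * math.sqrt(1.0 - rho**2), n)
        resid = lfilter([1.0], [1.0, -rho], eps)
    else:
        resid = np.zeros(n)
    tavg = seasonal + resid
    half_range = 0.5 * np.maximum(
        profile.diurnal_range + profile.diurnal_range_amplitude * np.cos(phase), 0.0
    )
    tmin = tavg - half_range
    tmax = tavg + half_range

    wet_p = np.asarray(profile.wet_prob, dtype=float)[month - 1]
    wet = rng.random(n) < wet_p
    amounts = rng.gamma(
        profile.rain_shape, profile.rain_mean / profile.rain_shape, n
    )
    precip = np.where(wet, np.maximum(amounts, WET_DAY_MM), 0.0)

    rad = np.maximum(
        profile.rad_mean
        + profile.rad_amplitude * np.cos(2.0 * math.pi * (doy - 172) / 365.25),
        profile.rad_min,
    )
    rad = np.where(wet, rad * profile.wet_day_rad_factor, rad)
    rad = np.maximum(rad, profile.rad_min)

    ea = profile.ea_fraction * saturation_vapor_pressure(tmin)
    wind10 = np.maximum(rng.normal(profile.wind_mean, profile.wind_sd, n), 0.0)

    df = pd.DataFrame(
        {
            "date": dates,
            "tmin": tmin,
            "tavg": tavg,
            "tmax": tmax,
            "precip": precip,
            "rad": rad,
            "ea": ea,
            "wind10": wind10,
        }
    )
    return WeatherSeries(df, profile_name=profile.name, seed=seed)


def apply_delta_change(baseline: WeatherSeries, deltas: ScenarioDeltas) -> WeatherSeries:
    """Build scenario weather from a baseline series by the delta-change
    method.

    Monthly offsets shift tmin/tavg/tmax; monthly factors scale rain; the
    explicit wet/dry transition plan flips individual days, adjusting global
    radiation by +-10% (a day turning dry is sunnier, one turning wet
    cloudier).  With the zero-delta baseline plan the output is identical to
    the input.
    """
    df = baseline.data.copy()
    month = pd.DatetimeIndex(df["date"]).month.to_numpy()
    offsets = np.asarray(deltas.temp_offsets, dtype=float)[month - 1]
    for col in ("tmin", "tavg", "tmax"):
        df[col] = df[col].to_numpy() + offsets
    factors = np.asarray(deltas.precip_factors, dtype=float)[month - 1]
    df["precip"] = df["precip"].to_numpy() * factors

    idx = pd.DatetimeIndex(baseline.data["date"])
    base_wet = baseline.data["precip"].to_numpy() >= WET_DAY_MM
    precip = df["precip"].to_numpy().copy()
    rad = df["rad"].to_numpy().copy()

    for d in deltas.wet_to_dry:
        pos = idx.get_indexer([pd.Timestamp(d)])
        if pos[0] < 0:
            raise ValueError(f"flip date {d} not in series")
        i = pos[0]
        if not base_wet[i]:
            raise ValueError(f"{d} flagged wet->dry but baseline day is dry")
        precip[i] = 0.0
        rad[i] *= 1.10
    for d, amount in deltas.dry_to_wet.items():
        pos = idx.get_indexer([pd.Timestamp(d)])
        if pos[0] < 0:
            raise ValueError(f"flip date {d} not in series")
        i = pos[0]
        if base_wet[i]:
            raise ValueError(f"{d} flagged dry->wet but baseline day is wet")
        precip[i] = max(float(amount), WET_DAY_MM)
        rad[i] *= 0.90

    df["precip"] = precip
    df["rad"] = rad
    return WeatherSeries(df, profile_name=baseline.profile_name, seed=baseline.seed)


def plan_flips(
    baseline: WeatherSeries,
    wet_to_dry_rate: Sequence[float] | float,
    dry_to_wet_rate: Sequence[float] | float,
    seed: int,
    rain_mean: float = 5.0,
    rain_shape: float = 0.75,
) -> tuple[list, dict]:
    """Draw an explicit wet/dry transition plan from monthly flip rates.

    Rates are the per-day probability that a baseline-wet day turns dry (and
    vice versa) in the scenario; the specific days are sampled here so the
    delta-change application itself stays deterministic and auditable.
    """
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(baseline.data["date"])
    month = dates.month.to_numpy()
    wd = np.broadcast_to(np.atleast_1d(np.asarray(wet_to_dry_rate, float)), (12,)) \
        if np.ndim(wet_to_dry_rate) == 0 else np.asarray(wet_to_dry_rate, float)
    dw = np.broadcast_to(np.atleast_1d(np.asarray(dry_to_wet_rate, float)), (12,)) \
        if np.ndim(dry_to_wet_rate) == 0 else np.asarray(dry_to_wet_rate, float)
    wet = baseline.data["precip"].to_numpy() >= WET_DAY_MM
    u = rng.random(len(dates))
    to_dry = wet & (u < wd[month - 1])
    to_wet = ~wet & (u < dw[month - 1])
    amounts = np.maximum(
        rng.gamma(rain_shape, rain_mean / rain_shape, len(dates)), WET_DAY_MM
    )
    wet_to_dry = [d for d, f in zip(dates, to_dry) if f]
    dry_to_wet = {d: float(a) for d, f, a in zip(dates, to_wet, amounts) if f}
    return wet_to_dry, dry_to_wet


# --------------------------------------------------------------------------
# soils and grid
# --------------------------------------------------------------------------

def wind_at_2m(u10):
    """Convert 10-m wind speed to 2 m with the FAO-56 logarithmic profile."""
    u10 = np.asarray(u10, dtype=float)
    if np.any(u10 < 0):
        raise ValueError("wind speed must be >= 0")
    out = u10 * 4.87 / math.log(67.8 * 10.0 - 5.42)
    return float(out) if out.ndim == 0 else out


def derive_field_capacity(
    wp: float, tawc: float, depth: float, saturation: float | None = None
) -> float:
    """Volumetric field capacity from wilting point, profile TAWC (mm) and
    rooting depth (cm): FC = WP + TAWC / (10 * depth)."""
    if depth < 40:
        raise ValueError("soils shallower than 40 cm are excluded")
    if tawc < 0:
        raise ValueError("TAWC must be >= 0")
    if not 0 < wp < 1:
        raise ValueError("WP must be a volumetric fraction in (0, 1)")
    fc = wp + tawc / (10.0 * depth)
    if saturation is not None and fc >= saturation:
        raise ValueError(f"derived FC {fc:.3f} reaches saturation {saturation}")
    return fc


def initial_soil_water(profile: SoilProfile, raw_fraction: float = 0.5) -> float:
    """Plant-available soil water (mm) at sowing: 30% depletion of the
    readily available water, RAW = raw_fraction * TAWC."""
    if not 0 < raw_fraction <= 1:
        raise ValueError("raw_fraction must be in (0, 1]")
    value = profile.tawc_mm - 0.3 * raw_fraction * profile.tawc_mm
    return min(max(value, 0.0), profile.tawc_mm)


def generate_grid(
    n_cells: int,
    seed: int,
    region_plan: RegionPlan,
    strict: bool = True,
    max_redraws: int = 100,
) -> list[GridCell]:
    """Generate ``n_cells`` grid cells assigned round-robin to the plan's
    regions.

    Soil depths shallower than 40 cm are rejected and redrawn (the count is
    logged); with ``strict`` an exhausted redraw budget raises, otherwise the
    candidate cell is dropped.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    plan = region_plan
    cells: list[GridCell] = []
    rejected = 0
    for i in range(n_cells):
        region = plan.regions[i % len(plan.regions)]
        band = plan.lat_band[region]
        soil = None
        for _ in range(max_redraws):
            depth = rng.normal(plan.depth_mean_cm, plan.depth_sd_cm)
            if depth < 40:
                rejected += 1
                continue
            wp = rng.uniform(*plan.wp_range)
            tawc = max(rng.normal(plan.tawc_mean_mm, plan.tawc_sd_mm), 20.0)
            try:
                fc = derive_field_capacity(wp, tawc, depth, plan.saturation)
            except ValueError:
                rejected += 1
                continue
            soil = SoilProfile(
                depth_cm=float(depth), tawc_mm=float(tawc), wp=float(wp),
                fc=float(fc), saturation=plan.saturation,
            )
            break
        if soil is None:
            if strict:
                raise ValueError(
                    f"could not draw a valid soil for cell {i} "
                    f"({rejected} rejections; depth rule excludes soils < 40 cm)"
                )
            logger.warning("dropping cell %d after %d redraws", i, max_redraws)
            continue
        irr_frac = plan.irrigated_fraction.get(region, 0.1)
        rainfed, irrigated = {}, {}
        for crop in plan.crops:
            total = plan.area_scale_ha * rng.lognormal(0.0, 0.5)
            rainfed[crop] = total * (1.0 - irr_frac)
            irrigated[crop] = total * irr_frac
        cells.append(
            GridCell(
                cell_id=f"c{i:04d}", region=region, lat_band=band, soil=soil,
                rainfed_area=rainfed, irrigated_area=irrigated,
            )
        )
    logger.info("grid: %d cells emitted, %d soil draws rejected", len(cells), rejected)
    if not cells:
        raise ValueError("all candidate cells rejected by the soil depth rule")
    return cells


def grid_to_frame(cells: Sequence[GridCell]) -> pd.DataFrame:
    """Long-format view of a grid (one row per cell and crop)."""
    rows = []
    for c in cells:
        for crop in c.rainfed_area:
            rows.append(
                dict(
                    cell=c.cell_id, region=c.region, lat_band=c.lat_band,
                    crop=crop, rainfed_area=c.rainfed_area[crop],
                    irrigated_area=c.irrigated_area[crop],
                    depth_cm=c.soil.depth_cm, tawc_mm=c.soil.tawc_mm,
                    wp=c.soil.wp, fc=c.soil.fc,
                )
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# observed yields
# --------------------------------------------------------------------------

def synthesize_observed_yields(
    truth: pd.Series,
    trend_slope: float,
    noise_sd: float,
    seed: int,
    intercept: float = 0.0,
    region: str = "",
) -> ObservedYieldSeries:
    """Build an "observed" regional yield series from a simulated truth.

    observed(y) = truth(y) + trend_slope * (y - y0) + intercept + N(0, sd);
    the technology trend and statistical noise are what the evaluation's
    de-trending must see through.  Yields are floored at 0.001 t/ha to keep
    the series positive.  Generating truth is retained in ``meta``.
    """
    if len(truth) < 3:
        raise ValueError("truth series must cover at least 3 years")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    years = np.asarray(truth.index, dtype=int)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, len(years)) if noise_sd > 0 else np.zeros(len(years))
    obs = truth.to_numpy(dtype=float) + trend_slope * (years - years[0]) + intercept + noise
    obs = np.maximum(obs, 1e-3)
    return ObservedYieldSeries(
        region=region,
        years=years,
        yields=obs,
        meta=dict(trend_slope=trend_slope, noise_sd=noise_sd, seed=seed,
                  intercept=intercept),
    )
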