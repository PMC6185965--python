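"""Factorial simulation protocol.

Runs the complete crossing treatments x CO2 arms x scenarios x pseudo-models
x GCM-analogues x cells x sowing years.  Each scenario is simulated twice,
once with ambient CO2 fixed at 360 ppm and once at the scenario's elevated
level, so the CO2 fertilisation effect is a separable on/off factor.

The "ensemble" is a set of parameter-perturbed variants of one generic crop
model; member 0 is always the unperturbed base, and the last ``n_air_only``
members do not simulate canopy temperature (their heat-stress driver falls
back to air temperature downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crop_model import (
    CANONICAL_TREATMENTS,
    CO2_AMBIENT_PPM,
    CropParameters,
    simulate_batch,
)
from .synthetic_data import GridCell, WeatherSeries, initial_soil_water

logger = logging.getLogger(__name__)

_HEAT_CODES = {"none": 0, "air": 1, "canopy": 2}

#: Default multiplicative jitter (sd of 1 + N(0, sd)) per parameter.
DEFAULT_JITTER: dict[str, float] = {
    "rue": 0.06,
    "te_c": 0.08,
    "tt_anthesis": 0.04,
    "tt_maturity": 0.04,
    "heat_slope": 0.15,
    "gamma_te": 0.10,
    "beta_rue": 0.10,
    "lambda_lai": 0.10,
    "max_lai": 0.08,
    "harvest_index": 0.04,
}

__all__ = [
    "EnsembleSpec",
    "DEFAULT_JITTER",
    "make_ensemble",
    "run_factorial",
    "check_complete",
    "seasonal_water_use",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """How to build a pseudo-ensemble from one base parameterisation."""

    n_models: int = 4
    seed: int = 0
    jitter: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_JITTER))
    n_air_only: int = 1  # trailing members without canopy-temperature support
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if any(sd < 0 for sd in self.jitter.values()):
            raise ValueError("jitter sds must be >= 0")
        if not 0 <= self.n_air_only < max(self.n_models, 1) + 1:
            raise ValueError("n_air_only out of range")


def make_ensemble(base: CropParameters, spec: EnsembleSpec) -> list[CropParameters]:
    """Perturb ``base`` into ``n_models`` parameter sets (member 0 = base)."""
    rng = np.random.default_rng(spec.seed)
    members = [base.replace(name=f"{base.name}_m0")]
    for i in range(1, spec.n_models):
        for attempt in range(spec.max_redraws):
            kw = {"name": f"{base.name}_m{i}"}
            for attr, sd in spec.jitter.items():
                factor = 1.0 + rng.normal(0.0, sd) if sd > 0 else 1.0
                kw[attr] = getattr(base, attr) * factor
            if base.crop_class == "C4":
                kw["beta_rue"] = 0.0
                kw["lambda_lai"] = 0.0
            try:
                members.append(base.replace(**kw))
                break
            except ValueError:
                continue
        else:
            raise ValueError(
                f"could not draw a valid member {i} in {spec.max_redraws} attempts"
            )
    n_air = min(spec.n_air_only, max(spec.n_models - 1, 0))
    for j in range(spec.n_models - n_air, spec.n_models):
        members[j] = members[j].replace(simulates_canopy=False)
    return members


def _weather_to_arrays(
    weather_by_cell: Mapping[str, WeatherSeries], cell_order: Sequence[str]
):
    first = weather_by_cell[cell_order[0]].data
    dates = pd.DatetimeIndex(first["date"])
    arrays = {}
    for var in ("tmin", "tavg", "tmax", "precip", "rad", "ea"):
        arrays[var] = np.stack(
            [weather_by_cell[c].data[var].to_numpy(dtype=float) for c in cell_order]
        )
    return arrays, dates


def run_factorial(
    cells: Sequence[GridCell],
    weather_sets: Mapping[tuple, Mapping[str, WeatherSeries]],
    ensemble: Sequence[CropParameters],
    scenario_co2: Mapping[str, float],
    treatments: Sequence[str] | None = None,
    raw_fraction: float = 0.5,
) -> pd.DataFrame:
    """Run the full factorial for one crop and return a long-format table.

    ``weather_sets`` maps (scenario_id, gcm_analogue) to per-cell weather;
    ``scenario_co2`` gives each scenario's elevated CO2 level.  Every
    (scenario, gcm) is simulated under both the ambient arm (360 ppm) and the
    elevated arm.  Sowing years are all years whose sowing date leaves at
    least one following calendar year in the record, so winter- and
    spring-sown crops yield the same balanced season count.
    """
    treatments = list(treatments or CANONICAL_TREATMENTS)
    unknown = [t for t in treatments if t not in CANONICAL_TREATMENTS]
    if unknown:
        raise ValueError(f"unknown treatments {unknown}")
    if not cells:
        raise ValueError("no grid cells")
    cell_ids = [c.cell_id for c in cells]
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("duplicate cell ids")
    crop = ensemble[0].crop_class
    names = [m.name for m in ensemble]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model names")

    n_models = len(ensemble)
    n_treat = len(treatments)
    frames = []
    for (scenario, gcm), weather_by_cell in sorted(weather_sets.items()):
        missing = [c for c in cell_ids if c not in weather_by_cell]
        if missing:
            raise ValueError(f"scenario {scenario}/{gcm} missing weather for {missing}")
        arrays, dates = _weather_to_arrays(weather_by_cell, cell_ids)
        years = np.unique(dates.year.values)
        sow_years = years[:-1]  # a season may run into the following year
        if len(sow_years) == 0:
            raise ValueError("need at least two calendar years of weather")
        co2_elev = float(scenario_co2[scenario])
        arms = [("ambient", CO2_AMBIENT_PPM), ("elevated", co2_elev)]

        # sowing-day index per (cell is irrelevant: shared dates) and year
        doy = dates.dayofyear.values
        year_of = dates.year.values
        sow_idx_by_year = {}
        for y in sow_years:
            hits = np.nonzero((year_of == y) & (doy == ensemble[0].sowing_doy))[0]
            if len(hits) == 0:
                raise ValueError(f"sowing day missing in year {y}")
            sow_idx_by_year[y] = int(hits[0])

        # build the season crossing: cell x year x model x treatment x arm
        idx = pd.MultiIndex.from_product(
            [range(len(cells)), sow_years, range(n_models), treatments,
             range(len(arms))],
            names=["cell_i", "year", "model_i", "treatment", "arm_i"],
        ).to_frame(index=False)
        S = len(idx)
        cell_i = idx["cell_i"].to_numpy()
        model_i = idx["model_i"].to_numpy()
        arm_i = idx["arm_i"].to_numpy()
        treat = idx["treatment"].to_numpy()
        sow_index = np.array([sow_idx_by_year[y] for y in idx["year"]], dtype=np.int64)

        param_arrays = {
            f: np.array([getattr(m, f) for m in ensemble], dtype=float)[model_i]
            for f in _param_fields()
        }
        water_limited = np.array(
            [CANONICAL_TREATMENTS[t].water_limited for t in treat]
        )
        heat_code = np.array(
            [_HEAT_CODES[CANONICAL_TREATMENTS[t].heat_mode] for t in treat],
            dtype=np.int64,
        )
        co2_vec = np.array([arms[a][1] for a in arm_i], dtype=float)
        tawc = np.array([c.soil.tawc_mm for c in cells], dtype=float)[cell_i]
        init = np.array(
            [initial_soil_water(c.soil, raw_fraction) for c in cells], dtype=float
        )[cell_i]

        res = simulate_batch(
            arrays,
            cell_index=cell_i,
            sow_index=sow_index,
            param_arrays=param_arrays,
            crop_is_c4=np.full(S, crop == "C4"),
            water_limited=water_limited,
            heat_mode_code=heat_code,
            co2_ppm=co2_vec,
            tawc_mm=tawc,
            initial_water_mm=init,
        )
        out = pd.DataFrame(
            {
                "crop": ensemble[0].name.rsplit("_m", 1)[0],
                "cell": np.array(cell_ids)[cell_i],
                "region": np.array([c.region for c in cells])[cell_i],
                "year": idx["year"].to_numpy(),
                "scenario": scenario,
                "gcm": gcm,
                "model": np.array(names)[model_i],
                "canopy_capable": np.array(
                    [m.simulates_canopy for m in ensemble]
                )[model_i],
                "treatment": treat,
                "co2_arm": np.array([arms[a][0] for a in arm_i]),
                "co2_ppm": co2_vec,
                "yield": res["yield_t_ha"],
                "biomass": res["biomass_t_ha"],
                "transpiration_mm": res["transpiration_mm"],
                "irrigation_mm": res["irrigation_mm"],
                "water_use_mm": res["transpiration_mm"],
                "mean_fw": res["mean_fw"],
                "heat_cdd": res["heat_exceedance_cdd"],
                "retention": res["retention"],
                "anthesis_doy": (
                    dates.dayofyear.values[
                        np.minimum(sow_index + res["anthesis_offset"], len(dates) - 1)
                    ]
                ),
                "maturity_offset": res["maturity_offset"],
                "matured": res["matured"],
            }
        )
        frames.append(out)
        logger.info("factorial: %s/%s -> %d seasons", scenario, gcm, S)
    table = pd.concat(frames, ignore_index=True)
    return table


def _param_fields():
    from .crop_model import _PARAM_FIELDS

    return _PARAM_FIELDS


KEY_COLUMNS = ["crop", "cell", "year", "scenario", "gcm", "model", "treatment", "co2_arm"]


def check_complete(table: pd.DataFrame) -> None:
    """Raise unless every key combination appears exactly once.

    Scenario x GCM is allowed to be unbalanced (an RCP-analogue may have
    fewer GCM-analogues); within each (scenario, gcm) the crossing over
    cells, years, models, treatments and CO2 arms must be complete.
    """
    if table.duplicated(KEY_COLUMNS).any():
        raise ValueError("duplicate factorial keys")
    for (crop, scen, gcm), sub in table.groupby(["crop", "scenario", "gcm"],
                                                sort=False):
        expected = 1
        for col in ("cell", "year", "model", "treatment", "co2_arm"):
            expected *= sub[col].nunique()
        if len(sub) != expected:
            raise ValueError(
                f"incomplete crossing in {crop}/{scen}/{gcm}: {len(sub)} rows, "
                f"expected {expected}"
            )


def seasonal_water_use(table: pd.DataFrame) -> pd.DataFrame:
    """Mean seasonal crop water use (mm; soil supply plus irrigation top-up)
    per (crop, cell, scenario, model, treatment, co2_arm)."""
    if table.empty:
        raise ValueError("empty factorial table")
    grouped = (
        table.groupby(
            ["crop", "cell", "scenario", "gcm", "model", "treatment", "co2_arm"],
            sort=False,
        )
        .agg(water_use_mm=("water_use_mm", "mean"),
             irrigation_mm=("irrigation_mm", "mean"))
        .reset_index()
    )
    return grouped
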