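"""Driver-of-loss accounting from the treatment factorial.

For each aggregation unit, model, GCM-analogue, scenario and CO2 arm the
treatment yields are converted into relative losses against the potential
yield Yp (= T1):

* drought loss       = 100 (Yp - Ywl) / Yp            (Ywl = T4)
* heat loss, irrig.  = 100 (Yp - Yhl) / Yp            (Yhl = T3, or T2 for
                                                       air-only members)
* heat loss, rainfed = 100 (Ywl - Ywh) / Yp           (Ywh = T6, or T5)
* potential change   = 100 (Yp_scen - Yp_base) / Yp_base
* loss change        = loss_scen - loss_base          (percentage points)

Drought and rainfed heat losses add exactly to the combined loss
100 (Yp - Ywh)/Yp -- an algebraic identity the test suite asserts to 1e-9.
Losses are evaluated for all years and for the lowest-decile years of the
fully limited yield series, and with/without CO2 fertilisation; their
difference sizes the CO2 effect.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "drought_loss",
    "heat_loss_irrigated",
    "heat_loss_rainfed",
    "potential_change",
    "loss_change",
    "co2_effect",
    "lowest_decile_years",
    "decompose",
    "ensemble_summary",
]


def drought_loss(y_pot: float, y_wl: float) -> float:
    """Yield loss (%) attributable to drought: potential minus water-limited,
    relative to potential."""
    if y_pot <= 0:
        raise ValueError("potential yield must be > 0")
    if not 0 <= y_wl <= y_pot * (1 + 1e-12):
        raise ValueError("need 0 <= y_wl <= y_pot")
    return 100.0 * (y_pot - y_wl) / y_pot


def heat_loss_irrigated(y_pot: float, y_hl: float) -> float:
    """Yield loss (%) from heat under full irrigation: potential minus
    heat-limited, relative to potential."""
    if y_pot <= 0:
        raise ValueError("potential yield must be > 0")
    if not 0 <= y_hl <= y_pot * (1 + 1e-12):
        raise ValueError("need 0 <= y_hl <= y_pot")
    return 100.0 * (y_pot - y_hl) / y_pot


def heat_loss_rainfed(y_wl: float, y_wh: float, y_pot: float) -> float:
    """Additional loss (%) from heat on top of drought: combined-stress
    deficit minus drought-only deficit, relative to potential."""
    if y_pot <= 0:
        raise ValueError("potential yield must be > 0")
    if y_wh > y_wl * (1 + 1e-12) or y_wl > y_pot * (1 + 1e-12):
        raise ValueError(
            "yield ordering y_wh <= y_wl <= y_pot violated "
            "(indicates a simulator monotonicity defect)"
        )
    return 100.0 * (y_wl - y_wh) / y_pot


def potential_change(y_pot_scen: float, y_pot_base: float) -> float:
    """Relative change (%) of potential yield in a scenario vs the baseline."""
    if y_pot_base <= 0:
        raise ValueError("baseline potential yield must be > 0")
    return 100.0 * (y_pot_scen - y_pot_base) / y_pot_base


def loss_change(loss_scen: float, loss_base: float) -> float:
    """Percentage-point change of a relative loss between scenario and
    baseline (each loss taken against its own period's potential)."""
    return loss_scen - loss_base


def co2_effect(metric_with: float, metric_without: float) -> float:
    """CO2 fertilisation effect (pp) on a loss: without-CO2 minus with-CO2;
    positive values mean elevated CO2 alleviates the loss."""
    return metric_without - metric_with


def lowest_decile_years(yields: pd.Series) -> list:
    """The ceil(n/10) years with the smallest yields (ties: earlier year)."""
    if len(yields) < 10:
        raise ValueError("need at least 10 years for a decile")
    k = math.ceil(len(yields) / 10)
    order = sorted(yields.items(), key=lambda kv: (kv[1], kv[0]))
    return [y for y, _ in order[:k]]


_METRICS = [
    "y_pot", "drought_loss", "heat_loss_irrigated", "heat_loss_rainfed",
    "combined_loss", "potential_change", "drought_loss_change",
    "heat_loss_rainfed_change", "combined_loss_change",
]


def decompose(
    agg: pd.DataFrame,
    baseline_scenario: str = "baseline",
    baseline_gcm: str = "obs",
    annual_ratios: bool = False,
) -> pd.DataFrame:
    """Apply the loss accounting to a rainfed-aggregated yield table.

    ``agg`` must hold rainfed-weighted aggregate yields per (crop, unit,
    scenario, gcm, model, treatment, co2_arm, year) for treatments T1-T6 and
    a ``canopy_capable`` flag per model (T3/T6 drive heat for
    canopy-capable members, T2/T5 otherwise).  Losses are computed from
    multi-year mean yields (or as means of annual loss ratios with
    ``annual_ratios=True``), for all years and for the lowest-decile years of
    the fully limited series, and compared against the baseline scenario.

    Returns a tidy frame keyed by (crop, unit, scenario, gcm, model, co2_arm,
    subset, metric).
    """
    required = {"T1", "T4"}
    if not required.issubset(set(agg["treatment"].unique())):
        raise ValueError("decomposition needs at least treatments T1 and T4")
    if "canopy_capable" not in agg.columns:
        raise ValueError("aggregated table lacks the canopy_capable flag")

    keys = ["crop", "unit", "model", "co2_arm"]
    rows = []
    for key_vals, sub in agg.groupby(keys, sort=False):
        cap = bool(sub["canopy_capable"].iloc[0])
        t_hl = "T3" if cap else "T2"
        t_wh = "T6" if cap else "T5"
        wide = sub.pivot_table(
            index=["scenario", "gcm", "year"], columns="treatment", values="yield",
            sort=False,
        )
        for t in ("T1", "T4", t_hl, t_wh):
            if t not in wide.columns:
                raise ValueError(f"missing treatment {t} in factorial slice")
        per_scenario = {}
        for (scen, gcm), block in wide.groupby(level=["scenario", "gcm"], sort=False):
            block = block.droplevel(["scenario", "gcm"])
            decile = lowest_decile_years(block[t_wh]) if len(block) >= 10 else list(block.index)
            for subset, years in (("all", list(block.index)), ("lowest_decile", decile)):
                sel = block.loc[years]
                if annual_ratios:
                    yp = sel["T1"]
                    vals = dict(
                        y_pot=float(yp.mean()),
                        drought_loss=float((100 * (yp - sel["T4"]) / yp).mean()),
                        heat_loss_irrigated=float((100 * (yp - sel[t_hl]) / yp).mean()),
                        heat_loss_rainfed=float(
                            (100 * (sel["T4"] - sel[t_wh]) / yp).mean()
                        ),
                    )
                else:
                    yp = float(sel["T1"].mean())
                    vals = dict(
                        y_pot=yp,
                        drought_loss=drought_loss(yp, float(sel["T4"].mean())),
                        heat_loss_irrigated=heat_loss_irrigated(
                            yp, float(sel[t_hl].mean())
                        ),
                        heat_loss_rainfed=heat_loss_rainfed(
                            float(sel["T4"].mean()), float(sel[t_wh].mean()), yp
                        ),
                    )
                vals["combined_loss"] = vals["drought_loss"] + vals["heat_loss_rainfed"]
                per_scenario[(scen, gcm, subset)] = vals
        for (scen, gcm, subset), vals in per_scenario.items():
            base = per_scenario.get((baseline_scenario, baseline_gcm, subset))
            out = dict(zip(keys, key_vals))
            out.update(scenario=scen, gcm=gcm, subset=subset, **vals)
            if base is not None and scen != baseline_scenario:
                out["potential_change"] = potential_change(vals["y_pot"], base["y_pot"])
                out["drought_loss_change"] = loss_change(
                    vals["drought_loss"], base["drought_loss"]
                )
                out["heat_loss_rainfed_change"] = loss_change(
                    vals["heat_loss_rainfed"], base["heat_loss_rainfed"]
                )
                out["combined_loss_change"] = loss_change(
                    vals["combined_loss"], base["combined_loss"]
                )
            rows.append(out)
    long = pd.DataFrame(rows)
    tidy = long.melt(
        id_vars=["crop", "unit", "scenario", "gcm", "model", "co2_arm", "subset"],
        value_vars=[m for m in _METRICS if m in long.columns],
        var_name="metric",
        value_name="value",
    ).dropna(subset=["value"])
    # the baseline gcm label only ever carries the baseline scenario; keep as is
    return tidy.reset_index(drop=True)


def ensemble_summary(tidy: pd.DataFrame) -> pd.DataFrame:
    """Median and 10th/90th percentiles across model x GCM combinations."""
    keys = ["crop", "unit", "scenario", "co2_arm", "subset", "metric"]
    g = tidy.groupby(keys, sort=False)["value"]
    out = g.agg(
        median="median",
        q10=lambda s: s.quantile(0.10),
        q90=lambda s: s.quantile(0.90),
        n="count",
    ).reset_index()
    return out


def co2_effect_table(tidy: pd.DataFrame) -> pd.DataFrame:
    """Per-key CO2 fertilisation effect: ambient-arm minus elevated-arm loss
    (pp; positive = CO2 alleviates) for every loss metric."""
    keys = ["crop", "unit", "scenario", "gcm", "model", "subset", "metric"]
    wide = tidy.pivot_table(index=keys, columns="co2_arm", values="value", sort=False)
    if not {"ambient", "elevated"}.issubset(wide.columns):
        raise ValueError("need both CO2 arms to size the fertilisation effect")
    wide["co2_effect_pp"] = wide["ambient"] - wide["elevated"]
    return wide.reset_index()
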