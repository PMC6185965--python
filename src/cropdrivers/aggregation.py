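"""Production-area-weighted aggregation of cell yields to region and EU level.

Aggregate production is yield times production area summed over cells;
aggregate yield is production divided by total area.  Weights are always the
baseline areas (no land-use change across scenarios).  The "mix" regime
reproduces the actual degree of irrigation by combining a water-limited
treatment on the rainfed area with its full-irrigation counterpart on the
irrigated area.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .synthetic_data import GridCell

#: Full-irrigation counterpart of each water-limited treatment.
MIX_COUNTERPART = {"T4": "T1", "T5": "T2", "T6": "T3"}

GROUP_KEYS = ["crop", "scenario", "gcm", "model", "treatment", "co2_arm", "year"]

__all__ = [
    "MIX_COUNTERPART",
    "area_frame",
    "aggregate_yield",
    "potential_on_rainfed_land",
    "environment_index",
]


def area_frame(cells: Sequence[GridCell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        for crop in c.rainfed_area:
            rows.append(
                dict(cell=c.cell_id, region=c.region, crop=crop,
                     rainfed_area=float(c.rainfed_area[crop]),
                     irrigated_area=float(c.irrigated_area[crop]))
            )
    return pd.DataFrame(rows)


def _weighted(table: pd.DataFrame, weight_col: str, unit_col: str) -> pd.DataFrame:
    df = table.copy()
    df["production"] = df["yield"] * df[weight_col]
    keys = ["crop", unit_col, "scenario", "gcm", "model", "treatment", "co2_arm", "year"]
    g = df.groupby(keys, sort=False).agg(
        production=("production", "sum"), area=(weight_col, "sum")
    )
    if (g["area"] <= 0).any():
        bad = g.index[g["area"] <= 0][:3].tolist()
        raise ValueError(f"zero total area in aggregation unit(s), e.g. {bad}")
    g["yield"] = g["production"] / g["area"]
    out = g.reset_index().rename(columns={unit_col: "unit"})
    return out[["crop", "unit", "scenario", "gcm", "model", "treatment",
                "co2_arm", "year", "yield", "production", "area"]]


def aggregate_yield(
    table: pd.DataFrame,
    cells: Sequence[GridCell],
    regime: str = "rainfed",
    level: str = "region",
) -> pd.DataFrame:
    """Area-weighted aggregate yield (t/ha) per unit and factorial key.

    ``level='region'`` aggregates within regions, ``level='all'`` to a single
    EU-wide unit.  For ``regime='mix'`` each water-limited treatment T4-T6 is
    combined with its irrigated counterpart T1-T3 (rainfed and irrigated
    areas respectively); treatments T1-T3 in a mix slice are weighted by
    total area (their yields carry no water limitation, so the regime split
    is immaterial).
    """
    if level not in ("region", "all"):
        raise ValueError("level must be 'region' or 'all'")
    if regime not in ("rainfed", "irrigated", "mix"):
        raise ValueError("regime must be rainfed, irrigated or mix")
    areas = area_frame(cells)[["cell", "crop", "rainfed_area", "irrigated_area"]]
    merged = table.merge(areas, on=["cell", "crop"], how="left")
    if level == "all":
        merged = merged.assign(region="EU")
    elif "region" not in merged.columns:
        raise ValueError("table lacks a region column for region-level aggregation")
    if merged["rainfed_area"].isna().any():
        missing = merged.loc[merged["rainfed_area"].isna(), "cell"].unique()[:5]
        raise ValueError(f"cells missing areas: {list(missing)}")

    if regime == "rainfed":
        return _weighted(merged, "rainfed_area", "region")
    if regime == "irrigated":
        return _weighted(merged, "irrigated_area", "region")

    # mix: pair water-limited treatments with their irrigated counterpart
    merged["total_area"] = merged["rainfed_area"] + merged["irrigated_area"]
    parts = []
    present = set(merged["treatment"].unique())
    plain = [t for t in present if t not in MIX_COUNTERPART]
    if plain:
        parts.append(
            _weighted(merged[merged["treatment"].isin(plain)], "total_area", "region")
        )
    key = ["crop", "cell", "region", "scenario", "gcm", "model", "co2_arm", "year"]
    for t_wl, t_irr in MIX_COUNTERPART.items():
        if t_wl not in present:
            continue
        if t_irr not in present:
            raise ValueError(
                f"mix aggregation of {t_wl} needs its counterpart {t_irr}"
            )
        wl = merged[merged["treatment"] == t_wl]
        irr = merged[merged["treatment"] == t_irr][key + ["yield"]]
        both = wl.merge(irr, on=key, suffixes=("", "_irr"))
        both["production"] = (
            both["yield"] * both["rainfed_area"]
            + both["yield_irr"] * both["irrigated_area"]
        )
        g = both.groupby(
            ["crop", "region", "scenario", "gcm", "model", "treatment",
             "co2_arm", "year"],
            sort=False,
        ).agg(production=("production", "sum"), area=("total_area", "sum"))
        if (g["area"] <= 0).any():
            raise ValueError("zero total area in a mix aggregation unit")
        g["yield"] = g["production"] / g["area"]
        parts.append(g.reset_index().rename(columns={"region": "unit"}))
    out = pd.concat(parts, ignore_index=True)
    return out[["crop", "unit", "scenario", "gcm", "model", "treatment",
                "co2_arm", "year", "yield", "production", "area"]]


def potential_on_rainfed_land(
    table: pd.DataFrame, cells: Sequence[GridCell], level: str = "region"
) -> pd.DataFrame:
    """Potential (T1-T3) yields aggregated over rainfed production area only."""
    sub = table[table["treatment"].isin(["T1", "T2", "T3"])]
    if sub.empty:
        raise ValueError("no potential-treatment rows (T1-T3) in slice")
    return aggregate_yield(sub, cells, regime="rainfed", level=level)


def environment_index(
    table: pd.DataFrame, cells: Sequence[GridCell], level: str = "region"
) -> pd.DataFrame:
    """Ratio of water-limited (T4) to potential (T1) yields on rainfed land.

    1 where drought is absent, below 1 where it bites; a simple environment
    index of how water-limited each unit is.
    """
    need = {"T1", "T4"}
    if not need.issubset(set(table["treatment"].unique())):
        raise ValueError("environment index needs treatments T1 and T4")
    agg = aggregate_yield(
        table[table["treatment"].isin(sorted(need))], cells,
        regime="rainfed", level=level,
    )
    keys = ["crop", "unit", "scenario", "gcm", "model", "co2_arm", "year"]
    wide = agg.pivot_table(index=keys, columns="treatment", values="yield",
                           sort=False)
    if (wide["T1"] <= 0).any():
        raise ValueError("zero potential yield; environment index undefined")
    wide["environment_index"] = wide["T4"] / wide["T1"]
    return wide.reset_index()[keys + ["environment_index"]]
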