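"""Skill assessment against (synthetic) observed yield statistics.

Observed and simulated regional yield series are de-trended by moving-window
anomalies -- a 5-year centred window (t-2..t+2) in the interior, 3-year
windows (t-1..t+1) at the second and penultimate positions, and the 2-year
window that exists at the extreme endpoints -- and compared by squared
Pearson correlation.  Six simulation cases are scored: potential (T1), heat
with air (T2) or canopy (T3) temperature under irrigation, and the
irrigation-share-weighted mixes of T4, T5 and T6 which reproduce the actual
degree of irrigation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import aggregate_yield
from .synthetic_data import GridCell, ObservedYieldSeries

#: Comparison case -> (treatment, aggregation regime).
CASES: dict[int, tuple[str, str]] = {
    1: ("T1", "mix"),
    2: ("T2", "mix"),
    3: ("T3", "mix"),
    4: ("T4", "mix"),
    5: ("T5", "mix"),
    6: ("T6", "mix"),
}

__all__ = [
    "CASES",
    "detrend_moving_window",
    "detrend_linear",
    "explained_variance",
    "case_yield_series",
    "evaluate_cases",
]


def detrend_moving_window(series: pd.Series, relative: bool = False) -> pd.Series:
    """Annual anomalies from a centred moving mean.

    Interior years use the 5-term window t-2..t+2; the second and
    penultimate years the 3-term window t-1..t+1; the first and last years
    the 2-term window available at the edge.  Centred windows annihilate any
    linear trend at interior points.  With ``relative`` the anomaly is
    (y - m)/m instead of y - m.
    """
    n = len(series)
    if n < 3:
        raise ValueError("series must cover at least 3 years")
    years = np.asarray(series.index)
    if not (np.diff(years) == 1).all():
        raise ValueError("series has year gaps")
    y = series.to_numpy(dtype=float)
    out = np.empty(n)
    for i in range(n):
        if 2 <= i <= n - 3:
            lo, hi = i - 2, i + 2
        elif i in (1, n - 2):
            lo, hi = i - 1, i + 1
        elif i == 0:
            lo, hi = 0, 1
        else:  # i == n - 1
            lo, hi = n - 2, n - 1
        m = y[lo : hi + 1].mean()
        out[i] = (y[i] - m) / m if relative else y[i] - m
    return pd.Series(out, index=series.index)


def detrend_linear(series: pd.Series, relative: bool = False) -> pd.Series:
    """Residuals from a least-squares linear trend over years."""
    if len(series) < 3:
        raise ValueError("series must cover at least 3 years")
    x = np.asarray(series.index, dtype=float)
    y = series.to_numpy(dtype=float)
    coef = np.polyfit(x, y, 1)
    fit = np.polyval(coef, x)
    out = (y - fit) / fit if relative else y - fit
    return pd.Series(out, index=series.index)


_DETREND = {"moving": detrend_moving_window, "linear": detrend_linear}


def explained_variance(obs_anom: pd.Series, sim_anom: pd.Series):
    """Squared Pearson correlation and its t-test p-value.

    R^2 ignores the correlation sign; callers that care about
    anti-correlation should inspect the sign of r separately.
    """
    a = np.asarray(obs_anom, dtype=float)
    b = np.asarray(sim_anom, dtype=float)
    if len(a) != len(b) or len(a) < 4:
        raise ValueError("series must have equal length >= 4")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in anomaly series")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in an anomaly series")
    r, p = stats.pearsonr(a, b)
    return float(r * r), float(p)


def case_yield_series(
    table: pd.DataFrame,
    cells: Sequence[GridCell],
    case: int,
    level: str = "region",
) -> pd.DataFrame:
    """Aggregate the factorial to the per-case regional yield series.

    Returns rows (crop, unit, model, year, yield) for the case's treatment
    under the irrigation-share mix.
    """
    treatment, regime = CASES[case]
    need = {treatment}
    from .aggregation import MIX_COUNTERPART

    if treatment in MIX_COUNTERPART:
        need.add(MIX_COUNTERPART[treatment])
    sub = table[table["treatment"].isin(sorted(need))]
    agg = aggregate_yield(sub, cells, regime=regime, level=level)
    agg = agg[agg["treatment"] == treatment]
    return agg


def evaluate_cases(
    obs: Mapping[str, ObservedYieldSeries],
    table: pd.DataFrame,
    cells: Sequence[GridCell],
    cases: Sequence[int] = (1, 2, 3, 4, 5, 6),
    alpha: float = 0.05,
    detrend: str = "moving",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score each comparison case against observed regional series.

    ``table`` should be a single-(scenario, gcm, co2_arm) factorial slice
    covering the observation period.  Returns (per-model table, summary):
    the per-model table has one row per (crop, region, case, model) with R^2
    and p; the summary counts models with p < alpha per case and averages
    R^2 over those significant models only (NaN when none are).
    """
    detrend_fn = _DETREND[detrend]
    for col in ("scenario", "gcm", "co2_arm"):
        if table[col].nunique() != 1:
            raise ValueError(f"evaluation slice must be single-{col}")
    records = []
    for case in cases:
        agg = case_yield_series(table, cells, case, level="region")
        for (crop, unit, model), sub in agg.groupby(["crop", "unit", "model"],
                                                    sort=False):
            if unit not in obs:
                continue
            sim = sub.set_index("year")["yield"].sort_index()
            o = obs[unit].as_series()
            common = sim.index.intersection(o.index)
            if len(common) != len(o):
                raise ValueError(
                    f"observed years for {unit} not fully covered by simulations"
                )
            r2, p = explained_variance(
                detrend_fn(o.loc[common]), detrend_fn(sim.loc[common])
            )
            records.append(
                dict(crop=crop, region=unit, case=case, model=model,
                     r_squared=r2, p_value=p, significant=p < alpha)
            )
    per_model = pd.DataFrame(records)
    if per_model.empty:
        raise ValueError("no (region, case) pairs evaluated; check obs regions")

    def _mean_sig(g: pd.DataFrame) -> pd.Series:
        sig = g[g["significant"]]
        return pd.Series(
            dict(
                n_models=len(g),
                n_significant=int(g["significant"].sum()),
                mean_r2_significant=sig["r_squared"].mean() if len(sig) else np.nan,
                mean_r2_all=g["r_squared"].mean(),
            )
        )

    summary = (
        per_model.groupby(["crop", "region", "case"], sort=False)
        .apply(_mean_sig, include_groups=False)
        .reset_index()
    )
    return per_model, summary
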