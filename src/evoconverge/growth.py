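"""Growth-rate estimation from serial-transfer density series.

Two rates are computed per transfer. The realized growth rate (RGR) spans a
whole transfer, including any lag or die-off: the post-transfer starting
density is inferred by dividing the previous transfer's final density by the
dilution factor, and the rate is ln(N_final/N_initial)/dt in days. The
exponential growth rate (EGR) is the slope of an ordinary least-squares fit
of ln(density) on time over the best log-linear window within the transfer,
reported with the fit's R^2 so poorly exponential windows can be filtered.

Per-transfer generation accounting uses log2 of the dilution factor: a
culture diluted D-fold must double log2(D) times to regrow, so k transfers
correspond to k*log2(D) generations. Evolutionary rates are the slope of
RGR against generation number, normalised by the regression intercept (the
estimated ancestral rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import GrowthSeries

HOURS_PER_DAY = 24.0


def generations_per_transfer(dilution_factor: float) -> float:
    """log2 of the dilution factor (doublings needed to regrow)."""
    if dilution_factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    return math.log2(dilution_factor)


def dilution_factor(transfer_volume_ml: float, final_volume_ml: float) -> float:
    """Fold dilution when ``transfer_volume`` is carried into ``final_volume``."""
    if transfer_volume_ml <= 0 or final_volume_ml <= 0:
        raise ValueError("volumes must be positive")
    if transfer_volume_ml >= final_volume_ml:
        raise ValueError("transfer volume must be smaller than final volume")
    return final_volume_ml / transfer_volume_ml


def redfield_nitrogen(phosphorus_uM: float, ratio: float = 16.0) -> float:
    """Nitrogen concentration at Redfield proportions to phosphorus (uM)."""
    if phosphorus_uM < 0:
        raise ValueError("phosphorus concentration must be nonnegative")
    return ratio * phosphorus_uM


@dataclass
class GrowthFit:
    lineage_id: str
    transfer_index: int
    rgr: Optional[float]  # per day
    egr: Optional[float]  # per day
    r_squared: Optional[float]
    generation: float


def rgr(series: GrowthSeries, transfer_index: int) -> float:
    """Realized growth rate over one transfer (per day).

    The starting density is the previous transfer's final density divided by
    the dilution factor; dt runs from the transfer event to the final
    reading of the window. Die-off gives a negative rate.
    """
    if transfer_index < 1:
        raise ValueError("RGR needs the previous transfer's final density")
    _, prev_dens = series.window(transfer_index - 1)
    times, dens = series.window(transfer_index)
    if prev_dens.size == 0 or dens.size == 0:
        raise ValueError(f"transfer {transfer_index}: empty observation window")
    n_initial = prev_dens[-1] / series.dilution_factor
    n_final = dens[-1]
    dt_days = (times[-1] - series.transfer_times_h[transfer_index]) / HOURS_PER_DAY
    if dt_days <= 0:
        raise ValueError(f"transfer {transfer_index}: nonpositive duration")
    return float(np.log(n_final / n_initial) / dt_days)


def egr(
    series: GrowthSeries,
    transfer_index: int,
    min_points: int = 3,
) -> tuple[Optional[float], Optional[float]]:
    """Exponential growth rate (per day) and R^2 of the log-linear fit.

    The fitting window is the contiguous run of >= max(min_points,
    ceil(n/2)) observations maximising R^2 (ties favour the longer, then the
    earlier window). Returns (None, None) when fewer than ``min_points``
    observations exist or the fit is degenerate (constant density).
    """
    times, dens = series.window(transfer_index)
    n = times.size
    if n < min_points:
        return None, None
    t_days = times / HOURS_PER_DAY
    logn = np.log(dens)
    min_len = max(min_points, -(-n // 2))  # ceil(n/2)
    best = None  # (r2, length, -start, slope)
    for length in range(min_len, n + 1):
        for start in range(0, n - length + 1):
            tt = t_days[start : start + length]
            yy = logn[start : start + length]
            if np.allclose(yy, yy[0]):
                continue
            fit = stats.linregress(tt, yy)
            r2 = fit.rvalue**2
            cand = (r2, length, -start, fit.slope)
            if best is None or cand > best:
                best = cand
    if best is None:
        return None, None
    r2, _, _, slope = best
    return float(slope), float(r2)


def fit_series(series: GrowthSeries) -> pd.DataFrame:
    """RGR and EGR for every transfer of one lineage."""
    gens = generations_per_transfer(series.dilution_factor)
    rows = []
    for k in range(series.n_transfers):
        times, _ = series.window(k)
        if times.size == 0:
            continue
        r = rgr(series, k) if k >= 1 else None
        e, r2 = egr(series, k)
        rows.append(
            {
                "lineage_id": series.lineage_id,
                "transfer_index": k,
                "rgr": r,
                "egr": e,
                "r_squared": r2,
                "generation": k * gens,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lineage_id", "transfer_index", "rgr", "egr", "r_squared", "generation"],
    )


def filter_growth(
    fits: pd.DataFrame,
    rgr_trim: float = 0.05,
    egr_min_r2: float = 0.95,
    strata: Sequence[str] = ("lineage_id",),
) -> pd.DataFrame:
    """Outlier filters: trim extreme RGRs, drop poorly exponential EGRs.

    Within each stratum the top and bottom ``rgr_trim`` fraction of RGR
    values are blanked; EGRs with R^2 < ``egr_min_r2`` are blanked (the
    boundary value is kept). Note trimming is not idempotent: re-trimming an
    already trimmed table removes further points.
    """
    out = fits.copy()

    def _trim(group: pd.DataFrame) -> pd.DataFrame:
        vals = group["rgr"].dropna()
        k = int(len(vals) * rgr_trim)
        if k > 0:
            order = vals.sort_values()
            drop = set(order.index[:k]) | set(order.index[-k:])
            group.loc[group.index.isin(drop), "rgr"] = np.nan
        return group

    if rgr_trim > 0:
        out = (
            out.groupby(list(strata), group_keys=False)[out.columns]
            .apply(_trim)
            .reset_index(drop=True)
        )
    bad_egr = out["r_squared"].notna() & (out["r_squared"] < egr_min_r2)
    out.loc[bad_egr, ["egr", "r_squared"]] = np.nan
    return out


@dataclass
class EvolutionaryRate:
    group_id: str
    slope: float  # rate change per generation
    intercept: float  # estimated ancestral rate
    normalized_rate: Optional[float]  # slope/intercept, per generation
    ci95: Optional[tuple[float, float]]
    n: int


def evolutionary_rate(
    fits: pd.DataFrame,
    group_id: str = "",
    rate_col: str = "rgr",
) -> EvolutionaryRate:
    """Regress growth rate on generation; normalise the slope by intercept.

    The 95% CI of slope/intercept comes from the delta method on the OLS
    estimates (Var and Cov of slope and intercept from the fit). Replicate
    lineages may be pooled by passing their concatenated fits. Requires
    >= 5 transfers with a defined rate; a nonpositive intercept leaves the
    normalised rate undefined.
    """
    df = fits.dropna(subset=[rate_col, "generation"])
    if len(df) < 5:
        raise ValueError("need >= 5 transfers with a defined growth rate")
    x = df["generation"].to_numpy(float)
    y = df[rate_col].to_numpy(float)
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if intercept <= 0:
        return EvolutionaryRate(group_id, slope, intercept, None, None, len(df))
    ratio = slope / intercept
    # delta method on (slope, intercept)
    n = len(df)
    resid = y - (intercept + slope * x)
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    var_slope = s2 / sxx
    var_inter = s2 * (1.0 / n + x.mean() ** 2 / sxx)
    cov = -s2 * x.mean() / sxx
    grad = np.array([1.0 / intercept, -slope / intercept**2])
    var_ratio = (
        grad[0] ** 2 * var_slope + grad[1] ** 2 * var_inter + 2 * grad[0] * grad[1] * cov
    )
    se = math.sqrt(max(var_ratio, 0.0))
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else float("nan")
    ci = (ratio - tcrit * se, ratio + tcrit * se)
    return EvolutionaryRate(group_id, slope, intercept, ratio, ci, len(df))
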