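"""Diel (ZT) time-series assembly and trend analysis of the starch ratio.

Builds per-genotype Zeitgeber-time series of the SHG/TPF ratio statistic from
area-level measurements, summarizes each ZT point as mean ± one standard
deviation over imaging areas, fits ordinary-least-squares slopes separately
over the light and dark phases (with a case-resampling bootstrap confidence
interval), and classifies the diel pattern: wild-type-like diel cycling
(rise in the light, fall in the dark) versus the non-degrading pattern of a
starch-degradation mutant.

The light/dark boundary defaults to ZT16 (16 h light / 8 h dark photoperiod)
and the boundary time point belongs to both phases.  ZT0 and ZT24 are
distinct measurements (this dawn versus the next), never wrapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

DEFAULT_LIGHT_OFF_ZT = 16.0
DEFAULT_BOOTSTRAP_REPS = 2000

PATTERN_DIEL_CYCLING = "diel-cycling"
PATTERN_NON_DEGRADING = "non-degrading"
PATTERN_INDETERMINATE = "indeterminate"

FLAG_SINGLE_AREA = "n=1"


class InsufficientDataError(ValueError):
    """Too few distinct time points to fit a phase trend."""


@dataclass(frozen=True)
class DielSeries:
    """Per-genotype ZT series of the ratio statistic.

    ``table`` has columns zt_hour, mean_ratio, sd_ratio, n_areas, flags; rows
    sorted by ZT.  ``sd_ratio`` is the sample SD (n−1 denominator) over valid
    area-level ratios; single-area rows carry sd 0 with an ``n=1`` flag.
    """

    genotype: str
    table: pd.DataFrame
    light_off_zt: float = DEFAULT_LIGHT_OFF_ZT


@dataclass(frozen=True)
class PhaseTrend:
    """OLS slope of ratio vs ZT over one photoperiod phase.

    ``slope_ci`` is a 95% percentile interval from a case-resampling
    bootstrap over area-level points; ``mean_level`` is the mean ratio over
    the phase points (used by the flat-but-high classification branch).
    """

    phase: str  # "light" | "dark"
    slope: float
    slope_ci: tuple[float, float]
    n_points: int
    mean_level: float
    n_boot: int
    seed: int


def aggregate(
    quant: pd.DataFrame,
    genotype: str = "",
    light_off_zt: float = DEFAULT_LIGHT_OFF_ZT,
) -> DielSeries:
    """Aggregate area-level ratios into a per-ZT mean ± SD series.

    ``quant`` needs columns ``zt_hour`` and ``ratio``; NaN ratios (flagged
    records) are excluded with their count logged per ZT, and a ZT with no
    valid ratio is omitted with a warning.
    """
    if "zt_hour" not in quant.columns or "ratio" not in quant.columns:
        raise ValueError("quant table must have zt_hour and ratio columns")
    rows = []
    for zt, grp in quant.groupby("zt_hour", sort=True):
        vals = grp["ratio"].to_numpy(dtype=float)
        valid = vals[np.isfinite(vals)]
        n_excluded = vals.size - valid.size
        if valid.size == 0:
            warnings.warn(
                f"ZT {zt:g}: no valid ratios ({n_excluded} flagged) — row omitted",
                stacklevel=2,
            )
            continue
        flags = []
        if n_excluded:
            flags.append(f"excluded={n_excluded}")
        if valid.size == 1:
            sd = 0.0
            flags.append(FLAG_SINGLE_AREA)
        else:
            sd = float(np.std(valid, ddof=1))
        rows.append(
            {
                "zt_hour": float(zt),
                "mean_ratio": float(np.mean(valid)),
                "sd_ratio": sd,
                "n_areas": int(valid.size),
                "flags": ";".join(flags),
            }
        )
    table = pd.DataFrame(
        rows, columns=["zt_hour", "mean_ratio", "sd_ratio", "n_areas", "flags"]
    )
    return DielSeries(genotype=genotype, table=table, light_off_zt=light_off_zt)


def _phase_points(
    quant: pd.DataFrame, phase: str, light_off_zt: float
) -> tuple[np.ndarray, np.ndarray]:
    zt = quant["zt_hour"].to_numpy(dtype=float)
    ratio = quant["ratio"].to_numpy(dtype=float)
    if phase == "light":
        sel = zt <= light_off_zt + 1e-9
    elif phase == "dark":
        sel = zt >= light_off_zt - 1e-9
    else:
        raise ValueError("phase must be 'light' or 'dark'")
    sel &= np.isfinite(ratio)
    return zt[sel], ratio[sel]


def _bootstrap_slopes(
    x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    xb, yb = x[idx], y[idx]
    xm = xb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    sxx = ((xb - xm) ** 2).sum(axis=1)
    sxy = ((xb - xm) * (yb - ym)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = sxy / sxx
    return slopes[np.isfinite(slopes)]  # drop degenerate resamples (all one ZT)


def phase_trend(
    quant: pd.DataFrame,
    phase: str,
    *,
    light_off_zt: float = DEFAULT_LIGHT_OFF_ZT,
    n_boot: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
) -> PhaseTrend:
    """OLS slope of area-level ratio vs ZT over one phase, with bootstrap CI.

    ``quant`` holds area-level points (columns ``zt_hour``, ``ratio``).  The
    light phase covers ZT ∈ [0, light_off], the dark phase
    [light_off, 24]; the boundary point belongs to both.  Requires at least
    three distinct ZT values in the phase.  The 95% CI comes from
    case-resampling the points ``n_boot`` times with a seeded generator, so a
    fixed seed gives a reproducible interval.
    """
    x, y = _phase_points(quant, phase, light_off_zt)
    if np.unique(x).size < 3:
        raise InsufficientDataError(
            f"{phase} phase has {np.unique(x).size} distinct ZT points; need >= 3"
        )
    sxx = float(((x - x.mean()) ** 2).sum())
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    rng = np.random.default_rng(seed)
    slopes = _bootstrap_slopes(x, y, n_boot, rng)
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return PhaseTrend(
        phase=phase, slope=slope, slope_ci=(float(lo), float(hi)),
        n_points=int(x.size), mean_level=float(y.mean()), n_boot=n_boot, seed=seed,
    )


def classify_pattern(
    light: PhaseTrend,
    dark: PhaseTrend,
    *,
    high_level: float | None = None,
) -> str:
    """Classify a diel starch pattern from the two phase trends.

    * ``diel-cycling`` — light-phase CI entirely positive and dark-phase CI
      entirely negative (synthesis by day, degradation by night).
    * ``non-degrading`` — light-phase CI positive (or, when ``high_level`` is
      given, flat at a level above it) while the dark-phase CI contains zero
      or is positive: starch accumulates but is not degraded.
    * ``indeterminate`` — anything else (e.g. wide overlapping intervals).
    """
    l_lo, l_hi = light.slope_ci
    d_lo, d_hi = dark.slope_ci
    light_up = l_lo > 0
    dark_down = d_hi < 0
    dark_flat_or_up = d_lo >= 0 or (d_lo <= 0 <= d_hi)
    light_flat_high = (
        high_level is not None
        and l_lo <= 0 <= l_hi
        and light.mean_level > high_level
        and dark.mean_level > high_level
    )
    if light_up and dark_down:
        return PATTERN_DIEL_CYCLING
    if (light_up or light_flat_high) and dark_flat_or_up:
        return PATTERN_NON_DEGRADING
    return PATTERN_INDETERMINATE


def truth_correlation(quant: pd.DataFrame) -> float:
    """Spearman correlation between per-ZT mean ratio and mean true starch mass.

    ``quant`` needs columns ``zt_hour``, ``ratio`` and ``true_starch_mass``
    (simulator runs carry the latter).  Used to check that the ratio
    statistic recovers the simulated diel kinetics.
    """
    per_zt = (
        quant.dropna(subset=["ratio"])
        .groupby("zt_hour")
        .agg(mean_ratio=("ratio", "mean"), mean_mass=("true_starch_mass", "mean"))
    )
    rho = spearmanr(per_zt["mean_ratio"], per_zt["mean_mass"]).statistic
    return float(rho)


def plot_series(series_list, path=None, ax=None):
    """Plot mean ± SD ratio vs ZT with a light/dark annotation bar.

    ``series_list`` is one DielSeries or an iterable of them (e.g. Col-0 and
    sex1 on shared axes).  Returns the matplotlib Axes.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(series_list, DielSeries):
        series_list = [series_list]
    series_list = list(series_list)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ymax = 0.0
    for series in series_list:
        t = series.table
        ax.errorbar(
            t["zt_hour"], t["mean_ratio"], yerr=t["sd_ratio"],
            marker="o", capsize=3, label=series.genotype or None,
        )
        if len(t):
            ymax = max(ymax, float((t["mean_ratio"] + t["sd_ratio"]).max()))
    light_off = series_list[0].light_off_zt if series_list else DEFAULT_LIGHT_OFF_ZT
    ax.axvline(light_off, linestyle="--", color="gray")
    ax.axvspan(light_off, 24.0, color="0.85", zorder=0)
    ax.set_xlabel("ZT (h)")
    ax.set_ylabel(r"$I_\mathrm{SHG}$ / $Cnt_\mathrm{TPF}$")
    ax.set_xlim(-0.5, 24.5)
    if any(s.genotype for s in series_list):
        ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
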