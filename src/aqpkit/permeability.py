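"""Permeability coefficients from oocyte swelling time courses.

The measurement chain is: cross-sectional areas -> relative volume
``V/V0 = (At/A0)^(3/2)`` -> ordinary-least-squares initial slope
``d(V/V0)/dt`` over a short fit window -> coefficient,

    Pf = V0 * slope / (S * Vw * |osm_in - osm_out|)        (water)
    Ps = V0 * slope / (S * Vw * |sol_in - sol_out|)        (solute)

with the gradient converted to amount/cm^3.  Both estimators use the
magnitude of the gradient so that influx-driven swelling yields a
positive coefficient.  Group statistics follow the assay convention:
two groups -> Welch t-test, more -> one-way ANOVA with Tukey HSD.

Note the Ps formula above includes the molar volume of water Vw; part
of the oocyte literature defines Ps without it (see docs/methods.md for
the convention discussion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .osmotic import BathCondition, OocyteGeometry
from .units import mm_to_internal, mosm_to_internal

__all__ = [
    "SwellingTimeCourse",
    "SlopeFit",
    "PermeabilityEstimate",
    "GroupComparison",
    "relative_volume",
    "initial_slope",
    "estimate_pf",
    "estimate_ps",
    "inhibition_percent",
    "compare_groups",
    "estimate_cohort",
    "summarize_groups",
    "DEFAULT_FIT_WINDOW",
    "R_SQUARED_FLAG_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: default initial-slope fit window, s (of the 60-s record)
DEFAULT_FIT_WINDOW: float = 20.0
#: fits with R^2 below this are flagged (never dropped)
R_SQUARED_FLAG_THRESHOLD: float = 0.8


@dataclass
class SwellingTimeCourse:
    """One oocyte's sampled cross-sectional areas plus bath condition."""

    oocyte_id: str
    group: str
    times: np.ndarray  # s, starting at 0, strictly increasing
    areas: np.ndarray  # cm^2
    bath: BathCondition

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times.size != self.areas.size:
            raise ValueError("times and areas must have equal length")
        if self.times.size < 3:
            raise ValueError("a swelling time course needs >= 3 samples")
        if self.times[0] != 0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        bad = np.flatnonzero(~(self.areas > 0))
        if bad.size:
            raise ValueError(f"non-positive area at sample index {bad[0]}")


@dataclass(frozen=True)
class SlopeFit:
    """OLS initial-slope fit of V/V0 on t."""

    slope: float         # 1/s
    intercept: float
    stderr: float        # 1/s
    r_squared: float
    window: float        # s
    n_points: int


@dataclass(frozen=True)
class PermeabilityEstimate:
    """A fitted slope with its derived permeability coefficient."""

    slope: float            # d(V/V0)/dt, 1/s
    slope_stderr: float
    fit_window: float       # s
    r_squared: float
    coefficient: float      # Pf or Ps, cm/s
    kind: str               # "water" | "solute"
    low_quality: bool = False  # True when r_squared < flag threshold


@dataclass(frozen=True)
class GroupComparison:
    """Result of the standard between-group test for an assay endpoint."""

    method: str             # "welch-t" | "anova-tukey"
    statistic: float
    p_value: float
    pairwise: tuple | None = None  # ((g1, g2), adjusted p) for the ANOVA branch


def relative_volume(tc: SwellingTimeCourse) -> np.ndarray:
    """Relative volume series (At/A0)^(3/2); first element exactly 1."""
    a0 = tc.areas[0]
    vv0 = (tc.areas / a0) ** 1.5
    vv0[0] = 1.0
    return vv0


def initial_slope(
    vv0: Sequence[float], times: Sequence[float], window: float
) -> SlopeFit:
    """OLS slope of V/V0 on t restricted to t <= window, intercept free.

    For a degenerate perfect fit (zero residual, e.g. a constant
    series) R^2 is reported as 1.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    t = np.asarray(times, dtype=float)
    y = np.asarray(vv0, dtype=float)
    mask = t <= window * (1 + 1e-12)
    t, y = t[mask], y[mask]
    n = t.size
    if n < 2:
        raise ValueError(f"need >= 2 points inside the {window}-s window, got {n}")
    tm, ym = t.mean(), y.mean()
    sxx = float(np.sum((t - tm) ** 2))
    sxy = float(np.sum((t - tm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * tm
    resid = y - (intercept + slope * t)
    ssr = float(np.sum(resid**2))
    sst = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if sst == 0 or ssr <= sst * 1e-15 else 1.0 - ssr / sst
    stderr = float(np.sqrt(ssr / (n - 2) / sxx)) if n > 2 else float("nan")
    return SlopeFit(slope, intercept, stderr, r2, float(window), n)


def _coefficient(slope: float, geom: OocyteGeometry, gradient_internal: float) -> float:
    if gradient_internal == 0:
        raise ValueError("zero gradient: permeability is undefined")
    return slope * geom.v0 / (geom.s * geom.vw * abs(gradient_internal))


def _wrap(fit: SlopeFit | float) -> SlopeFit:
    if isinstance(fit, SlopeFit):
        return fit
    return SlopeFit(float(fit), np.nan, np.nan, np.nan, np.nan, 0)


def estimate_pf(
    fit: SlopeFit | float,
    geom: OocyteGeometry,
    osm_in: float,
    osm_out: float,
) -> PermeabilityEstimate:
    """Osmotic water permeability Pf (cm/s) from an initial slope.

    ``fit`` may be a :class:`SlopeFit` or a bare slope in 1/s; the
    osmotic gradient is given in mOsm.
    """
    fit = _wrap(fit)
    grad = mosm_to_internal(osm_in) - mosm_to_internal(osm_out)
    pf = _coefficient(fit.slope, geom, grad)
    low = bool(np.isfinite(fit.r_squared) and fit.r_squared < R_SQUARED_FLAG_THRESHOLD)
    if low:
        logger.warning("low-quality water fit flagged: R^2=%.3f", fit.r_squared)
    return PermeabilityEstimate(
        fit.slope, fit.stderr, fit.window, fit.r_squared, pf, "water", low
    )


def estimate_ps(
    fit: SlopeFit | float,
    geom: OocyteGeometry,
    sol_in: float,
    sol_out: float,
) -> PermeabilityEstimate:
    """Solute permeability Ps (cm/s) from an initial slope; gradient in mM."""
    fit = _wrap(fit)
    grad = mm_to_internal(sol_in) - mm_to_internal(sol_out)
    ps = _coefficient(fit.slope, geom, grad)
    low = bool(np.isfinite(fit.r_squared) and fit.r_squared < R_SQUARED_FLAG_THRESHOLD)
    if low:
        logger.warning("low-quality solute fit flagged: R^2=%.3f", fit.r_squared)
    return PermeabilityEstimate(
        fit.slope, fit.stderr, fit.window, fit.r_squared, ps, "solute", low
    )


def inhibition_percent(
    coef_treated: float, coef_untreated: float, clip_negative: bool = False
) -> float:
    """Percent inhibition 100*(1 - treated/untreated).

    Stimulation (treated > untreated) is reported as a negative value
    unless ``clip_negative`` is set.
    """
    if coef_untreated <= 0:
        raise ValueError("untreated coefficient must be > 0")
    pct = 100.0 * (1.0 - coef_treated / coef_untreated)
    return max(pct, 0.0) if clip_negative else pct


def compare_groups(values: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Between-group test: Welch t for 2 groups, one-way ANOVA + Tukey HSD beyond.

    Each group needs at least 2 values.  Degenerate all-identical data
    return statistic 0 and p 1.
    """
    if len(values) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    groups = list(arrays)
    data = [arrays[g] for g in groups]

    if len(groups) == 2:
        if np.array_equal(data[0], data[1]):
            return GroupComparison("welch-t", 0.0, 1.0)
        res = stats.ttest_ind(data[0], data[1], equal_var=False)
        return GroupComparison("welch-t", float(res.statistic), float(res.pvalue))

    if np.ptp(np.concatenate(data)) == 0:
        pairwise = tuple(((a, b), 1.0) for a, b in combinations(groups, 2))
        return GroupComparison("anova-tukey", 0.0, 1.0, pairwise)
    f_stat, p = stats.f_oneway(*data)
    tukey = stats.tukey_hsd(*data)
    pairwise = tuple(
        ((groups[i], groups[j]), float(tukey.pvalue[i, j]))
        for i, j in combinations(range(len(groups)), 2)
    )
    return GroupComparison("anova-tukey", float(f_stat), float(p), pairwise)


def estimate_cohort(
    timecourses: Sequence[SwellingTimeCourse],
    mode: str = "water",
    window: float = DEFAULT_FIT_WINDOW,
    geom: OocyteGeometry = OocyteGeometry(),
    osm_in: float = 200.0,
    sol_in: float = 0.0,
):
    """Per-oocyte slope fits and coefficients for a cohort, as a tidy table.

    ``mode='water'`` derives Pf against the gradient ``osm_in -
    bath.osm_out``; ``mode='solute'`` derives Ps against ``sol_in -
    bath.sol_out``.  Returns a pandas DataFrame with one row per oocyte.
    """
    if mode not in ("water", "solute"):
        raise ValueError("mode must be 'water' or 'solute'")
    rows = []
    for tc in timecourses:
        vv0 = relative_volume(tc)
        fit = initial_slope(vv0, tc.times, window)
        if mode == "water":
            est = estimate_pf(fit, geom, osm_in, tc.bath.osm_out)
        else:
            est = estimate_ps(fit, geom, sol_in, tc.bath.sol_out)
        rows.append(
            {
                "oocyte_id": tc.oocyte_id,
                "group": tc.group,
                "slope_per_s": est.slope,
                "slope_stderr": est.slope_stderr,
                "r_squared": est.r_squared,
                "coefficient_cm_per_s": est.coefficient,
                "kind": est.kind,
                "low_quality": est.low_quality,
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(per_oocyte: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean/SD/SEM/n of the per-oocyte coefficients."""
    g = per_oocyte.groupby("group")["coefficient_cm_per_s"]
    out = g.agg(["mean", "std", "count"]).rename(
        columns={"mean": "coef_mean", "std": "coef_sd", "count": "n"}
    )
    out["coef_sem"] = out["coef_sd"] / np.sqrt(out["n"])
    return out.reset_index()
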