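"""In vivo endpoints: blood-meal excretion, excreta urea, engorgement, fecundity.

A :class:`BugRecord` carries one insect's weight series around a blood
meal: pre-feed weight ``w_prefeed`` (W_{t-1}), replete weight ``w_fed``
(W_t0), and weights at the standard post-meal hours {1, 2, 3, 4, 6, 8,
12, 24}.  Excretion is expressed as the percentage of the gained meal
weight lost by hour n,

    % excreted(n) = 100 * (W_t0 - W_tn) / (W_t0 - W_{t-1}),

reported as a positive magnitude.  Engorgement is the meal gain as a
percentage of pre-fed weight.  Excreta urea is back-calculated from a
linear colorimetric standard curve and scaled from the 20-uL reaction
aliquot to the 100-uL well.  Endpoints are compared between two dsRNA
treatment groups by a two-sided Welch t-test with a 95% CI on the
difference of means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .permeability import GroupComparison

__all__ = [
    "EXCRETION_HOURS",
    "BugRecord",
    "UreaStandardCurve",
    "UreaResult",
    "EndpointComparison",
    "percent_excreted",
    "engorgement_percent",
    "fit_urea_curve",
    "urea_per_bug",
    "endpoint_comparison",
]

logger = logging.getLogger(__name__)

#: hours post blood meal at which weights are recorded
EXCRETION_HOURS = (1, 2, 3, 4, 6, 8, 12, 24)


@dataclass
class BugRecord:
    """One bug's pre/post-feed weight series plus optional endpoints."""

    bug_id: str
    group: str
    w_prefeed: float                  # mg, W_{t-1}
    w_fed: float                      # mg, W_t0
    weights: dict = field(default_factory=dict)  # hour -> mg
    urea_absorbance: float | None = None
    eggs_per_day: list | None = None

    def __post_init__(self) -> None:
        if self.w_prefeed <= 0:
            raise ValueError(f"{self.bug_id}: pre-feed weight must be > 0")

    @property
    def w_gained(self) -> float:
        """Meal weight, mg: W_t0 - W_{t-1}."""
        return self.w_fed - self.w_prefeed

    @property
    def total_eggs(self) -> int | None:
        if self.eggs_per_day is None:
            return None
        return int(sum(self.eggs_per_day))


@dataclass(frozen=True)
class UreaStandardCurve:
    """OLS line through the urea standards: absorbance = slope*nmol + intercept."""

    levels: tuple          # nmol
    absorbances: tuple
    slope: float           # absorbance per nmol
    intercept: float
    r_squared: float

    @property
    def top_level(self) -> float:
        return max(self.levels)


@dataclass(frozen=True)
class UreaResult:
    """Back-calculated urea for one bug."""

    nmol_reaction: float
    nmol_per_bug: float
    extrapolated: bool      # absorbance above the top standard
    floored: bool           # absorbance below the intercept, clamped to 0


@dataclass(frozen=True)
class EndpointComparison:
    """Welch t-test on a phenotype endpoint, with effect size."""

    endpoint: str
    comparison: GroupComparison
    mean_difference: float          # group2 - group1
    ci_low: float
    ci_high: float
    group_means: tuple
    n_per_group: tuple
    excluded: tuple = ()            # bug_ids dropped for missing values


def percent_excreted(rec: BugRecord, flag_nonmonotone: bool = True) -> pd.DataFrame:
    """Percent of the meal weight excreted at each recorded hour.

    Weight gains after t0 (balance jitter, regurgitation) produce
    negative values; they are flagged, never truncated.  Returns a
    frame with columns ``hour, percent_excreted, flagged``.
    """
    gained = rec.w_gained
    if gained <= 0:
        raise ValueError(f"{rec.bug_id}: non-positive meal weight ({gained:.3f} mg)")
    hours = sorted(rec.weights)
    pct = np.array([100.0 * (rec.w_fed - rec.weights[h]) / gained for h in hours])
    flagged = np.zeros(len(hours), dtype=bool)
    flagged |= pct < 0
    if len(pct) > 1:
        flagged[1:] |= np.diff(pct) < 0  # excretion should not reverse
    if flag_nonmonotone and flagged.any():
        logger.warning(
            "%s: non-monotone or negative excretion at hours %s",
            rec.bug_id,
            [hours[i] for i in np.flatnonzero(flagged)],
        )
    return pd.DataFrame(
        {"hour": hours, "percent_excreted": pct, "flagged": flagged}
    )


def engorgement_percent(rec: BugRecord) -> float:
    """Meal gain as percent of pre-fed weight: 100*(W_t0 - W_{t-1})/W_{t-1}."""
    return 100.0 * (rec.w_fed - rec.w_prefeed) / rec.w_prefeed


def fit_urea_curve(
    levels: Sequence[float], absorbances: Sequence[float]
) -> UreaStandardCurve:
    """OLS standard curve through >= 2 distinct urea levels.

    A flat (or inverted) curve is rejected: the assay cannot be read
    against a non-increasing standard line.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if x.size != y.size:
        raise ValueError("levels and absorbances must have equal length")
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct standard levels")
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
        raise ValueError(f"degenerate standard curve: slope {slope:.4g} <= 0")
    resid = y - (intercept + slope * x)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return UreaStandardCurve(
        tuple(x.tolist()), tuple(y.tolist()), float(slope), float(intercept), r2
    )


def urea_per_bug(
    absorbance: float,
    curve: UreaStandardCurve,
    sample_volume_ul: float = 20.0,
    well_volume_ul: float = 100.0,
) -> UreaResult:
    """Urea content of one bug's excreta well, nmol.

    The reaction uses ``sample_volume_ul`` of the ``well_volume_ul``
    excreta suspension, so the per-bug amount is the in-reaction amount
    times well/sample (factor 5 at the defaults).  Absorbances below
    the intercept floor at 0 with a warning; absorbances above the top
    standard are returned flagged as extrapolated.
    """
    if sample_volume_ul <= 0 or well_volume_ul <= 0:
        raise ValueError("volumes must be > 0")
    nmol_rxn = (absorbance - curve.intercept) / curve.slope
    floored = nmol_rxn < 0
    if floored:
        warnings.warn(
            f"absorbance {absorbance:.3f} below curve intercept; urea floored at 0",
            stacklevel=2,
        )
        nmol_rxn = 0.0
    top_abs = curve.intercept + curve.slope * curve.top_level
    extrapolated = absorbance > top_abs + 1e-9
    if extrapolated:
        logger.warning(
            "absorbance %.3f above top standard (%.3f): extrapolated", absorbance, top_abs
        )
    factor = well_volume_ul / sample_volume_ul
    return UreaResult(nmol_rxn, nmol_rxn * factor, bool(extrapolated), bool(floored))


def _endpoint_value(
    rec: BugRecord, endpoint: str, curve: UreaStandardCurve | None
) -> float | None:
    if endpoint == "excreted_24h":
        if 24 not in rec.weights:
            return None
        return float(
            percent_excreted(rec, flag_nonmonotone=False)
            .set_index("hour")
            .loc[24, "percent_excreted"]
        )
    if endpoint == "urea":
        if rec.urea_absorbance is None or curve is None:
            return None
        return urea_per_bug(rec.urea_absorbance, curve).nmol_per_bug
    if endpoint == "eggs":
        total = rec.total_eggs
        return None if total is None else float(total)
    raise ValueError(f"unknown endpoint {endpoint!r}")


def endpoint_comparison(
    records: Mapping[str, Sequence[BugRecord]],
    endpoint: str,
    curve: UreaStandardCurve | None = None,
    confidence: float = 0.95,
) -> EndpointComparison:
    """Two-group Welch t-test on a phenotype endpoint.

    ``endpoint`` is one of ``excreted_24h`` (percent of meal excreted by
    24 h), ``urea`` (nmol per bug; requires ``curve``), or ``eggs``
    (total eggs until oviposition ceased).  Bugs missing the endpoint
    are excluded with a log entry.  The effect size is the difference
    of group means (second group minus first) with a Welch-df CI.
    """
    if len(records) != 2:
        raise ValueError("endpoint comparison is defined for exactly 2 groups")
    groups = list(records)
    values, excluded = {}, []
    for g in groups:
        vals = []
        for rec in records[g]:
            v = _endpoint_value(rec, endpoint, curve)
            if v is None:
                excluded.append(rec.bug_id)
                logger.warning("%s excluded from %s: missing value", rec.bug_id, endpoint)
            else:
                vals.append(v)
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 usable bugs")
        values[g] = np.asarray(vals)

    a, b = values[groups[0]], values[groups[1]]
    diff = float(b.mean() - a.mean())
    if np.array_equal(a, b):
        comp = GroupComparison("welch-t", 0.0, 1.0)
        ci_low = ci_high = diff
    else:
        res = stats.ttest_ind(b, a, equal_var=False)
        comp = GroupComparison("welch-t", float(res.statistic), float(res.pvalue))
        ci = res.confidence_interval(confidence_level=confidence)
        ci_low, ci_high = float(ci.low), float(ci.high)
    return EndpointComparison(
        endpoint,
        comp,
        diff,
        ci_low,
        ci_high,
        (float(a.mean()), float(b.mean())),
        (a.size, b.size),
        tuple(excluded),
    )
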