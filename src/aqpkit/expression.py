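"""Relative gene expression by the comparative-Ct (2^-ddCt) method.

A Ct table is a tidy pandas DataFrame with one row per well:
``sample_id, group, gene, is_reference, ct, replicate``.  Replicate Cts
are averaged per (group, gene) before differencing:

    dCt   = mean Ct(target) - mean Ct(reference gene)   per group
    ddCt  = dCt(group) - dCt(calibrator group)
    RQ    = 2 ** (-ddCt)

so the calibrator group has RQ exactly 1 by construction.  Replicate
SDs are combined as sqrt(sd_target^2 + sd_ref^2) and propagated to a
fold range 2^-(ddCt +/- SD).  Primer pairs are admitted through a
dilution-series efficiency gate (0.9 <= E <= 1.1); groups measured with
a failing primer set are excluded with a logged warning rather than
efficiency-corrected.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CT_COLUMNS",
    "EfficiencyFit",
    "efficiency_from_dilution_series",
    "relative_expression",
    "knockdown_timecourse",
    "validate_ct_table",
    "EFFICIENCY_GATE",
]

logger = logging.getLogger(__name__)

CT_COLUMNS = ("sample_id", "group", "gene", "is_reference", "ct", "replicate")

#: admissible amplification-efficiency band
EFFICIENCY_GATE = (0.9, 1.1)

# E above this is rejected outright as non-physical (better than one
# full doubling-and-a-half per cycle cannot occur; it signals inputs
# entered in the wrong order or on the wrong scale).
_E_NONPHYSICAL = 1.5


@dataclass(frozen=True)
class EfficiencyFit:
    """Dilution-series calibration of one primer pair."""

    gene: str
    slope: float        # cycles per log10 dilution step
    efficiency: float   # E = 10**(-1/slope) - 1
    passes_gate: bool
    r_squared: float


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the Ct-table schema and value invariants; return the table."""
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
        raise ValueError("all Ct values must be finite and > 0")
    for group, sub in table.groupby("group"):
        if not sub["is_reference"].any():
            raise ValueError(f"group {group!r} lacks the reference gene")
    return table


def efficiency_from_dilution_series(
    gene: str,
    log10_dilutions: Sequence[float],
    cts: Sequence[float],
) -> EfficiencyFit:
    """Fit Ct against log10 template quantity and derive amplification efficiency.

    ``log10_dilutions`` are the log10 relative template quantities
    (0, -1, -2, ... for a 10-fold dilution series).  Ct must increase
    as template decreases (negative slope); the fitted slope gives
    E = 10**(-1/slope) - 1, and the gate flag records whether E lies
    in [0.9, 1.1].
    """
    x = np.asarray(log10_dilutions, dtype=float)
    y = np.asarray(cts, dtype=float)
    if x.size != y.size:
        raise ValueError("dilutions and cts must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 dilution points")
    if np.ptp(x) == 0:
        raise ValueError("dilution levels are degenerate")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    if slope >= 0:
        raise ValueError(
            f"{gene}: Ct does not increase as template is diluted "
            f"(slope {slope:.3f}); check input ordering"
        )
    eff = 10.0 ** (-1.0 / slope) - 1.0
    if eff > _E_NONPHYSICAL:
        raise ValueError(
            f"{gene}: non-physical amplification efficiency E={eff:.2f} "
            f"(slope {slope:.3f} cycles/log10); check input ordering/scale"
        )
    passes = EFFICIENCY_GATE[0] <= eff <= EFFICIENCY_GATE[1]
    return EfficiencyFit(gene, float(slope), float(eff), bool(passes), r2)


def _mean_sd(sub: pd.DataFrame) -> tuple[float, float]:
    ct = sub["ct"].to_numpy(dtype=float)
    sd = float(np.std(ct, ddof=1)) if ct.size > 1 else 0.0
    return float(ct.mean()), sd


def relative_expression(
    table: pd.DataFrame,
    calibrator: str,
    efficiency_fits: Mapping[str, EfficiencyFit] | None = None,
) -> pd.DataFrame:
    """Per-group relative quantity of every target gene vs the calibrator.

    Returns a tidy frame with columns ``group, gene, delta_ct,
    delta_delta_ct, rq, rq_low, rq_high``.  If ``efficiency_fits`` is
    given, genes whose primer pair fails the efficiency gate are
    dropped with a warning.
    """
    validate_ct_table(table)
    if calibrator not in set(table["group"]):
        raise ValueError(f"calibrator group {calibrator!r} not in table")

    genes = sorted(set(table.loc[~table["is_reference"], "gene"]))
    if efficiency_fits:
        kept = []
        for g in genes:
            fit = efficiency_fits.get(g)
            if fit is not None and not fit.passes_gate:
                msg = f"gene {g!r} excluded: efficiency {fit.efficiency:.2f} outside gate"
                logger.warning(msg)
                warnings.warn(msg, stacklevel=2)
            else:
                kept.append(g)
        genes = kept

    # per-group mean/SD of the reference gene
    ref_stats = {
        group: _mean_sd(sub[sub["is_reference"]])
        for group, sub in table.groupby("group")
    }

    rows = []
    for gene in genes:
        tgt = table[(table["gene"] == gene) & (~table["is_reference"])]
        dct, dct_sd = {}, {}
        for group, sub in tgt.groupby("group"):
            m_t, s_t = _mean_sd(sub)
            m_r, s_r = ref_stats[group]
            dct[group] = m_t - m_r
            dct_sd[group] = math.sqrt(s_t**2 + s_r**2)
        if calibrator not in dct:
            raise ValueError(f"gene {gene!r} has no wells in calibrator {calibrator!r}")
        for group in dct:
            ddct = dct[group] - dct[calibrator]
            sd = dct_sd[group]
            rows.append(
                {
                    "group": group,
                    "gene": gene,
                    "delta_ct": dct[group],
                    "delta_delta_ct": ddct,
                    "rq": 2.0 ** (-ddct),
                    "rq_low": 2.0 ** (-(ddct + sd)),
                    "rq_high": 2.0 ** (-(ddct - sd)),
                }
            )
    return pd.DataFrame(rows)


def knockdown_timecourse(
    tables: Mapping[float, pd.DataFrame],
    treatment: str,
    control: str,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-day relative expression of the treatment vs its matched-day control.

    ``tables`` maps days-post-injection to Ct tables that each contain
    both the ``treatment`` and ``control`` groups.  Every non-reference
    gene present is quantified (``genes`` restricts the set), so
    off-target transcripts ride along and can be checked for RQ ~= 1.
    Days missing either group are skipped with a warning.  Returns a
    frame with columns ``dpi, gene, rq, rq_low, rq_high``.
    """
    if not tables:
        warnings.warn("empty day map: no knockdown time course", stacklevel=2)
        return pd.DataFrame(columns=["dpi", "gene", "rq", "rq_low", "rq_high"])

    rows = []
    for dpi in sorted(tables):
        table = tables[dpi]
        present = set(table["group"])
        if treatment not in present or control not in present:
            warnings.warn(f"day {dpi}: missing group, skipped", stacklevel=2)
            continue
        sub = table[table["group"].isin([treatment, control])]
        rel = relative_expression(sub, calibrator=control)
        rel = rel[rel["group"] == treatment]
        if genes is not None:
            rel = rel[rel["gene"].isin(genes)]
        for _, r in rel.iterrows():
            rows.append(
                {
                    "dpi": dpi,
                    "gene": r["gene"],
                    "rq": r["rq"],
                    "rq_low": r["rq_low"],
                    "rq_high": r["rq_high"],
                }
            )
    return pd.DataFrame(rows, columns=["dpi", "gene", "rq", "rq_low", "rq_high"])
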