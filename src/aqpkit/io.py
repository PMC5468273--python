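"""Tidy delimited-text serialization shared by the CLI and the library.

Swelling cohorts travel as long-form tables (one row per frame), bug
cohorts as wide tables (one row per bug), Ct tables and plates as the
long-form frames the analysis functions consume directly.  All files
are plain CSV.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .osmotic import BathCondition
from .permeability import SwellingTimeCourse
from .phenotype import EXCRETION_HOURS, BugRecord

__all__ = [
    "swelling_to_frame",
    "frame_to_swelling",
    "bugs_to_frame",
    "frame_to_bugs",
]


def swelling_to_frame(cohort: Sequence[SwellingTimeCourse]) -> pd.DataFrame:
    """Long-form frame: oocyte_id, group, time_s, area_cm2 + bath columns."""
    rows = []
    for tc in cohort:
        for t, a in zip(tc.times, tc.areas):
            rows.append(
                {
                    "oocyte_id": tc.oocyte_id,
                    "group": tc.group,
                    "time_s": t,
                    "area_cm2": a,
                    "osm_out_mosm": tc.bath.osm_out,
                    "sol_out_mm": tc.bath.sol_out,
                    "solute": tc.bath.solute,
                    "hg_treated": tc.bath.hg_treated,
                    "reversal": tc.bath.reversal,
                }
            )
    return pd.DataFrame(rows)


def frame_to_swelling(df: pd.DataFrame) -> list[SwellingTimeCourse]:
    """Inverse of :func:`swelling_to_frame`."""
    cohort = []
    for oid, sub in df.groupby("oocyte_id", sort=False):
        sub = sub.sort_values("time_s")
        first = sub.iloc[0]
        bath = BathCondition(
            osm_out=float(first["osm_out_mosm"]),
            sol_out=float(first.get("sol_out_mm", 0.0)),
            solute=str(first.get("solute", "water-only")),
            hg_treated=bool(first.get("hg_treated", False)),
            reversal=bool(first.get("reversal", False)),
        )
        cohort.append(
            SwellingTimeCourse(
                oocyte_id=str(oid),
                group=str(first["group"]),
                times=sub["time_s"].to_numpy(),
                areas=sub["area_cm2"].to_numpy(),
                bath=bath,
            )
        )
    return cohort


def bugs_to_frame(records: Sequence[BugRecord]) -> pd.DataFrame:
    """Wide frame: one row per bug, weight columns w_1h ... w_24h."""
    rows = []
    for rec in records:
        row = {
            "bug_id": rec.bug_id,
            "group": rec.group,
            "w_prefeed_mg": rec.w_prefeed,
            "w_fed_mg": rec.w_fed,
        }
        for h in EXCRETION_HOURS:
            row[f"w_{h}h_mg"] = rec.weights.get(h)
        row["urea_absorbance"] = rec.urea_absorbance
        row["eggs_per_day"] = (
            ";".join(str(int(e)) for e in rec.eggs_per_day)
            if rec.eggs_per_day is not None
            else None
        )
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_bugs(df: pd.DataFrame) -> list[BugRecord]:
    """Inverse of :func:`bugs_to_frame`."""
    records = []
    for _, row in df.iterrows():
        weights = {}
        for h in EXCRETION_HOURS:
            col = f"w_{h}h_mg"
            if col in row and pd.notna(row[col]):
                weights[h] = float(row[col])
        eggs = None
        if "eggs_per_day" in row and pd.notna(row["eggs_per_day"]):
            eggs = [int(x) for x in str(row["eggs_per_day"]).split(";") if x != ""]
        urea = (
            float(row["urea_absorbance"])
            if "urea_absorbance" in row and pd.notna(row["urea_absorbance"])
            else None
        )
        records.append(
            BugRecord(
                bug_id=str(row["bug_id"]),
                group=str(row["group"]),
                w_prefeed=float(row["w_prefeed_mg"]),
                w_fed=float(row["w_fed_mg"]),
                weights=weights,
                urea_absorbance=urea,
                eggs_per_day=eggs,
            )
        )
    return records
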