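"""Non-ALPS marker derivation, grading scales, grouping and exclusions.

Covers: log-transformed WMH burden, TIV-normalized choroid plexus volume,
the two perivascular-space (PVS) visual rating scales (basal ganglia and
white matter), amyloid positivity from global AV45 SUVR, assignment to the
AD-continuum groups (CN-, CN+, MCI+, AD+), and the participant-level QC
exclusion rules (depression score, chin-up head position, PET-DTI
interval).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .alps import chin_up_excluded

__all__ = [
    "AMYLOID_SUVR_CUTOFF",
    "GROUPS",
    "log_wmh_burden",
    "normalize_choroid",
    "rate_pvs_bg",
    "rate_pvs_wm",
    "amyloid_positive",
    "assign_group",
    "apply_exclusions",
    "vascular_risk_score",
    "filter_cohort",
    "group_column",
]

#: Global AV45 SUVR positivity cutoff (strictly greater than).
AMYLOID_SUVR_CUTOFF = 1.11

GROUPS = ("CN-", "CN+", "MCI+", "AD+")

VASCULAR_FLAGS = ("hypertension", "diabetes", "hyperlipidemia", "smoking", "heart_disease")

_DIAGNOSES = {"CN", "MCI", "dementia"}


def log_wmh_burden(wmh_volume_ml: float, floor_ml: float | None = None) -> float:
    """WMH burden: base-10 log of the lesion volume in ml.

    Zero or negative volumes are an error unless a positive ``floor_ml``
    (e.g. 0.01) is supplied, in which case the volume is floored first.
    """
    v = float(wmh_volume_ml)
    if v <= 0:
        if floor_ml is None:
            raise ValueError(
                f"WMH volume must be positive (got {v}); pass floor_ml "
                "(e.g. 0.01) to floor empty segmentations"
            )
        if floor_ml <= 0:
            raise ValueError("floor_ml must be positive")
        v = max(v, floor_ml)
    elif floor_ml is not None:
        v = max(v, floor_ml)
    return math.log10(v)


def normalize_choroid(choroid_mm3: float, tiv_ml: float) -> float:
    """Choroid plexus volume (mm^3) over TIV (ml converted to mm^3), x 10^3.

    Numerically this is ``choroid_mm3 / tiv_ml`` and yields values near 1
    for typical volumes (e.g. 1600 mm^3 / 1480 ml -> 1.081).
    """
    if not tiv_ml > 0:
        raise ValueError(f"TIV must be positive, got {tiv_ml}")
    if choroid_mm3 < 0:
        raise ValueError(f"choroid volume must be non-negative, got {choroid_mm3}")
    return choroid_mm3 / (tiv_ml * 1e3) * 1e3


def rate_pvs_bg(count: int | None = None, countable: bool = True) -> int:
    """Basal-ganglia PVS visual grade (1-4).

    Grade 1: fewer than 5 PVS; grade 2: 5-10 (inclusive); grade 3: more
    than 10 but still countable; grade 4: uncountable.
    """
    if not countable:
        return 4
    if count is None:
        raise ValueError("count is required when countable")
    if count < 0:
        raise ValueError(f"PVS count must be non-negative, got {count}")
    if count < 5:
        return 1
    if count <= 10:
        return 2
    return 3


def rate_pvs_wm(total_count: int, max_per_section: int) -> int:
    """White-matter PVS visual grade (1-4).

    Grade 1: fewer than 10 PVS in total; grade 2: 10 or more in total but
    no more than 10 in any single section; grade 3: 11-20 in the section
    with the most PVS; grade 4: more than 20 in any single section.
    """
    if total_count < 0 or max_per_section < 0:
        raise ValueError("PVS counts must be non-negative")
    if max_per_section > total_count:
        raise ValueError(
            f"max_per_section ({max_per_section}) exceeds total_count ({total_count})"
        )
    if total_count < 10:
        return 1
    if max_per_section <= 10:
        return 2
    if max_per_section <= 20:
        return 3
    return 4


def amyloid_positive(suvr: float, cutoff: float = AMYLOID_SUVR_CUTOFF) -> bool:
    """Amyloid positivity: global AV45 SUVR strictly above the cutoff."""
    if not suvr > 0:
        raise ValueError(f"SUVR must be positive, got {suvr}")
    return suvr > cutoff


def assign_group(diagnosis: str, amyloid_pos: bool, fazekas: int) -> str:
    """AD-continuum group, or ``excluded:<reason>``.

    CN- requires cognitively normal, amyloid-negative and no severe
    small-vessel disease (WMH Fazekas grade below 2); CN+/MCI+/AD+ require
    amyloid positivity with the matching clinical diagnosis.
    """
    if diagnosis not in _DIAGNOSES:
        raise ValueError(f"unknown diagnosis label {diagnosis!r}; expected one of {sorted(_DIAGNOSES)}")
    if amyloid_pos:
        return {"CN": "CN+", "MCI": "MCI+", "dementia": "AD+"}[diagnosis]
    if diagnosis == "CN":
        if fazekas < 2:
            return "CN-"
        return "excluded:amyloid-negative CN with Fazekas >= 2"
    return f"excluded:amyloid-negative {diagnosis}"


def apply_exclusions(record: Mapping, lenient: bool = False) -> tuple[bool, list[str]]:
    """QC filter for one participant: (keep, reasons-for-dropping).

    Drops when the depression score (GDS) is 5 or more, the AC-PC angle
    exceeds 20 degrees (chin-up), or the PET-DTI interval is 12 months or
    more.  Missing QC fields raise unless ``lenient`` is set (then the
    missing rule is skipped).
    """
    reasons: list[str] = []
    checks = (
        ("gds", lambda v: v >= 5, "GDS >= 5"),
        ("acpc_angle_deg", chin_up_excluded, "chin-up (AC-PC angle > 20 deg)"),
        ("pet_dti_interval_months", lambda v: v >= 12, "PET-DTI interval >= 12 months"),
    )
    for fieldname, rule, reason in checks:
        value = record.get(fieldname) if hasattr(record, "get") else record[fieldname]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            if lenient:
                continue
            raise ValueError(f"missing QC field {fieldname!r} (use lenient=True to skip)")
        if rule(value):
            reasons.append(reason)
    return (len(reasons) == 0, reasons)


def vascular_risk_score(record: Mapping) -> int:
    """Count of recorded vascular risk factors (0-5)."""
    return int(sum(int(bool(record[f])) for f in VASCULAR_FLAGS))


def group_column(df: pd.DataFrame) -> pd.Series:
    """Vectorized group assignment for a cohort table."""
    return pd.Series(
        [
            assign_group(d, amyloid_positive(s), int(f))
            for d, s, f in zip(df["diagnosis"], df["suvr"], df["fazekas"])
        ],
        index=df.index,
        name="group",
    )


@dataclass
class FilterReport:
    kept: pd.DataFrame
    dropped: pd.DataFrame  # columns: id, reasons
    group_counts: dict[str, int]

    def write(self, out_dir, stem: str = "cohort_filter") -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report_path = out_dir / f"{stem}_report.tsv"
        self.dropped.to_csv(report_path, sep="\t", index=False)
        counts_path = out_dir / f"{stem}_groups.json"
        counts_path.write_text(json.dumps(self.group_counts, indent=2, sort_keys=True))
        return {"report": report_path, "group_counts": counts_path}


def filter_cohort(df: pd.DataFrame, lenient: bool = False) -> FilterReport:
    """Apply QC exclusions and group assignment to a cohort table.

    Returns the kept rows (with a ``group`` column), a drop report
    (id, accumulated reasons) and per-group counts.  Every input row lands
    in exactly one of CN-, CN+, MCI+, AD+ or the drop report.
    """
    keep_mask = []
    drop_rows = []
    for _, row in df.iterrows():
        keep, reasons = apply_exclusions(row, lenient=lenient)
        group = assign_group(row["diagnosis"], amyloid_positive(row["suvr"]), int(row["fazekas"]))
        if group.startswith("excluded:"):
            keep = False
            reasons = reasons + [group.split(":", 1)[1]]
        keep_mask.append(keep)
        if not keep:
            drop_rows.append({"id": row["id"], "reasons": "; ".join(reasons)})
    kept = df.loc[keep_mask].copy()
    kept["group"] = group_column(kept)
    dropped = pd.DataFrame(drop_rows, columns=["id", "reasons"])
    counts = kept["group"].value_counts().to_dict()
    counts["excluded"] = len(dropped)
    return FilterReport(kept=kept, dropped=dropped, group_counts=counts)
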