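"""Composite immunohistochemistry scoring and the three-marker IHC panel test.

Each antibody has its own high/low rule. AREG: high iff more than 50% of
tumour cells stain (intensity recorded but unused by the stated rule). CCNA1:
intensity 0-3 times a proportion score of 1 (<=10% stained cells) or 2 (>10%);
high iff the product is 3 or above. DDX20: intensity 0-3 times a proportion
score of 1/2/3 for <=33% / 34-66% / >66% stained cells; high iff the product is
3 or above. Category edges on the continuous percent scale are the half-open
completion (<=33, (33, 66], >66) of the printed integer labels.

The CCNA1 rule's descriptive gloss ("level 3 intensity or more than 10% of
positive cells") disagrees with its product rule for weak staining of many
cells; the product rule is authoritative here, with the disjunctive reading
available as ``ccna1_rule='disjunctive'`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .panel_classifier import (
    StratificationReport,
    risk_group_from_count,
    stratified_survival_analysis,
)
from .survival_core import logrank_test
from .errors import DegenerateDataError

MARKERS = ("AREG", "CCNA1", "DDX20")
HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class IHCRecord:
    """One marker staining observation for one patient."""

    patient_id: str
    marker: str
    intensity: int
    percent_positive: float
    compartment: Optional[str] = None  # informational: nuclear / cytoplasmic

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise InputError(f"unknown marker {self.marker!r}")
        if self.intensity not in (0, 1, 2, 3):
            raise InputError(f"intensity must be 0..3 (got {self.intensity!r})")
        if not 0.0 <= self.percent_positive <= 100.0:
            raise InputError(
                f"percent_positive must lie in [0, 100] (got {self.percent_positive!r})"
            )


@dataclass(frozen=True)
class IHCMarkerScore:
    marker: str
    proportion_score: Optional[int]   # None for AREG (rule uses percent directly)
    composite: Optional[int]          # intensity x proportion where applicable
    call: str                         # 'high' / 'low'


def ccna1_proportion_score(percent: float) -> int:
    return 1 if percent <= 10.0 else 2


def ddx20_proportion_score(percent: float) -> int:
    if percent <= 33.0:
        return 1
    if percent <= 66.0:
        return 2
    return 3


def score_marker(record: IHCRecord, ccna1_rule: str = "product") -> IHCMarkerScore:
    """Apply the marker's stated high/low rule to one record."""
    if record.marker == "AREG":
        call = HIGH if record.percent_positive > 50.0 else LOW
        return IHCMarkerScore("AREG", None, None, call)
    if record.marker == "CCNA1":
        prop = ccna1_proportion_score(record.percent_positive)
        composite = record.intensity * prop
        if ccna1_rule == "product":
            call = HIGH if composite >= 3 else LOW
        elif ccna1_rule == "disjunctive":
            call = HIGH if (record.intensity == 3 or record.percent_positive > 10.0) else LOW
        else:
            raise InputError(f"unknown ccna1_rule {ccna1_rule!r}")
        return IHCMarkerScore("CCNA1", prop, composite, call)
    # DDX20
    prop = ddx20_proportion_score(record.percent_positive)
    composite = record.intensity * prop
    return IHCMarkerScore("DDX20", prop, composite, HIGH if composite >= 3 else LOW)


def score_patient_panel(records: list, ccna1_rule: str = "product") -> pd.Series:
    """Count 'high' calls over the three markers for one patient.

    Returns a Series with activation_count (0..3) and risk_group ('good' for
    0-1 high markers, 'poor' for 2-3), mirroring the transcriptomic grouping.
    """
    seen = {r.marker: r for r in records}
    missing = [m for m in MARKERS if m not in seen]
    if missing:
        raise InputError(f"missing markers: {missing}")
    count = sum(
        1 for m in MARKERS if score_marker(seen[m], ccna1_rule=ccna1_rule).call == HIGH
    )
    return pd.Series(
        {"activation_count": count, "risk_group": risk_group_from_count(count)}
    )


def score_ihc_table(table: pd.DataFrame, ccna1_rule: str = "product") -> pd.DataFrame:
    """Score every (patient, marker) record and pivot to per-patient calls.

    Returns a DataFrame indexed by patient_id with one high/low column per
    marker plus activation_count and risk_group.
    """
    required = {"patient_id", "marker", "intensity", "percent_positive"}
    if not required.issubset(table.columns):
        raise InputError(f"IHC table needs columns {sorted(required)}")
    calls = {}
    for _, row in table.iterrows():
        rec = IHCRecord(
            patient_id=str(row["patient_id"]),
            marker=str(row["marker"]),
            intensity=int(row["intensity"]),
            percent_positive=float(row["percent_positive"]),
        )
        calls.setdefault(rec.patient_id, {})[rec.marker] = score_marker(
            rec, ccna1_rule=ccna1_rule
        ).call
    rows = []
    for pid, marker_calls in calls.items():
        missing = [m for m in MARKERS if m not in marker_calls]
        if missing:
            raise InputError(f"patient {pid!r} missing markers: {missing}")
        count = sum(1 for m in MARKERS if marker_calls[m] == HIGH)
        rows.append(
            {
                "patient_id": pid,
                **{m: marker_calls[m] for m in MARKERS},
                "activation_count": count,
                "risk_group": risk_group_from_count(count),
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def ihc_cohort_analysis(
    table: pd.DataFrame, clinical: pd.DataFrame, ccna1_rule: str = "product"
) -> dict:
    """Panel and per-marker survival analyses of a scored IHC cohort.

    The panel analysis delegates to the activation-count stratification; each
    marker additionally gets its own two-group (high vs low) log-rank, as in
    the per-antibody validation.
    """
    scored = score_ihc_table(table, ccna1_rule=ccna1_rule)
    unmatched = [p for p in scored.index if p not in clinical.index]
    if unmatched:
        raise InputError(f"IHC patients absent from clinical table: {unmatched[:5]}")
    scores = scored[["activation_count", "risk_group"]]
    panel_report = stratified_survival_analysis(scores, clinical.loc[scored.index])

    per_marker = {}
    clin = clinical.loc[scored.index]
    time = clin["os_months"].to_numpy(float)
    event = clin["event"].to_numpy(int)
    for marker in MARKERS:
        labels = scored[marker].to_numpy()
        try:
            per_marker[marker] = logrank_test(time, event, labels).to_dict()
        except DegenerateDataError as exc:
            per_marker[marker] = {"skipped": str(exc)}
    return {
        "scored": scored,
        "panel_report": panel_report,
        "per_marker_logrank": per_marker,
        "ccna1_rule": ccna1_rule,
    }
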