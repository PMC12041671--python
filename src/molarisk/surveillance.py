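"""UK hCG surveillance-protocol classifier and case-series descriptives.

Under the current UK protocol, patients whose hCG normalises in <56 days are
monitored until six months after uterine evacuation, while those normalising
in >=56 days are monitored for a further six months after the first normal
value.  Measured from the first normal hCG value, monitoring therefore ends at
``max(0, 183 - days_to_normalisation)`` days for EARLY patients and at 183
days for LATE patients (six months = 183 days, i.e. 365.25/2 rounded; both
conventions 180 and 183 classify the published cases identically).

The descriptive report reproduces the published case-series summary:
presentation, metastatic disease, chemotherapy regimen class, intervening
pregnancies and tumour genetics, all over a fixed denominator of the full case
count with unknowns reported as their own category.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .cohort import (
    METASTASIS_TAGS,
    Genetics,
    Outcome,
    PatientRecord,
    assign_group,
    days_to_months,
    Group,
)

__all__ = [
    "ProtocolSpec",
    "RegimenClass",
    "monitoring_end_day",
    "classify_post_protocol",
    "classify_regimen",
    "descriptive_report",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Current UK surveillance schedule parameters."""

    months_after_evac_if_early: int = 6
    months_after_normal_if_late: int = 6
    days_per_6_months: int = 183

    def __post_init__(self):
        if min(
            self.months_after_evac_if_early,
            self.months_after_normal_if_late,
            self.days_per_6_months,
        ) <= 0:
            raise ValueError("protocol durations must be positive")


class RegimenClass(str, enum.Enum):
    SINGLE_AGENT = "SINGLE_AGENT"
    MULTI_AGENT = "MULTI_AGENT"
    SURGERY_ONLY = "SURGERY_ONLY"


def monitoring_end_day(record: PatientRecord, spec: ProtocolSpec = ProtocolSpec()) -> int:
    """Day (from first normal hCG) on which protocol monitoring ends.

    EARLY: six months after evacuation, so 183 minus the days already spent
    reaching normalisation, floored at zero.  LATE: six months after the first
    normal value.
    """
    if assign_group(record) is Group.EARLY:
        return max(0, spec.days_per_6_months - record.days_evac_to_normal)
    return spec.days_per_6_months


def classify_post_protocol(record: PatientRecord, spec: ProtocolSpec = ProtocolSpec()) -> bool:
    """True iff the GTN diagnosis fell after monitoring had ended."""
    if record.outcome is not Outcome.GTN:
        raise ValueError(f"patient {record.patient_id} is censored, not a GTN case")
    return record.days_normal_to_end > monitoring_end_day(record, spec)


# Regimen token lexicon, frozen from the published abbreviations.
_MONO_TOKENS = {"MTX", "METHOTREXATE", "DACT", "DACTINOMYCIN"}
_MULTI_TOKENS = {
    "EMACO",
    "EMAEP",
    "EP",
    "HUMMP",
    "CHAMOCA",
    "VAC",
    "IVA",
    "TETP",
    "PEMBRO",
    "PEMBROLIZUMAB",
}
_DECLINED_RE = re.compile(r"\b(declined|no additional)\b.*\bchemotherapy\b", re.IGNORECASE)


def classify_regimen(treatment_text: str) -> RegimenClass:
    """Classify a free-text treatment description.

    SURGERY_ONLY when no chemotherapy token appears; SINGLE_AGENT when every
    chemotherapy token is a monotherapy (methotrexate or dactinomycin);
    MULTI_AGENT otherwise.  Matching is case-insensitive on whole tokens.  A
    mention of chemotherapy with no recognised agent token — unless explicitly
    declined or withheld — raises a warning and is classed MULTI_AGENT as the
    conservative choice.
    """
    if not treatment_text.strip():
        raise ValueError("empty treatment text")
    tokens = {t.upper() for t in re.split(r"[^A-Za-z]+", treatment_text) if t}
    if tokens & _MULTI_TOKENS:
        return RegimenClass.MULTI_AGENT
    if tokens & _MONO_TOKENS:
        return RegimenClass.SINGLE_AGENT
    if ("CHEMOTHERAPY" in tokens or "CHEMO" in tokens) and not _DECLINED_RE.search(
        treatment_text
    ):
        warnings.warn(
            f"unrecognised chemotherapy description {treatment_text!r}; "
            "classifying as MULTI_AGENT",
            stacklevel=2,
        )
        return RegimenClass.MULTI_AGENT
    return RegimenClass.SURGERY_ONLY


def _count_pct(count: int, denom: int) -> Dict[str, float]:
    return {"count": count, "pct": round(100.0 * count / denom, 1) if denom else 0.0}


def _day_column_stats(days: Sequence[int]) -> Dict[str, float]:
    if not days:
        return {}
    months = [days_to_months(d) for d in days]
    raws = np.array([m.raw for m in months])
    order = np.argsort(raws)
    return {
        "min_days": int(min(days)),
        "max_days": int(max(days)),
        "min_months": months[order[0]].display,
        "max_months": months[order[-1]].display,
        "median_months": float(np.median(raws)),
    }


def descriptive_report(cases: Sequence[PatientRecord], spec: ProtocolSpec = ProtocolSpec()) -> dict:
    """Structured counts/percentages describing a set of GTN cases.

    All percentages use the full case count as denominator (one decimal);
    unknown values are reported as their own category rather than dropped, so
    categories sum to the denominator.
    """
    n = len(cases)
    tag_counts: Dict[str, int] = {}
    for rec in cases:
        for tag in rec.presentation_tags:
            tag_counts[tag] = tag_counts.get(tag, 0) + 1

    regimens = [classify_regimen(r.treatment_text) for r in cases if r.treatment_text]
    pregnancies = {
        "zero": sum(1 for r in cases if r.n_interval_pregnancies == 0),
        "one_or_more": sum(
            1 for r in cases if r.n_interval_pregnancies is not None and r.n_interval_pregnancies >= 1
        ),
        "unknown": sum(1 for r in cases if r.n_interval_pregnancies is None),
    }
    gtn_cases = [r for r in cases if r.outcome is Outcome.GTN]
    post_protocol = sum(1 for r in gtn_cases if classify_post_protocol(r, spec))

    report = {
        "n_cases": n,
        "presentation": {
            tag: _count_pct(tag_counts.get(tag, 0), n) for tag in sorted(tag_counts)
        },
        "any_metastasis": _count_pct(
            sum(1 for r in cases if r.presentation_tags & METASTASIS_TAGS), n
        ),
        "metastasis_sites": {
            site: _count_pct(tag_counts.get(site, 0), n)
            for site in ("brain_met", "lung_met", "vaginal_met", "kidney_met")
        },
        "regimen": {
            cls.value: _count_pct(sum(1 for r in regimens if r is cls), n)
            for cls in RegimenClass
        },
        "interval_pregnancies": {k: _count_pct(v, n) for k, v in pregnancies.items()},
        "genetics": {
            g.value: _count_pct(sum(1 for r in cases if r.genetics is g), n)
            for g in Genetics
        },
        "post_protocol_diagnoses": _count_pct(post_protocol, len(gtn_cases) or 1)
        if gtn_cases
        else _count_pct(0, 1),
        "days_evac_to_normal": _day_column_stats([r.days_evac_to_normal for r in cases]),
        "days_normal_to_end": _day_column_stats([r.days_normal_to_end for r in cases]),
    }
    return report
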