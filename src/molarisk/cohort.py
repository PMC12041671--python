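"""Patient-level cohort data model, CSV I/O, exclusions and grouping.

A cohort record describes one patient's timeline after uterine evacuation of a
complete hydatidiform mole: the number of days until serum hCG first returned
to normal, and — measured from that first normal value — either the day
treatment for gestational trophoblastic neoplasia (GTN) started or the day
follow-up ended without the disease.  Patients are stratified by how quickly
hCG normalised: in fewer than ``cutoff_days`` days (EARLY) or in at least that
many (LATE); 56 days is the clinically established cut-off.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence, TextIO, Union

__all__ = [
    "Outcome",
    "Genetics",
    "Group",
    "PatientRecord",
    "Months",
    "PRESENTATION_TAGS",
    "EXCLUSION_FLAGS",
    "DEFAULT_CUTOFF_DAYS",
    "CohortSchemaError",
    "CohortValidationError",
    "parse_cohort",
    "write_cohort",
    "apply_exclusions",
    "assign_group",
    "days_to_months",
    "load_table1_fixture",
]

DEFAULT_CUTOFF_DAYS = 56

PRESENTATION_TAGS = frozenset(
    {
        "raised_hcg",
        "vaginal_bleeding",
        "abdominal_pain",
        "brain_met",
        "lung_met",
        "vaginal_met",
        "kidney_met",
        "other",
        "unknown",
    }
)

EXCLUSION_FLAGS = frozenset(
    {
        "treated_before_normalisation",
        "twin_with_cotwin",
        "recurrent_mole",
        "incomplete_followup",
    }
)

METASTASIS_TAGS = frozenset({"brain_met", "lung_met", "vaginal_met", "kidney_met"})


class Outcome(str, enum.Enum):
    """End state of post-normalisation follow-up."""

    GTN = "GTN"
    CENSORED = "CENSORED"


class Genetics(str, enum.Enum):
    """Microsatellite-genotyping result for the GTN, where available."""

    MATCHED_ORIGINAL = "MATCHED_ORIGINAL"
    INVASIVE_CHM_RELAPSE_ONLY = "INVASIVE_CHM_RELAPSE_ONLY"
    UNKNOWN = "UNKNOWN"


class Group(str, enum.Enum):
    """hCG-normalisation speed stratum."""

    EARLY = "EARLY"  # normalised in < cutoff days
    LATE = "LATE"  # normalised in >= cutoff days


class CohortSchemaError(ValueError):
    """A required column is missing from a cohort file."""


class CohortValidationError(ValueError):
    """A row or field violates the data model; carries the offending row."""

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's post-evacuation timeline plus descriptive fields.

    Day counts are whole, zero-based days.  ``days_normal_to_end`` is the day
    GTN treatment started when ``outcome`` is GTN, otherwise the last day of
    follow-up.  ``n_interval_pregnancies``, ``figo_score`` use ``None`` for
    unknown.
    """

    patient_id: str
    days_evac_to_normal: int
    outcome: Outcome
    days_normal_to_end: int
    presentation_tags: frozenset = frozenset()
    treatment_text: str = ""
    n_interval_pregnancies: Optional[int] = None
    genetics: Genetics = Genetics.UNKNOWN
    figo_score: Optional[int] = None
    exclusion_flags: frozenset = frozenset()

    def __post_init__(self):
        for name in ("days_evac_to_normal", "days_normal_to_end"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise CohortValidationError(f"{name} must be a non-negative integer, got {v!r}")
        bad = self.presentation_tags - PRESENTATION_TAGS
        if bad:
            raise CohortValidationError(f"unknown presentation tags {sorted(bad)}")
        bad = self.exclusion_flags - EXCLUSION_FLAGS
        if bad:
            raise CohortValidationError(f"unknown exclusion flags {sorted(bad)}")
        if self.n_interval_pregnancies is not None and self.n_interval_pregnancies < 0:
            raise CohortValidationError("n_interval_pregnancies must be >= 0 or None")


_COLUMNS = [
    "patient_id",
    "days_evac_to_normal",
    "outcome",
    "days_normal_to_end",
    "presentation_tags",
    "treatment_text",
    "n_interval_pregnancies",
    "genetics",
    "figo_score",
    "exclusion_flags",
]
_REQUIRED = _COLUMNS[:4]


def _parse_int(value: str, name: str, row: int) -> int:
    try:
        out = int(value)
    except (TypeError, ValueError):
        raise CohortValidationError(f"{name} must be an integer, got {value!r}", row=row)
    if out < 0:
        raise CohortValidationError(f"{name} must be non-negative, got {out}", row=row)
    return out


def _parse_opt_int(value: str, name: str, row: int) -> Optional[int]:
    value = (value or "").strip()
    if value in ("", "NA", "UNKNOWN"):
        return None
    return _parse_int(value, name, row)


def parse_cohort(source: Union[str, Path, TextIO]) -> list:
    """Read a cohort CSV into a list of :class:`PatientRecord`.

    The file must have a header row with at least the columns
    ``patient_id, days_evac_to_normal, outcome, days_normal_to_end``.
    Optional columns missing or blank map to empty/unknown values.
    Row numbers (1-based, excluding the header) are preserved in errors.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return parse_cohort(fh)
    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise CohortSchemaError("empty file: no header row")
    for col in _REQUIRED:
        if col not in reader.fieldnames:
            raise CohortSchemaError(f"missing required column {col!r}")
    records = []
    for i, row in enumerate(reader, start=1):
        try:
            outcome = Outcome(row["outcome"].strip())
        except ValueError:
            raise CohortValidationError(f"outcome must be GTN or CENSORED, got {row['outcome']!r}", row=i)
        tags = frozenset(t for t in (row.get("presentation_tags") or "").split(";") if t)
        flags = frozenset(t for t in (row.get("exclusion_flags") or "").split(";") if t)
        gen_raw = (row.get("genetics") or "").strip()
        genetics = Genetics(gen_raw) if gen_raw else Genetics.UNKNOWN
        try:
            rec = PatientRecord(
                patient_id=row["patient_id"],
                days_evac_to_normal=_parse_int(row["days_evac_to_normal"], "days_evac_to_normal", i),
                outcome=outcome,
                days_normal_to_end=_parse_int(row["days_normal_to_end"], "days_normal_to_end", i),
                presentation_tags=tags,
                treatment_text=row.get("treatment_text") or "",
                n_interval_pregnancies=_parse_opt_int(
                    row.get("n_interval_pregnancies", ""), "n_interval_pregnancies", i
                ),
                genetics=genetics,
                figo_score=_parse_opt_int(row.get("figo_score", ""), "figo_score", i),
                exclusion_flags=flags,
            )
        except CohortValidationError as exc:
            if exc.row is None:
                raise CohortValidationError(str(exc), row=i) from exc
            raise
        records.append(rec)
    return records


def write_cohort(records: Iterable[PatientRecord], dest: Union[str, Path, TextIO]) -> None:
    """Write records to the cohort CSV dialect (inverse of :func:`parse_cohort`)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            write_cohort(records, fh)
        return
    writer = csv.writer(dest, lineterminator="\n")
    writer.writerow(_COLUMNS)
    for r in records:
        writer.writerow(
            [
                r.patient_id,
                r.days_evac_to_normal,
                r.outcome.value,
                r.days_normal_to_end,
                ";".join(sorted(r.presentation_tags)),
                r.treatment_text,
                "NA" if r.n_interval_pregnancies is None else r.n_interval_pregnancies,
                r.genetics.value,
                "NA" if r.figo_score is None else r.figo_score,
                ";".join(sorted(r.exclusion_flags)),
            ]
        )


def apply_exclusions(records: Sequence[PatientRecord]):
    """Drop flagged records; return (analysis cohort, per-flag count log).

    A record with *any* exclusion flag never enters an analysis cohort.  The
    log has one count per known flag (a record with two flags increments both)
    plus ``excluded`` and ``retained`` totals.
    """
    log = {flag: 0 for flag in sorted(EXCLUSION_FLAGS)}
    cohort = []
    excluded = 0
    for r in records:
        if r.exclusion_flags:
            excluded += 1
            for flag in r.exclusion_flags:
                log[flag] += 1
        else:
            cohort.append(r)
    log["excluded"] = excluded
    log["retained"] = len(cohort)
    return cohort, log


def assign_group(record: PatientRecord, cutoff_days: int = DEFAULT_CUTOFF_DAYS) -> Group:
    """EARLY iff hCG normalised in strictly fewer than ``cutoff_days`` days."""
    return Group.EARLY if record.days_evac_to_normal < cutoff_days else Group.LATE


class Months(NamedTuple):
    """Day count expressed in 30-day months: exact value and display rounding."""

    raw: float
    display: float


def days_to_months(days: int) -> Months:
    """Convert whole days to 30-day months.

    The exact quotient ``days/30`` is returned alongside the presentation
    value: rounded half-up to two decimals below one month and to one decimal
    at or above (so 4 days prints as 0.13 and 2697 days as 89.9).
    """
    if days < 0:
        raise CohortValidationError(f"days must be non-negative, got {days}")
    exact = Decimal(days) / Decimal(30)
    quantum = Decimal("0.01") if exact < 1 else Decimal("0.1")
    return Months(days / 30.0, float(exact.quantize(quantum, rounding=ROUND_HALF_UP)))


def load_table1_fixture() -> list:
    """The 31 GTN cases diagnosed after hCG normalisation, as published.

    Patients 1-3 normalised in <56 days (EARLY), patients 4-31 in >=56 days
    (LATE).  Presentation free text is pre-tokenised into tags so descriptive
    counts are deterministic.
    """
    from .table1 import TABLE1_RECORDS

    return list(TABLE1_RECORDS)
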