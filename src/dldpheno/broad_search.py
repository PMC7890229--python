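"""Broad-search sample selection (phase A of the pipeline).

Selects pediatric records carrying at least one LD-symptom code while
excluding records that carry hearing-loss, intellectual-disability or
chromosomal-abnormality codes at any age, and records whose first LD
code appears at or after the pediatric age bound. Exclusion codes are
disqualifying regardless of when they occur relative to the LD code —
they are record-level criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import ContractError, DataValidationError
from .model import CodeCriterion, PatientRecord, first_ld_age

__all__ = [
    "LD_INCLUSION_CODES",
    "PEDIATRIC_AGE_DAYS",
    "RejectionReason",
    "BroadSearchCriteria",
    "BroadSearchResult",
    "default_criteria",
    "passes_inclusion",
    "has_exclusion",
    "pediatric_onset",
    "apply_broad_search",
]

logger = logging.getLogger(__name__)

#: The six LD-symptom codes clinicians commonly use for DLD: ICD-9
#: 315.31 / 315.32 / 315.39 and ICD-10 F80.1 / F80.2 / F80.89.
#: F80.9 is deliberately NOT among them.
LD_INCLUSION_CODES = frozenset(
    {"31531", "31532", "31539", "F801", "F802", "F8089"}
)

HEARING_LOSS_PREFIXES = frozenset({"389", "H90", "H91"})
INTELLECTUAL_DISABILITY_PREFIXES = frozenset(
    {"317", "318", "319", "F70", "F71", "F72", "F73", "F78", "F79"}
)
#: Chromosomal abnormality groups: ICD-9 758 and ICD-10 Q90–Q99,
#: the range expanded into explicit prefixes at configuration time.
CHROMOSOMAL_PREFIXES = frozenset({"758"} | {f"Q9{i}" for i in range(10)})

#: "Before the age of 18 years" as strictly less than 18 x 365.25 days,
#: rounded to 6,574.
PEDIATRIC_AGE_DAYS = 6574


class RejectionReason(str, Enum):
    NO_LD_CODE = "no_ld_code"
    EXCLUSION_CODE = "exclusion_code"
    ADULT_ONSET = "adult_onset"


@dataclass(frozen=True)
class BroadSearchCriteria:
    """Inclusion/exclusion code sets plus the pediatric age threshold."""

    ld_inclusion: CodeCriterion = field(
        default_factory=lambda: CodeCriterion(exact_codes=LD_INCLUSION_CODES)
    )
    hearing_loss: CodeCriterion = field(
        default_factory=lambda: CodeCriterion(prefix_codes=HEARING_LOSS_PREFIXES)
    )
    intellectual_disability: CodeCriterion = field(
        default_factory=lambda: CodeCriterion(
            prefix_codes=INTELLECTUAL_DISABILITY_PREFIXES
        )
    )
    chromosomal: CodeCriterion = field(
        default_factory=lambda: CodeCriterion(prefix_codes=CHROMOSOMAL_PREFIXES)
    )
    pediatric_age_days: int = PEDIATRIC_AGE_DAYS

    def __post_init__(self):
        if self.pediatric_age_days <= 0:
            raise DataValidationError("pediatric_age_days must be > 0")

    @property
    def exclusion_criteria(self) -> Tuple[CodeCriterion, ...]:
        return (self.hearing_loss, self.intellectual_disability, self.chromosomal)


def default_criteria() -> BroadSearchCriteria:
    """The standard criteria set (six LD codes, three exclusion groups)."""
    return BroadSearchCriteria()


@dataclass
class BroadSearchResult:
    """Sampled records plus an audit trail of per-record rejection reasons."""

    sample: List[PatientRecord]
    rejections: Dict[str, RejectionReason]

    @property
    def sample_ids(self) -> List[str]:
        return [r.record_id for r in self.sample]


def passes_inclusion(record: PatientRecord, criteria: BroadSearchCriteria) -> bool:
    """True iff at least one event matches the LD inclusion criterion."""
    return any(criteria.ld_inclusion.matches(e.code) for e in record.events)


def has_exclusion(record: PatientRecord, criteria: BroadSearchCriteria) -> bool:
    """True iff any event, at any age, matches an exclusion group."""
    return any(
        crit.matches(e.code)
        for e in record.events
        for crit in criteria.exclusion_criteria
    )


def pediatric_onset(record: PatientRecord, criteria: BroadSearchCriteria) -> bool:
    """True iff the first LD code occurs strictly before the age bound.

    Precondition: the record passes inclusion (has at least one LD code).
    """
    onset = first_ld_age(record, criteria.ld_inclusion)
    if onset is None:
        raise ContractError(
            f"pediatric_onset requires an LD code; record {record.record_id!r} has none"
        )
    return onset < criteria.pediatric_age_days


def apply_broad_search(
    cohort: Sequence[PatientRecord],
    criteria: Optional[BroadSearchCriteria] = None,
) -> BroadSearchResult:
    """Partition a cohort into the study sample and rejected records.

    Rejection reasons use the fixed precedence no_ld_code >
    exclusion_code > adult_onset so the audit trail is deterministic.
    Input order is preserved in the sample.
    """
    if criteria is None:
        criteria = default_criteria()
    cohort = list(cohort)
    if not cohort:
        raise DataValidationError("broad search requires a non-empty cohort")
    seen = set()
    sample: List[PatientRecord] = []
    rejections: Dict[str, RejectionReason] = {}
    for record in cohort:
        if record.record_id in seen:
            raise DataValidationError(f"duplicate record_id {record.record_id!r}")
        seen.add(record.record_id)
        if not passes_inclusion(record, criteria):
            rejections[record.record_id] = RejectionReason.NO_LD_CODE
        elif has_exclusion(record, criteria):
            rejections[record.record_id] = RejectionReason.EXCLUSION_CODE
        elif not pediatric_onset(record, criteria):
            rejections[record.record_id] = RejectionReason.ADULT_ONSET
        else:
            sample.append(record)
    logger.info(
        "broad search: %d in, %d sampled, %d rejected",
        len(cohort), len(sample), len(rejections),
    )
    return BroadSearchResult(sample=sample, rejections=rejections)
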