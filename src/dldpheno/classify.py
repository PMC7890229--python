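"""Hierarchical classification of records against trained category filters.

Priority runs 4 > 3 > 2 > 1. Category 4 (acquired LD) is date-aware:
it fires only when a filter-4 code occurs on-or-before the record's
first LD code — trauma coded after language disorder onset does not
explain it, so such records fall through to the lower categories.
Categories 3, 2 and 1 are date-free. A record matching no filter is
category 0 (unclassified) and never counted as a DLD inclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .errors import ContractError, DataValidationError
from .model import PatientRecord, first_ld_age
from .training import CategoryFilters

__all__ = [
    "ClassificationResult",
    "classify_record",
    "classify_cohort",
    "brute_force_classify",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassificationResult:
    """Category assignment for one record.

    ``trigger_codes`` are all the winning category's filter codes found
    in the record (for category 4, only the date-eligible ones);
    ``included`` is the DLD inclusion status (categories 1 and 2).
    """

    record_id: str
    category: int
    trigger_codes: Tuple[str, ...]
    first_ld_age: int

    @property
    def included(self) -> bool:
        return self.category in (1, 2)


def _cat4_trigger_codes(
    record: PatientRecord, filters: CategoryFilters, onset: int
) -> List[str]:
    if filters.cat4_inclusive:
        eligible = (e for e in record.events if e.age_days <= onset)
    else:
        eligible = (e for e in record.events if e.age_days < onset)
    return sorted({e.code for e in eligible if e.code in filters.filter_4})


def classify_record(
    record: PatientRecord, filters: CategoryFilters
) -> ClassificationResult:
    """Assign the record a category using the hierarchical priority rule."""
    onset = first_ld_age(record, filters.ld_criterion)
    if onset is None:
        raise ContractError(
            f"record {record.record_id!r} has no LD code; classification "
            "applies only to broad-search records"
        )
    triggers = _cat4_trigger_codes(record, filters, onset)
    if triggers:
        category = 4
    else:
        codes = record.codes
        for k, filt in ((3, filters.filter_3), (2, filters.filter_2), (1, filters.filter_1)):
            hit = sorted(codes & filt)
            if hit:
                category, triggers = k, hit
                break
        else:
            category, triggers = 0, []
            logger.warning(
                "record %s matches no category filter; left unclassified",
                record.record_id,
            )
    return ClassificationResult(
        record_id=record.record_id,
        category=category,
        trigger_codes=tuple(triggers),
        first_ld_age=onset,
    )


def classify_cohort(
    records: Sequence[PatientRecord], filters: CategoryFilters
) -> List[ClassificationResult]:
    """Classify every record, preserving input order."""
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise DataValidationError("duplicate record_id in cohort to classify")
    results = [classify_record(r, filters) for r in records]
    if results:
        counts = {k: sum(1 for r in results if r.category == k) for k in range(5)}
        logger.info("classified %d records: per-category counts %s", len(results), counts)
    return results


def brute_force_classify(record: PatientRecord, filters: CategoryFilters) -> int:
    """Independent re-derivation of the category by exhaustive enumeration.

    Enumerates every (event, filter) pair with no early exit and
    re-applies the priority decision from the resulting match table;
    used as a test oracle for :func:`classify_record`.
    """
    onset = first_ld_age(record, filters.ld_criterion)
    if onset is None:
        raise ContractError(f"record {record.record_id!r} has no LD code")
    matched = {1: False, 2: False, 3: False, 4: False}
    for event in record.events:
        for k in (1, 2, 3, 4):
            if event.code in filters.filter_for(k):
                if k == 4:
                    before = (
                        event.age_days <= onset
                        if filters.cat4_inclusive
                        else event.age_days < onset
                    )
                    if before:
                        matched[4] = True
                else:
                    matched[k] = True
    for k in (4, 3, 2, 1):
        if matched[k]:
            return k
    return 0
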