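"""Learning the four category code filters by systematic subtraction.

From a manually labeled sample, the raw code list of each category is
the union of all ICD codes seen in records of that category — except
Category 4 (acquired LD), whose raw list is date-restricted to codes
occurring on or before the record's first LD code, because trauma must
precede the language disorder to define the category. The filters are
then made pairwise disjoint by subtracting lower-priority lists:

    filter_1 = R1
    filter_2 = R2 - R1
    filter_3 = R3 - R2 - R1
    filter_4 = R4 - R3 - R2 - R1

LD codes themselves stay in the raw lists; whenever any Category-1
record exists they land in filter_1 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

from .broad_search import LD_INCLUSION_CODES
from .errors import DataValidationError
from .model import CategoryLabel, CodeCriterion, PatientRecord, first_ld_age

__all__ = [
    "LabeledCohort",
    "CategoryFilters",
    "extract_raw_code_lists",
    "systematic_subtraction",
    "train_filters",
]

logger = logging.getLogger(__name__)

CATEGORIES = (1, 2, 3, 4)


def _as_label(value) -> CategoryLabel:
    if isinstance(value, CategoryLabel):
        return value
    return CategoryLabel(int(value))


@dataclass
class LabeledCohort:
    """Records paired one-to-one with manual category labels."""

    records: Sequence[PatientRecord]
    labels: Mapping[str, CategoryLabel]

    def __post_init__(self):
        self.records = list(self.records)
        self.labels = {rid: _as_label(lab) for rid, lab in dict(self.labels).items()}
        record_ids = [r.record_id for r in self.records]
        if len(set(record_ids)) != len(record_ids):
            raise DataValidationError("duplicate record_id in labeled cohort")
        missing = set(record_ids) - set(self.labels)
        extra = set(self.labels) - set(record_ids)
        if missing:
            raise DataValidationError(f"records without labels: {sorted(missing)[:5]}")
        if extra:
            raise DataValidationError(f"labels without records: {sorted(extra)[:5]}")

    def by_category(self) -> Dict[int, list]:
        groups: Dict[int, list] = {k: [] for k in CATEGORIES}
        for record in self.records:
            groups[self.labels[record.record_id].category].append(record)
        return groups


@dataclass(frozen=True)
class CategoryFilters:
    """The trained algorithm state: four disjoint code sets + LD criterion.

    ``cat4_inclusive`` records the date-rule convention the filters were
    trained under (trauma on-or-before vs strictly-before the first LD
    code) so classification applies the same rule.
    """

    filter_1: frozenset
    filter_2: frozenset
    filter_3: frozenset
    filter_4: frozenset
    ld_criterion: CodeCriterion
    cat4_inclusive: bool = True
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        sets = [self.filter_1, self.filter_2, self.filter_3, self.filter_4]
        for i in range(4):
            for j in range(i + 1, 4):
                if sets[i] & sets[j]:
                    raise DataValidationError(
                        f"category filters {i + 1} and {j + 1} are not disjoint"
                    )

    def filter_for(self, category: int) -> frozenset:
        return (self.filter_1, self.filter_2, self.filter_3, self.filter_4)[
            category - 1
        ]


def extract_raw_code_lists(
    cohort: LabeledCohort,
    ld_criterion: Optional[CodeCriterion] = None,
    cat4_inclusive: bool = True,
) -> Tuple[frozenset, frozenset, frozenset, frozenset]:
    """Per-category raw code unions (R1..R4), R4 date-restricted.

    R4 keeps, for each Category-4 record, only codes from events dated
    on-or-before (``cat4_inclusive``) or strictly before the record's
    first LD code.
    """
    if ld_criterion is None:
        ld_criterion = CodeCriterion(exact_codes=LD_INCLUSION_CODES)
    if not cohort.records:
        raise DataValidationError("cannot extract code lists from an empty cohort")
    groups = cohort.by_category()
    for k in CATEGORIES:
        if not groups[k]:
            logger.warning("no records labeled category %d; raw list empty", k)

    raw: Dict[int, set] = {k: set() for k in CATEGORIES}
    for k in (1, 2, 3):
        for record in groups[k]:
            raw[k] |= record.codes
    for record in groups[4]:
        onset = first_ld_age(record, ld_criterion)
        if onset is None:
            raise DataValidationError(
                f"category-4 record {record.record_id!r} has no LD code"
            )
        for event in record.events:
            if event.age_days <= onset if cat4_inclusive else event.age_days < onset:
                raw[4].add(event.code)
    return tuple(frozenset(raw[k]) for k in CATEGORIES)


def systematic_subtraction(
    r1: frozenset, r2: frozenset, r3: frozenset, r4: frozenset,
    ld_criterion: Optional[CodeCriterion] = None,
    cat4_inclusive: bool = True,
    provenance: Optional[dict] = None,
) -> CategoryFilters:
    """Make the raw lists pairwise disjoint by hierarchical subtraction."""
    if ld_criterion is None:
        ld_criterion = CodeCriterion(exact_codes=LD_INCLUSION_CODES)
    r1, r2, r3, r4 = map(frozenset, (r1, r2, r3, r4))
    return CategoryFilters(
        filter_1=r1,
        filter_2=r2 - r1,
        filter_3=r3 - r2 - r1,
        filter_4=r4 - r3 - r2 - r1,
        ld_criterion=ld_criterion,
        cat4_inclusive=cat4_inclusive,
        provenance=provenance or {},
    )


def train_filters(
    cohort: LabeledCohort,
    ld_criterion: Optional[CodeCriterion] = None,
    cat4_inclusive: bool = True,
) -> CategoryFilters:
    """Extract raw per-category code lists and subtract them into filters.

    Every record must pass broad-search inclusion (carry at least one
    LD code); provenance records per-category record counts and raw vs
    filtered code-list sizes.
    """
    if ld_criterion is None:
        ld_criterion = CodeCriterion(exact_codes=LD_INCLUSION_CODES)
    for record in cohort.records:
        if first_ld_age(record, ld_criterion) is None:
            raise DataValidationError(
                f"training record {record.record_id!r} has no LD code; "
                "it cannot have passed the broad search"
            )
    raw = extract_raw_code_lists(cohort, ld_criterion, cat4_inclusive)
    groups = cohort.by_category()
    filters = systematic_subtraction(
        *raw, ld_criterion=ld_criterion, cat4_inclusive=cat4_inclusive
    )
    provenance = {
        "n_records": len(cohort.records),
        "records_per_category": {str(k): len(groups[k]) for k in CATEGORIES},
        "raw_code_counts": {str(k): len(raw[k - 1]) for k in CATEGORIES},
        "filter_code_counts": {
            str(k): len(filters.filter_for(k)) for k in CATEGORIES
        },
    }
    logger.info(
        "trained filters on %d records: sizes %s",
        len(cohort.records), provenance["filter_code_counts"],
    )
    return CategoryFilters(
        filter_1=filters.filter_1,
        filter_2=filters.filter_2,
        filter_3=filters.filter_3,
        filter_4=filters.filter_4,
        ld_criterion=ld_criterion,
        cat4_inclusive=cat4_inclusive,
        provenance=provenance,
    )
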