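"""Seeded synthetic EHR cohort generator.

Emulates the statistical structure the phenotyping algorithm assumes:
every qualifying record carries at least one of the six real LD-symptom
codes with pediatric onset; each rubric category has a characteristic
code pool on top of a shared common-condition pool; Category-4 records
carry trauma codes dated on-or-before the first LD code; Category-2
records may carry trauma-shaped codes strictly after it (the situation
the rubric assigns to Category 2 rather than 4); a configurable
``leakage`` probability plants codes from other categories' pools,
degrading held-out (but never training-set) accuracy. Non-qualifying
records each violate exactly one broad-search criterion.

Synthetic category codes live in a reserved-looking ICD-10-shaped
namespace (``X99``-prefixed) so they can never collide with the real LD
inclusion codes or real exclusion prefixes, which are genuine so the
default broad-search criteria are exercised.

Ground-truth metadata (true category, qualifying flag and reason,
leaked codes, trauma timing) is emitted alongside the cohort so every
downstream property test has an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from .broad_search import PEDIATRIC_AGE_DAYS
from .errors import DataValidationError
from .model import CodeEvent, CodeSystem, PatientRecord

__all__ = ["CodePools", "SimulationConfig", "generate_record", "generate_cohort"]

LD_CODES = ("31531", "31532", "31539", "F801", "F802", "F8089")

#: Real exclusion-criteria codes (hearing loss, intellectual disability,
#: chromosomal) used only by non-qualifying records.
EXCLUSION_CODES = (
    "3890", "38910", "H903", "H9190",  # hearing loss
    "317", "3180", "F70", "F719",      # intellectual disability
    "75800", "Q935",                   # chromosomal
)


def _system_for(code: str) -> CodeSystem:
    return CodeSystem.ICD9 if code[0].isdigit() else CodeSystem.ICD10


def _pool(prefix: str, size: int) -> Tuple[str, ...]:
    return tuple(f"X99{prefix}{i:02d}" for i in range(size))


@dataclass(frozen=True)
class CodePools:
    """Disjoint code namespaces the generator draws from.

    ``late_trauma_pool`` holds trauma-shaped codes used only for
    post-LD trauma events on Category-2 records; keeping it disjoint
    from ``cat4_trauma_pool`` mirrors the rubric's reading that trauma
    after language-disorder onset characterizes Category 2, and keeps
    the category structure recoverable from a leakage-free cohort.
    """

    ld_codes: Tuple[str, ...] = LD_CODES
    common_pool: Tuple[str, ...] = _pool("A", 40)
    cat2_pool: Tuple[str, ...] = _pool("B", 25)
    cat3_pool: Tuple[str, ...] = _pool("C", 25)
    cat4_trauma_pool: Tuple[str, ...] = _pool("D", 15)
    late_trauma_pool: Tuple[str, ...] = _pool("E", 10)
    exclusion_pool: Tuple[str, ...] = EXCLUSION_CODES

    def __post_init__(self):
        pools = [
            self.ld_codes, self.common_pool, self.cat2_pool, self.cat3_pool,
            self.cat4_trauma_pool, self.late_trauma_pool, self.exclusion_pool,
        ]
        for p in pools:
            if not p:
                raise DataValidationError("all code pools must be non-empty")
        flat = [c for p in pools for c in p]
        if len(set(flat)) != len(flat):
            raise DataValidationError("code pools must be pairwise disjoint")

    def characteristic_pool(self, category: int) -> Tuple[str, ...]:
        """Pool of codes unique to one category (category 1: common pool)."""
        return {
            1: self.common_pool,
            2: self.cat2_pool,
            3: self.cat3_pool,
            4: self.cat4_trauma_pool,
        }[category]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults: 50 records per category, 30 non-qualifying records, 3–8
    common-pool codes per record, 20% cross-category leakage, LD onset
    uniform over ages 1–18 years, trauma preceding the first LD code by
    0–365 days, and a 25% chance of post-LD trauma on Category-2
    records.
    """

    n_per_category: Tuple[int, int, int, int] = (50, 50, 50, 50)
    n_nonqualifying: int = 30
    codes_per_record: Tuple[int, int] = (3, 8)
    leakage: float = 0.2
    ld_onset_age_days: Tuple[int, int] = (365, 6570)
    trauma_gap_days: Tuple[int, int] = (0, 365)
    post_ld_trauma_prob: float = 0.25
    pediatric_age_days: int = PEDIATRIC_AGE_DAYS
    pools: CodePools = field(default_factory=CodePools)
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_category) != 4 or min(self.n_per_category) < 0:
            raise DataValidationError("n_per_category must be four counts >= 0")
        if self.n_nonqualifying < 0:
            raise DataValidationError("n_nonqualifying must be >= 0")
        lo, hi = self.codes_per_record
        if not 1 <= lo <= hi:
            raise DataValidationError("codes_per_record must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.leakage <= 1.0:
            raise DataValidationError("leakage must be in [0, 1]")
        if not 0.0 <= self.post_ld_trauma_prob <= 1.0:
            raise DataValidationError("post_ld_trauma_prob must be in [0, 1]")
        lo, hi = self.ld_onset_age_days
        if not 0 <= lo <= hi < self.pediatric_age_days:
            raise DataValidationError(
                "ld_onset_age_days must lie within the pediatric bound"
            )
        lo, hi = self.trauma_gap_days
        if not 0 <= lo <= hi:
            raise DataValidationError("trauma_gap_days must satisfy 0 <= lo <= hi")


def _event(code: str, age: int) -> CodeEvent:
    return CodeEvent(code=code, system=_system_for(code), age_days=int(age))


def _draw(rng: np.random.Generator, pool: Tuple[str, ...], k: int) -> List[str]:
    idx = rng.integers(0, len(pool), size=k)
    return [pool[int(i)] for i in idx]


def generate_record(
    category: int,
    pools: CodePools,
    config: SimulationConfig,
    rng: np.random.Generator,
    record_id: str = "synthetic",
) -> Tuple[PatientRecord, dict]:
    """One qualifying record of the given true category, plus metadata."""
    if category not in (1, 2, 3, 4):
        raise DataValidationError(f"category must be 1-4, got {category!r}")
    onset = int(rng.integers(config.ld_onset_age_days[0], config.ld_onset_age_days[1] + 1))
    horizon = onset + 1500
    events = [_event(pools.ld_codes[int(rng.integers(0, len(pools.ld_codes)))], onset)]
    if rng.random() < 0.3:  # repeat LD coding at a later visit
        later = onset + int(rng.integers(30, 1000))
        events.append(_event(events[0].code, later))

    n_common = int(rng.integers(config.codes_per_record[0], config.codes_per_record[1] + 1))
    for code in _draw(rng, pools.common_pool, n_common):
        events.append(_event(code, int(rng.integers(0, horizon + 1))))

    meta = {
        "category": category,
        "qualifying": True,
        "reason": None,
        "first_ld_age": onset,
        "leaked_codes": [],
        "trauma_ages": [],
        "post_ld_trauma": False,
    }

    if category == 2:
        for code in _draw(rng, pools.cat2_pool, int(rng.integers(1, 4))):
            events.append(_event(code, int(rng.integers(0, horizon + 1))))
        if rng.random() < config.post_ld_trauma_prob:
            code = pools.late_trauma_pool[int(rng.integers(0, len(pools.late_trauma_pool)))]
            events.append(_event(code, onset + int(rng.integers(1, 731))))
            meta["post_ld_trauma"] = True
    elif category == 3:
        for code in _draw(rng, pools.cat3_pool, int(rng.integers(1, 4))):
            events.append(_event(code, int(rng.integers(0, horizon + 1))))
    elif category == 4:
        for code in _draw(rng, pools.cat4_trauma_pool, int(rng.integers(1, 3))):
            gap = int(rng.integers(config.trauma_gap_days[0], config.trauma_gap_days[1] + 1))
            age = max(0, onset - gap)
            events.append(_event(code, age))
            meta["trauma_ages"].append(age)

    if rng.random() < config.leakage:
        other = [k for k in (2, 3, 4) if k != category]
        source = other[int(rng.integers(0, len(other)))]
        code = pools.characteristic_pool(source)[
            int(rng.integers(0, len(pools.characteristic_pool(source))))
        ]
        age = int(rng.integers(0, horizon + 1))
        events.append(_event(code, age))
        meta["leaked_codes"].append([code, age, source])

    return PatientRecord(record_id=record_id, events=tuple(events)), meta


def _generate_nonqualifying(
    reason: str,
    pools: CodePools,
    config: SimulationConfig,
    rng: np.random.Generator,
    record_id: str,
) -> Tuple[PatientRecord, dict]:
    n_common = int(rng.integers(config.codes_per_record[0], config.codes_per_record[1] + 1))
    events = [
        _event(code, int(rng.integers(0, 6001)))
        for code in _draw(rng, pools.common_pool, n_common)
    ]
    first_ld = None
    if reason == "exclusion_code":
        onset = int(rng.integers(config.ld_onset_age_days[0], config.ld_onset_age_days[1] + 1))
        events.append(_event(pools.ld_codes[int(rng.integers(0, len(pools.ld_codes)))], onset))
        code = pools.exclusion_pool[int(rng.integers(0, len(pools.exclusion_pool)))]
        events.append(_event(code, int(rng.integers(0, onset + 1501))))
        first_ld = onset
    elif reason == "adult_onset":
        onset = int(rng.integers(config.pediatric_age_days, config.pediatric_age_days + 3651))
        events.append(_event(pools.ld_codes[int(rng.integers(0, len(pools.ld_codes)))], onset))
        first_ld = onset
    elif reason != "no_ld_code":
        raise DataValidationError(f"unknown non-qualifying reason {reason!r}")
    meta = {
        "category": None,
        "qualifying": False,
        "reason": reason,
        "first_ld_age": first_ld,
        "leaked_codes": [],
        "trauma_ages": [],
        "post_ld_trauma": False,
    }
    return PatientRecord(record_id=record_id, events=tuple(events)), meta


def generate_cohort(
    config: SimulationConfig,
) -> Tuple[List[PatientRecord], Dict[str, int], dict]:
    """Generate (records, true_labels, ground_truth) for one config.

    ``true_labels`` maps qualifying record ids to their true category;
    non-qualifying records appear only in the ground-truth metadata,
    tagged with the single broad-search criterion they violate.
    Identical config and seed produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    pools = config.pools
    records: List[PatientRecord] = []
    labels: Dict[str, int] = {}
    truth_records: Dict[str, dict] = {}

    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"R{counter:05d}"

    for category, n in zip((1, 2, 3, 4), config.n_per_category):
        for _ in range(n):
            rid = next_id()
            record, meta = generate_record(category, pools, config, rng, rid)
            records.append(record)
            labels[rid] = category
            truth_records[rid] = meta

    reasons = ("no_ld_code", "exclusion_code", "adult_onset")
    for i in range(config.n_nonqualifying):
        rid = next_id()
        record, meta = _generate_nonqualifying(
            reasons[i % 3], pools, config, rng, rid
        )
        records.append(record)
        truth_records[rid] = meta

    order = rng.permutation(len(records))
    records = [records[int(i)] for i in order]

    truth = {
        "seed": int(config.seed),
        "n_qualifying": int(sum(config.n_per_category)),
        "n_nonqualifying": int(config.n_nonqualifying),
        "leakage": float(config.leakage),
        "pools": {
            "ld_codes": list(pools.ld_codes),
            "common_pool": list(pools.common_pool),
            "cat2_pool": list(pools.cat2_pool),
            "cat3_pool": list(pools.cat3_pool),
            "cat4_trauma_pool": list(pools.cat4_trauma_pool),
            "late_trauma_pool": list(pools.late_trauma_pool),
            "exclusion_pool": list(pools.exclusion_pool),
        },
        "records": truth_records,
    }
    return records, labels, truth
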