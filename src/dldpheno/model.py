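"""Core EHR data types and ICD code matching semantics.

The whole pipeline operates on de-identified longitudinal records: each
record is a sequence of dated ICD diagnosis codes, with dates expressed
as patient age in days (the only temporal operations needed downstream
are ordering and an age threshold, so no calendar arithmetic is ever
done). ICD-9 and ICD-10 codes share one namespace of normalized strings
(uppercase, no periods); no cross-version mapping is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .errors import DataValidationError, InvalidCodeError

__all__ = [
    "CodeSystem",
    "CodeEvent",
    "PatientRecord",
    "CodeCriterion",
    "CategoryLabel",
    "normalize_code",
    "code_matches",
    "first_ld_age",
]

_WHITESPACE = re.compile(r"\s")
# ICD-9 codes start with a digit or the E/V supplementary prefixes;
# ICD-10 codes start with a letter followed by a digit.
_ICD9_SHAPE = re.compile(r"^[0-9EV]")
_ICD10_SHAPE = re.compile(r"^[A-Z][0-9]")


class CodeSystem(str, Enum):
    """Coding system of a diagnosis event; both appear mixed in one record."""

    ICD9 = "9"
    ICD10 = "10"

    @classmethod
    def coerce(cls, value) -> "CodeSystem":
        if isinstance(value, CodeSystem):
            return value
        text = str(value).strip().upper().replace("ICD-", "").replace("ICD", "")
        try:
            return cls(text)
        except ValueError:
            raise DataValidationError(
                f"icd_version must be 9 or 10, got {value!r}"
            ) from None


def normalize_code(raw: str) -> str:
    """Return the canonical form of an ICD code string.

    Uppercased, surrounding whitespace stripped and all periods removed,
    so ``"315.31"`` and ``" f80.1 "`` become ``"31531"`` and ``"F801"``.
    Idempotent. Raises :class:`InvalidCodeError` for empty, all-whitespace
    or internally-spaced input.
    """
    if not isinstance(raw, str):
        raise InvalidCodeError(f"ICD code must be a string, got {type(raw).__name__}")
    code = raw.strip().upper().replace(".", "")
    if not code:
        raise InvalidCodeError(f"empty ICD code: {raw!r}")
    if _WHITESPACE.search(code):
        raise InvalidCodeError(f"ICD code contains whitespace: {raw!r}")
    return code


@dataclass(frozen=True)
class CodeEvent:
    """One dated ICD diagnosis assignment within a patient record.

    Parameters
    ----------
    code
        Normalized ICD code (no periods, uppercase, no whitespace).
    system
        :class:`CodeSystem` the code was entered under.
    age_days
        Non-negative patient age in days at code entry.
    """

    code: str
    system: CodeSystem
    age_days: int

    def __post_init__(self):
        if not self.code or "." in self.code or _WHITESPACE.search(self.code):
            raise DataValidationError(f"code not normalized: {self.code!r}")
        if self.code != self.code.upper():
            raise DataValidationError(f"code not uppercase: {self.code!r}")
        object.__setattr__(self, "system", CodeSystem.coerce(self.system))
        if not isinstance(self.age_days, (int,)) or isinstance(self.age_days, bool):
            raise DataValidationError(f"age_days must be an integer, got {self.age_days!r}")
        if self.age_days < 0:
            raise DataValidationError(f"age_days must be >= 0, got {self.age_days}")
        shape = _ICD9_SHAPE if self.system is CodeSystem.ICD9 else _ICD10_SHAPE
        if not shape.match(self.code):
            raise DataValidationError(
                f"code {self.code!r} inconsistent with ICD-{self.system.value} shape"
            )


@dataclass(frozen=True)
class PatientRecord:
    """A de-identified longitudinal sequence of :class:`CodeEvent`.

    Events are stored sorted non-decreasing by ``age_days``; ties keep
    their input order (stable sort). A record must contain at least one
    event.
    """

    record_id: str
    events: tuple
    gender: Optional[str] = None
    race: Optional[str] = None

    def __post_init__(self):
        if not self.record_id:
            raise DataValidationError("record_id must be a non-empty string")
        events = tuple(sorted(self.events, key=lambda e: e.age_days))
        if not events:
            raise DataValidationError(f"record {self.record_id!r} has no events")
        object.__setattr__(self, "events", events)

    @property
    def codes(self) -> frozenset:
        """Set of distinct normalized codes in the record."""
        return frozenset(e.code for e in self.events)


@dataclass(frozen=True)
class CodeCriterion:
    """A code-set membership test: exact codes plus prefix families.

    A code matches iff it equals one of ``exact_codes`` or starts with
    one of ``prefix_codes`` (how "Group H90" or "Groups Q90–Q99" style
    criteria are expressed after range expansion). Both sets may be
    empty, in which case nothing matches.
    """

    exact_codes: frozenset = frozenset()
    prefix_codes: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(
            self, "exact_codes", frozenset(normalize_code(c) for c in self.exact_codes)
        )
        object.__setattr__(
            self, "prefix_codes", frozenset(normalize_code(c) for c in self.prefix_codes)
        )

    def matches(self, code: str) -> bool:
        if code in self.exact_codes:
            return True
        return any(code.startswith(p) for p in self.prefix_codes)


def code_matches(code: str, criterion: CodeCriterion) -> bool:
    """True iff ``code`` (already normalized) satisfies ``criterion``."""
    return criterion.matches(code)


@dataclass(frozen=True)
class CategoryLabel:
    """Manual chart-review category, 1–4.

    Categories 1 (common conditions) and 2 (significant non-neuro-
    developmental medical conditions) are DLD inclusion; 3 (neuro-
    developmental/genetic conditions) and 4 (acquired LD: trauma on or
    before the first LD code) are exclusion.
    """

    category: int

    def __post_init__(self):
        if self.category not in (1, 2, 3, 4):
            raise DataValidationError(
                f"category must be one of 1, 2, 3, 4, got {self.category!r}"
            )

    @property
    def included(self) -> bool:
        return self.category in (1, 2)


def first_ld_age(record: PatientRecord, ld_criterion: CodeCriterion) -> Optional[int]:
    """Age in days of the earliest LD-symptom code, or None if absent."""
    ages = [e.age_days for e in record.events if ld_criterion.matches(e.code)]
    return min(ages) if ages else None
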