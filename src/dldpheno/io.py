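"""Readers and writers for the delimited-text interchange formats.

Events CSV: columns ``record_id, icd_version (9|10), icd_code, age_days``
(codes dotted or undotted; normalized at load). Labels CSV:
``record_id, category`` with category in 1–4. Filters are a JSON
document; evaluation reports are JSON plus a plain-text table. Broad-
search criteria load from YAML or JSON, with ``A-B`` style code ranges
expanded into explicit prefix sets.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .broad_search import BroadSearchCriteria
from .classify import ClassificationResult
from .errors import DataValidationError
from .metrics import EvaluationReport, format_percent
from .model import (
    CodeCriterion,
    CodeEvent,
    CodeSystem,
    PatientRecord,
    normalize_code,
)
from .training import CategoryFilters

__all__ = [
    "read_events",
    "write_events",
    "read_labels",
    "write_labels",
    "read_filters",
    "write_filters",
    "read_classifications",
    "write_classifications",
    "write_report",
    "render_report",
    "read_criteria",
    "expand_code_range",
]

EVENT_COLUMNS = ["record_id", "icd_version", "icd_code", "age_days"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing column(s) {missing}")


def read_events(path, demographics: Optional[str] = None) -> List[PatientRecord]:
    """Load an events CSV into validated PatientRecords.

    Events are grouped by ``record_id`` (first-appearance order) and
    sorted by ``age_days`` within each record; parse errors name the
    offending data row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, EVENT_COLUMNS, path)
    demo: Dict[str, dict] = {}
    if demographics is not None:
        ddf = pd.read_csv(demographics, dtype=str, keep_default_na=False)
        _require_columns(ddf, ["record_id"], demographics)
        for row in ddf.itertuples(index=False):
            demo[row.record_id] = {
                "gender": getattr(row, "gender", None) or None,
                "race": getattr(row, "race", None) or None,
            }

    grouped: Dict[str, List[CodeEvent]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            age = int(row.age_days)
        except (TypeError, ValueError):
            raise DataValidationError(
                f"{path}: row {i}: age_days must be an integer, got {row.age_days!r}"
            ) from None
        try:
            event = CodeEvent(
                code=normalize_code(row.icd_code),
                system=CodeSystem.coerce(row.icd_version),
                age_days=age,
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{path}: row {i}: {exc}") from None
        grouped.setdefault(row.record_id, []).append(event)

    records = []
    for rid, events in grouped.items():
        extra = demo.get(rid, {})
        records.append(PatientRecord(record_id=rid, events=tuple(events), **extra))
    return records


def write_events(records: Sequence[PatientRecord], path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "icd_version": e.system.value,
            "icd_code": e.code,
            "age_days": e.age_days,
        }
        for r in records
        for e in r.events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_labels(path) -> Dict[str, int]:
    """Load a labels CSV into a record_id -> category map."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["record_id", "category"], path)
    labels: Dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.record_id in labels:
            raise DataValidationError(
                f"{path}: row {i}: duplicate record_id {row.record_id!r}"
            )
        try:
            category = int(row.category)
        except ValueError:
            category = -1
        if category not in (1, 2, 3, 4):
            raise DataValidationError(
                f"{path}: row {i}: category must be 1-4, got {row.category!r}"
            )
        labels[row.record_id] = category
    return labels


def write_labels(labels: Mapping[str, int], path) -> None:
    rows = [{"record_id": rid, "category": cat} for rid, cat in labels.items()]
    pd.DataFrame(rows, columns=["record_id", "category"]).to_csv(path, index=False)


_FILTER_KEYS = ("category_1", "category_2", "category_3", "category_4")


def write_filters(filters: CategoryFilters, path) -> None:
    doc = {
        "ld_codes": sorted(filters.ld_criterion.exact_codes),
        "ld_prefixes": sorted(filters.ld_criterion.prefix_codes),
        "cat4_inclusive": filters.cat4_inclusive,
        **{key: sorted(filters.filter_for(k)) for k, key in enumerate(_FILTER_KEYS, 1)},
        "provenance": filters.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_filters(path) -> CategoryFilters:
    doc = json.loads(Path(path).read_text())
    missing = [k for k in ("ld_codes", *_FILTER_KEYS) if k not in doc]
    if missing:
        raise DataValidationError(f"{path}: filters document missing keys {missing}")
    return CategoryFilters(
        filter_1=frozenset(doc["category_1"]),
        filter_2=frozenset(doc["category_2"]),
        filter_3=frozenset(doc["category_3"]),
        filter_4=frozenset(doc["category_4"]),
        ld_criterion=CodeCriterion(
            exact_codes=frozenset(doc["ld_codes"]),
            prefix_codes=frozenset(doc.get("ld_prefixes", [])),
        ),
        cat4_inclusive=bool(doc.get("cat4_inclusive", True)),
        provenance=doc.get("provenance", {}),
    )


def write_classifications(results: Sequence[ClassificationResult], path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "category": r.category,
            "included": int(r.included),
            "trigger_codes": ";".join(r.trigger_codes),
            "first_ld_age": r.first_ld_age,
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["record_id", "category", "included", "trigger_codes", "first_ld_age"],
    ).to_csv(path, index=False)


def read_classifications(path) -> Dict[str, int]:
    """Load a classification CSV into a record_id -> category map."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["record_id", "category"], path)
    out: Dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.record_id in out:
            raise DataValidationError(f"{path}: row {i}: duplicate record_id")
        out[row.record_id] = int(row.category)
    return out


def render_report(report: EvaluationReport) -> str:
    """Human-readable table: whole percents, half rounded away from zero."""

    def pct(value) -> str:
        return "N/A" if value is None else format_percent(value)

    c = report.confusion
    lines = [
        f"records compared        {report.n}",
        f"a/b/c/d                 {c.a}/{c.b}/{c.c}/{c.d}",
        f"TPR category 1          {pct(report.tpr_by_category.get(1))}",
        f"TPR category 2          {pct(report.tpr_by_category.get(2))}",
        f"TNR category 3          {pct(report.tnr_by_category.get(3))}",
        f"TNR category 4          {pct(report.tnr_by_category.get(4))}",
        f"inclusion concordance   {pct(report.concordance_inclusion)}",
        f"exclusion concordance   {pct(report.concordance_exclusion)}",
        f"overall correctness     {pct(report.overall_correctness)}",
    ]
    if report.gold_confusion is not None:
        lines += [
            f"PPV (gold standard)     {pct(report.ppv)}",
            f"NPV (gold standard)     {pct(report.npv)}",
        ]
    return "\n".join(lines)


def write_report(report: EvaluationReport, path) -> None:
    Path(path).write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )


_RANGE = re.compile(r"^([A-Z]*)(\d+)-([A-Z]*)(\d+)$")


def expand_code_range(text: str) -> List[str]:
    """Expand ``"Q90-Q99"`` (or ``"317-319"``) into explicit prefixes."""
    text = normalize_code(text)
    m = _RANGE.match(text)
    if not m:
        return [text]
    lo_alpha, lo_num, hi_alpha, hi_num = m.groups()
    if lo_alpha != hi_alpha or len(lo_num) != len(hi_num) or int(lo_num) > int(hi_num):
        raise DataValidationError(f"cannot expand code range {text!r}")
    width = len(lo_num)
    return [f"{lo_alpha}{i:0{width}d}" for i in range(int(lo_num), int(hi_num) + 1)]


def _criterion_from(entry) -> CodeCriterion:
    if entry is None:
        return CodeCriterion()
    exact = entry.get("exact", [])
    prefixes = [p for item in entry.get("prefix", []) for p in expand_code_range(str(item))]
    return CodeCriterion(
        exact_codes=frozenset(normalize_code(str(c)) for c in exact),
        prefix_codes=frozenset(prefixes),
    )


def read_criteria(path) -> BroadSearchCriteria:
    """Load broad-search criteria from YAML or JSON.

    Schema mirrors the criteria type: per-group ``exact`` and
    ``prefix`` lists (dotted codes and ``A-B`` ranges permitted), plus
    ``pediatric_age_days``. Omitted groups keep their defaults.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise DataValidationError(f"{path}: criteria file must be a mapping")
    defaults = BroadSearchCriteria()
    kwargs = {}
    for name in ("ld_inclusion", "hearing_loss", "intellectual_disability", "chromosomal"):
        kwargs[name] = (
            _criterion_from(doc[name]) if name in doc else getattr(defaults, name)
        )
    kwargs["pediatric_age_days"] = int(
        doc.get("pediatric_age_days", defaults.pediatric_age_days)
    )
    return BroadSearchCriteria(**kwargs)
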