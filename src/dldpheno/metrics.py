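"""Validation metrics for algorithm-vs-reference phenotype comparisons.

All comparisons at the DLD inclusion/exclusion level reduce to four
counts: a (true positives: included by both), b (true negatives:
excluded by both), c (false positives: algorithm includes, reference
excludes) and d (false negatives: algorithm excludes, reference
includes). From these:

    TPR = a/(a+d)                 TNR = b/(b+c)
    inclusion concordance = a/(a+c)
    exclusion concordance = b/(b+d)
    PPV = a/(a+c)  NPV = b/(b+d)  (against a gold-standard subset)

Per-category agreement is the proportion of reference-category-k
records the algorithm also assigns to k. Undefined metrics (zero
denominator) raise :class:`UndefinedMetricError` and are rendered as
"N/A", never coerced to 0 or 1; reports re-derive every percentage
from raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Mapping, Optional, Tuple

from .errors import DataValidationError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "inclusion_confusion",
    "tpr",
    "tnr",
    "concordance",
    "ppv_npv",
    "category_agreement",
    "overall_correctness",
    "prevalence",
    "percent_agreement",
    "evaluate",
    "format_percent",
]

INCLUSION_CATEGORIES = (1, 2)
EXCLUSION_CATEGORIES = (3, 4)


def _is_included(category: int) -> bool:
    return category in INCLUSION_CATEGORIES


@dataclass(frozen=True)
class ConfusionCounts:
    """a/b/c/d accounting at the inclusion/exclusion level."""

    a: int  # true positives
    b: int  # true negatives
    c: int  # false positives
    d: int  # false negatives

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _check_aligned(predicted: Mapping, reference: Mapping) -> None:
    if not predicted or not reference:
        raise DataValidationError("metric inputs must be non-empty")
    if set(predicted) != set(reference):
        diff = set(predicted) ^ set(reference)
        raise DataValidationError(
            f"predicted and reference record ids differ (e.g. {sorted(diff)[:5]})"
        )


def inclusion_confusion(
    predicted: Mapping[str, bool], reference: Mapping[str, bool]
) -> ConfusionCounts:
    """Count a/b/c/d from aligned record_id -> included maps."""
    _check_aligned(predicted, reference)
    a = b = c = d = 0
    for rid, ref_in in reference.items():
        pred_in = predicted[rid]
        if pred_in and ref_in:
            a += 1
        elif not pred_in and not ref_in:
            b += 1
        elif pred_in and not ref_in:
            c += 1
        else:
            d += 1
    return ConfusionCounts(a=a, b=b, c=c, d=d)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: zero denominator")
    return num / den


def tpr(counts: ConfusionCounts) -> float:
    """True positive rate a/(a+d)."""
    return _ratio(counts.a, counts.a + counts.d, "TPR")


def tnr(counts: ConfusionCounts) -> float:
    """True negative rate b/(b+c)."""
    return _ratio(counts.b, counts.b + counts.c, "TNR")


def concordance(counts: ConfusionCounts, side: str) -> float:
    """Inclusion concordance a/(a+c) or exclusion concordance b/(b+d)."""
    if side == "inclusion":
        return _ratio(counts.a, counts.a + counts.c, "inclusion concordance")
    if side == "exclusion":
        return _ratio(counts.b, counts.b + counts.d, "exclusion concordance")
    raise DataValidationError(f"side must be 'inclusion' or 'exclusion', got {side!r}")


def ppv_npv(counts: ConfusionCounts) -> Tuple[float, float]:
    """(PPV, NPV) = (a/(a+c), b/(b+d)) against a gold-standard reference."""
    return (
        _ratio(counts.a, counts.a + counts.c, "PPV"),
        _ratio(counts.b, counts.b + counts.d, "NPV"),
    )


def category_agreement(
    predicted: Mapping[str, int], reference: Mapping[str, int], k: int
) -> float:
    """Proportion of reference-category-k records predicted as k."""
    _check_aligned(predicted, reference)
    ref_k = [rid for rid, cat in reference.items() if cat == k]
    if not ref_k:
        raise UndefinedMetricError(f"no reference records of category {k}")
    hits = sum(1 for rid in ref_k if predicted[rid] == k)
    return hits / len(ref_k)


def overall_correctness(
    predicted: Mapping[str, int], reference: Mapping[str, int]
) -> float:
    """Fraction of records whose predicted category equals the reference."""
    _check_aligned(predicted, reference)
    return sum(1 for rid in reference if predicted[rid] == reference[rid]) / len(
        reference
    )


def prevalence(n_dld: int, n_total_pediatric: int) -> float:
    """Cohort size relative to the total pediatric record count."""
    if n_total_pediatric <= 0:
        raise UndefinedMetricError("prevalence undefined: zero pediatric total")
    if not 0 <= n_dld <= n_total_pediatric:
        raise DataValidationError("n_dld must be between 0 and n_total_pediatric")
    return n_dld / n_total_pediatric


def percent_agreement(
    labels_x: Mapping[str, int], labels_y: Mapping[str, int]
) -> float:
    """Intercoder percent agreement: fraction of records labeled equally."""
    _check_aligned(labels_x, labels_y)
    return sum(1 for rid in labels_x if labels_x[rid] == labels_y[rid]) / len(labels_x)


def format_percent(fraction: float, decimals: int = 0) -> str:
    """Render a fraction as a percent, rounding half away from zero."""
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(repr(fraction)) * 100).quantize(quantum, rounding=ROUND_HALF_UP)
    return f"{value}%"


@dataclass
class EvaluationReport:
    """Full validation summary; None marks an undefined (N/A) metric."""

    confusion: ConfusionCounts
    tpr_by_category: Dict[int, Optional[float]]
    tnr_by_category: Dict[int, Optional[float]]
    concordance_inclusion: Optional[float]
    concordance_exclusion: Optional[float]
    overall_correctness: float
    n: int
    ppv: Optional[float] = None
    npv: Optional[float] = None
    gold_confusion: Optional[ConfusionCounts] = None

    def to_dict(self) -> dict:
        def pct(x, decimals=0):
            return None if x is None else format_percent(x, decimals)

        return {
            "n": self.n,
            "counts": {
                "a": self.confusion.a,
                "b": self.confusion.b,
                "c": self.confusion.c,
                "d": self.confusion.d,
            },
            "tpr_by_category": {
                str(k): v for k, v in self.tpr_by_category.items()
            },
            "tnr_by_category": {
                str(k): v for k, v in self.tnr_by_category.items()
            },
            "concordance_inclusion": self.concordance_inclusion,
            "concordance_exclusion": self.concordance_exclusion,
            "overall_correctness": self.overall_correctness,
            "ppv": self.ppv,
            "npv": self.npv,
            "gold_counts": None
            if self.gold_confusion is None
            else {
                "a": self.gold_confusion.a,
                "b": self.gold_confusion.b,
                "c": self.gold_confusion.c,
                "d": self.gold_confusion.d,
            },
            "rendered": {
                "tpr_by_category": {
                    str(k): pct(v) for k, v in self.tpr_by_category.items()
                },
                "tnr_by_category": {
                    str(k): pct(v) for k, v in self.tnr_by_category.items()
                },
                "concordance_inclusion": pct(self.concordance_inclusion),
                "concordance_exclusion": pct(self.concordance_exclusion),
                "overall_correctness": pct(self.overall_correctness),
                "ppv": pct(self.ppv),
                "npv": pct(self.npv),
            },
        }


def _maybe(fn, *args) -> Optional[float]:
    try:
        return fn(*args)
    except UndefinedMetricError:
        return None


def evaluate(
    predicted: Mapping[str, int],
    reference: Mapping[str, int],
    gold: Optional[Mapping[str, int]] = None,
) -> EvaluationReport:
    """Compute the full report from category maps.

    ``predicted`` may contain category 0 (unclassified); such records
    count as excluded at the inclusion/exclusion level and never match
    any reference category. ``gold`` is an optional clinician-labeled
    subset of the same ids, used for PPV/NPV.
    """
    _check_aligned(predicted, reference)
    pred_inc = {rid: _is_included(cat) for rid, cat in predicted.items()}
    ref_inc = {rid: _is_included(cat) for rid, cat in reference.items()}
    counts = inclusion_confusion(pred_inc, ref_inc)

    report = EvaluationReport(
        confusion=counts,
        tpr_by_category={
            k: _maybe(category_agreement, predicted, reference, k)
            for k in INCLUSION_CATEGORIES
        },
        tnr_by_category={
            k: _maybe(category_agreement, predicted, reference, k)
            for k in EXCLUSION_CATEGORIES
        },
        concordance_inclusion=_maybe(concordance, counts, "inclusion"),
        concordance_exclusion=_maybe(concordance, counts, "exclusion"),
        overall_correctness=overall_correctness(predicted, reference),
        n=counts.n,
    )
    if gold:
        missing = set(gold) - set(predicted)
        if missing:
            raise DataValidationError(
                f"gold-standard ids absent from predictions: {sorted(missing)[:5]}"
            )
        gold_counts = inclusion_confusion(
            {rid: pred_inc[rid] for rid in gold},
            {rid: _is_included(cat) for rid, cat in gold.items()},
        )
        report.gold_confusion = gold_counts
        report.ppv = _maybe(lambda c: ppv_npv(c)[0], gold_counts)
        report.npv = _maybe(lambda c: ppv_npv(c)[1], gold_counts)
    return report
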