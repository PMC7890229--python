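"""scikit-learn-style estimator wrapping filter training and classification.

``DLDPhenotyper.fit`` learns the four disjoint category code filters by
systematic subtraction from a labeled record sample; ``predict`` applies
the hierarchical date-aware priority rule. X is a sequence of
:class:`~dldpheno.model.PatientRecord` (records are structured event
sequences, not feature vectors), y an array-like of categories 1–4.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .classify import classify_cohort
from .errors import DataValidationError
from .model import CodeCriterion, PatientRecord
from .training import LabeledCohort, train_filters

__all__ = ["DLDPhenotyper"]


class DLDPhenotyper(ClassifierMixin, BaseEstimator):
    """Rule-based DLD phenotype classifier for ICD-coded records.

    Parameters
    ----------
    ld_criterion
        Criterion defining the LD-symptom codes; defaults to the six
        standard codes (315.31/315.32/315.39, F80.1/F80.2/F80.89).
    cat4_inclusive
        Whether trauma on the same day as the first LD code counts as
        preceding it (the rubric's "concurrently with or prior to"
        reading). Applied in both training and classification.

    Attributes
    ----------
    filters_ : CategoryFilters
        The trained, pairwise-disjoint per-category code sets.
    classes_ : ndarray
        Category labels seen during fit.

    Examples
    --------
    >>> clf = DLDPhenotyper().fit(records, labels)
    >>> clf.predict(records[:3])
    array([1, 3, 4])
    """

    def __init__(
        self,
        ld_criterion: Optional[CodeCriterion] = None,
        cat4_inclusive: bool = True,
    ):
        self.ld_criterion = ld_criterion
        self.cat4_inclusive = cat4_inclusive

    def fit(self, X: Sequence[PatientRecord], y):
        """Learn category filters from records X and manual categories y."""
        X = list(X)
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise DataValidationError(
                f"X has {len(X)} records but y has {len(y)} labels"
            )
        cohort = LabeledCohort(
            records=X,
            labels={r.record_id: int(lab) for r, lab in zip(X, y)},
        )
        self.filters_ = train_filters(
            cohort,
            ld_criterion=self.ld_criterion,
            cat4_inclusive=self.cat4_inclusive,
        )
        self.classes_ = np.unique(y)
        self.n_features_in_ = 1  # records are structured objects, not features
        return self

    def predict(self, X: Sequence[PatientRecord]) -> np.ndarray:
        """Assigned category per record (0 = matched no filter)."""
        self._check_fitted()
        return np.array([r.category for r in self.predict_details(X)], dtype=int)

    def predict_details(self, X: Sequence[PatientRecord]):
        """Full per-record :class:`ClassificationResult` objects."""
        self._check_fitted()
        return classify_cohort(list(X), self.filters_)

    def predict_included(self, X: Sequence[PatientRecord]) -> np.ndarray:
        """Boolean DLD inclusion status (category 1 or 2) per record."""
        self._check_fitted()
        return np.array([r.included for r in self.predict_details(X)], dtype=bool)

    def _check_fitted(self):
        if not hasattr(self, "filters_"):
            raise DataValidationError(
                "this DLDPhenotyper instance is not fitted yet; call fit first"
            )
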