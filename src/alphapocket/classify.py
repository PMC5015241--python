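"""Knob-level threshold classification of drug response.

A single-feature decision stump: mutants are split into "Response" and
"No-response" by one knob-level boundary.  Fitting enumerates every midpoint
of consecutive distinct training values (plus ±∞) in both orientations and
keeps the boundary with the highest training accuracy; ties prefer the
Response-below orientation (responding pockets sit at lower knob levels) and
then the smallest boundary.  A value exactly on the boundary is assigned to
the Response side.

Two scikit-learn estimators are provided so the whole trajectory → knob
level → response path composes with sklearn pipelines and model selection:

* :class:`KnobLevelTransformer` — (Trajectory, BindingSite) pairs or
  curvature profiles → an (n, 1) knob-level feature matrix.
* :class:`ThresholdResponseClassifier` — knob levels → response labels.

Thin functional wrappers (:func:`fit_threshold_classifier`,
:func:`predict_response`) cover the cohort-record workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .curvature import CurvatureProfile, trajectory_curvature
from .knob import CohortRecord, DEFAULT_THRESHOLD, knob_level

RESPONSE = "Response"
NO_RESPONSE = "No-response"


@dataclass
class ClassifierResult:
    """Fitted knob-level boundary with its training performance."""

    boundary: float
    orientation: Literal["response-below", "response-above"]
    accuracy: float
    errors: list[str]

    def predict(self, knob: float) -> str:
        if self.orientation == "response-below":
            return RESPONSE if knob <= self.boundary else NO_RESPONSE
        return RESPONSE if knob >= self.boundary else NO_RESPONSE


def _candidate_boundaries(values: np.ndarray) -> np.ndarray:
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if distinct.size > 1 else np.zeros(0)
    return np.concatenate([[-np.inf], mids, [np.inf]])


def _search_boundary(x: np.ndarray, is_response: np.ndarray
                     ) -> tuple[float, str, float, np.ndarray]:
    """Best (boundary, orientation, accuracy, misclassified mask)."""
    n = x.size
    best = None
    for boundary in _candidate_boundaries(x):
        for orientation in ("response-below", "response-above"):
            pred = x <= boundary if orientation == "response-below" else x >= boundary
            acc = float(np.mean(pred == is_response))
            key = (-acc, 0 if orientation == "response-below" else 1, boundary)
            if best is None or key < best[0]:
                best = (key, boundary, orientation, acc, pred != is_response)
    _, boundary, orientation, acc, wrong = best
    assert abs(acc - (1.0 - wrong.sum() / n)) < 1e-12
    return float(boundary), orientation, acc, wrong


class ThresholdResponseClassifier(ClassifierMixin, BaseEstimator):
    """Decision stump on a single knob-level feature.

    Parameters
    ----------
    prefer_response_below
        Tie-break orientation when both orientations reach the same training
        accuracy.  The default matches the physics: responding variants have
        the lower knob levels.

    Attributes
    ----------
    boundary_ : float
        Fitted knob-level boundary (may be ±inf for one-sided fits).
    orientation_ : {"response-below", "response-above"}
    accuracy_ : float
        Training accuracy, ``1 − |errors_| / n``.
    errors_ : ndarray
        Indices of misclassified training samples.
    classes_ : ndarray of the two labels.
    """

    def __init__(self, prefer_response_below: bool = True):
        self.prefer_response_below = prefer_response_below

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_2d=False, dtype=float)
        x = X.ravel() if X.ndim > 1 else X
        if X.ndim > 1 and X.shape[1] != 1:
            raise ValueError("exactly one feature (the knob level) expected")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("both response groups must be present in y")
        is_response = np.asarray(y) == RESPONSE
        if RESPONSE not in set(map(str, y)):
            # generic binary labels: treat the lexicographically first as Response
            is_response = np.asarray(y) == self.classes_[0]
        if not self.prefer_response_below:
            boundary, orientation, acc, wrong = _search_boundary(-x, is_response)
            boundary, orientation = -boundary, (
                "response-above" if orientation == "response-below" else "response-below")
        else:
            boundary, orientation, acc, wrong = _search_boundary(x, is_response)
        self.boundary_ = boundary
        self.orientation_ = orientation
        self.accuracy_ = acc
        self.errors_ = np.nonzero(wrong)[0]
        self.n_features_in_ = 1
        self._response_label = (RESPONSE if RESPONSE in set(map(str, y))
                                else self.classes_[0])
        self._noresponse_label = next(c for c in self.classes_
                                      if c != self._response_label)
        return self

    def predict(self, X):
        check_is_fitted(self, "boundary_")
        X = check_array(X, ensure_2d=False, dtype=float)
        x = X.ravel()
        if self.orientation_ == "response-below":
            resp = x <= self.boundary_
        else:
            resp = x >= self.boundary_
        return np.where(resp, self._response_label, self._noresponse_label)

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


class KnobLevelTransformer(TransformerMixin, BaseEstimator):
    """Stateless transformer: trajectories (or profiles) → knob levels.

    ``transform`` accepts a sequence of :class:`CurvatureProfile` or of
    ``(Trajectory, BindingSite)`` pairs; each element becomes one row of an
    (n, 1) knob-level matrix computed with the configured method and
    solid-angle threshold.

    Parameters
    ----------
    method : {"A", "B"}
        "A": mean over frames of the per-frame average convex degree;
        "B": average convex degree of the trajectory-mean site.
    threshold : float
        Solid-angle threshold defining convex atoms (default 0.01).
    alpha : float
        Alpha-shape filtration value, Å² (default 0, the zero-shape).
    """

    def __init__(self, method: Literal["A", "B"] = "A",
                 threshold: float = DEFAULT_THRESHOLD, alpha: float = 0.0):
        self.method = method
        self.threshold = threshold
        self.alpha = alpha

    def fit(self, X=None, y=None):
        if self.method not in ("A", "B"):
            raise ValueError("method must be 'A' or 'B'")
        if self.threshold < 0:
            raise ValueError("threshold must be ≥ 0")
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        self.fit()
        out = np.empty((len(X), 1))
        for i, item in enumerate(X):
            profile = item if isinstance(item, CurvatureProfile) else \
                trajectory_curvature(item[0], item[1], self.alpha)
            out[i, 0] = knob_level(profile, self.threshold, self.method).knob_level
        return out


def fit_threshold_classifier(records: Sequence[CohortRecord],
                             which: Literal["A", "B"] = "A") -> ClassifierResult:
    """Fit the response boundary on a cohort's knob levels.

    Returns the boundary, orientation, training accuracy and the ids of the
    misclassified mutants.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 cohort records")
    groups = {r.group for r in records}
    if groups != {RESPONSE, NO_RESPONSE}:
        raise ValueError("both Response and No-response groups must be present")
    x = np.array([r.knob(which) for r in records], dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("cohort records carry non-finite knob levels")
    y = np.array([r.group for r in records])
    clf = ThresholdResponseClassifier().fit(x[:, None], y)
    errors = [records[i].mutant_id for i in clf.errors_]
    return ClassifierResult(boundary=clf.boundary_, orientation=clf.orientation_,
                            accuracy=clf.accuracy_, errors=errors)


def predict_response(knob_level_value: float, clf: ClassifierResult) -> str:
    """Assign a new mutant's knob level to a response group (boundary ties go
    to the Response side)."""
    return clf.predict(float(knob_level_value))
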