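"""scikit-learn estimator wrappers around the scores and cutoff selection.

``RiskScoreTransformer`` turns a cohort DataFrame into score totals (a
stateless transform — the scores have fixed weights).  ``CutpointClassifier``
learns a Youden-optimal cutoff on training scores and labels, then predicts
``score >= cutoff_``.  Both follow sklearn conventions (get_params /
set_params, trailing-underscore fitted attributes) and compose in a
``Pipeline``::

    Pipeline([("score", RiskScoreTransformer("mortality2")),
              ("cutoff", CutpointClassifier())])
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import frame_to_records
from .records import InfarctClass
from .scoring import (
    DEFAULT_CONFIG,
    ScoreConfig,
    classify_infarct,
    compute_chads2,
    compute_cmca_score,
    compute_mortality_score1,
    compute_mortality_score2,
)
from .stats import best_cutoff, roc_curve, sens_spec

__all__ = ["RiskScoreTransformer", "CutpointClassifier"]

_SCORES = ("chads2", "cmca", "mortality1", "mortality2")


class RiskScoreTransformer(TransformerMixin, BaseEstimator):
    """Compute a rule-based risk score for every row of a cohort frame.

    Parameters
    ----------
    score : {"chads2", "cmca", "mortality1", "mortality2"}
        Which score to compute.
    config : ScoreConfig, optional
        Threshold configuration; defaults to the published cutoffs.

    ``transform`` accepts a DataFrame in the cohort-file schema (see
    :mod:`lhirisk.io`) and returns an ``(n, 1)`` float array of totals.
    Mortality scores are NaN for patients below the LHI threshold.
    """

    def __init__(self, score: str = "mortality2", config: ScoreConfig | None = None):
        self.score = score
        self.config = config

    def fit(self, X, y=None):
        if self.score not in _SCORES:
            raise ValueError(f"score must be one of {_SCORES}")
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else None
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        self.fit(X)
        cfg = self.config or DEFAULT_CONFIG
        records = frame_to_records(X)
        out = np.full(len(records), np.nan)
        for i, rec in enumerate(records):
            if self.score == "chads2":
                out[i] = compute_chads2(rec, cfg).total
                continue
            if self.score == "cmca":
                out[i] = compute_cmca_score(rec, cfg).total
                continue
            infarct = classify_infarct(rec.territories, rec.mca_fraction, cfg)
            if infarct is InfarctClass.NOT_LHI:
                continue  # stays NaN: mortality scores undefined below LHI
            if self.score == "mortality1":
                out[i] = compute_mortality_score1(rec, infarct, cfg).total
            else:
                out[i] = compute_mortality_score2(rec, infarct, cfg).total
        return out.reshape(-1, 1)

    def get_feature_names_out(self, input_features=None):
        return np.array([f"{self.score}_total"])


class CutpointClassifier(ClassifierMixin, BaseEstimator):
    """Dichotomize an ordinal score at the Youden-optimal cutoff.

    ``fit(X, y)`` builds the empirical ROC of the score (column 0 of X)
    against the binary label, selects the threshold maximizing
    J = sensitivity + specificity - 1 (ties toward higher sensitivity,
    then lower threshold), and stores:

    - ``cutoff_`` — the selected threshold
    - ``auc_`` — trapezoidal AUC
    - ``roc_`` — the full :class:`~lhirisk.stats.RocResult`
    - ``sensitivity_``, ``specificity_`` — at ``cutoff_``

    ``predict`` applies the inclusive rule ``score >= cutoff_``.
    """

    def __init__(self, cutoff: float | None = None):
        self.cutoff = cutoff  # fixed cutoff; None -> select by Youden's J

    def fit(self, X, y):
        scores = self._scores(X)
        y = np.asarray(y, dtype=int)
        roc = roc_curve(scores, y)
        self.roc_ = roc
        self.auc_ = roc.auc
        self.cutoff_ = float(self.cutoff) if self.cutoff is not None else best_cutoff(roc)
        self.sensitivity_, self.specificity_ = sens_spec(scores, y, self.cutoff_)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "cutoff_")
        return (self._scores(X) >= self.cutoff_).astype(int)

    def decision_function(self, X):
        check_is_fitted(self, "cutoff_")
        return self._scores(X) - self.cutoff_

    @staticmethod
    def _scores(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2:
            if arr.shape[1] != 1:
                raise ValueError("expected a single score column")
            arr = arr[:, 0]
        if np.isnan(arr).any():
            raise ValueError("scores contain NaN (e.g. NOT_LHI mortality scores); "
                             "filter those rows first")
        return arr
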