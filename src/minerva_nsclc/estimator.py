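"""scikit-learn-style estimator wrapping the screen -> weight -> score ->
classify pipeline, so the signature composes with sklearn model selection.

``X`` is the binary patients x features alteration table (a pandas DataFrame
or a :class:`~minerva_nsclc.io.FeatureMatrix`); ``y`` is the clinical table
(a DataFrame or a list of :class:`~minerva_nsclc.io.ClinicalRecord`) and is
only required when weights are refit from the data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigError
from .io import FeatureMatrix
from .score import (
    MinervaWeights,
    ScoreResult,
    classify,
    compute_score,
    published_weights,
    refit_weights,
)
from .screen import screen_interactions

__all__ = ["MinervaScorer"]


def _as_feature_matrix(X) -> FeatureMatrix:
    if isinstance(X, FeatureMatrix):
        return X
    frame = pd.DataFrame(X)
    return FeatureMatrix(
        list(frame.index), list(frame.columns), frame.to_numpy(dtype=np.int8)
    )


class MinervaScorer(BaseEstimator):
    """Composite treatment-preference scorer for two-arm survival cohorts.

    Parameters
    ----------
    weights : "published", "refit", or a feature_id -> weight mapping.
        "published" uses the five-marker signature's published interaction
        z weights; "refit" screens ``X`` against ``y`` for treatment
        interactions and uses the z of the selected features.
    alpha, min_altered, ties, endpoint : screening settings (refit mode).
    cutoffs : (low, high) score cutoffs; HTP iff score <= low,
        CP iff score >= high, TP otherwise.

    Attributes
    ----------
    weights_ : MinervaWeights — fitted weight map.
    results_ : list of InteractionResult (refit mode only).
    selected_ : the selected screening results (refit mode only).
    feature_ids_ : weighted feature ids.
    """

    def __init__(
        self,
        weights="published",
        alpha: float = 0.05,
        min_altered: int = 10,
        cutoffs: tuple = (-0.5, 0.5),
        endpoint: str = "dfs",
        ties: str = "efron",
    ):
        self.weights = weights
        self.alpha = alpha
        self.min_altered = min_altered
        self.cutoffs = cutoffs
        self.endpoint = endpoint
        self.ties = ties

    def fit(self, X, y=None):
        low, high = self.cutoffs
        if not low < high:
            raise ConfigError(f"cutoffs must satisfy low < high, got {self.cutoffs}")
        if self.weights == "published":
            self.weights_ = published_weights()
        elif self.weights == "refit":
            if y is None:
                raise ConfigError("weights='refit' requires the clinical table as y")
            fm = _as_feature_matrix(X)
            self.results_, self.selected_ = screen_interactions(
                fm,
                y,
                endpoint=self.endpoint,
                alpha=self.alpha,
                min_altered=self.min_altered,
                ties=self.ties,
            )
            self.weights_ = refit_weights(self.selected_)
        elif isinstance(self.weights, dict):
            self.weights_ = MinervaWeights(dict(self.weights), source="custom")
        else:
            raise ConfigError(
                f"weights must be 'published', 'refit' or a mapping, got {self.weights!r}"
            )
        self.feature_ids_ = list(self.weights_.weights)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per-patient composite scores (lower = greater relative TKI benefit)."""
        check_is_fitted(self, "weights_")
        return compute_score(self.weights_, _as_feature_matrix(X)).scores.to_numpy()

    def transform(self, X) -> np.ndarray:
        return self.decision_function(X).reshape(-1, 1)

    def predict(self, X) -> np.ndarray:
        """Subgroup labels: HTP / TP / CP."""
        return self.score_result(X).subgroups.to_numpy()

    def score_result(self, X) -> ScoreResult:
        """Scores plus subgroup labels as a :class:`ScoreResult`."""
        check_is_fitted(self, "weights_")
        scored = compute_score(self.weights_, _as_feature_matrix(X))
        return classify(scored, self.cutoffs)
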