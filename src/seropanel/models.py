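"""The five-algorithm classification suite behind a uniform fit/score contract.

Algorithms: GLM (unpenalized logistic regression), RIDGE (L2-penalized
logistic regression with the penalty chosen by internal cross-validation),
SVM (RBF support vector machine, margins mapped to [0, 1] by a logistic
sigmoid — a monotone calibration, so rank-based metrics are unaffected),
RF (random forest, score = fraction of trees voting case), and GLM_RF (the
unweighted mean of the GLM and RF probability-scale scores, pairing a linear
and a non-linear learner).

Every algorithm is exposed through :class:`PanelClassifier`, a scikit-learn
estimator, so the search pipeline is algorithm-agnostic and the suite
composes with sklearn model selection.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .exceptions import ConfigurationError

#: The closed set of supported algorithms.
ALGORITHMS: tuple[str, ...] = ("GLM", "RIDGE", "SVM", "RF", "GLM_RF")


def combine_glm_rf(glm_scores: np.ndarray, rf_scores: np.ndarray) -> np.ndarray:
    """Element-wise mean of aligned GLM and RF probability-scale scores."""
    glm_scores = np.asarray(glm_scores, dtype=float)
    rf_scores = np.asarray(rf_scores, dtype=float)
    if glm_scores.shape != rf_scores.shape:
        raise ConfigurationError(
            f"score length mismatch: {glm_scores.shape} vs {rf_scores.shape}"
        )
    return 0.5 * (glm_scores + rf_scores)


class PanelClassifier(ClassifierMixin, BaseEstimator):
    """One of the five classification algorithms, with probability-scale scores.

    Parameters
    ----------
    algorithm:
        ``GLM``, ``RIDGE``, ``SVM``, ``RF`` or ``GLM_RF``.
    ridge_C:
        Fixed inverse L2 penalty for RIDGE.  ``None`` (default) selects the
        penalty from ``ridge_Cs`` by stratified 3-fold CV (AUC criterion) on
        the training data.
    n_trees, rf_max_features:
        Random forest size and per-split feature sampling.
    svm_C, svm_gamma, svm_tol, svm_max_iter:
        RBF-SVM regularization, kernel width and solver stopping controls
        (``svm_max_iter=-1`` means unlimited).
    feature_cap:
        Hard upper bound on the number of features accepted at fit time.
    random_state:
        Seed for the stochastic learners; fits are deterministic given it.

    Fitted scores live in [0, 1] with higher values more case-like; use
    :meth:`score_samples` (``predict_proba`` gives the usual two-column form).
    """

    def __init__(
        self,
        algorithm: str = "GLM",
        *,
        ridge_C: float | None = None,
        ridge_Cs: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0),
        n_trees: int = 500,
        rf_max_features: str | float = "sqrt",
        svm_C: float = 1.0,
        svm_gamma: str | float = "scale",
        svm_tol: float = 1e-3,
        svm_max_iter: int = -1,
        feature_cap: int = 64,
        random_state: int | None = None,
    ):
        self.algorithm = algorithm
        self.ridge_C = ridge_C
        self.ridge_Cs = ridge_Cs
        self.n_trees = n_trees
        self.rf_max_features = rf_max_features
        self.svm_C = svm_C
        self.svm_gamma = svm_gamma
        self.svm_tol = svm_tol
        self.svm_max_iter = svm_max_iter
        self.feature_cap = feature_cap
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _standardize_fit(self, X: np.ndarray) -> np.ndarray:
        self.center_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
        self.scale_ = scale
        return (X - self.center_) / self.scale_

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center_) / self.scale_

    def _make_glm(self) -> LogisticRegression:
        # Unpenalized logistic link; Newton solver converges in few iterations
        # for n >> p and is capped so separable data cannot spin.
        return LogisticRegression(C=np.inf, solver="newton-cholesky", max_iter=100)

    def _make_rf(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.rf_max_features,
            random_state=self.random_state,
            n_jobs=1,
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y) -> "PanelClassifier":
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if classes.size != 2:
            raise ConfigurationError(
                f"training labels must contain exactly two classes, got {classes}"
            )
        if X.shape[1] > self.feature_cap:
            raise ConfigurationError(
                f"{X.shape[1]} features exceeds feature_cap={self.feature_cap}"
            )
        counts = np.bincount((y == classes[1]).astype(int))
        if counts.min() < 2:
            raise ConfigurationError("need at least 2 subjects per class to fit")
        self.classes_ = classes
        y01 = (y == classes[1]).astype(int)
        self.n_features_in_ = X.shape[1]

        with warnings.catch_warnings():
            # Near-separable training folds trip harmless solver warnings
            # (unpenalized logistic weights diverge; Newton solve is
            # ill-conditioned); scores remain deterministic and valid.
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", FutureWarning)
            if self.algorithm == "GLM":
                self.model_ = self._make_glm().fit(X, y01)
            elif self.algorithm == "RIDGE":
                Xs = self._standardize_fit(X)
                if self.ridge_C is not None:
                    self.model_ = LogisticRegression(
                        C=self.ridge_C, solver="newton-cholesky", max_iter=100
                    ).fit(Xs, y01)
                else:
                    cv = min(3, counts.min())
                    self.model_ = LogisticRegressionCV(
                        Cs=list(self.ridge_Cs),
                        solver="lbfgs",
                        cv=cv,
                        scoring="roc_auc",
                        max_iter=1000,
                    ).fit(Xs, y01)
            elif self.algorithm == "SVM":
                Xs = self._standardize_fit(X)
                self.model_ = SVC(
                    kernel="rbf",
                    C=self.svm_C,
                    gamma=self.svm_gamma,
                    tol=self.svm_tol,
                    max_iter=self.svm_max_iter,
                ).fit(Xs, y01)
            elif self.algorithm == "RF":
                self.model_ = self._make_rf().fit(X, y01)
            else:  # GLM_RF
                self.glm_ = self._make_glm().fit(X, y01)
                self.rf_ = self._make_rf().fit(X, y01)
                self.model_ = None
        return self

    def score_samples(self, X) -> np.ndarray:
        """Probability-scale score per row: in [0, 1], higher = more case-like."""
        check_is_fitted(self, "classes_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[1] != self.n_features_in_:
            raise ConfigurationError(
                f"feature schema mismatch: fitted on {self.n_features_in_} "
                f"columns, got {X.shape[1]}"
            )
        if X.shape[0] == 0:
            return np.empty(0)
        if self.algorithm in ("GLM", "RIDGE"):
            Xp = X if self.algorithm == "GLM" else self._standardize(X)
            return self.model_.predict_proba(Xp)[:, 1]
        if self.algorithm == "SVM":
            return expit(self.model_.decision_function(self._standardize(X)))
        if self.algorithm == "RF":
            return self.model_.predict_proba(X)[:, 1]
        return combine_glm_rf(
            self.glm_.predict_proba(X)[:, 1], self.rf_.predict_proba(X)[:, 1]
        )

    def predict_proba(self, X) -> np.ndarray:
        s = self.score_samples(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.score_samples(X) > 0.5).astype(int)]
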