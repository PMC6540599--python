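"""Repeatability, PCA and LDA for sensor-array feature matrices.

``compute_rsd`` quantifies replicate repeatability as the relative
standard deviation of each sensor's steady-state response mean across
replicate measurements of one grade; an array whose sensors all stay
below 5 % is considered repeatable.

``PrincipalComponents`` / ``pca_fit`` project min-max-normalized,
mean-centered feature matrices onto their principal axes for a first
look at between-grade structure.  ``FisherDiscriminant`` / ``lda_fit``
fit Fisher linear discriminant directions (between- over within-class
scatter) and classify by the nearest class centroid in discriminant
space; six grades yield exactly five discriminant functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.preprocessing import MinMaxScaler

from .errors import DegenerateInputError
from .features import FeatureMatrix, steady_state_mean
from .preprocessing import apply_minmax, fit_minmax
from .samples import SampleSet

__all__ = [
    "RSDTable",
    "PCAResult",
    "LDAResult",
    "compute_rsd",
    "PrincipalComponents",
    "FisherDiscriminant",
    "pca_fit",
    "lda_fit",
    "LDA_PROTOCOLS",
]

logger = logging.getLogger(__name__)

LDA_PROTOCOLS = ("resubstitution", "loo_cv")


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RSDTable:
    """Per-sensor relative standard deviation (percent) for one grade."""

    grade: int
    t0: float
    rsd: dict[str, float]

    def max(self) -> float:
        return max(self.rsd.values())


def compute_rsd(sample_set: SampleSet, grade: int, t0: float = 29.0) -> RSDTable:
    """RSD (%) of the steady-state mean across replicates of ``grade``.

    Uses the sample standard deviation (denominator n-1).  Raw traces
    are used; smoothing barely moves a late-window mean.
    """
    replicates = sample_set.of_grade(grade)
    if len(replicates) < 2:
        raise ValueError(
            f"grade {grade} has {len(replicates)} replicate(s); need at least 2"
        )
    rsd: dict[str, float] = {}
    for sensor_id in sample_set.sensor_ids:
        means = np.array(
            [steady_state_mean(rec.trace(sensor_id), t0) for rec in replicates]
        )
        center = means.mean()
        if center == 0:
            raise DegenerateInputError(
                f"sensor {sensor_id}: zero mean steady-state response"
            )
        rsd[sensor_id] = float(100.0 * means.std(ddof=1) / center)
    return RSDTable(grade=int(grade), t0=float(t0), rsd=rsd)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Loadings, scores and explained-variance ratios of a fitted PCA."""

    loadings: np.ndarray  # (k_eff, p)
    scores: np.ndarray  # (n, k_eff)
    explained_variance_ratio: np.ndarray  # (n_components,), zero-padded
    all_ratios: np.ndarray  # over every available component; sums to 1
    columns: list[str]


class PrincipalComponents(BaseEstimator, TransformerMixin):
    """PCA on min-max-normalized, column-centered feature data.

    Component signs are fixed by making each component's
    largest-magnitude loading positive, so results are deterministic.

    Parameters
    ----------
    n_components : int
        Number of components to expose; requesting more than the data's
        rank zero-pads the explained-variance ratios.
    normalize : bool
        Min-max normalize columns before centering (the analysis
        convention for mixed-unit feature blocks).
    """

    def __init__(self, n_components: int = 2, normalize: bool = True):
        self.n_components = n_components
        self.normalize = normalize

    def fit(self, X, y=None) -> "PrincipalComponents":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-d matrix with more than one row")
        if self.n_components < 1 or self.n_components > X.shape[1]:
            raise ValueError("n_components must be in 1..n_columns")
        if self.normalize:
            self.scaler_ = MinMaxScaler().fit(X)
            Xn = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xn = X
        pca = PCA(n_components=None).fit(Xn)
        components = pca.components_.copy()
        flip = np.sign(
            components[np.arange(components.shape[0]),
                       np.argmax(np.abs(components), axis=1)]
        )
        flip[flip == 0] = 1.0
        components *= flip[:, None]
        self.mean_ = pca.mean_
        self.components_ = components
        self.all_ratios_ = pca.explained_variance_ratio_
        k = min(self.n_components, components.shape[0])
        self.scores_ = (Xn - self.mean_) @ components[:k].T
        ratios = np.zeros(self.n_components)
        ratios[: self.all_ratios_.size] = self.all_ratios_[: self.n_components]
        self.explained_variance_ratio_ = ratios
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        k = min(self.n_components, self.components_.shape[0])
        return (X - self.mean_) @ self.components_[:k].T


def pca_fit(fm: FeatureMatrix, n_components: int = 2) -> PCAResult:
    """Fit PCA to a feature matrix (normalized, centered); see
    :class:`PrincipalComponents`."""
    model = PrincipalComponents(n_components=n_components).fit(fm.values)
    k = min(n_components, model.components_.shape[0])
    return PCAResult(
        loadings=model.components_[:k],
        scores=model.scores_,
        explained_variance_ratio=model.explained_variance_ratio_,
        all_ratios=model.all_ratios_,
        columns=list(fm.columns),
    )


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------


@dataclass
class LDAResult:
    """Fisher discriminant functions plus classification diagnostics."""

    discriminant_functions: np.ndarray  # (n_functions, p)
    scores: np.ndarray  # (n, n_functions), full-data coordinates
    confusion_matrix: np.ndarray  # rows = true class, cols = predicted
    accuracy: float
    protocol: str
    classes: np.ndarray

    @property
    def n_functions(self) -> int:
        return self.discriminant_functions.shape[0]


class FisherDiscriminant(BaseEstimator, ClassifierMixin):
    """Fisher LDA with nearest-centroid classification in discriminant space.

    Directions are eigenvectors of within-class-scatter^-1 times
    between-class scatter; at most (n_classes - 1) exist.  A singular
    within-class scatter triggers ridge (shrinkage) regularization with
    a logged warning.
    """

    def __init__(self, ridge: float = 1e-4):
        self.ridge = ridge

    def fit(self, X, y) -> "FisherDiscriminant":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least two classes")
        if np.any(counts < 2):
            small = classes[counts < 2].tolist()
            raise ValueError(f"classes with fewer than two samples: {small}")
        try:
            lda = LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
        except np.linalg.LinAlgError:
            logger.warning(
                "within-class scatter is singular; refitting with ridge "
                "shrinkage %g", self.ridge
            )
            lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=self.ridge).fit(X, y)
        self.classes_ = lda.classes_
        n_functions = min(classes.size - 1, X.shape[1])
        self.scalings_ = lda.scalings_[:, :n_functions]
        self.functions_ = self.scalings_.T
        self.centroids_ = lda.means_ @ self.scalings_
        return self

    def transform(self, X) -> np.ndarray:
        # no centering: nearest-centroid distances are shift-invariant
        return np.asarray(X, dtype=float) @ self.scalings_

    def predict(self, X) -> np.ndarray:
        Z = self.transform(X)
        d2 = ((Z[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _loo_predictions(fm: FeatureMatrix) -> np.ndarray:
    """Leave-one-out predictions; scaler and LDA refitted in every fold."""
    n = fm.n_samples
    preds = np.empty(n, dtype=fm.grades.dtype)
    for i in range(n):
        train_idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        scaler = MinMaxScaler().fit(fm.values[train_idx])
        clf = FisherDiscriminant().fit(
            scaler.transform(fm.values[train_idx]), fm.grades[train_idx]
        )
        preds[i] = clf.predict(scaler.transform(fm.values[i : i + 1]))[0]
    return preds


def lda_fit(fm: FeatureMatrix, protocol: str = "resubstitution") -> LDAResult:
    """Fit Fisher LDA to a feature matrix and report classification accuracy.

    ``resubstitution`` scores the training data itself (the convention
    used when a single campaign is analysed in full); ``loo_cv`` scores
    honest leave-one-out predictions instead.  Features are min-max
    normalized before fitting (within each fold for ``loo_cv``).
    """
    if protocol not in LDA_PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {LDA_PROTOCOLS}")
    normalized = apply_minmax(fm, fit_minmax(fm))
    clf = FisherDiscriminant().fit(normalized.values, normalized.grades)
    if protocol == "resubstitution":
        preds = clf.predict(normalized.values)
    else:
        preds = _loo_predictions(fm)
    classes = clf.classes_
    cm = confusion_matrix(fm.grades, preds, labels=classes)
    accuracy = float(np.trace(cm) / cm.sum())
    return LDAResult(
        discriminant_functions=clf.functions_,
        scores=clf.transform(normalized.values),
        confusion_matrix=cm,
        accuracy=accuracy,
        protocol=protocol,
        classes=classes,
    )
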