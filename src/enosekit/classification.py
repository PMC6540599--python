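"""Single-feature classifier benchmark.

For each of the six characteristic parameters, the per-sensor values
form a 10-dimensional input; each grade contributes ``train_per_class``
randomly chosen samples (default 21 of 30) to the training set and the
rest to the validation set.  Five classifiers — multilayer perceptron,
random forest, 3-nearest-neighbours, RBF support vector machine and
Gaussian naive Bayes — are fitted on min-max-normalized training
features (bounds fitted on the training split only) and scored on both
splits, yielding a feature x algorithm accuracy grid.

Hyperparameters not fixed by the protocol are held at documented
defaults: MLP with one hidden layer of 10 units and at most 1000
iterations, 100 trees for the forest, C = 1 with the scale bandwidth
heuristic for the SVM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import accuracy_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .features import FEATURE_CODES, FeatureConfig, FeatureMatrix, extract_features
from .io import dump_json
from .samples import SampleSet

__all__ = [
    "ALGORITHMS",
    "SplitSpec",
    "BenchmarkReport",
    "stratified_split",
    "make_classifier",
    "train_and_score",
    "run_benchmark",
]

ALGORITHMS = ("MLPNN", "RF", "KNN", "SVM", "NaiveBayes")


@dataclass(frozen=True)
class SplitSpec:
    """Stratified split: ``train_per_class`` samples of every grade train."""

    train_per_class: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train_per_class < 1:
            raise ValueError("train_per_class must be positive")


def _split_indices(grades: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    train, validation = [], []
    for cls in np.unique(grades):
        idx = np.flatnonzero(grades == cls)
        if idx.size < spec.train_per_class + 1:
            raise ValueError(
                f"class {cls} has {idx.size} samples; need at least "
                f"{spec.train_per_class + 1} for a {spec.train_per_class}-per-class split"
            )
        perm = rng.permutation(idx)
        train.append(perm[: spec.train_per_class])
        validation.append(perm[spec.train_per_class :])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(validation))


def stratified_split(
    fm: FeatureMatrix, spec: SplitSpec
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split a feature matrix into disjoint train/validation parts."""
    train_idx, val_idx = _split_indices(fm.grades, spec)
    return fm.take(train_idx), fm.take(val_idx)


def make_classifier(algorithm: str, seed: int = 0, hyper: dict | None = None):
    """Construct one of the five benchmark classifiers."""
    hyper = dict(hyper or {})
    if algorithm == "MLPNN":
        defaults = dict(hidden_layer_sizes=(10,), max_iter=1000, random_state=seed)
        return MLPClassifier(**{**defaults, **hyper})
    if algorithm == "RF":
        defaults = dict(n_estimators=100, random_state=seed)
        return RandomForestClassifier(**{**defaults, **hyper})
    if algorithm == "KNN":
        defaults = dict(n_neighbors=3)
        return KNeighborsClassifier(**{**defaults, **hyper})
    if algorithm == "SVM":
        defaults = dict(kernel="rbf", C=1.0, gamma="scale")
        return SVC(**{**defaults, **hyper})
    if algorithm == "NaiveBayes":
        return GaussianNB(**hyper)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def train_and_score(
    train: FeatureMatrix,
    validation: FeatureMatrix,
    algorithm: str,
    seed: int = 0,
    hyper: dict | None = None,
) -> tuple[float, float]:
    """Fit one classifier and return (train %, validation %) accuracies.

    Normalization bounds are fitted on the training split only and
    applied unchanged to the validation split.
    """
    if train.columns != validation.columns:
        raise ValueError("train and validation matrices have different columns")
    if np.unique(train.grades).size < 2:
        raise ValueError("training split contains a single class")
    pipe = Pipeline(
        [("scale", MinMaxScaler()), ("clf", make_classifier(algorithm, seed, hyper))]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pipe.fit(train.values, train.grades)
    train_acc = 100.0 * accuracy_score(train.grades, pipe.predict(train.values))
    val_acc = 100.0 * accuracy_score(validation.grades, pipe.predict(validation.values))
    return float(train_acc), float(val_acc)


@dataclass
class BenchmarkReport:
    """feature_code x algorithm grid of {train, validation} accuracies (%)."""

    accuracies: dict[str, dict[str, dict[str, float]]]
    spec: SplitSpec = field(default_factory=SplitSpec)

    def __post_init__(self) -> None:
        for code, row in self.accuracies.items():
            for algo, cell in row.items():
                for kind, acc in cell.items():
                    if not 0.0 <= acc <= 100.0:
                        raise ValueError(
                            f"{code}/{algo}/{kind}: accuracy {acc} outside [0, 100]"
                        )

    def get(self, code: str, algorithm: str, kind: str = "validation") -> float:
        return self.accuracies[code][algorithm][kind]

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "split": {"train_per_class": self.spec.train_per_class, "seed": self.spec.seed},
            "accuracies": self.accuracies,
        }
        return dump_json(payload, path)


def run_benchmark(
    sample_set: SampleSet,
    spec: SplitSpec | None = None,
    codes: Sequence[str] | None = None,
    algorithms: Sequence[str] | None = None,
    feature_cfg: FeatureConfig | None = None,
) -> BenchmarkReport:
    """Run the full single-feature benchmark on one stratified split.

    The split of sample indices is drawn once and shared by every
    feature block, mirroring a campaign where the same physical samples
    are assigned to train or validation regardless of which feature is
    being scored.
    """
    spec = spec or SplitSpec()
    codes = list(codes) if codes is not None else list(FEATURE_CODES)
    algorithms = list(algorithms) if algorithms is not None else list(ALGORITHMS)
    unknown = [a for a in algorithms if a not in ALGORITHMS]
    if unknown:
        raise ValueError(f"unknown algorithms: {unknown}")
    fm = extract_features(sample_set, codes=codes, cfg=feature_cfg)
    train_idx, val_idx = _split_indices(fm.grades, spec)
    grid: dict[str, dict[str, dict[str, float]]] = {}
    for code in codes:
        block = fm.select_feature(code)
        train, validation = block.take(train_idx), block.take(val_idx)
        grid[code] = {}
        for algo in algorithms:
            train_acc, val_acc = train_and_score(train, validation, algo, seed=spec.seed)
            grid[code][algo] = {"train": train_acc, "validation": val_acc}
    return BenchmarkReport(accuracies=grid, spec=spec)
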