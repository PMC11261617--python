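"""Congruence-invariant shape features and tree-ensemble classification.

Reconstructed per-molecule shapes are encoded in features invariant under
rotation, translation, and reflection: the sorted pairwise distances plus
their sum (perimeter) and, for triangles, the Heron area.  Sorted distances
are a complete congruence invariant for three points and a near-complete one
for four.  A gradient-boosted tree ensemble is trained on a molecule-level
split, so accuracy is always reported on held-out molecules.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split

from .geometry import ReconstructedShape, pairwise_distances

_DEGENERATE_TOL = 1e-9


@dataclass(frozen=True)
class InvariantFeatures:
    distances: tuple   # sorted non-decreasing
    perimeter: float
    area: float        # Heron area for triangles, 0.0 otherwise
    degenerate: bool

    def vector(self) -> np.ndarray:
        return np.array(list(self.distances) + [self.perimeter, self.area])


def featurize(shape) -> InvariantFeatures:
    """Rigid-motion- and reflection-invariant encoding of a shape."""
    coords = shape.coords if isinstance(shape, ReconstructedShape) else np.asarray(shape, float)
    n = coords.shape[0]
    d = pairwise_distances(coords)
    iu = np.triu_indices(n, 1)
    dists = np.sort(d[iu])
    if dists[-1] < _DEGENERATE_TOL:
        k = len(dists)
        return InvariantFeatures(tuple(0.0 for _ in range(k)), 0.0, 0.0, True)
    perimeter = float(dists.sum())
    area = 0.0
    if n == 3:
        a, b, c = dists
        s = perimeter / 2.0
        area = float(np.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0)))
    return InvariantFeatures(tuple(float(x) for x in dists), perimeter, area, False)


def feature_matrix(shapes) -> np.ndarray:
    return np.vstack([featurize(s).vector() for s in shapes])


@dataclass
class ConfusionMatrix:
    """Row-normalized confusion matrix on held-out molecules."""

    labels: tuple
    fractions: np.ndarray  # rows sum to 1
    counts: np.ndarray
    overall_accuracy: float

    def __post_init__(self):
        rows = self.fractions.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("confusion-matrix rows must sum to 1")

    @property
    def per_class_accuracy(self) -> np.ndarray:
        return np.diag(self.fractions)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "fractions": self.fractions.tolist(),
            "counts": self.counts.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy.tolist(),
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.fractions, index=list(self.labels), columns=list(self.labels)).to_csv(
            path, sep="\t", float_format="%.4f"
        )


@dataclass
class TrainedClassifier:
    model: HistGradientBoostingClassifier
    confusion: ConfusionMatrix
    train_molecules: tuple
    test_molecules: tuple

    def predict(self, X) -> np.ndarray:
        return self.model.predict(np.asarray(X, float))


def train_classifier(X, y, molecule_ids=None, split_seed: int = 0,
                     test_fraction: float = 0.3, max_depth: int = 3) -> TrainedClassifier:
    """Train a gradient-boosted tree ensemble with a molecule-level held-out
    split and return it with the held-out confusion matrix.

    Each molecule contributes one feature row; the train/test partition is on
    molecules, so no molecule appears on both sides.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if molecule_ids is None:
        molecule_ids = np.arange(len(y))
    molecule_ids = np.asarray(molecule_ids)
    if not (len(X) == len(y) == len(molecule_ids)):
        raise ValueError("X, y, molecule_ids must have equal length")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise ValueError(f"classes with fewer than 2 molecules: {bad.tolist()}")
    if np.any(counts < 10):
        warnings.warn("some classes have fewer than 10 molecules; accuracy will be noisy")
    uniq_mols, first_row = np.unique(molecule_ids, return_index=True)
    mol_label = y[first_row]
    train_mols, test_mols = train_test_split(
        uniq_mols, test_size=test_fraction, random_state=split_seed, stratify=mol_label
    )
    train_idx = np.flatnonzero(np.isin(molecule_ids, train_mols))
    test_idx = np.flatnonzero(np.isin(molecule_ids, test_mols))
    assert not set(molecule_ids[train_idx]) & set(molecule_ids[test_idx])
    model = HistGradientBoostingClassifier(max_depth=max_depth, random_state=split_seed)
    model.fit(X[train_idx], y[train_idx])
    y_pred = model.predict(X[test_idx])
    counts_mat = _sk_confusion(y[test_idx], y_pred, labels=classes)
    row_sums = counts_mat.sum(axis=1, keepdims=True)
    fractions = counts_mat / np.maximum(row_sums, 1)
    # rows with no held-out molecules cannot occur under stratified splitting,
    # but normalize defensively
    for i in np.flatnonzero(row_sums.ravel() == 0):
        fractions[i, i] = 1.0
    overall = float((y_pred == y[test_idx]).mean())
    cm = ConfusionMatrix(tuple(classes.tolist()), fractions, counts_mat, overall)
    return TrainedClassifier(model, cm, tuple(np.unique(molecule_ids[train_idx]).tolist()),
                             tuple(np.unique(molecule_ids[test_idx]).tolist()))
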