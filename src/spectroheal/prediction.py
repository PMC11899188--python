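"""Probability maps over the PC1-PC2 plane from a small neural classifier.

A feed-forward network is trained on the 2-D PCA scores with their three
group labels (healthy, preoperative CRC, postoperative CRC) and then queried
on a dense grid covering the score plane, yielding a per-class probability
surface.  The map turns the qualitative reading of a score plot into an
explicit statement: a region where the postoperative class has high
probability, separate from both the healthy and the preoperative
high-probability regions, is the operational form of a distinct
"healing state".

The architecture is deliberately small (two 16-unit ReLU layers, L2 1e-4,
softmax output) because the training set is ~40 points; with an L-BFGS solver
and a fixed seed the trained model, and therefore the map, is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier

__all__ = [
    "ClassifierSpec",
    "ProbabilityMap",
    "CLASS_ORDER",
    "train_classifier",
    "predict_grid",
    "probability_bands",
]

CLASS_ORDER = ("healthy", "crc_pre", "crc_post")


@dataclass(frozen=True)
class ClassifierSpec:
    hidden_layers: tuple[int, ...] = (16, 16)
    activation: str = "relu"  # "relu" | "tanh"
    max_iter: int = 2000
    seed: int = 0
    l2_weight: float = 1e-4

    def __post_init__(self) -> None:
        if not self.hidden_layers or any(w <= 0 for w in self.hidden_layers):
            raise ValueError("need at least one hidden layer of positive width")
        if self.activation not in ("relu", "tanh"):
            raise ValueError("activation must be 'relu' or 'tanh'")
        if self.l2_weight < 0:
            raise ValueError("l2_weight must be >= 0")


@dataclass
class TrainedClassifier:
    model: MLPClassifier
    spec: ClassifierSpec
    classes: tuple[str, ...]
    train_accuracy: float
    final_loss: float

    def predict_proba(self, points: np.ndarray) -> np.ndarray:
        """Class probabilities in CLASS_ORDER for rows of ``points``."""
        raw = self.model.predict_proba(np.asarray(points, dtype=float))
        order = [list(self.model.classes_).index(c) for c in self.classes]
        return raw[:, order]


@dataclass
class ProbabilityMap:
    pc1_axis: np.ndarray
    pc2_axis: np.ndarray
    probs: np.ndarray  # len(pc1) x len(pc2) x n_classes, CLASS_ORDER
    classes: tuple[str, ...]
    spec: ClassifierSpec


def train_classifier(
    scores: np.ndarray,
    labels: Sequence[str],
    spec: ClassifierSpec | None = None,
) -> TrainedClassifier:
    """Fit the softmax network on 2-D scores.

    Requires at least 2 examples of each of the three classes; training uses
    all points (no held-out split — the map is a description of the training
    geometry, not a generalization claim; use leave-one-out separately for
    that).
    """
    if spec is None:
        spec = ClassifierSpec()
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array of PC1/PC2 coordinates")
    present = {str(c) for c in np.unique(y)}
    missing = set(CLASS_ORDER) - present
    if missing:
        raise ValueError(f"missing classes in labels: {sorted(missing)}")
    for c in CLASS_ORDER:
        if int((y == c).sum()) < 2:
            raise ValueError(f"class {c!r} needs at least 2 examples")
    model = MLPClassifier(
        hidden_layer_sizes=spec.hidden_layers,
        activation=spec.activation,
        alpha=spec.l2_weight,
        max_iter=spec.max_iter,
        random_state=spec.seed,
        solver="lbfgs",
    )
    model.fit(X, y)
    acc = float(model.score(X, y))
    return TrainedClassifier(
        model=model,
        spec=spec,
        classes=CLASS_ORDER,
        train_accuracy=acc,
        final_loss=float(model.loss_),
    )


def loo_accuracy(
    scores: np.ndarray, labels: Sequence[str], spec: ClassifierSpec | None = None
) -> float:
    """Leave-one-out accuracy — a diagnostic, not part of the map."""
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    hits = 0
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        try:
            clf = train_classifier(X[keep], y[keep], spec)
        except ValueError:  # a class lost its second example
            continue
        pred = clf.model.predict(X[i : i + 1])[0]
        hits += int(pred == y[i])
    return hits / len(y)


def predict_grid(
    clf: TrainedClassifier,
    bounds: tuple[float, float, float, float] | None = None,
    resolution: tuple[int, int] = (200, 200),
    train_scores: np.ndarray | None = None,
    margin: float = 0.10,
) -> ProbabilityMap:
    """Evaluate class probabilities on a regular PC1-PC2 grid.

    Without explicit ``bounds`` the grid is the bounding box of
    ``train_scores`` expanded by ``margin`` on each side.
    """
    n1, n2 = resolution
    if n1 < 1 or n2 < 1:
        raise ValueError("resolution must be at least 1 x 1")
    if bounds is None:
        if train_scores is None:
            raise ValueError("provide bounds or train_scores")
        ts = np.asarray(train_scores, dtype=float)
        lo1, hi1 = float(ts[:, 0].min()), float(ts[:, 0].max())
        lo2, hi2 = float(ts[:, 1].min()), float(ts[:, 1].max())
        pad1, pad2 = margin * (hi1 - lo1), margin * (hi2 - lo2)
        bounds = (lo1 - pad1, hi1 + pad1, lo2 - pad2, hi2 + pad2)
    lo1, hi1, lo2, hi2 = bounds
    pc1 = np.linspace(lo1, hi1, n1) if n1 > 1 else np.array([(lo1 + hi1) / 2])
    pc2 = np.linspace(lo2, hi2, n2) if n2 > 1 else np.array([(lo2 + hi2) / 2])
    g1, g2 = np.meshgrid(pc1, pc2, indexing="ij")
    pts = np.column_stack([g1.ravel(), g2.ravel()])
    probs = clf.predict_proba(pts).reshape(len(pc1), len(pc2), len(clf.classes))
    return ProbabilityMap(
        pc1_axis=pc1, pc2_axis=pc2, probs=probs, classes=clf.classes, spec=clf.spec
    )


def probability_bands(
    pmap: ProbabilityMap,
    class_name: str,
    bands: Sequence[float] = (0.30, 0.70),
) -> np.ndarray:
    """Band label per grid cell for one class's probability surface.

    With thresholds (t1, .., tk) cell band b means probability in
    [t_b, t_{b+1}) — lower edge inclusive, upper exclusive — so with the
    default (0.3, 0.7): 0 = low (< 0.3), 1 = medium [0.3, 0.7), 2 = high
    (>= 0.7).
    """
    thr = list(bands)
    if any(b2 <= b1 for b1, b2 in zip(thr[:-1], thr[1:])) or not thr:
        raise ValueError("band thresholds must be strictly ascending")
    if thr[0] < 0 or thr[-1] > 1:
        raise ValueError("band thresholds must lie in [0, 1]")
    if class_name not in pmap.classes:
        raise ValueError(f"unknown class {class_name!r}; have {pmap.classes}")
    p = pmap.probs[:, :, pmap.classes.index(class_name)]
    return np.digitize(p, thr, right=False)
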