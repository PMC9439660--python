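"""Six-class tile classification behind a pluggable backend interface.

The original workflow fine-tunes a large convolutional network on GPU;
at desk scale the same interface is served by classical backends working
on the 21 color/texture/morphometry tile features:

* ``forest`` (default): a random forest grown in increments with early
  stopping on validation accuracy;
* ``mlp``: a small multilayer perceptron on standardized features,
  trained by epoch-wise ``partial_fit`` with validation early stopping.

Both are deterministic given their seed and comfortably exceed the
benchmark accuracy targets on the synthetic textures.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_curve
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .constants import CLASS_LABELS, CLASS_TO_CODE, N_CLASSES
from .preprocess import Tile
from .signatures import tile_feature_matrix

__all__ = [
    "TrainConfig",
    "TileClassifier",
    "EvalReport",
    "split_dataset",
    "train_classifier",
    "evaluate",
]


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(
    tiles: Sequence[Tile],
    ratios: Tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
) -> Tuple[List[Tile], List[Tile], List[Tile]]:
    """Stratified train/validation/test split (default 8:1:1), seeded."""
    by_class: Dict[str, List[Tile]] = {}
    for t in tiles:
        if t.label is None:
            raise ValueError("split_dataset requires labeled tiles")
        by_class.setdefault(t.label, []).append(t)
    for label, group in by_class.items():
        if len(group) < 3:
            raise ValueError(f"class {label!r} has {len(group)} tiles; need ≥ 3")
    rng = np.random.default_rng(seed)
    total = float(sum(ratios))
    train: List[Tile] = []
    val: List[Tile] = []
    test: List[Tile] = []
    for label in sorted(by_class):
        group = by_class[label]
        order = rng.permutation(len(group))
        n = len(group)
        n_val = max(1, int(n * ratios[1] / total))
        n_test = max(1, int(n * ratios[2] / total))
        idx_val = order[:n_val]
        idx_test = order[n_val : n_val + n_test]
        idx_train = order[n_val + n_test :]
        val.extend(group[i] for i in idx_val)
        test.extend(group[i] for i in idx_test)
        train.extend(group[i] for i in idx_train)
    return train, val, test


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    backend: str = "forest"
    seed: int = 0
    tile_side: int = 96
    # forest backend
    trees_per_round: int = 50
    max_trees: int = 400
    # mlp backend
    hidden: Tuple[int, ...] = (64, 32)
    max_epochs: int = 200
    # early stopping: rounds/epochs without val-accuracy improvement.
    # The MLP needs a long fuse: its validation accuracy moves in plateaus
    # of ~10 epochs between improvements.
    patience: int = 3
    mlp_patience: int = 25
    min_delta: float = 1e-3


@dataclass
class TileClassifier:
    """A fitted backend plus the metadata needed to apply it consistently."""

    backend: str
    estimator: object
    scaler: Optional[StandardScaler]
    trained_classes: List[str]
    tile_side: int
    class_labels: Tuple[str, ...] = CLASS_LABELS

    def _features(self, pixel_stack: np.ndarray) -> np.ndarray:
        x = tile_feature_matrix(list(pixel_stack))
        if self.scaler is not None:
            x = self.scaler.transform(x)
        return x

    def predict_proba_pixels(self, pixel_stack: np.ndarray) -> np.ndarray:
        """Class probabilities, columns in the fixed six-class order."""
        raw = self.estimator.predict_proba(self._features(pixel_stack))
        out = np.zeros((raw.shape[0], N_CLASSES))
        for j, cls_idx in enumerate(self.estimator.classes_):
            out[:, CLASS_TO_CODE[self.trained_classes[int(cls_idx)]]] = raw[:, j]
        return out

    def predict_proba(self, tiles: Sequence[Tile]) -> np.ndarray:
        return self.predict_proba_pixels(np.stack([t.pixels for t in tiles]))

    def predict_labels(self, tiles: Sequence[Tile]) -> List[str]:
        p = self.predict_proba(tiles)
        return [CLASS_LABELS[i] for i in p.argmax(axis=1)]

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str) -> "TileClassifier":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a TileClassifier")
        return model

    def sidecar(self) -> dict:
        return {
            "backend": self.backend,
            "class_order": list(self.class_labels),
            "tile_side": self.tile_side,
        }


def _encode(tiles: Sequence[Tile]) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    labels = [t.label for t in tiles]
    classes = sorted(set(labels))
    for lbl in classes:
        if lbl not in CLASS_LABELS:
            raise ValueError(f"unknown tile label {lbl!r}")
    y = np.array([classes.index(lbl) for lbl in labels])
    x = tile_feature_matrix(tiles)
    return x, y, classes


def train_classifier(
    train: Sequence[Tile],
    val: Sequence[Tile],
    config: Optional[TrainConfig] = None,
) -> TileClassifier:
    """Fit the configured backend with validation-based early stopping."""
    config = config or TrainConfig()
    if len(val) == 0:
        raise ValueError("validation set is empty")
    if len(train) == 0:
        raise ValueError("training set is empty")
    x_train, y_train, classes = _encode(train)
    xv = tile_feature_matrix(val)
    yv = np.array([classes.index(t.label) if t.label in classes else -1 for t in val])

    if config.backend == "forest":
        est = RandomForestClassifier(
            n_estimators=0, warm_start=True, random_state=config.seed, n_jobs=1
        )
        best, stale = -np.inf, 0
        while est.n_estimators < config.max_trees:
            est.n_estimators += config.trees_per_round
            est.fit(x_train, y_train)
            acc = float((est.predict(xv) == yv).mean())
            if acc > best + config.min_delta:
                best, stale = acc, 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
        scaler = None
    elif config.backend == "mlp":
        scaler = StandardScaler().fit(x_train)
        xs, xvs = scaler.transform(x_train), scaler.transform(xv)
        est = MLPClassifier(
            hidden_layer_sizes=config.hidden,
            random_state=config.seed,
            max_iter=1,
            warm_start=False,
        )
        est.partial_fit(xs, y_train, classes=np.unique(y_train))
        rng = np.random.default_rng(config.seed)
        best, stale = -np.inf, 0
        for _ in range(config.max_epochs):
            order = rng.permutation(len(xs))
            est.partial_fit(xs[order], y_train[order])
            acc = float((est.predict(xvs) == yv).mean())
            if acc > best + config.min_delta:
                best, stale = acc, 0
            else:
                stale += 1
                if stale >= config.mlp_patience:
                    break
    else:
        raise ValueError(f"unknown backend {config.backend!r}")
    return TileClassifier(
        backend=config.backend,
        estimator=est,
        scaler=scaler,
        trained_classes=classes,
        tile_side=config.tile_side,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Accuracy, row-normalized confusion and one-vs-rest PR per class."""

    overall_accuracy: float
    confusion: np.ndarray                  # 6×6, rows normalized by support
    zero_support: List[str]                # classes absent from the test set
    per_class_pr: Dict[str, dict]          # label -> {precision, recall, auc}

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "confusion": self.confusion.tolist(),
            "zero_support": self.zero_support,
            "pr_auc": {k: v["auc"] for k, v in self.per_class_pr.items()},
        }


def pr_auc(precision: np.ndarray, recall: np.ndarray) -> float:
    """Area under the precision-recall curve by trapezoid over recall.

    Integrates along the curve path (as returned by
    ``precision_recall_curve``, reversed so recall ascends); tied recall
    values contribute zero width rather than being re-paired by a sort.
    """
    p = np.asarray(precision)[::-1]
    r = np.asarray(recall)[::-1]
    return float(np.trapezoid(p, r))


def evaluate(model: TileClassifier, test: Sequence[Tile]) -> EvalReport:
    """Accuracy, row-normalized confusion matrix and per-class PR curves."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    for t in test:
        if t.label not in CLASS_LABELS:
            raise ValueError(f"label {t.label!r} outside the six classes")
    probs = model.predict_proba(test)
    y_true = np.array([CLASS_TO_CODE[t.label] for t in test])
    y_pred = probs.argmax(axis=1)
    acc = float((y_true == y_pred).mean())
    confusion = np.zeros((N_CLASSES, N_CLASSES))
    for t_code, p_code in zip(y_true, y_pred):
        confusion[t_code, p_code] += 1
    support = confusion.sum(axis=1)
    zero_support = [CLASS_LABELS[i] for i in range(N_CLASSES) if support[i] == 0]
    with np.errstate(invalid="ignore"):
        confusion = np.where(support[:, None] > 0, confusion / support[:, None], 0.0)
    per_class: Dict[str, dict] = {}
    for code, label in enumerate(CLASS_LABELS):
        y_bin = (y_true == code).astype(int)
        if y_bin.sum() == 0:
            per_class[label] = {"precision": [], "recall": [], "auc": float("nan")}
            continue
        prec, rec, _ = precision_recall_curve(y_bin, probs[:, code])
        per_class[label] = {
            "precision": prec.tolist(),
            "recall": rec.tolist(),
            "auc": pr_auc(prec, rec),
        }
    return EvalReport(acc, confusion, zero_support, per_class)
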