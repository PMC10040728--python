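"""Fidgety-movement classification from keypoint feature matrices.

The model is deliberately shallow: one temporal convolution (64 filters
of length 7 over the frame axis, spanning all coordinate channels)
followed by one or two fully connected layers, with batch normalization
and 10% dropout after the convolutional and FC blocks, and a single
sigmoid output. The question it serves is not peak accuracy but whether
head keypoints carry indispensable information for the FM+/FM-
decision, so the same architecture is trained on features with (250x42)
and without (250x32) the head channels and the two cross-validated
accuracy distributions are compared with a two-sample t-test.

Training follows a restart/early-stop protocol: ``val_fraction`` of the
training data is split off for validation stop (no improvement in
validation accuracy for ``patience`` consecutive epochs ends a run),
the run is repeated ``restarts`` times from independent
initializations, and the model with the highest validation accuracy is
kept. Evaluation is stratified k-fold cross-validation reporting the
mean fold accuracy with a t-based 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._net import (
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    Network,
    ReLU,
    accuracy,
    train_early_stop,
)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters of the shallow conv + FC model."""

    n_filters: int = 64
    filter_len: int = 7
    fc_sizes: tuple[int, ...] = (200, 100)
    dropout: float = 0.10
    batchnorm: bool = True

    def __post_init__(self) -> None:
        if not 1 <= len(self.fc_sizes) <= 2:
            raise ValueError("fc_sizes must list 1 or 2 fully connected widths")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.filter_len < 1 or self.filter_len % 2 == 0:
            raise ValueError("filter_len must be odd and >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (Adam + binary cross-entropy throughout)."""

    batch_size: int = 32
    patience: int = 10
    val_fraction: float = 1.0 / 8.0
    restarts: int = 10
    max_epochs: int = 200
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if min(self.batch_size, self.patience, self.restarts, self.max_epochs) < 1:
            raise ValueError("all protocol counts must be positive")


@dataclass
class FoldResults:
    """Per-fold accuracies of one feature condition, with mean and CI."""

    fold_accuracies: np.ndarray      # in [0, 1]
    condition_with_head: bool
    spec: NetworkSpec

    @property
    def mean(self) -> float:
        """Mean fold accuracy, percent."""
        return float(np.mean(self.fold_accuracies)) * 100.0

    @property
    def ci95(self) -> float:
        """Half-width of the t-based 95% CI of the mean, percent."""
        k = len(self.fold_accuracies)
        if k < 2:
            return float("nan")
        sd = float(np.std(self.fold_accuracies, ddof=1))
        return float(stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k)) * 100.0

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_percent": self.mean,
            "ci95_percent": self.ci95,
            "ci_method": "t-distribution, df=k-1",
            "with_head": self.condition_with_head,
            "spec": {
                "n_filters": self.spec.n_filters,
                "filter_len": self.spec.filter_len,
                "fc_sizes": list(self.spec.fc_sizes),
                "dropout": self.spec.dropout,
                "batchnorm": self.spec.batchnorm,
            },
        }


def build_network(spec: NetworkSpec, input_shape: tuple[int, int],
                  rng: np.random.Generator) -> Network:
    """Assemble the layer stack for a given input shape.

    conv -> [BN] -> ReLU -> dropout -> flatten, then per FC width:
    dense -> [BN] -> ReLU -> dropout, then a single-logit dense head.
    Parameter initialization is drawn from ``rng``, so two builds from
    the same seed are identical.
    """
    t, c = input_shape
    if t < spec.filter_len:
        raise ValueError(
            f"input has {t} frames, shorter than filter length {spec.filter_len}"
        )
    layers: list = [Conv1D(c, spec.n_filters, spec.filter_len, rng)]
    if spec.batchnorm:
        layers.append(BatchNorm(spec.n_filters))
    layers += [ReLU(), Dropout(spec.dropout), Flatten()]
    width = (t - spec.filter_len + 1) * spec.n_filters
    for h in spec.fc_sizes:
        layers.append(Dense(width, h, rng))
        if spec.batchnorm:
            layers.append(BatchNorm(h))
        layers += [ReLU(), Dropout(spec.dropout)]
        width = h
    layers.append(Dense(width, 1, rng, scale="glorot"))
    return Network(layers)


class FidgetyNetClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn estimator wrapping the shallow conv + FC network.

    ``X`` is a float array of shape (n_snippets, n_frames, n_channels)
    as produced by :class:`fidgetkit.preprocess.KeypointFeaturizer`;
    ``y`` holds binary labels (FM- = 0, FM+ = 1, or any two values).

    Parameters mirror :class:`NetworkSpec` and :class:`TrainConfig`;
    ``random_state`` seeds everything (validation split, weight
    initialization, restarts, batch shuffling, dropout).
    """

    def __init__(self, n_filters: int = 64, filter_len: int = 7,
                 fc_sizes: tuple[int, ...] = (200, 100), dropout: float = 0.10,
                 batchnorm: bool = True, batch_size: int = 32,
                 patience: int = 10, val_fraction: float = 1.0 / 8.0,
                 restarts: int = 10, max_epochs: int = 200,
                 learning_rate: float = 1e-3, random_state: int | None = None):
        self.n_filters = n_filters
        self.filter_len = filter_len
        self.fc_sizes = fc_sizes
        self.dropout = dropout
        self.batchnorm = batchnorm
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.restarts = restarts
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _spec(self) -> NetworkSpec:
        return NetworkSpec(self.n_filters, self.filter_len, tuple(self.fc_sizes),
                           self.dropout, self.batchnorm)

    def _cfg(self) -> TrainConfig:
        return TrainConfig(self.batch_size, self.patience, self.val_fraction,
                           self.restarts, self.max_epochs, self.learning_rate)

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (n_snippets, n_frames, n_channels), got shape {X.shape}"
            )
        return X

    def fit(self, X, y) -> "FidgetyNetClassifier":
        X = self._validate_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"training set must contain exactly 2 classes, got {len(self.classes_)}"
            )
        y01 = (y == self.classes_[1]).astype(float)
        spec, cfg = self._spec(), self._cfg()
        master = np.random.default_rng(self.random_state)
        split_seed = int(master.integers(2**31))
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y01, test_size=cfg.val_fraction, stratify=y01,
            random_state=split_seed,
        )
        if len(np.unique(y_tr)) < 2:
            raise ValueError("training split lost a class; dataset too small")
        best_net, best_acc = None, -1.0
        for _restart in range(cfg.restarts):
            rng = np.random.default_rng(master.integers(2**31))
            net = build_network(spec, X.shape[1:], rng)
            val_acc = train_early_stop(
                net, X_tr, y_tr, X_val, y_val, rng,
                batch_size=cfg.batch_size, patience=cfg.patience,
                max_epochs=cfg.max_epochs, lr=cfg.learning_rate,
            )
            if val_acc > best_acc:
                best_net, best_acc = net, val_acc
        self.network_ = best_net
        self.validation_accuracy_ = best_acc
        self.n_features_in_ = X.shape[1] * X.shape[2]
        self.input_shape_ = X.shape[1:]
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate_X(X)
        p1 = self.network_.predict_proba(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_with_restarts(
    X: np.ndarray, y: np.ndarray,
    spec: NetworkSpec | None = None,
    cfg: TrainConfig | None = None,
    seed: int | None = None,
) -> FidgetyNetClassifier:
    """Fit the classifier under the restart/early-stop protocol."""
    spec = spec or NetworkSpec()
    cfg = cfg or TrainConfig()
    clf = FidgetyNetClassifier(
        n_filters=spec.n_filters, filter_len=spec.filter_len,
        fc_sizes=spec.fc_sizes, dropout=spec.dropout, batchnorm=spec.batchnorm,
        batch_size=cfg.batch_size, patience=cfg.patience,
        val_fraction=cfg.val_fraction, restarts=cfg.restarts,
        max_epochs=cfg.max_epochs, learning_rate=cfg.learning_rate,
        random_state=seed,
    )
    return clf.fit(X, y)


def cross_validate(
    X: np.ndarray, y: np.ndarray,
    spec: NetworkSpec | None = None,
    cfg: TrainConfig | None = None,
    k: int = 5,
    seed: int | None = None,
    with_head: bool = True,
) -> FoldResults:
    """Stratified k-fold cross-validation of the classifier.

    Each fold trains on (k-1)/k of the data (with the validation split
    carved out of that) and is scored on the held-out fold; reports the
    per-fold accuracies with their mean and t-based 95% CI. Fold
    membership and every training seed derive from ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    spec = spec or NetworkSpec()
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    master = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(master.integers(2**31)))
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        clf = train_with_restarts(
            X[train_idx], y[train_idx], spec, cfg,
            seed=int(master.integers(2**31)),
        )
        accs.append(clf.score(X[test_idx], y[test_idx]))
    return FoldResults(
        fold_accuracies=np.asarray(accs),
        condition_with_head=with_head,
        spec=spec,
    )


def ablation_grid(
    datasets: dict[bool, tuple[np.ndarray, np.ndarray]],
    grid: list[NetworkSpec],
    cfg: TrainConfig | None = None,
    k: int = 5,
    seed: int | None = None,
) -> list[dict]:
    """Cross-validate every spec under both head conditions.

    ``datasets`` maps with_head -> (X, y). Returns one row per
    (spec, condition) with the best row per condition flagged, the way
    accuracy tables bold their column-best entries.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    master = np.random.default_rng(seed)
    rows = []
    for with_head, (X, y) in datasets.items():
        group = []
        for spec in grid:
            res = cross_validate(X, y, spec, cfg, k=k,
                                 seed=int(master.integers(2**31)),
                                 with_head=with_head)
            group.append(res.to_dict())
        best = int(np.argmax([r["mean_percent"] for r in group]))
        for i, row in enumerate(group):
            row["best_in_group"] = i == best
        rows += group
    return rows


def compare_conditions(a: FoldResults, b: FoldResults) -> dict:
    """Two-sample t-test between two conditions' fold accuracies.

    Two-sided; equal fold counts required. Identical zero-variance
    vectors yield p = 1 by convention.
    """
    fa, fb = np.asarray(a.fold_accuracies), np.asarray(b.fold_accuracies)
    if len(fa) != len(fb):
        raise ValueError("conditions must use the same number of folds")
    if np.std(fa) == 0 and np.std(fb) == 0:
        if np.mean(fa) == np.mean(fb):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float("inf") * np.sign(np.mean(fa) - np.mean(fb)), 0.0
    else:
        t_stat, p = stats.ttest_ind(fa, fb)
    return {
        "t": float(t_stat),
        "p": float(p),
        "significant": bool(p < 0.05),
        "mean_a_percent": a.mean,
        "mean_b_percent": b.mean,
    }
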