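"""Class-weighted SGD training, 4-fold cross-validation, and metrics.

Training follows the published recipe: stochastic gradient descent
(learning rate 0.021, momentum 0.5) on stratified batches of 46
six-fold-augmented patches, class-weighted softmax cross-entropy,
dropout 0.3 after the first fully connected layer, 50 epochs, and
4-fold cross-validation with the best validation score per criterion.

Metrics: ACA is the overall correct-prediction rate of the test set;
MCA is the unweighted mean of the per-class correct-classification
rates CCR_k, so it is insensitive to class imbalance.  A uniform
random predictor has expected ACA = MCA = 25 % for four classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .model import ModelSpec, Network, default_spec
from .nn import MomentumSGD, weighted_cross_entropy
from .patches import PatchSet, augment_set

N_CLASSES = 4


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.021
    momentum: float = 0.5
    batch_size: int = 46
    epochs: int = 50
    folds: int = 4
    dropout_rate: float = 0.3
    augment: bool = True
    transform_labels: bool = True
    select_by: str = "mca"      # model-selection criterion: "mca" | "aca"
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.select_by not in ("mca", "aca"):
            raise ValueError("select_by must be 'mca' or 'aca'")

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class Metrics:
    aca: float                      # percent
    mca: float                      # percent
    ccr: tuple[float, ...]          # per-class percent (nan for empty classes)

    def __str__(self) -> str:
        ccr = ", ".join(f"{c:.1f}" for c in self.ccr)
        return f"ACA {self.aca:.2f}%  MCA {self.mca:.2f}%  CCR [{ccr}]"


def class_weights(counts: np.ndarray, n: int = N_CLASSES) -> np.ndarray:
    """w_k = ΣN / (n · N_k): up-weights rare directions so each class
    contributes equally to the loss in expectation."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size != n:
        raise ValueError(f"expected {n} class counts")
    if np.any(counts <= 0):
        raise ValueError("every class needs at least one training sample")
    return counts.sum() / (n * counts)


def confusion(y_true: np.ndarray, y_pred: np.ndarray, n: int = N_CLASSES) -> np.ndarray:
    """n×n count matrix, rows = true class, columns = predicted class."""
    return _sk_confusion(y_true, y_pred, labels=np.arange(n))


def metrics_from_confusion(cm: np.ndarray) -> Metrics:
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    aca = 100.0 * np.trace(cm) / total if total else float("nan")
    row = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ccr = 100.0 * np.diag(cm) / row
    if np.any(row == 0):
        warnings.warn("empty class in test set; its CCR is excluded from MCA")
    mca = float(np.nanmean(ccr))
    return Metrics(aca=float(aca), mca=mca, ccr=tuple(ccr))


def evaluate(model: Network, test: PatchSet, batch_size: int = 64
             ) -> tuple[np.ndarray, Metrics]:
    """Confusion matrix and ACA/MCA of a model on a patch set."""
    if len(test) == 0:
        raise ValueError("empty test set")
    preds = predict(model, test.patches, batch_size)
    cm = confusion(test.labels, preds)
    return cm, metrics_from_confusion(cm)


def predict(model: Network, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = []
    for i in range(0, len(patches), batch_size):
        out.append(model.predict_label(patches[i:i + batch_size]))
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def make_batches(labels: np.ndarray, batch_size: int,
                 rng: np.random.Generator) -> list[np.ndarray]:
    """Stratified batch index lists.

    Each batch receives each class in proportion to its share of the
    training set (within ±1 sample), with per-epoch shuffling both of
    samples within classes and of positions within batches.
    """
    n = labels.size
    n_batches = max(1, int(np.ceil(n / batch_size)))
    slots: list[list[int]] = [[] for _ in range(n_batches)]
    for k in np.unique(labels):
        idx = np.nonzero(labels == k)[0]
        idx = idx[rng.permutation(idx.size)]
        base, rem = divmod(idx.size, n_batches)
        extra = rng.permutation(n_batches)[:rem]
        counts = np.full(n_batches, base)
        counts[extra] += 1
        pos = 0
        for b in range(n_batches):
            slots[b].extend(idx[pos:pos + counts[b]])
            pos += counts[b]
    return [np.array(s)[rng.permutation(len(s))] for s in slots if s]


def _effective_spec(spec: ModelSpec, config: TrainConfig) -> ModelSpec:
    """The architecture actually trained: config.dropout_rate wins."""
    if config.dropout_rate == spec.dropout_rate:
        return spec
    return ModelSpec(layers=spec.layers, input_px=spec.input_px,
                     input_channels=spec.input_channels,
                     dropout_rate=config.dropout_rate)


@dataclass
class FoldResult:
    """Per-epoch validation metrics and the best checkpoints of one fold."""

    history: list[Metrics]
    best_epoch_mca: int
    best_epoch_aca: int
    best_mca: float
    best_aca: float
    best_weights_mca: dict[str, np.ndarray]
    best_weights_aca: dict[str, np.ndarray]
    train_loss: list[float] = field(default_factory=list)


def train_fold(
    train: PatchSet,
    val: PatchSet,
    spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
    model_seed: int = 0,
) -> FoldResult:
    """Train one fold and record validation metrics every epoch.

    Augmentation (when enabled) is applied to the training fold only.
    The per-criterion best epoch is kept, matching the "best score of
    each criterion over the epochs" selection rule.
    """
    config = config or TrainConfig()
    spec = _effective_spec(spec or default_spec(), config)
    model = Network.build(spec, seed=model_seed)
    opt = MomentumSGD(config.learning_rate, config.momentum)

    tset = augment_set(train, config.transform_labels) if config.augment else train
    weights = class_weights(np.bincount(train.labels, minlength=N_CLASSES))
    X = tset.patches[..., None]          # NHWC
    y = tset.labels

    result = FoldResult([], -1, -1, -np.inf, -np.inf, {}, {})
    for epoch in range(config.epochs):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xE0, epoch)))
        losses = []
        for batch_idx in make_batches(y, config.batch_size, rng):
            logits = model.logits(X[batch_idx], train=True, rng=rng)
            loss, dlogits = weighted_cross_entropy(logits, y[batch_idx], weights)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss became {loss} at epoch {epoch}; lower the learning rate"
                )
            model.backward(dlogits)
            opt.step(model.layers)
            losses.append(loss)
        result.train_loss.append(float(np.mean(losses)))
        _, m = evaluate(model, val)
        result.history.append(m)
        if m.mca > result.best_mca:
            result.best_mca, result.best_epoch_mca = m.mca, epoch
            result.best_weights_mca = model.copy_weights()
        if m.aca > result.best_aca:
            result.best_aca, result.best_epoch_aca = m.aca, epoch
            result.best_weights_aca = model.copy_weights()
    return result


def select_checkpoint(fold_results: list[FoldResult],
                      select_by: str = "mca") -> tuple[int, int, float]:
    """Pick the (fold, epoch) with the best validation score.

    Ties resolve to the earlier epoch, then the lower fold index.
    Returns (fold, epoch, score).
    """
    best = (-np.inf, np.inf, np.inf)
    sel_fold = sel_epoch = 0
    for fold, fr in enumerate(fold_results):
        if select_by == "mca":
            score, epoch = fr.best_mca, fr.best_epoch_mca
        else:
            score, epoch = fr.best_aca, fr.best_epoch_aca
        if (score, -epoch, -fold) > best:
            best = (score, -epoch, -fold)
            sel_fold, sel_epoch = fold, epoch
    return sel_fold, sel_epoch, best[0]


@dataclass
class CVResult:
    model: Network                  # the selected checkpoint
    fold_results: list[FoldResult]
    selected_fold: int
    selected_epoch: int
    selected_score: float
    config: TrainConfig
    spec: ModelSpec


def cross_validate(
    pool: PatchSet,
    spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
) -> CVResult:
    """Stratified k-fold CV; returns the best (fold, epoch) checkpoint.

    Selection is by validation MCA by default (``config.select_by``);
    ties resolve to the earlier epoch, then the lower fold index.
    """
    config = config or TrainConfig()
    spec = _effective_spec(spec or default_spec(), config)
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    fold_results = []
    for tr_idx, va_idx in skf.split(pool.patches, pool.labels):
        fold = len(fold_results)
        fold_results.append(
            train_fold(pool.subset(tr_idx), pool.subset(va_idx), spec, config,
                       model_seed=config.seed + fold)
        )
    sel_fold, sel_epoch, sel_score = select_checkpoint(fold_results,
                                                       config.select_by)
    model = Network.build(spec, seed=config.seed + sel_fold)
    fr = fold_results[sel_fold]
    model.load_state_dict(
        fr.best_weights_mca if config.select_by == "mca" else fr.best_weights_aca
    )
    return CVResult(model, fold_results, sel_fold, sel_epoch, sel_score, config, spec)


# ---------------------------------------------------------------------------
# Model/Results front-end

class DirectionClassifier:
    """Direction-prediction CNN bound to a labelled patch dataset.

    Thin modelling front-end: construct from data, call :meth:`fit` to
    run cross-validated training, and work with the returned
    :class:`DirectionResults`.

    Parameters
    ----------
    patches : (N, S, S) float array in [0, 1]
    labels : (N,) int array of direction quadrants (0 UR, 1 UL, 2 LL, 3 LR)
    spec : architecture, defaults to the 14-layer stack sized to S
    config : training hyperparameters
    """

    def __init__(self, patches: np.ndarray, labels: np.ndarray,
                 spec: ModelSpec | None = None, config: TrainConfig | None = None):
        patches = np.asarray(patches, dtype=np.float32)
        labels = np.asarray(labels, dtype=np.int64)
        if patches.ndim != 3 or patches.shape[1] != patches.shape[2]:
            raise ValueError("patches must be (N, S, S)")
        self.data = PatchSet(patches, labels, np.arange(len(labels)), np.zeros(len(labels)))
        self.spec = spec or default_spec(input_px=patches.shape[1])
        self.config = config or TrainConfig()

    @classmethod
    def from_patchset(cls, pset: PatchSet, spec: ModelSpec | None = None,
                      config: TrainConfig | None = None) -> "DirectionClassifier":
        obj = cls.__new__(cls)
        obj.data = pset
        obj.spec = spec or default_spec(input_px=pset.patches.shape[1])
        obj.config = config or TrainConfig()
        return obj

    def fit(self) -> "DirectionResults":
        cv = cross_validate(self.data, self.spec, self.config)
        return DirectionResults(self, cv)


class DirectionResults:
    """Fitted cross-validation results; carries the selected network."""

    def __init__(self, classifier: DirectionClassifier, cv: CVResult):
        self.model_info = classifier
        self.cv = cv
        self.network = cv.model

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return predict(self.network, np.asarray(patches, dtype=np.float32))

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        return self.network.forward(np.asarray(patches, dtype=np.float32))

    def evaluate(self, test: PatchSet) -> tuple[np.ndarray, Metrics]:
        return evaluate(self.network, test)

    def summary(self) -> str:
        cv, cfg = self.cv, self.cv.config
        lines = [
            "Direction-prediction CNN — cross-validation summary",
            "=" * 55,
            f"pool size: {len(self.model_info.data)}   "
            f"classes: {np.bincount(self.model_info.data.labels, minlength=4).tolist()}",
            f"folds: {cfg.folds}   epochs: {cfg.epochs}   batch: {cfg.batch_size}   "
            f"lr: {cfg.learning_rate}   momentum: {cfg.momentum}",
            f"augmentation: {'6-fold geometric' if cfg.augment else 'off'}   "
            f"dropout: {cfg.dropout_rate}",
            f"parameters: {cv.model.parameter_count():,}",
            "-" * 55,
        ]
        for i, fr in enumerate(cv.fold_results):
            lines.append(
                f"fold {i}: best MCA {fr.best_mca:6.2f}% @ epoch {fr.best_epoch_mca:3d}"
                f"   best ACA {fr.best_aca:6.2f}% @ epoch {fr.best_epoch_aca:3d}"
            )
        lines.append("-" * 55)
        lines.append(
            f"selected: fold {cv.selected_fold}, epoch {cv.selected_epoch} "
            f"(validation {cfg.select_by.upper()} {cv.selected_score:.2f}%)"
        )
        return "\n".join(lines)
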