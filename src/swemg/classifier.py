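"""Residual CNN over the 16 x 31 x 125 tensor, split protocol, training
and evaluation for the eleven swallowing actions.

The network treats the tensor as a 16-channel image of 31 segments x 125
points: three convolutional stages, each an identity-shortcut residual
block, with 2x2 max pooling after the first two stages; then two fully
connected layers of 512 nodes and a softmax head of length 11.  Training
minimizes cross-entropy with Adam; the checkpoint with the best
validation accuracy is kept and test metrics are reported from it.

The split protocol is recording-level stratified shuffling with all
subjects pooled ("scrambled"), 60/20/20 by default.  Splitting at
recording granularity avoids leakage between overlapping windows of one
recording.

A deterministic non-neural fallback (multinomial logistic regression on
per-channel RMS features) ships alongside for quick sanity analyses.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from swemg.nn import (
    Adam,
    Dense,
    Dropout,
    Flatten,
    Layer,
    MaxPool,
    ReLU,
    ResidualBlock,
    cross_entropy_grad,
    softmax,
)
from swemg.segmentation import segment, to_model_input
from swemg.simulate import ActionLabel, Recording

__all__ = [
    "ClassifierConfig",
    "SplitSpec",
    "TrainReport",
    "SwallowNet",
    "split_corpus",
    "build_model",
    "corpus_to_tensors",
    "train",
    "evaluate",
    "RmsLogisticBaseline",
]

LABELS = list(ActionLabel)
LABEL_TO_INDEX = {lab: i for i, lab in enumerate(LABELS)}


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and optimization settings of the residual CNN."""

    n_classes: int = 11
    in_channels: int = 16
    conv_widths: tuple[int, int, int] = (16, 32, 64)
    kernel_size: int = 3
    fc_nodes: int = 512
    pool_shape: tuple[int, int] = (2, 5)
    lr: float = 2e-3
    epochs: int = 40
    batch_size: int = 16
    patience: int = 12
    dropout: float = 0.2
    weight_decay: float = 1e-4
    augment_shift_segments: int = 4
    tta_shift_segments: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_widths) != 3:
            raise ValueError("exactly three convolutional stages are required")
        if self.n_classes < 2 or self.fc_nodes < 1:
            raise ValueError("invalid head configuration")


@dataclass(frozen=True)
class SplitSpec:
    """Recording-level scrambled stratified split."""

    train_frac: float = 0.60
    val_frac: float = 0.20
    test_frac: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train_frac, self.val_frac, self.test_frac) <= 0:
            raise ValueError("all three partitions must be non-empty fractions")


@dataclass
class TrainReport:
    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: np.ndarray  # (n_classes, n_classes) counts, rows = truth
    split_sizes: tuple[int, int, int]
    config: ClassifierConfig | None = None
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "confusion": self.confusion.tolist(),
            "split_sizes": list(self.split_sizes),
            "train_loss": self.train_loss,
            "val_accuracy": self.val_accuracy,
        }


class SplitError(ValueError):
    pass


def split_corpus(
    corpus: list[Recording], spec: SplitSpec = SplitSpec()
) -> tuple[list[Recording], list[Recording], list[Recording]]:
    """Stratified scrambled split of whole recordings into train/val/test.

    Recordings of each class are shuffled (all subjects pooled) and cut
    at the configured fractions; every class must land in every
    partition.  Deterministic in the spec's seed.
    """
    if not corpus:
        raise SplitError("corpus is empty")
    rng = np.random.default_rng(spec.seed)
    by_class: dict[ActionLabel, list[int]] = {}
    for i, rec in enumerate(corpus):
        by_class.setdefault(rec.label, []).append(i)

    train_idx, val_idx, test_idx = [], [], []
    for label in sorted(by_class, key=lambda l: l.value):
        idx = np.array(by_class[label])
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(spec.train_frac * n))
        n_val = int(round(spec.val_frac * n))
        parts = (idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :])
        if any(len(p) == 0 for p in parts):
            raise SplitError(
                f"class {label.value} has {n} recordings, too few to cover all three "
                "partitions; collect more repetitions or merge classes"
            )
        train_idx.extend(parts[0])
        val_idx.extend(parts[1])
        test_idx.extend(parts[2])
    return ([corpus[i] for i in train_idx], [corpus[i] for i in val_idx], [corpus[i] for i in test_idx])


class SwallowNet:
    """The residual CNN; forward/backward over the layer graph."""

    def __init__(self, cfg: ClassifierConfig, input_hw: tuple[int, int] = (31, 125)):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3 = cfg.conv_widths
        h, w = input_hw
        ph, pw = cfg.pool_shape
        self.block1 = ResidualBlock(cfg.in_channels, c1, rng, cfg.kernel_size)
        self.pool1 = MaxPool(ph, pw)
        self.block2 = ResidualBlock(c1, c2, rng, cfg.kernel_size)
        self.pool2 = MaxPool(ph, pw)
        self.block3 = ResidualBlock(c2, c3, rng, cfg.kernel_size)
        h3, w3 = h // ph // ph, w // pw // pw
        self.flatten = Flatten()
        self.fc1 = Dense(c3 * h3 * w3, cfg.fc_nodes, rng)
        self.relu_fc1 = ReLU()
        self.drop1 = Dropout(cfg.dropout, np.random.default_rng(cfg.seed + 17))
        self.fc2 = Dense(cfg.fc_nodes, cfg.fc_nodes, rng)
        self.relu_fc2 = ReLU()
        self.drop2 = Dropout(cfg.dropout, np.random.default_rng(cfg.seed + 29))
        self.head = Dense(cfg.fc_nodes, cfg.n_classes, rng)
        self._input_hw = input_hw

    # -- plumbing ----------------------------------------------------------
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for blk in (self.block1, self.block2, self.block3):
            out.extend(blk.sublayers())
        out += [self.fc1, self.fc2, self.head]
        return out

    def set_training(self, training: bool) -> None:
        for lay in self.layers():
            lay.training = training
        for blk in (self.block1, self.block2, self.block3):
            blk.training = training
        for drop in (self.drop1, self.drop2):
            drop.training = training

    def state_dict(self) -> list[dict[str, np.ndarray]]:
        state = [copy.deepcopy(lay.params) for lay in self.layers()]
        for lay in self.layers():
            if hasattr(lay, "running_mean"):
                state.append({"rm": lay.running_mean.copy(), "rv": lay.running_var.copy()})
        return state

    def load_state_dict(self, state: list[dict[str, np.ndarray]]) -> None:
        lays = self.layers()
        for lay, params in zip(lays, state):
            lay.params = copy.deepcopy(params)
        bn_states = state[len(lays):]
        bns = [lay for lay in lays if hasattr(lay, "running_mean")]
        for lay, s in zip(bns, bn_states):
            lay.running_mean = s["rm"].copy()
            lay.running_var = s["rv"].copy()

    # -- computation -------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels or x.shape[2:] != self._input_hw:
            raise ValueError(
                f"expected input (N, {self.cfg.in_channels}, {self._input_hw[0]}, "
                f"{self._input_hw[1]}), got {x.shape}"
            )
        x = x.astype(np.float32)
        x = self.pool1.forward(self.block1.forward(x))
        x = self.pool2.forward(self.block2.forward(x))
        x = self.block3.forward(x)
        x = self.drop1.forward(self.relu_fc1.forward(self.fc1.forward(self.flatten.forward(x))))
        x = self.drop2.forward(self.relu_fc2.forward(self.fc2.forward(x)))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.fc2.backward(self.relu_fc2.backward(self.drop2.backward(d)))
        d = self.flatten.backward(self.fc1.backward(self.relu_fc1.backward(self.drop1.backward(d))))
        d = self.block3.backward(d)
        d = self.block2.backward(self.pool2.backward(d))
        self.block1.backward(self.pool1.backward(d))

    def predict_proba(self, x: np.ndarray, batch_size: int = 64, tta: bool = True) -> np.ndarray:
        """Class probabilities; averages the softmax over small temporal
        shifts (deterministic test-time augmentation) unless disabled."""
        self.set_training(False)
        k = self.cfg.tta_shift_segments if tta else 0
        shifts = range(-k, k + 1) if k > 0 else (0,)
        total = np.zeros((len(x), self.cfg.n_classes))
        for sh in shifts:
            xs = np.roll(x, sh, axis=2) if sh else x
            out = [softmax(self.forward(xs[i : i + batch_size])) for i in range(0, len(xs), batch_size)]
            total += np.concatenate(out, axis=0)
        return total / len(list(shifts))

    def predict(self, x: np.ndarray, tta: bool = True) -> np.ndarray:
        return self.predict_proba(x, tta=tta).argmax(axis=1)


def build_model(cfg: ClassifierConfig = ClassifierConfig(), input_hw: tuple[int, int] = (31, 125)) -> SwallowNet:
    """Construct the residual CNN for a segments x points input plane."""
    return SwallowNet(cfg, input_hw)


def corpus_to_tensors(recordings: list[Recording]) -> tuple[np.ndarray, np.ndarray]:
    """Segment + normalize every recording into the model input array.

    Returns (X, y): X is (N, channels, segments, points) float32, y the
    integer class index per recording.
    """
    xs, ys = [], []
    for rec in recordings:
        xs.append(to_model_input(segment(rec)).astype(np.float32))
        ys.append(LABEL_TO_INDEX[rec.label])
    return np.stack(xs), np.array(ys, dtype=np.int64)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _report_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int, split_sizes: tuple[int, int, int]
) -> TrainReport:
    cm = _confusion(y_true, y_pred, n_classes)
    row = cm.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_class = np.where(row > 0, cm.diagonal() / np.maximum(row, 1), np.nan)
    names = [l.value for l in LABELS[:n_classes]] if n_classes <= len(LABELS) else [str(i) for i in range(n_classes)]
    return TrainReport(
        overall_accuracy=float(cm.trace() / max(cm.sum(), 1)),
        per_class_accuracy={name: float(a) for name, a in zip(names, per_class)},
        confusion=cm,
        split_sizes=split_sizes,
    )


def train(
    model: SwallowNet,
    partitions: tuple[list[Recording], list[Recording], list[Recording]],
    cfg: ClassifierConfig | None = None,
) -> TrainReport:
    """Fit the CNN and report test-set metrics from the best-validation
    checkpoint.  All randomness (init, batch order) is seeded via cfg."""
    cfg = cfg if cfg is not None else model.cfg
    train_recs, val_recs, test_recs = partitions
    if not train_recs or not val_recs or not test_recs:
        raise ValueError("all three partitions must be non-empty")
    x_train, y_train = corpus_to_tensors(train_recs)
    x_val, y_val = corpus_to_tensors(val_recs)
    x_test, y_test = corpus_to_tensors(test_recs)

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.layers(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    best_state, best_val, best_epoch = model.state_dict(), -1.0, -1
    losses: list[float] = []
    val_accs: list[float] = []

    for epoch in range(cfg.epochs):
        model.set_training(True)
        # cosine decay from lr to lr/10 stabilizes the late epochs
        opt.lr = cfg.lr * (0.55 + 0.45 * np.cos(np.pi * epoch / max(cfg.epochs - 1, 1)))
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb = x_train[idx]
            if cfg.augment_shift_segments > 0:
                # emulate onset variability: per-sample circular shift along the segment axis
                xb = xb.copy()
                shifts = rng.integers(-cfg.augment_shift_segments, cfg.augment_shift_segments + 1, len(idx))
                for j, sh in enumerate(shifts):
                    if sh:
                        xb[j] = np.roll(xb[j], int(sh), axis=1)
            logits = model.forward(xb)
            loss, dlogits = cross_entropy_grad(logits, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss (lr={cfg.lr})"
                )
            model.backward(dlogits.astype(np.float32))
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / len(order))

        # plain forward for the per-epoch checkpoint criterion; TTA only at test time
        val_acc = float((model.predict(x_val, tta=False) == y_val).mean())
        val_accs.append(val_acc)
        if val_acc > best_val:
            best_val, best_state, best_epoch = val_acc, model.state_dict(), epoch
        if val_acc >= 1.0 or epoch - best_epoch >= cfg.patience:
            break

    model.load_state_dict(best_state)
    y_pred = model.predict(x_test)
    report = _report_from_predictions(
        y_test, y_pred, cfg.n_classes, (len(train_recs), len(val_recs), len(test_recs))
    )
    report.config = cfg
    report.train_loss = losses
    report.val_accuracy = val_accs
    return report


def evaluate(model: SwallowNet, test_recs: list[Recording]) -> TrainReport:
    """Confusion matrix and accuracies of a trained model on a test set."""
    if not test_recs:
        raise ValueError("test partition is empty")
    x_test, y_test = corpus_to_tensors(test_recs)
    y_pred = model.predict(x_test)
    return _report_from_predictions(y_test, y_pred, model.cfg.n_classes, (0, 0, len(test_recs)))


class RmsLogisticBaseline:
    """Multinomial logistic regression on per-channel RMS + active-duration
    features; a fast deterministic reference point next to the CNN."""

    def __init__(self, seed: int = 0, max_iter: int = 5000):
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        self._clf = make_pipeline(
            StandardScaler(), LogisticRegression(C=10.0, max_iter=max_iter, random_state=seed)
        )

    @staticmethod
    def features(recordings: list[Recording]) -> np.ndarray:
        feats = []
        for rec in recordings:
            ch_rms = np.sqrt(np.mean(rec.data**2, axis=1))
            t = segment(rec)
            from swemg.segmentation import activity_mask

            mask = activity_mask(t)
            feats.append(np.concatenate([np.log1p(ch_rms), [mask.mean()]]))
        return np.array(feats)

    def fit(self, recordings: list[Recording]) -> "RmsLogisticBaseline":
        y = np.array([LABEL_TO_INDEX[r.label] for r in recordings])
        self._clf.fit(self.features(recordings), y)
        return self

    def score(self, recordings: list[Recording]) -> float:
        y = np.array([LABEL_TO_INDEX[r.label] for r in recordings])
        return float(self._clf.score(self.features(recordings), y))
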