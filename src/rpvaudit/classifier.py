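"""Two-phase transfer training and argmax inference.

The training contract mirrors fine-tuning practice with pretrained vision
backbones: phase 1 trains only the classification head for a fixed number of
epochs with the backbone frozen; phase 2 unfreezes everything except the
bottom ``frozen_bottom_layers`` and continues until validation accuracy
stops improving on its phase-2 running best (patience 1), after which the
best-epoch weights are restored.  The backbone is pluggable through
:class:`BackboneSpec`; the default is a small dense network
(:mod:`rpvaudit.network`) that runs in seconds on a CPU while exercising the
same freeze/early-stop/restore semantics as a large convolutional model.

:class:`SmallImageClassifier` is a scikit-learn estimator (``fit`` /
``predict`` / ``predict_proba``); the module-level :func:`train_classifier`
and :func:`predict` are thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import transform as sktransform
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import precision_recall_fscore_support

from .network import DenseNet


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture description: which layers exist, which stay frozen."""

    name: str
    n_layers: int
    frozen_bottom_layers: int
    input_size: int

    def __post_init__(self):
        if not 0 <= self.frozen_bottom_layers <= self.n_layers:
            raise ValueError("frozen_bottom_layers must lie in [0, n_layers]")


@dataclass
class TrainingOutcome:
    """Result of one two-phase fit.

    ``trace`` holds per-epoch validation accuracy over both phases
    (phase 1 first); ``best_epoch`` is the 0-based index of the maximum
    (earliest on ties), whose weights the model carries after restore.
    """

    model: "SmallImageClassifier"
    trace: list[float]
    best_epoch: int
    phase1_epochs: int
    stopped_early: bool
    config: dict = field(default_factory=dict)

    @property
    def phase2_trace(self) -> list[float]:
        return self.trace[self.phase1_epochs :]


def _resize_to_input(images, input_size: int) -> np.ndarray:
    """Stack images as flattened float vectors in [0, 1] at input_size^2 x 3."""
    out = np.empty((len(images), input_size * input_size * 3), dtype=np.float64)
    for i, img in enumerate(images):
        arr = np.asarray(img)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[:2] != (input_size, input_size):
            arr = sktransform.resize(
                arr.astype(np.float64) / 255.0,
                (input_size, input_size),
                order=1,
                anti_aliasing=True,
                preserve_range=True,
            )
        else:
            arr = arr.astype(np.float64) / 255.0 if arr.dtype == np.uint8 else arr
        out[i] = np.clip(arr, 0.0, 1.0).reshape(-1)
    return out


class SmallImageClassifier(BaseEstimator, ClassifierMixin):
    """Dense softmax image classifier trained with the two-phase protocol.

    Parameters
    ----------
    input_size : side length images are resized to before flattening.
    hidden_sizes : backbone layer widths; the head is the final softmax layer.
    frozen_bottom_layers : layers (counted from the input) never trained.
    phase1_epochs : head-only epochs with the whole backbone frozen.
    max_epochs : cap on phase-2 fine-tuning epochs.
    random_state : seed for weight initialisation and batch shuffling; two
        fits with the same seed and data are bit-identical.
    """

    def __init__(
        self,
        input_size: int = 32,
        hidden_sizes: tuple = (128, 64),
        frozen_bottom_layers: int = 1,
        phase1_epochs: int = 5,
        max_epochs: int = 100,
        learning_rate: float = 3e-3,
        batch_size: int = 32,
        random_state: int = 0,
    ):
        self.input_size = input_size
        self.hidden_sizes = hidden_sizes
        self.frozen_bottom_layers = frozen_bottom_layers
        self.phase1_epochs = phase1_epochs
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------------
    def backbone_spec(self) -> BackboneSpec:
        return BackboneSpec(
            name="tiny-dense",
            n_layers=len(self.hidden_sizes) + 1,
            frozen_bottom_layers=self.frozen_bottom_layers,
            input_size=self.input_size,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on training images; early stopping uses the validation set.

        ``X`` may be a 4-D array or a list of (H, W, 3) images of any sizes.
        Without an explicit validation set the training set doubles as one
        (useful only for smoke tests).
        """
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain at least 2 classes")
        if X_val is None:
            X_val, y_val = X, y
        y_val = np.asarray(y_val)
        unseen = set(np.unique(y_val)) - set(classes)
        if unseen:
            raise ValueError(f"validation labels not present in training set: {unseen}")

        self.classes_ = classes
        class_index = {c: i for i, c in enumerate(classes)}
        yt = np.array([class_index[c] for c in y])
        yv = np.array([class_index[c] for c in y_val])
        Xt = _resize_to_input(X, self.input_size)
        Xv = _resize_to_input(X_val, self.input_size)

        spec = self.backbone_spec()
        rng = np.random.default_rng(self.random_state)
        net = DenseNet(
            [Xt.shape[1], *self.hidden_sizes, classes.size], rng
        )
        n_layers = net.n_layers

        trace: list[float] = []
        best_acc, best_epoch, best_snapshot = -np.inf, -1, None

        def evaluate() -> float:
            pred = net.predict_proba(Xv).argmax(axis=1)
            return float((pred == yv).mean())

        def record(acc: float):
            nonlocal best_acc, best_epoch, best_snapshot
            trace.append(acc)
            if acc > best_acc:
                best_acc, best_epoch = acc, len(trace) - 1
                best_snapshot = net.get_weights()

        # phase 1: backbone frozen, head only, fixed epoch count
        head_only = [False] * (n_layers - 1) + [True]
        for e in range(self.phase1_epochs):
            net.train_epoch(
                Xt, yt, head_only, self.learning_rate, self.batch_size, rng,
                epoch_index=len(trace),
            )
            record(evaluate())

        # phase 2: unfreeze all but the bottom layers; fresh optimiser state;
        # stop at the first epoch that fails to improve the phase-2 running
        # best (patience 1), then restore the best weights seen overall
        net.reset_optimizer()
        finetune = [i >= spec.frozen_bottom_layers for i in range(n_layers)]
        phase2_best = -np.inf
        stopped_early = False
        for e in range(self.max_epochs):
            net.train_epoch(
                Xt, yt, finetune, self.learning_rate, self.batch_size, rng,
                epoch_index=len(trace),
            )
            acc = evaluate()
            record(acc)
            if acc > phase2_best:
                phase2_best = acc
            elif e > 0:
                stopped_early = True
                break

        if best_snapshot is not None:
            net.set_weights(best_snapshot)
        self.net_ = net
        self.training_trace_ = trace
        self.best_epoch_ = best_epoch
        self.stopped_early_ = stopped_early
        self.n_phase1_epochs_ = self.phase1_epochs
        return self

    # -- inference ---------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise ValueError("classifier is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self.net_.predict_proba(_resize_to_input(X, self.input_size))

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]

    def saliency_map(self, image) -> np.ndarray:
        """|gradient| of the predicted-class score w.r.t. the input pixels,
        summed over channels and upsampled to the image's own size.

        A simple gradient saliency stand-in for CAM-style methods; any other
        method producing a non-negative (H, W) map can be used with
        :func:`rpvaudit.preprocess.attention_on_specimen_fraction`.
        """
        self._check_fitted()
        x = _resize_to_input([image], self.input_size)[0]
        probs = self.net_.predict_proba(x[None, :])
        grad = self.net_.input_gradient(x, int(probs.argmax()))
        sal = np.abs(grad).reshape(self.input_size, self.input_size, 3).sum(axis=2)
        h, w = np.asarray(image).shape[:2]
        if (h, w) != (self.input_size, self.input_size):
            sal = sktransform.resize(sal, (h, w), order=1, preserve_range=True)
        return np.maximum(sal, 0.0)


# -- functional wrappers --------------------------------------------------------


def train_classifier(
    train_images, train_labels, val_images, val_labels, backbone=None, config=None
) -> TrainingOutcome:
    """Fit a classifier with the two-phase protocol and return its outcome.

    ``backbone`` may be a :class:`BackboneSpec` (its freeze counts and input
    size are honoured) or None for the default; ``config`` is a
    :class:`rpvaudit.config.PipelineConfig` supplying hyperparameters.
    """
    kwargs = {}
    if config is not None:
        kwargs = dict(
            input_size=config.input_size,
            hidden_sizes=tuple(config.hidden_sizes),
            frozen_bottom_layers=config.frozen_bottom_layers,
            phase1_epochs=config.phase1_epochs,
            max_epochs=config.max_epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            random_state=config.model_init_seed,
        )
    if backbone is not None:
        kwargs["input_size"] = backbone.input_size
        kwargs["frozen_bottom_layers"] = backbone.frozen_bottom_layers
    clf = SmallImageClassifier(**kwargs)
    clf.fit(train_images, train_labels, X_val=val_images, y_val=val_labels)
    return TrainingOutcome(
        model=clf,
        trace=list(clf.training_trace_),
        best_epoch=clf.best_epoch_,
        phase1_epochs=clf.n_phase1_epochs_,
        stopped_early=clf.stopped_early_,
        config=clf.get_params(),
    )


def predict(model: SmallImageClassifier, images):
    """Argmax inference: list of ``(predicted_label, confidence)``."""
    probs = model.predict_proba(images)
    idx = probs.argmax(axis=1)
    return [
        (model.classes_[i], float(p[i])) for i, p in zip(idx, probs)
    ]


@dataclass
class F1Report:
    macro_f1: float
    micro_f1: float
    per_class: pd.DataFrame  # index: label; columns precision, recall, f1, support


def f1_score(prediction_records) -> F1Report:
    """Macro-averaged F1 with per-class precision/recall.

    ``prediction_records`` is a DataFrame (or convertible) with
    ``current_label`` (the label under audit, treated as ground truth for
    scoring a run) and ``predicted_label`` columns.  Classes with no
    predictions and no support score F1 = 0.
    """
    df = pd.DataFrame(prediction_records)
    if df.empty:
        raise ValueError("need at least one prediction record")
    y_true = df["current_label"].to_numpy()
    y_pred = df["predicted_label"].to_numpy()
    labels = sorted(set(y_true) | set(y_pred))
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=pd.Index(labels, name="label"),
    )
    micro = float((y_true == y_pred).mean())
    return F1Report(macro_f1=float(f1.mean()), micro_f1=micro, per_class=per_class)
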