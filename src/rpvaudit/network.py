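"""A small fully-connected softmax network in numpy.

This is the desk-scale training engine behind the classifier contract: it
supports per-layer freezing (bottom layers locked during fine-tuning, the
whole backbone locked during head-only training), deterministic seeded
initialisation and shuffling, Adam updates, and gradients with respect to
the input (for saliency maps).  Layer 0 is the layer closest to the input;
the last layer is the classification head.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingFailureError

_DTYPE = np.float64  # reproducibility over speed; sizes here are small


class DenseNet:
    def __init__(self, layer_sizes: list[int], rng: np.random.Generator):
        """``layer_sizes`` = [n_in, hidden..., n_classes]; He-initialised."""
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, (fan_in, fan_out)).astype(_DTYPE))
            self.biases.append(np.zeros(fan_out, dtype=_DTYPE))
        self._adam_state = None

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    # -- forward / inference -------------------------------------------------
    def _forward(self, X: np.ndarray):
        acts = [X.astype(_DTYPE, copy=False)]
        for i in range(self.n_layers):
            z = acts[-1] @ self.weights[i] + self.biases[i]
            if i < self.n_layers - 1:
                z = np.maximum(z, 0.0)  # ReLU on hidden layers
            acts.append(z)
        logits = acts[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(logits)
        probs = ez / ez.sum(axis=1, keepdims=True)
        return acts, probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X)[1]

    # -- training ------------------------------------------------------------
    def reset_optimizer(self) -> None:
        self._adam_state = None

    def train_epoch(
        self,
        X: np.ndarray,
        y_idx: np.ndarray,
        trainable: list[bool],
        learning_rate: float,
        batch_size: int,
        rng: np.random.Generator,
        epoch_index: int = 0,
    ) -> float:
        """One shuffled pass of Adam/cross-entropy; returns mean loss.

        Layers with ``trainable[i] == False`` receive no update, so their
        parameters stay bit-identical.
        """
        n = X.shape[0]
        if len(trainable) != self.n_layers:
            raise ValueError("trainable mask length must equal layer count")
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "mW": [np.zeros_like(w) for w in self.weights],
                "vW": [np.zeros_like(w) for w in self.weights],
                "mb": [np.zeros_like(b) for b in self.biases],
                "vb": [np.zeros_like(b) for b in self.biases],
            }
        st = self._adam_state
        b1, b2, eps = 0.9, 0.999, 1e-8
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            acts, probs = self._forward(X[idx])
            batch = len(idx)
            p = np.clip(probs[np.arange(batch), y_idx[idx]], 1e-12, None)
            losses.append(float(-np.log(p).mean()))
            # backprop
            delta = probs.copy()
            delta[np.arange(batch), y_idx[idx]] -= 1.0
            delta /= batch
            grads_W = [None] * self.n_layers
            grads_b = [None] * self.n_layers
            for i in range(self.n_layers - 1, -1, -1):
                grads_W[i] = acts[i].T @ delta
                grads_b[i] = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ self.weights[i].T) * (acts[i] > 0)
            st["t"] += 1
            corr1 = 1.0 - b1 ** st["t"]
            corr2 = 1.0 - b2 ** st["t"]
            for i in range(self.n_layers):
                if not trainable[i]:
                    continue
                for g, m, v, param in (
                    (grads_W[i], st["mW"][i], st["vW"][i], self.weights[i]),
                    (grads_b[i], st["mb"][i], st["vb"][i], self.biases[i]),
                ):
                    m *= b1
                    m += (1 - b1) * g
                    v *= b2
                    v += (1 - b2) * g * g
                    param -= learning_rate * (m / corr1) / (np.sqrt(v / corr2) + eps)
        mean_loss = float(np.mean(losses))
        if not np.isfinite(mean_loss):
            raise TrainingFailureError("non-finite training loss", epoch=epoch_index)
        return mean_loss

    # -- weights snapshot / restore -------------------------------------------
    def get_weights(self):
        return (
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
        )

    def set_weights(self, snapshot) -> None:
        ws, bs = snapshot
        self.weights = [w.copy() for w in ws]
        self.biases = [b.copy() for b in bs]

    # -- input gradient (saliency) --------------------------------------------
    def input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        """d score(class) / d input for one flattened input vector."""
        acts, probs = self._forward(x[None, :])
        delta = np.zeros_like(probs)
        delta[0, class_index] = 1.0
        # gradient of the chosen softmax output
        delta = probs * (delta - probs[:, [class_index]])
        for i in range(self.n_layers - 1, 0, -1):
            delta = (delta @ self.weights[i].T) * (acts[i] > 0)
        return (delta @ self.weights[0].T)[0]
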