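"""Fully connected inverse model: log-normalized reflectance -> (water, lipid).

The network is deliberately small — an input layer of 9 or 12 reflectance
channels, three hidden layers of 20 rectified-linear units, and a linear
two-node output — trained with Adam (learning rate 0.001) on a mean-squared
-error loss.  Labels are scaled from percent to fraction (0-1) during
training so the converged loss is in fraction^2 units; predictions are
reported back in percent and are not clamped to [0, 100].

Inputs are log-normalized: per channel, ln Rd is standardized with the mean
and SD fitted on the training set; those statistics travel with the weights
so a saved model is self-contained.

Early stopping follows a 200-epoch moving-average rule: training halts when
the mean loss over the most recent 200 epochs is no longer below the mean
over the 200 epochs before that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NormStats",
    "log_normalize",
    "InverseModel",
    "TrainingReport",
    "RecoveryReport",
    "train",
    "evaluate_recovery",
]

#: floor on the per-channel SD of ln Rd, guarding constant channels
SD_FLOOR = 1e-12

HIDDEN_LAYERS = (20, 20, 20)
DEFAULT_LR = 1e-3
DEFAULT_BATCH = 256
STOP_WINDOW = 200


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class NormStats:
    """Per-channel mean/SD of ln Rd fitted on a training set."""

    mean: np.ndarray
    sd: np.ndarray


def log_normalize(vectors: np.ndarray, stats: NormStats | None = None):
    """Standardize ln Rd per channel.

    With ``stats=None`` the statistics are fitted on ``vectors`` and
    returned alongside the normalized array; otherwise the supplied
    statistics are applied.  All reflectance values must be positive.
    """
    x = np.asarray(vectors, dtype=float)
    if np.any(x <= 0):
        raise ValueError("log-normalization requires strictly positive Rd")
    logx = np.log(x)
    if stats is None:
        mean = logx.mean(axis=0)
        sd = np.maximum(logx.std(axis=0), SD_FLOOR)
        stats = NormStats(mean=mean, sd=sd)
        return (logx - stats.mean) / stats.sd, stats
    return (logx - stats.mean) / stats.sd


@dataclass
class TrainingReport:
    """Per-epoch training trace and stopping context."""

    loss: np.ndarray  # epoch-mean MSE, fraction^2
    epochs_run: int
    stopping_reason: str
    seed: int


@dataclass
class RecoveryReport:
    """Recovery-error statistics, error = estimated - true, percent units."""

    mean_water: float
    sd_water: float
    mean_lipid: float
    sd_lipid: float
    errors_pct: np.ndarray = field(repr=False, default=None)  # (n, 2)
    true_pct: np.ndarray = field(repr=False, default=None)
    recovered_pct: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "mean_water_pct": self.mean_water,
            "sd_water_pct": self.sd_water,
            "mean_lipid_pct": self.mean_lipid,
            "sd_lipid_pct": self.sd_lipid,
        }

    def __str__(self) -> str:
        return (
            f"water error {self.mean_water:+.2f} +/- {self.sd_water:.2f} %, "
            f"lipid error {self.mean_lipid:+.2f} +/- {self.sd_lipid:.2f} %"
        )


def _init_layers(widths: list[int], rng: np.random.Generator):
    """Uniform fan-in initialization, biases at zero."""
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        bound = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


class InverseModel:
    """Trained MLP mapping a reflectance vector to (water %, lipid %).

    Carries the weights, the log-normalization statistics, and the channel
    labels of the geometry it was trained on; prediction refuses input whose
    channel labels differ from the training ordering.
    """

    def __init__(
        self,
        input_width: int,
        channel_labels: list[str] | None = None,
        hidden: tuple[int, ...] = HIDDEN_LAYERS,
        seed: int = 0,
        n_outputs: int = 2,
    ):
        self.input_width = int(input_width)
        self.channel_labels = list(channel_labels) if channel_labels else None
        self.hidden = tuple(hidden)
        self.seed = int(seed)
        self.n_outputs = int(n_outputs)
        widths = [self.input_width, *self.hidden, self.n_outputs]
        rng = np.random.default_rng(seed)
        self.weights, self.biases = _init_layers(widths, rng)
        self.norm_stats: NormStats | None = None

    # -- forward / backward ------------------------------------------------
    def _forward(self, z: np.ndarray):
        activations = [z]
        a = z
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w + b, 0.0)
            activations.append(a)
        out = a @ self.weights[-1] + self.biases[-1]
        return out, activations

    def predict_normalized(self, z: np.ndarray) -> np.ndarray:
        """Forward pass on already log-normalized input, fraction units."""
        out, _ = self._forward(np.asarray(z, dtype=float))
        return out

    def predict(
        self, reflectance: np.ndarray, channel_labels: list[str] | None = None
    ) -> np.ndarray:
        """Water/lipid predictions in percent for raw reflectance vectors.

        ``reflectance`` is (n, input_width) or a single vector.  If channel
        labels are supplied they must match the training ordering exactly.
        """
        if self.norm_stats is None:
            raise RuntimeError("model has not been trained")
        x = np.atleast_2d(np.asarray(reflectance, dtype=float))
        if x.shape[1] != self.input_width:
            raise ValueError(
                f"input width {x.shape[1]} != model width {self.input_width}"
            )
        if (
            channel_labels is not None
            and self.channel_labels is not None
            and list(channel_labels) != self.channel_labels
        ):
            raise ValueError("channel ordering differs from the training ordering")
        z = log_normalize(x, self.norm_stats)
        out = self.predict_normalized(z) * 100.0
        return out[0] if np.ndim(reflectance) == 1 else out

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        if self.norm_stats is None:
            raise RuntimeError("refusing to save an untrained model")
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        meta = {
            "input_width": self.input_width,
            "hidden": list(self.hidden),
            "n_outputs": self.n_outputs,
            "seed": self.seed,
            "channel_labels": self.channel_labels,
        }
        np.savez(
            path,
            norm_mean=self.norm_stats.mean,
            norm_sd=self.norm_stats.sd,
            meta=np.str_(json.dumps(meta)),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "InverseModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            model = cls(
                input_width=meta["input_width"],
                channel_labels=meta["channel_labels"],
                hidden=tuple(meta["hidden"]),
                seed=meta["seed"],
                n_outputs=meta["n_outputs"],
            )
            model.weights = [z[f"w{i}"] for i in range(len(model.weights))]
            model.biases = [z[f"b{i}"] for i in range(len(model.biases))]
            model.norm_stats = NormStats(
                mean=z["norm_mean"].copy(), sd=z["norm_sd"].copy()
            )
        return model


def train(
    model: InverseModel,
    rd: np.ndarray,
    labels_pct: np.ndarray,
    epochs: int = 2000,
    lr: float = DEFAULT_LR,
    batch_size: int = DEFAULT_BATCH,
    seed: int = 0,
    early_stopping: bool = True,
) -> TrainingReport:
    """Train in place with Adam on MSE of fraction-scaled labels.

    ``rd`` is (n, width) raw reflectance (the log-normalization statistics
    are fitted here and stored on the model); ``labels_pct`` is (n, 2) in
    percent.  The reported per-epoch loss is the mean over minibatches, in
    fraction^2 units.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rd = np.asarray(rd, dtype=float)
    y = np.asarray(labels_pct, dtype=float) / 100.0
    if rd.shape[0] == 0:
        raise ValueError("training set is empty")
    if rd.shape[1] != model.input_width:
        raise ValueError(f"input width {rd.shape[1]} != model {model.input_width}")

    z, stats = log_normalize(rd)
    model.norm_stats = stats
    rng = np.random.default_rng(seed)
    n = z.shape[0]

    # Adam state
    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    losses = []
    stopping_reason = "epoch budget exhausted"
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            zb, yb = z[idx], y[idx]
            out, acts = model._forward(zb)
            err = out - yb
            loss = float(np.mean(err**2))
            epoch_loss += loss
            n_batches += 1

            # backprop
            grad = 2.0 * err / err.size
            grads_w = [None] * len(model.weights)
            grads_b = [None] * len(model.biases)
            delta = grad
            for layer in range(len(model.weights) - 1, -1, -1):
                grads_w[layer] = acts[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ model.weights[layer].T) * (acts[layer] > 0)

            t += 1
            corr1 = 1.0 - beta1**t
            corr2 = 1.0 - beta2**t
            for layer in range(len(model.weights)):
                m_w[layer] = beta1 * m_w[layer] + (1 - beta1) * grads_w[layer]
                v_w[layer] = beta2 * v_w[layer] + (1 - beta2) * grads_w[layer] ** 2
                model.weights[layer] -= lr * (m_w[layer] / corr1) / (
                    np.sqrt(v_w[layer] / corr2) + eps
                )
                m_b[layer] = beta1 * m_b[layer] + (1 - beta1) * grads_b[layer]
                v_b[layer] = beta2 * v_b[layer] + (1 - beta2) * grads_b[layer] ** 2
                model.biases[layer] -= lr * (m_b[layer] / corr1) / (
                    np.sqrt(v_b[layer] / corr2) + eps
                )

        mean_loss = epoch_loss / n_batches
        if not np.isfinite(mean_loss):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch}: {mean_loss}"
            )
        losses.append(mean_loss)

        if early_stopping and len(losses) >= 2 * STOP_WINDOW:
            recent = float(np.mean(losses[-STOP_WINDOW:]))
            previous = float(np.mean(losses[-2 * STOP_WINDOW : -STOP_WINDOW]))
            if recent >= previous:
                stopping_reason = (
                    f"{STOP_WINDOW}-epoch mean loss stopped decreasing "
                    f"({recent:.3e} >= {previous:.3e})"
                )
                break

    return TrainingReport(
        loss=np.asarray(losses),
        epochs_run=len(losses),
        stopping_reason=stopping_reason,
        seed=int(seed),
    )


def evaluate_recovery(
    model: InverseModel, rd: np.ndarray, labels_pct: np.ndarray
) -> RecoveryReport:
    """Recovery-error statistics (estimated - true, %) on a labeled set."""
    pred = np.atleast_2d(model.predict(rd))
    true = np.asarray(labels_pct, dtype=float)
    err = pred - true
    return RecoveryReport(
        mean_water=float(err[:, 0].mean()),
        sd_water=float(err[:, 0].std(ddof=1)) if err.shape[0] > 1 else 0.0,
        mean_lipid=float(err[:, 1].mean()),
        sd_lipid=float(err[:, 1].std(ddof=1)) if err.shape[0] > 1 else 0.0,
        errors_pct=err,
        true_pct=true,
        recovered_pct=pred,
    )
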