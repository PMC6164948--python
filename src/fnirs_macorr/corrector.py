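"""Neural-network reconstruction of a contaminated fNIRS channel.

The corrector is a feed-forward back-propagation network that maps, sample
by sample, the 11 wavelet sub-band components of a contaminated channel to
a *preferred* signal: the samplewise mean of the channel's clean neighbor
channels (the channels sharing its uncontaminated optode).  Because the
artifact is concentrated in a few sub-bands while the hemodynamics span
others, the network learns a sub-band reweighting that suppresses the
artifact and keeps the physiology.

Architecture: 11 inputs -> six hidden layers (default widths
128/96/64/64/48/32, totalling 432 rectifier units) -> one linear output.
Training minimizes mean squared error with the Adam optimizer, full batch.
A trained network's weights can be transferred to a sibling channel that
shares the faulty optode and fine-tuned for a small number of iterations,
which reaches comparable quality at a fraction of the training cost.

Everything is plain numpy with an explicit seeded RNG, so training,
transfer, and the save/load round-trip are bit-reproducible.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field

import numpy as np

from .mra import MRADecomposition
from .probe import ProbeLayout

__all__ = [
    "CorrectorModel",
    "TrainingTarget",
    "build_target",
    "train_corrector",
    "transfer_correct",
    "save_model",
    "load_model",
]

DEFAULT_HIDDEN = (128, 96, 64, 64, 48, 32)  # six layers, 432 units total


@dataclass
class TrainingTarget:
    """Preferred signal for one channel: mean of its clean-side neighbors."""

    channel: int
    target: np.ndarray
    source_channels: tuple[int, ...]


def build_target(
    recording: np.ndarray,
    layout: ProbeLayout,
    ch: int,
    around_optode: str,
) -> TrainingTarget:
    """Samplewise mean of the channels around `around_optode`, excluding `ch`.

    `around_optode` should be the channel's *clean* optode, so the target
    reflects uncontaminated physiology from the same cortical patch.
    """
    sources = sorted(layout.neighbor_channels(around_optode, exclude=ch))
    if not sources:
        raise ValueError(f"no neighbor channels of CH{ch} around {around_optode}")
    idx = [layout.channel_ids.index(c) for c in sources]
    target = np.mean(np.asarray(recording, dtype=float)[idx], axis=0)
    return TrainingTarget(ch, target, tuple(sources))


# -- network ---------------------------------------------------------------


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _tanh(x: np.ndarray) -> np.ndarray:
    return np.tanh(x)


_ACTIVATIONS = {"relu": _relu, "tanh": _tanh}


@dataclass
class CorrectorModel:
    """Trained corrector: layer weights, feature scaler, and Adam state."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str
    feat_mean: np.ndarray  # per-sub-band standardization parameters
    feat_std: np.ndarray
    seed: int
    train_log: list[float] = field(default_factory=list)
    adam_state: dict | None = None

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    @property
    def hidden_layers(self) -> list[int]:
        return [w.shape[1] for w in self.weights[:-1]]

    def copy(self) -> "CorrectorModel":
        return CorrectorModel(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.activation,
            self.feat_mean.copy(),
            self.feat_std.copy(),
            self.seed,
            list(self.train_log),
            None if self.adam_state is None else {
                "t": self.adam_state["t"],
                "m": [m.copy() for m in self.adam_state["m"]],
                "v": [v.copy() for v in self.adam_state["v"]],
            },
        )

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Predict the corrected signal from an L x 11 feature matrix."""
        act = _ACTIVATIONS[self.activation]
        h = (features - self.feat_mean) / self.feat_std
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = act(h @ w + b)
        return (h @ self.weights[-1] + self.biases[-1]).ravel()


def _init_model(
    input_dim: int, hidden: tuple[int, ...], activation: str, seed: int,
    feat_mean: np.ndarray, feat_std: np.ndarray,
) -> CorrectorModel:
    rng = np.random.default_rng(seed)
    dims = [input_dim, *hidden, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        # He scaling suits the rectifier; harmless for tanh at these widths
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return CorrectorModel(weights, biases, activation, feat_mean, feat_std, seed)


def _features(decomp: MRADecomposition) -> np.ndarray:
    return decomp.stack().T  # L x (levels+1)


def _adam_fit(
    model: CorrectorModel,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    lr: float,
    tol_rel: float = 1e-6,
    patience: int = 500,
) -> None:
    """Full-batch MSE training with Adam, in place.  Stops early when the
    relative loss improvement over `patience` epochs falls below `tol_rel`."""
    act_name = model.activation
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    params = model.weights + model.biases
    if model.adam_state is None:
        model.adam_state = {
            "t": 0,
            "m": [np.zeros_like(p) for p in params],
            "v": [np.zeros_like(p) for p in params],
        }
    st = model.adam_state
    n = x.shape[0]
    xs = (x - model.feat_mean) / model.feat_std
    y = y.reshape(-1, 1)
    best = np.inf
    for _ in range(epochs):
        # forward
        hs = [xs]
        h = xs
        pre = []
        for w, b in zip(model.weights[:-1], model.biases[:-1]):
            z = h @ w + b
            pre.append(z)
            h = _relu(z) if act_name == "relu" else _tanh(z)
            hs.append(h)
        out = h @ model.weights[-1] + model.biases[-1]
        resid = out - y
        loss = float(np.mean(resid ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError("training diverged: non-finite loss")
        model.train_log.append(loss)
        # backward
        grad_out = 2.0 * resid / n
        grads_w = [None] * len(model.weights)
        grads_b = [None] * len(model.biases)
        g = grad_out
        grads_w[-1] = hs[-1].T @ g
        grads_b[-1] = g.sum(axis=0)
        for li in range(len(model.weights) - 2, -1, -1):
            g = g @ model.weights[li + 1].T
            if act_name == "relu":
                g = g * (pre[li] > 0)
            else:
                g = g * (1.0 - hs[li + 1] ** 2)
            grads_w[li] = hs[li].T @ g
            grads_b[li] = g.sum(axis=0)
        # Adam step
        st["t"] += 1
        t = st["t"]
        grads = grads_w + grads_b
        for p, gr, m, v in zip(params, grads, st["m"], st["v"]):
            m *= beta1
            m += (1 - beta1) * gr
            v *= beta2
            v += (1 - beta2) * gr ** 2
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        # early stopping on relative improvement
        if len(model.train_log) >= patience and len(model.train_log) % patience == 0:
            window = model.train_log[-patience:]
            if best < np.inf and (best - min(window)) < tol_rel * max(best, 1e-30):
                break
            best = min(best, min(window))


def train_corrector(
    features: MRADecomposition,
    target: TrainingTarget,
    epochs: int = 2000,
    learning_rate: float = 1e-3,
    seed: int = 0,
    hidden: tuple[int, ...] = DEFAULT_HIDDEN,
    activation: str = "relu",
) -> tuple[CorrectorModel, np.ndarray]:
    """Train the corrector on one channel and return (model, corrected).

    The per-sample regression pairs the 11 sub-band values at sample n with
    the neighbor-mean target at n.  Features are standardized per sub-band
    (parameters stored in the model); the target stays in physical units.
    """
    x = _features(features)
    y = np.asarray(target.target, dtype=float)
    if x.shape[0] != y.size:
        raise ValueError(f"feature length {x.shape[0]} != target length {y.size}")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    model = _init_model(x.shape[1], tuple(hidden), activation, seed, mean, std)
    _adam_fit(model, x, y, epochs=epochs, lr=learning_rate)
    return model, model.forward(x)


def transfer_correct(
    model: CorrectorModel,
    sibling_features: MRADecomposition,
    sibling_target: TrainingTarget,
    iters: int = 100,
    learning_rate: float = 1e-3,
) -> tuple[CorrectorModel, np.ndarray]:
    """Correct a sibling channel by transferring trained weights.

    The sibling shares the faulty optode with the trained channel, so its
    artifact has the same sub-band signature; starting from the trained
    weights, a brief fine-tune (default 100 iterations) on the sibling's own
    neighbor-mean target suffices.  `iters=0` is a pure forward pass.
    """
    x = _features(sibling_features)
    if x.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dimension {x.shape[1]} != model input {model.input_dim}"
        )
    y = np.asarray(sibling_target.target, dtype=float)
    if x.shape[0] != y.size:
        raise ValueError("sibling feature/target length mismatch")
    tuned = model.copy()
    tuned.adam_state = None  # fresh optimizer for the fine-tune
    if iters > 0:
        _adam_fit(tuned, x, y, epochs=iters, lr=learning_rate)
    return tuned, tuned.forward(x)


# -- persistence -----------------------------------------------------------


def save_model(model: CorrectorModel, path) -> None:
    """Serialize to a single JSON file (weights base64-packed, bit-exact)."""
    def pack(a: np.ndarray) -> dict:
        return {
            "shape": list(a.shape),
            "data": base64.b64encode(np.ascontiguousarray(a, dtype="<f8").tobytes()).decode(),
        }

    doc = {
        "format": "fnirs-macorr corrector v1",
        "activation": model.activation,
        "seed": model.seed,
        "hidden_layers": model.hidden_layers,
        "feat_mean": pack(model.feat_mean),
        "feat_std": pack(model.feat_std),
        "weights": [pack(w) for w in model.weights],
        "biases": [pack(b) for b in model.biases],
        "train_log_tail": model.train_log[-10:],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> CorrectorModel:
    def unpack(d: dict) -> np.ndarray:
        return np.frombuffer(base64.b64decode(d["data"]), dtype="<f8").reshape(d["shape"]).copy()

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "fnirs-macorr corrector v1":
        raise ValueError(f"{path}: not a corrector model file")
    return CorrectorModel(
        [unpack(w) for w in doc["weights"]],
        [unpack(b) for b in doc["biases"]],
        doc["activation"],
        unpack(doc["feat_mean"]),
        unpack(doc["feat_std"]),
        int(doc["seed"]),
        list(doc["train_log_tail"]),
    )
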