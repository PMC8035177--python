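"""ANN training, ANN-to-SNN conversion and integrate-and-fire inference.

A fully connected rectifier network (input - 100 hidden - 10 output, no bias,
no regularization) is trained by mini-batch gradient descent on softmax
cross-entropy. For spiking inference the ReLU units are replaced by
integrate-and-fire neurons

    V_mem(t+1) = V_mem(t) + sum(w * X(t)),

which emit a spike and reset to the zero resting potential whenever the
membrane potential crosses the layer threshold. Thresholds are set by
threshold balancing: each layer's threshold is the maximum pre-activation
observed while replaying encoder-generated calibration spike trains through
the layers in order. Input spike trains come from the encoder front end —
per-pixel Bernoulli samples of the closed-form rate-mode spike probability
(or, behind a flag, a full device-level pulse simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .device import DeviceParams, psc_current
from .encoding import PulseProgram, spike_probability
from .workbench import substream

__all__ = [
    "SNNModel",
    "train_ann",
    "ann_predict",
    "threshold_balance",
    "if_step",
    "encoder_frontend",
    "snn_infer",
    "InferenceResult",
]


@dataclass
class SNNModel:
    """Two bias-free weight matrices plus per-layer firing thresholds."""

    w1: np.ndarray                 # (d, n_hidden)
    w2: np.ndarray                 # (n_hidden, n_classes)
    v_th: tuple | None = None      # (layer-1, layer-2) thresholds after balancing
    input_shape: tuple = (28, 28)
    loss_history: np.ndarray | None = None

    def save(self, path) -> None:
        np.savez(
            path,
            w1=self.w1,
            w2=self.w2,
            v_th=np.asarray(self.v_th if self.v_th is not None else [np.nan, np.nan]),
            input_shape=np.asarray(self.input_shape),
        )

    @classmethod
    def load(cls, path) -> "SNNModel":
        z = np.load(path)
        v_th = tuple(z["v_th"])
        if np.any(np.isnan(v_th)):
            v_th = None
        return cls(
            w1=z["w1"], w2=z["w2"], v_th=v_th, input_shape=tuple(int(s) for s in z["input_shape"])
        )


def _flatten_images(images) -> np.ndarray:
    """Images of shape (n, H, W) or (n, d) to float (n, d) scaled to [0, 1]."""
    x = np.asarray(images)
    if x.ndim == 3:
        shape = x.shape[1:]
        x = x.reshape(x.shape[0], -1)
    elif x.ndim == 2:
        shape = (x.shape[1],)
    else:
        raise ValueError("images must be (n, H, W) or (n, d)")
    x = x.astype(float)
    if x.max() > 1.0:
        x = x / 255.0
    return x, shape


def train_ann(
    train_images,
    labels,
    lr: float = 1e-4,
    epochs: int = 100,
    n_hidden: int = 100,
    batch_size: int = 32,
    seed: int = 0,
) -> SNNModel:
    """Train the rectifier network by mini-batch SGD on cross-entropy.

    Inputs are flattened and scaled to [0, 1]; the hidden layer is ReLU and
    the output layer linear into a softmax loss. Gradients are summed (not
    averaged) over each mini-batch, so ``lr`` is a per-sample step size. No
    bias terms, no momentum, no regularization. Deterministic given ``seed``.
    The mean per-epoch loss is stored on ``model.loss_history``.
    """
    x, shape = _flatten_images(train_images)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    n_out = int(classes.max()) + 1
    n, d = x.shape
    rng = substream(seed, "ann-init")
    w1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, n_hidden))
    w2 = rng.normal(0.0, np.sqrt(2.0 / n_hidden), size=(n_hidden, n_out))
    shuffler = substream(seed, "ann-shuffle")
    onehot = np.eye(n_out)[y]
    losses = []
    for _ in range(epochs):
        order = shuffler.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], onehot[idx]
            a1 = xb @ w1
            h = np.maximum(a1, 0.0)
            logits = h @ w2
            logits -= logits.max(axis=1, keepdims=True)
            ez = np.exp(logits)
            p = ez / ez.sum(axis=1, keepdims=True)
            epoch_loss += -np.sum(np.log(np.maximum(p[np.arange(len(idx)), y[idx]], 1e-300)))
            g = p - yb
            gw2 = h.T @ g
            gh = (g @ w2.T) * (a1 > 0)
            gw1 = xb.T @ gh
            w1 -= lr * gw1
            w2 -= lr * gw2
        losses.append(epoch_loss / n)
    return SNNModel(
        w1=w1, w2=w2, v_th=None, input_shape=shape, loss_history=np.asarray(losses)
    )


def ann_predict(model: SNNModel, images) -> np.ndarray:
    """ANN class predictions (argmax of the logits; ties to the lowest index)."""
    x, _ = _flatten_images(images)
    return np.argmax(np.maximum(x @ model.w1, 0.0) @ model.w2, axis=1)


def if_step(v_mem: np.ndarray, x: np.ndarray, weights: np.ndarray, v_th: float):
    """One integrate-and-fire update: accumulate, threshold, reset to zero.

    ``x`` is a binary spike vector (or batch of them); returns the updated
    membrane potentials and the emitted binary output spikes.
    """
    x = np.asarray(x)
    if x.shape[-1] != weights.shape[0]:
        raise ValueError(
            f"input size {x.shape[-1]} does not match weight rows {weights.shape[0]}"
        )
    v_mem = v_mem + x @ weights
    out = v_mem > v_th
    v_mem = np.where(out, 0.0, v_mem)
    return v_mem, out


def threshold_balance(model: SNNModel, calib_spikes) -> tuple:
    """Per-layer thresholds from calibration spike trains (and set them).

    ``calib_spikes`` is an array (n_instances, d, T) of encoder-generated
    binary trains. Layer 1's threshold is the maximum pre-activation
    ``X(t) . w1`` over instances and timesteps; layer 2's is the maximum
    ``s1(t) . w2`` where s1 is layer 1's spiking output simulated with the
    freshly balanced threshold.
    """
    calib = np.asarray(calib_spikes)
    if calib.size == 0:
        raise ValueError("calibration set must be nonempty")
    if calib.ndim != 3:
        raise ValueError("calibration spikes must have shape (n, d, T)")
    n, d, t_total = calib.shape
    # layer 1: max over every instance and timestep of the input pre-activation
    x_flat = calib.transpose(0, 2, 1).reshape(n * t_total, d).astype(float)
    v1 = float((x_flat @ model.w1).max())
    if v1 <= 0:
        raise ValueError("calibration produced no positive layer-1 activation")
    # layer 2: replay through layer 1's IF dynamics with v1
    v2 = -np.inf
    for i in range(n):
        vm = np.zeros(model.w1.shape[1])
        for t in range(t_total):
            vm, s1 = if_step(vm, calib[i, :, t].astype(float), model.w1, v1)
            pre2 = s1.astype(float) @ model.w2
            m = float(pre2.max())
            if m > v2:
                v2 = m
    if v2 <= 0:
        raise ValueError("calibration produced no positive layer-2 activation")
    model.v_th = (v1, v2)
    return model.v_th


def encoder_frontend(
    image,
    program: PulseProgram,
    device: DeviceParams,
    i_st: float,
    timesteps: int,
    seed: int | None = None,
    device_level: bool = False,
) -> np.ndarray:
    """Spike-encode one image into a (d, T) binary tensor.

    Pixel intensities 0-255 map linearly to 0-5 V. The default path samples
    per-pixel Bernoulli spikes at the closed-form rate-mode probability;
    ``device_level=True`` instead simulates every sampling pulse through the
    device model (statistically indistinguishable, much slower).
    """
    if program.mode != "rate":
        raise ValueError("the classification front end uses rate encoding")
    img = np.asarray(image, dtype=float)
    v = img.ravel() * (5.0 / 255.0)
    d = v.size
    rng = substream(program.seed if seed is None else seed, "frontend")
    if device_level:
        amps = rng.normal(program.mu_tg, program.sigma_tg, size=(timesteps, d))
        cur = psc_current(v[None, :], amps, device, rng=rng)
        return (cur > i_st).T
    p = np.asarray(spike_probability(v, program, device, i_st))
    return (rng.random((timesteps, d)) < p[None, :]).T


@dataclass
class InferenceResult:
    predictions: np.ndarray
    checkpoints: np.ndarray
    error_trace: np.ndarray | None = None
    checkpoint_predictions: dict = field(default_factory=dict)


def snn_infer(
    images,
    model: SNNModel,
    program: PulseProgram,
    device: DeviceParams,
    i_st: float,
    timesteps: int,
    seed: int = 0,
    labels=None,
    checkpoints=None,
    readout: str = "spikes",
) -> InferenceResult:
    """Spiking inference over a batch of images.

    Each timestep draws a fresh Bernoulli spike frame per image at the
    closed-form front-end probability, pushes it through both IF layers, and
    accumulates output spikes. The prediction is the argmax of cumulative
    output-spike counts (ties break to the lowest class index);
    ``readout='membrane'`` instead ranks classes by total integrated drive
    (spike count scaled by threshold plus residual membrane potential).
    Returns predictions at ``timesteps`` plus an error trace at the requested
    checkpoints when labels are supplied.
    """
    if model.v_th is None:
        raise ValueError("model thresholds not balanced; run threshold_balance first")
    if readout not in ("spikes", "membrane"):
        raise ValueError("readout must be 'spikes' or 'membrane'")
    x, _ = _flatten_images(images)
    n, d = x.shape
    v = x * 5.0  # [0,1] gray back to volts
    p = np.asarray(spike_probability(v.ravel(), program, device, i_st)).reshape(n, d)
    v1, v2 = model.v_th
    rng = substream(seed, "snn-infer")
    vm1 = np.zeros((n, model.w1.shape[1]))
    vm2 = np.zeros((n, model.w2.shape[1]))
    counts = np.zeros((n, model.w2.shape[1]))
    if checkpoints is None:
        checkpoints = [timesteps]
    checkpoints = sorted({int(c) for c in checkpoints if 1 <= c <= timesteps} | {timesteps})
    errors, cp_preds = [], {}
    y = None if labels is None else np.asarray(labels, dtype=int)
    for t in range(1, timesteps + 1):
        xt = rng.random((n, d)) < p
        vm1, s1 = if_step(vm1, xt.astype(float), model.w1, v1)
        vm2, s2 = if_step(vm2, s1.astype(float), model.w2, v2)
        counts += s2
        if t in checkpoints:
            score = counts if readout == "spikes" else counts * v2 + vm2
            preds = np.argmax(score, axis=1)
            cp_preds[t] = preds
            if y is not None:
                errors.append(float(np.mean(preds != y)))
    return InferenceResult(
        predictions=cp_preds[timesteps],
        checkpoints=np.asarray(checkpoints),
        error_trace=None if y is None else np.asarray(errors),
        checkpoint_predictions=cp_preds,
    )
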