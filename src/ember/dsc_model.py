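"""The multi-target screening classifier.

Nine depthwise-separable convolution layers with PReLU activations extract
features from the 7x1024 fingerprint tensor; a 64/32/32 ReLU perceptron with
20 independent sigmoid outputs performs the multi-label classification.
Spatial kernels run along the 1024-bit axis only (the input is a 1024x1
"image" with 7 fingerprint channels).  Downsampling uses stride-2 depthwise
convolution on the first five layers, taking the spatial axis 1024 -> 32.

The reference configuration, with width schedule
(32, 64, 64, 512, 1024, 1024, 512, 64, 16) drawn from the
[1024, 512, 256, 128, 64, 32, 16] filter grid and a 13x1 depthwise kernel,
has exactly 2,252,959 trainable parameters: depthwise kernels carry no bias,
each pointwise filter carries one, and the PReLU slope is the fixed constant
0.25 (learnable alphas are available behind a flag and are then counted).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .embedding import EmberTensor, stack

log = logging.getLogger(__name__)

REFERENCE_WIDTHS: tuple[int, ...] = (32, 64, 64, 512, 1024, 1024, 512, 64, 16)
REFERENCE_STRIDES: tuple[int, ...] = (2, 2, 2, 2, 2, 1, 1, 1, 1)
REFERENCE_KERNEL = 13


@dataclass(frozen=True)
class ActivationSpec:
    """PReLU slope; alpha = 0 reduces to ReLU, learnable=False keeps it fixed."""

    alpha: float = 0.25
    learnable: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")


@dataclass(frozen=True)
class ConvLayerSpec:
    """One depthwise-separable convolution layer (kernel size s, depth d in,
    ``out_channels`` out) followed by PReLU."""

    out_channels: int
    kernel: int = REFERENCE_KERNEL
    stride: int = 1
    activation: ActivationSpec = field(default_factory=ActivationSpec)
    pointwise_bias: bool = True

    def __post_init__(self) -> None:
        if self.out_channels < 1 or self.kernel < 1 or self.stride < 1:
            raise ValueError("out_channels, kernel and stride must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description: conv stack, MLP head, output width."""

    conv_layers: tuple[ConvLayerSpec, ...]
    mlp_units: tuple[int, ...] = (64, 32, 32)
    n_outputs: int = 20
    in_channels: int = 7
    in_length: int = 1024

    def __post_init__(self) -> None:
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be positive")

    def spatial_lengths(self) -> list[int]:
        """Spatial length after each conv layer ('same' padding)."""
        lengths, L = [], self.in_length
        for layer in self.conv_layers:
            L = -(-L // layer.stride)
            lengths.append(L)
        return lengths

    def flat_features(self) -> int:
        if not self.conv_layers:
            return self.in_channels * self.in_length
        return self.conv_layers[-1].out_channels * self.spatial_lengths()[-1]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        raw = json.loads(text)
        convs = tuple(
            ConvLayerSpec(out_channels=c["out_channels"], kernel=c["kernel"],
                          stride=c["stride"],
                          activation=ActivationSpec(**c["activation"]),
                          pointwise_bias=c["pointwise_bias"])
            for c in raw["conv_layers"])
        return cls(conv_layers=convs, mlp_units=tuple(raw["mlp_units"]),
                   n_outputs=raw["n_outputs"], in_channels=raw["in_channels"],
                   in_length=raw["in_length"])


def reference_model_spec(n_outputs: int = 20) -> ModelSpec:
    """The full nine-layer configuration (2,252,959 parameters at 20 outputs)."""
    convs = tuple(
        ConvLayerSpec(out_channels=w, kernel=REFERENCE_KERNEL, stride=s)
        for w, s in zip(REFERENCE_WIDTHS, REFERENCE_STRIDES))
    return ModelSpec(conv_layers=convs, n_outputs=n_outputs)


def reduced_model_spec(n_outputs: int, widths: tuple[int, ...] = (8, 16, 16),
                       strides: tuple[int, ...] = (4, 4, 2),
                       kernel: int = REFERENCE_KERNEL,
                       mlp_units: tuple[int, ...] = (32,)) -> ModelSpec:
    """A small configuration of the same family, for desk-scale experiments."""
    convs = tuple(ConvLayerSpec(out_channels=w, kernel=kernel, stride=s)
                  for w, s in zip(widths, strides, strict=True))
    return ModelSpec(conv_layers=convs, mlp_units=mlp_units, n_outputs=n_outputs)


def count_parameters(spec: ModelSpec) -> int:
    """Analytic trainable-parameter count of a specification.

    Per conv layer: s*d depthwise weights, d*f pointwise weights, f pointwise
    biases (when enabled), plus one alpha when the PReLU slope is learnable.
    Dense layers count in*out weights + out biases.
    """
    total, d = 0, spec.in_channels
    for layer in spec.conv_layers:
        total += layer.kernel * d + d * layer.out_channels
        if layer.pointwise_bias:
            total += layer.out_channels
        if layer.activation.learnable:
            total += 1
        d = layer.out_channels
    units = spec.flat_features()
    for width in (*spec.mlp_units, spec.n_outputs):
        total += units * width + width
        units = width
    return total


def count_parameters_classical(spec: ModelSpec) -> int:
    """Parameter count had each conv layer used a full (non-separable) kernel
    of the same spatial size: s*d*f weights + f biases per layer."""
    total, d = 0, spec.in_channels
    for layer in spec.conv_layers:
        total += layer.kernel * d * layer.out_channels
        if layer.pointwise_bias:
            total += layer.out_channels
        if layer.activation.learnable:
            total += 1
        d = layer.out_channels
    units = spec.flat_features()
    for width in (*spec.mlp_units, spec.n_outputs):
        total += units * width + width
        units = width
    return total


@dataclass
class TrainingConfig:
    """Optimizer and schedule settings for :func:`train`."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    checkpoint: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1e-5 <= self.learning_rate <= 1e-1):
            raise ValueError("learning_rate outside [1e-5, 1e-1]")
        if not (1 <= self.batch_size <= 4096):
            raise ValueError("batch_size out of range")


class TrainedModel:
    """A built (possibly fitted) network plus its spec and training history."""

    def __init__(self, spec: ModelSpec, network: nn.Sequential):
        self.spec = spec
        self.network = network
        self.n_parameters = network.n_parameters()
        self.history: dict[str, list[float]] = {}
        analytic = count_parameters(spec)
        if self.n_parameters != analytic:
            raise RuntimeError(
                f"built network has {self.n_parameters} parameters, "
                f"analytic count is {analytic}")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 *[p.value for p in self.network.params()])
        path.with_suffix(".spec.json").write_text(self.spec.to_json())
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "TrainedModel":
        path = Path(path)
        spec = ModelSpec.from_json(path.with_suffix(".spec.json").read_text())
        model = build_model(spec, seed=seed)
        data = np.load(path.with_suffix(".npz"))
        model.network.load_state([data[k] for k in data.files])
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> TrainedModel:
    """Instantiate the network with seeded He-normal initialization."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    d = spec.in_channels
    for i, conv in enumerate(spec.conv_layers):
        layers.append(nn.SeparableConv1D(d, conv.out_channels, conv.kernel,
                                         stride=conv.stride, rng=rng,
                                         pointwise_bias=conv.pointwise_bias))
        layers.append(nn.PReLU(alpha=conv.activation.alpha,
                               learnable=conv.activation.learnable))
        d = conv.out_channels
    layers.append(nn.Flatten())
    units = spec.flat_features()
    for width in spec.mlp_units:
        layers.append(nn.Dense(units, width, rng=rng))
        layers.append(nn.ReLU())
        units = width
    layers.append(nn.Dense(units, spec.n_outputs, rng=rng))
    layers.append(nn.Sigmoid())
    return TrainedModel(spec, nn.Sequential(layers))


def _as_array(tensors) -> np.ndarray:
    if isinstance(tensors, np.ndarray):
        x = tensors
    elif len(tensors) and isinstance(tensors[0], EmberTensor):
        x = stack(tensors)
    else:
        x = np.asarray(tensors)
    if x.ndim == 2:
        x = x[None]
    return x.astype(np.float64)


def predict(model: TrainedModel, tensors, batch_size: int = 256) -> np.ndarray:
    """Per-target probabilities, shape (n, n_outputs); rows do not sum to 1."""
    x = _as_array(tensors)
    if x.shape[1:] != (model.spec.in_channels, model.spec.in_length):
        raise ValueError(
            f"input shape {x.shape[1:]} does not match "
            f"({model.spec.in_channels}, {model.spec.in_length})")
    out = [model.network.forward(x[i: i + batch_size])
           for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(out, axis=0)


def train(model: TrainedModel,
          train_data: tuple[np.ndarray, np.ndarray],
          val_data: tuple[np.ndarray, np.ndarray],
          config: TrainingConfig | None = None) -> TrainedModel:
    """Fit with Adam on mean binary cross-entropy over all outputs.

    Early stopping monitors validation loss with the configured patience;
    when checkpointing is on, the returned model carries the weights of the
    best-validation epoch.  Mini-batch order is seeded, so the recorded
    history is reproducible bit-for-bit given (data, config, initial weights).
    """
    config = config or TrainingConfig()
    x_tr, y_tr = _as_array(train_data[0]), np.asarray(train_data[1], dtype=np.float64)
    x_va, y_va = _as_array(val_data[0]), np.asarray(val_data[1], dtype=np.float64)
    if y_tr.ndim == 1:
        y_tr = y_tr[:, None]
    if y_va.ndim == 1:
        y_va = y_va[:, None]
    if not len(x_tr) or not len(x_va):
        raise ValueError("train and validation partitions must be non-empty")
    net = model.network
    opt = nn.Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: dict[str, list[float]] = {
        "train_loss": [], "val_loss": [], "train_acc": [], "val_acc": []}
    best_val = np.inf
    best_state = net.state() if config.checkpoint else None
    stale = 0
    n = len(x_tr)
    for epoch in range(config.max_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            net.zero_grad()
            # forward through all but the final sigmoid, then fuse
            z = xb
            for layer in net.layers[:-1]:
                z = layer.forward(z, train=True)
            p = net.layers[-1].forward(z, train=True)
            losses.append(nn.binary_cross_entropy(p, yb))
            if not np.isfinite(losses[-1]):
                raise FloatingPointError(
                    f"training diverged to non-finite loss at epoch {epoch}")
            grad_z = (p - yb) / p.size  # d(mean BCE)/d(logits), sigmoid fused
            for layer in reversed(net.layers[:-1]):
                grad_z = layer.backward(grad_z)
            opt.step()
        p_va = predict(model, x_va)
        val_loss = nn.binary_cross_entropy(p_va, y_va)
        p_tr = predict(model, x_tr)
        history["train_loss"].append(nn.binary_cross_entropy(p_tr, y_tr))
        history["val_loss"].append(val_loss)
        history["train_acc"].append(float(np.mean((p_tr > 0.5) == (y_tr > 0.5))))
        history["val_acc"].append(float(np.mean((p_va > 0.5) == (y_va > 0.5))))
        log.info("epoch %d: train %.4f val %.4f (%.1fs)", epoch,
                 history["train_loss"][-1], val_loss, time.perf_counter() - t0)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            stale = 0
            if config.checkpoint:
                best_state = net.state()
        else:
            stale += 1
            if stale >= config.patience:
                log.info("early stopping after %d stagnant epochs", stale)
                break
    if config.checkpoint and best_state is not None:
        net.load_state(best_state)
    model.history = history
    return model
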