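"""Additive feature attribution over the embedding channels.

Relevance is propagated backwards through the network with the rescale
rule: linear layers pass multipliers through their transpose, elementwise
nonlinearities rescale by the ratio of output to input activation
differences between the explained input and a reference.  Because every
layer of the classifier is either linear or elementwise, the per-bit scores
phi satisfy the summation-to-delta constraint sum_i phi_i = t - t0 exactly
(up to floating error), where t is the explained output probability and t0
its value at the reference.  With a reference *set*, attributions are
averaged over references and t0 is the set's mean output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import nn
from .dsc_model import TrainedModel

#: below this activation difference the rescale ratio falls back to the
#: derivative (the limit value), avoiding 0/0
_DELTA_EPS = 1e-9


@dataclass
class AttributionMap:
    """Per-bit relevance scores for a batch of inputs on one target.

    ``phi`` has shape (n, channels, n_bits); ``t`` and ``t0`` are the
    explained outputs and the reference-mean output.
    """

    phi: np.ndarray
    t: np.ndarray
    t0: float
    target_index: int
    background_size: int

    @property
    def delta(self) -> np.ndarray:
        return self.t - self.t0

    def check_summation_to_delta(self, rtol: float = 1e-3, atol: float = 1e-6) -> bool:
        totals = self.phi.sum(axis=(1, 2))
        return bool(np.all(np.abs(totals - self.delta)
                           <= rtol * np.abs(self.delta) + atol))


def _multipliers(network: nn.Sequential, acts_x: list[np.ndarray],
                 acts_r: list[np.ndarray], target_index: int) -> np.ndarray:
    """Backpropagate rescale multipliers from one output unit to the input."""
    out = acts_x[-1]
    m = np.zeros_like(out)
    m[:, target_index] = 1.0
    for i in reversed(range(len(network.layers))):
        layer = network.layers[i]
        x_in, r_in = acts_x[i], acts_r[i]
        if layer.is_elementwise:
            dx = x_in - r_in
            dy = layer.f(x_in) - layer.f(r_in)
            ratio = np.where(np.abs(dx) > _DELTA_EPS,
                             dy / np.where(np.abs(dx) > _DELTA_EPS, dx, 1.0),
                             layer.f_prime(x_in))
            m = m * ratio
        elif isinstance(layer, nn.SeparableConv1D):
            m = layer.transpose_to_input(m, in_length=x_in.shape[2])
        elif isinstance(layer, nn.Flatten):
            m = m.reshape(x_in.shape)
        elif isinstance(layer, nn.Dense):
            m = layer.backprop_input(m)
        else:  # pragma: no cover - no other layer kinds exist
            raise TypeError(f"cannot propagate multipliers through {type(layer)}")
    return m


def attribute(model: TrainedModel, inputs, background,
              target_index: int = 0) -> AttributionMap:
    """Per-bit additive relevance of each input against a background set.

    ``inputs`` and ``background`` are (n, channels, n_bits) arrays (or lists
    of embedding tensors).  The result averages single-reference rescale
    attributions over the background, so summation-to-delta holds against
    the background-mean reference output.
    """
    from .dsc_model import _as_array

    x = _as_array(inputs)
    bg = _as_array(background)
    if bg.shape[0] == 0:
        raise ValueError("background must be non-empty")
    if not (0 <= target_index < model.spec.n_outputs):
        raise ValueError(f"target_index {target_index} out of range")
    net = model.network
    acts_x = net.forward_cached(x)
    t = acts_x[-1][:, target_index].copy()
    phi = np.zeros_like(x, dtype=np.float64)
    t0_sum = 0.0
    for b in range(bg.shape[0]):
        acts_r = net.forward_cached(bg[b: b + 1])
        t0_sum += float(acts_r[-1][0, target_index])
        m = _multipliers(net, acts_x, acts_r, target_index)
        phi += m * (x - bg[b: b + 1])
    phi /= bg.shape[0]
    return AttributionMap(phi=phi, t=t, t0=t0_sum / bg.shape[0],
                          target_index=target_index, background_size=bg.shape[0])


@dataclass
class BinnedAttribution:
    """Bin means over contiguous groups of bits, per channel.

    ``values`` has shape (n, channels, n_bins); multiplying by the bin width
    and summing recovers each channel's total attribution.
    """

    values: np.ndarray
    bin_width: int

    def channel_totals(self) -> np.ndarray:
        return self.values.sum(axis=2) * self.bin_width


def bin_attributions(amap: AttributionMap, n_bins: int = 64) -> BinnedAttribution:
    """Compress the bit axis into ``n_bins`` contiguous bins (mean per bin)."""
    n, c, n_bits = amap.phi.shape
    if n_bits % n_bins:
        raise ValueError(f"{n_bits} bits not divisible into {n_bins} bins")
    width = n_bits // n_bins
    values = amap.phi.reshape(n, c, n_bins, width).mean(axis=3)
    return BinnedAttribution(values=values, bin_width=width)


@dataclass
class TargetAttributionSummary:
    """Per-fingerprint aggregate relevance for one target."""

    mean_abs: np.ndarray        # (channels,) mean |phi| per channel
    mean_signed: np.ndarray     # (channels,) signed mean phi per channel
    ranking: list[int]          # channel indices, most relevant first
    non_contributing: list[int]  # channels whose binned scores all fall below eps


def aggregate_by_target(maps: Mapping[str, AttributionMap], n_bins: int = 64,
                        epsilon: float = 1e-6
                        ) -> dict[str, TargetAttributionSummary]:
    """Mean attribution magnitude per fingerprint channel, per target.

    Channels are ranked by mean |phi|; a channel is flagged non-contributing
    when every one of its bin-level mean scores is below ``epsilon`` in
    magnitude.
    """
    out: dict[str, TargetAttributionSummary] = {}
    for name, amap in maps.items():
        mean_abs = np.abs(amap.phi).mean(axis=(0, 2))
        mean_signed = amap.phi.mean(axis=(0, 2))
        bins = bin_attributions(amap, n_bins=n_bins).values.mean(axis=0)
        non_contrib = [c for c in range(bins.shape[0])
                       if np.all(np.abs(bins[c]) < epsilon)]
        ranking = list(np.argsort(-mean_abs))
        out[name] = TargetAttributionSummary(
            mean_abs=mean_abs, mean_signed=mean_signed,
            ranking=ranking, non_contributing=non_contrib)
    return out


def export_attributions(maps: Mapping[str, AttributionMap],
                        molecule_ids: Sequence[str],
                        channel_names: Sequence[str],
                        path: str | Path, n_bins: int = 64) -> Path:
    """Tidy CSV: molecule, target, channel, bin, value (bin-mean phi)."""
    rows = []
    for target, amap in maps.items():
        binned = bin_attributions(amap, n_bins=n_bins)
        n, c, k = binned.values.shape
        for i in range(n):
            for ch in range(c):
                for b in range(k):
                    rows.append((molecule_ids[i], target, channel_names[ch],
                                 b, binned.values[i, ch, b]))
    frame = pd.DataFrame(rows, columns=["molecule", "target", "channel",
                                        "bin", "value"])
    path = Path(path)
    frame.to_csv(path, index=False)
    return path
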