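"""Screening-oriented evaluation.

Enrichment Factor EF(x%) = N_experimental / (N_active * x/100), the TP/P
ratio at the same slice, the Matthews correlation coefficient, a rank-based
AUC, and conventional accuracy / sensitivity / F1 — reported per target.
Printed EF values follow the convention of rounding to the nearest integer;
the raw value is always available alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import nn

DEFAULT_PERCENTAGES: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0)


@dataclass
class RankedScreen:
    """Scores and binary ground truth for one target over a test set."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels).astype(int)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D of equal length")

    @property
    def n_test(self) -> int:
        return self.scores.size

    @property
    def n_active(self) -> int:
        return int(self.labels.sum())


@dataclass(frozen=True)
class EnrichmentResult:
    ef: float           # raw EF value
    ef_rounded: int     # nearest-integer convention used in printed tables
    tp: int             # actives found in the slice
    slice_n: int        # molecules in the top x% slice


def _top_slice(screen: RankedScreen, x_percent: float) -> tuple[int, int]:
    """(actives in slice, slice size) with stable tie-break by input order."""
    if not (0 < x_percent <= 100):
        raise ValueError("x_percent must be in (0, 100]")
    slice_n = int(np.rint(screen.n_test * x_percent / 100.0))
    # stable sort on -score keeps earlier molecules first among ties
    order = np.argsort(-screen.scores, kind="stable")
    tp = int(screen.labels[order[:slice_n]].sum())
    return tp, slice_n


def enrichment_factor(screen: RankedScreen, x_percent: float) -> EnrichmentResult:
    """EF at the top x% of the ranked screen."""
    if screen.n_active == 0:
        raise ValueError("EF undefined: no active molecule in the screen")
    tp, slice_n = _top_slice(screen, x_percent)
    ef = tp / (screen.n_active * x_percent / 100.0)
    return EnrichmentResult(ef=ef, ef_rounded=int(np.rint(ef)), tp=tp, slice_n=slice_n)


def tp_p(screen: RankedScreen, x_percent: float) -> tuple[int, int]:
    """(true positives in the top x% slice, total positives in the screen)."""
    if screen.n_active == 0:
        raise ValueError("TP/P undefined: no active molecule in the screen")
    tp, _ = _top_slice(screen, x_percent)
    return tp, screen.n_active


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient of a 2x2 confusion table.

    Returns 0 when any margin is zero (the usual convention); raises when
    the table is empty.
    """
    for v in (tp, fp, fn, tn):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion table")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) statistic.

    Ties in scores contribute 1/2.  Returns nan when only one class is
    present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum = ranks[labels].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class TargetMetrics:
    accuracy: float
    loss: float
    sensitivity: float
    mcc: float
    auc: float
    f1: float
    ef: dict[float, EnrichmentResult]
    tp_p: dict[float, tuple[int, int]]


@dataclass
class MetricsReport:
    """Per-target metrics over a prediction matrix."""

    per_target: dict[str, TargetMetrics]
    n: int
    percentages: tuple[float, ...] = DEFAULT_PERCENTAGES

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.per_target.items():
            row = {"target": name, "accuracy": m.accuracy, "loss": m.loss,
                   "sensitivity": m.sensitivity, "mcc": m.mcc, "auc": m.auc,
                   "f1": m.f1}
            for x in self.percentages:
                res = m.ef.get(x)
                tp, p = m.tp_p.get(x, (0, 0))
                row[f"tp_p_{x:g}%"] = f"{tp}/{p}"
                row[f"ef_{x:g}%"] = res.ef_rounded if res else float("nan")
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n": self.n,
            "percentages": list(self.percentages),
            "targets": {
                name: {
                    "accuracy": m.accuracy, "loss": m.loss,
                    "sensitivity": m.sensitivity, "mcc": m.mcc,
                    "auc": m.auc, "f1": m.f1,
                    "ef": {f"{x:g}": {"raw": r.ef, "rounded": r.ef_rounded,
                                      "tp": r.tp, "slice_n": r.slice_n}
                           for x, r in m.ef.items()},
                    "tp_p": {f"{x:g}": list(v) for x, v in m.tp_p.items()},
                }
                for name, m in self.per_target.items()
            },
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate(predictions: np.ndarray, labels: np.ndarray,
             target_names: Sequence[str] | None = None,
             threshold: float = 0.5,
             percentages: Sequence[float] = DEFAULT_PERCENTAGES) -> MetricsReport:
    """Per-target metrics for a (n, n_targets) probability matrix.

    Loss is the per-target mean binary cross-entropy restricted to that
    target's output.  Targets whose labels are single-class get AUC nan and,
    when no active exists, no EF/TP-P entries.
    """
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels).astype(int)
    if predictions.ndim == 1:
        predictions = predictions[:, None]
    if labels.ndim == 1:
        labels = labels[:, None]
    if predictions.shape != labels.shape:
        raise ValueError(
            f"shape mismatch: predictions {predictions.shape}, labels {labels.shape}")
    n, n_targets = predictions.shape
    if target_names is None:
        target_names = [f"target_{t}" for t in range(n_targets)]
    per_target: dict[str, TargetMetrics] = {}
    for t, name in enumerate(target_names):
        p, y = predictions[:, t], labels[:, t]
        pred = (p >= threshold).astype(int)
        tp_ = int(((pred == 1) & (y == 1)).sum())
        fp_ = int(((pred == 1) & (y == 0)).sum())
        fn_ = int(((pred == 0) & (y == 1)).sum())
        tn_ = int(((pred == 0) & (y == 0)).sum())
        n_pos = tp_ + fn_
        sensitivity = tp_ / n_pos if n_pos else float("nan")
        precision = tp_ / (tp_ + fp_) if (tp_ + fp_) else 0.0
        f1 = (2 * precision * sensitivity / (precision + sensitivity)
              if n_pos and (precision + sensitivity) > 0 else 0.0)
        screen = RankedScreen(scores=p, labels=y)
        efs, tpps = {}, {}
        if screen.n_active > 0:
            for x in percentages:
                efs[x] = enrichment_factor(screen, x)
                tpps[x] = tp_p(screen, x)
        per_target[name] = TargetMetrics(
            accuracy=float((tp_ + tn_) / n),
            loss=nn.binary_cross_entropy(p, y.astype(float)),
            sensitivity=sensitivity,
            mcc=mcc(tp_, fp_, fn_, tn_),
            auc=auc(p, y),
            f1=f1,
            ef=efs,
            tp_p=tpps,
        )
    return MetricsReport(per_target=per_target, n=n,
                         percentages=tuple(percentages))
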