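"""Segmentation/classification metrics and the extrinsic-review sampler.

Dice and IoU follow the usual set definitions with the convention that two
empty masks agree perfectly (metric = 1), which keeps batch evaluation of
background-only tiles NaN-free.  Average precision is the pixel-level,
rank-based area under the precision-recall curve: thresholds sweep the
distinct score values and AP = sum precision(k) * delta-recall(k).

The extrinsic-review helpers reproduce a slide-selection scheme for manual
model audit: slides in the extreme tails (default lower/upper 5%) of a
per-slide TSR score-ratio distribution are selected, and a bounded random
subset of their interface patches (at least 10, strictly fewer than 30) is
drawn for review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SegMetrics:
    dsc: float
    iou: float
    ap: float


def _as_binary_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1 when both empty."""
    a, b = _as_binary_pair(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union |A∩B| / |A∪B|; 1 when both empty."""
    a, b = _as_binary_pair(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def average_precision(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based area under the precision-recall curve.

    ``scores`` are per-pixel confidences, ``truth`` the binary reference.
    Thresholds sweep the distinct score values in decreasing order (ties
    grouped), accumulating precision(k) * delta-recall(k).  Undefined (an
    error) when the truth has no positives.  A constant score vector yields
    a single PR point, AP = prevalence.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same number of elements")
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ValueError("average precision is undefined without positives in truth")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    tp = np.cumsum(t)
    fp = np.cumsum(~t)
    # indices closing each group of tied scores
    distinct = np.nonzero(np.r_[s[1:] != s[:-1], True])[0]
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    delta = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * delta))


def seg_metrics(pred: np.ndarray, truth: np.ndarray, scores: np.ndarray | None = None) -> SegMetrics:
    """Bundle Dice/IoU (binary pred vs truth) and AP (scores default to the
    binary prediction itself)."""
    sc = np.asarray(pred, dtype=float) if scores is None else scores
    return SegMetrics(dsc=dice(pred, truth), iou=iou(pred, truth), ap=average_precision(sc, truth))


def confusion_matrix_scores(
    true_scores: Sequence[int], pred_scores: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """3x3 confusion matrix over TSR scores (rows = truth, columns =
    prediction) and per-class accuracy (diagonal over row sums; NaN for an
    absent class)."""
    t = np.asarray(true_scores, dtype=int)
    p = np.asarray(pred_scores, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted score vectors must have equal length")
    for arr, name in ((t, "true"), (p, "predicted")):
        if arr.size and (arr.min() < 0 or arr.max() > 2):
            raise ValueError(f"{name} scores outside {{0,1,2}}")
    mat = np.zeros((3, 3), dtype=int)
    np.add.at(mat, (t, p), 1)
    row_sums = mat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row_sums > 0, np.diag(mat) / row_sums, np.nan)
    return mat, per_class


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    return float((pred == truth).mean())


# ---------------------------------------------------------------------------
# extrinsic review sampling

def select_extrinsic_slides(
    ratios: pd.DataFrame | pd.Series,
    low_q: float = 0.05,
    high_q: float = 0.95,
) -> list[str]:
    """Slides in the tails of the per-slide score-ratio distribution.

    ``ratios`` maps slide id -> TSR score ratio (a Series, or a DataFrame
    with ``slide_id`` and ``ratio`` columns).  Quantiles use the empirical
    inverse-CDF (type-1) definition for cross-platform determinism, with
    the high quantile mirrored (upper inverse CDF) so the two tails are
    symmetric; slides with ratio <= the low quantile or >= the high
    quantile are selected.  When all ratios are equal both quantiles
    coincide and every slide is selected (with a warning).
    """
    if isinstance(ratios, pd.DataFrame):
        ratios = ratios.set_index("slide_id")["ratio"]
    if ratios.empty:
        raise ValueError("empty score-ratio table")
    if len(ratios) < 20:
        warnings.warn("fewer than 20 slides: tail quantiles are degenerate", stacklevel=2)
    values = ratios.to_numpy(dtype=float)
    # type-1 inverse CDF via explicit order statistics (immune to the
    # floating-point slop of q*n landing a hair above an integer)
    n = len(values)
    srt = np.sort(values)
    k_lo = max(int(np.ceil(low_q * n - 1e-9)), 1)
    k_hi = max(int(np.ceil((1.0 - high_q) * n - 1e-9)), 1)
    lo = srt[k_lo - 1]
    hi = srt[n - k_hi]
    if lo == hi:
        warnings.warn(
            "degenerate quantiles (all ratios equal): selecting every slide",
            stacklevel=2,
        )
    selected = ratios[(ratios <= lo) | (ratios >= hi)]
    return list(selected.index)


def sample_review_patches(
    patches: Sequence,
    n_min: int = 10,
    n_max: int = 30,
    seed: int = 0,
) -> list:
    """Uniform without-replacement sample of interface patches for manual
    review: at least ``n_min`` but strictly fewer than ``n_max``, capped at
    availability (with a warning when fewer than ``n_min`` exist).
    Deterministic per seed."""
    available = len(patches)
    target = min(available, min(n_max - 1, max(n_min, available)))
    if available < n_min:
        warnings.warn(
            f"only {available} patches available (< {n_min} requested minimum)",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(available, size=target, replace=False) if available else []
    return [patches[i] for i in sorted(idx)]
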