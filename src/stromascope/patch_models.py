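"""Patch-model backend contracts and classical reference implementations.

The pipeline treats patch-level tumor/stroma segmentation and three-criterion
TSR scoring as pluggable *backends*.  Any model — including externally
trained deep networks — can be dropped in as long as it satisfies the two
small contracts below; everything downstream (stitching, interface
detection, summarization, association) depends on backends only through
these contracts.

The reference backends here are deliberately classical: a per-pixel
color/texture classifier for segmentation and a patch-summary-feature
classifier for TSR scoring.  They are fast, deterministic given a seed, and
accurate on phantom slides whose textures are separable by construction,
which is what end-to-end testing needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage
from sklearn.tree import DecisionTreeClassifier

from .tiling_io import PatchRecord

# label codes for segmentation rasters
BACKGROUND, TUMOR, STROMA = 0, 1, 2
LABEL_NAMES = {BACKGROUND: "background", TUMOR: "tumor", STROMA: "stroma"}
VALID_LABELS = frozenset(LABEL_NAMES)

SCORES = (0, 1, 2)


@runtime_checkable
class SegmenterBackend(Protocol):
    """Contract: per-pixel tumor/stroma/background labeling of an RGB patch."""

    name: str
    version: str

    def segment(self, image: np.ndarray) -> np.ndarray:
        """Return an integer label raster (values in {0,1,2}) with the same
        spatial dims as ``image``."""


@runtime_checkable
class TSRScorerBackend(Protocol):
    """Contract: patch-level TSR score for one criterion.

    ``score`` returns ``(predicted score in {0,1,2}, probability 3-vector)``;
    probabilities are nonnegative, sum to 1 within 1e-6, and their argmax
    equals the predicted score.
    """

    name: str
    version: str

    def score(self, image: np.ndarray, criterion: str) -> tuple[int, np.ndarray]: ...


class BackendContractError(RuntimeError):
    """A backend violated its declared contract."""


# ---------------------------------------------------------------------------
# per-pixel features

def _pixel_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel features: RGB plus local gray-level standard deviation."""
    img = np.asarray(image, dtype=np.float32)
    gray = img.mean(axis=2)
    mu = ndimage.uniform_filter(gray, size=5)
    mu2 = ndimage.uniform_filter(gray * gray, size=5)
    local_sd = np.sqrt(np.maximum(mu2 - mu * mu, 0.0))
    feats = np.empty(img.shape[:2] + (4,), dtype=np.float32)
    feats[..., :3] = img
    feats[..., 3] = local_sd
    return feats.reshape(-1, 4)


@dataclass
class ReferenceSegmenter:
    """Pixelwise decision-tree classifier on color + local variance."""

    name: str = "reference-segmenter"
    version: str = "1"
    _clf: DecisionTreeClassifier = field(default=None, repr=False)

    def segment(self, image: np.ndarray) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("segmenter is not fitted")
        image = np.asarray(image)
        labels = self._clf.predict(_pixel_features(image))
        return labels.reshape(image.shape[:2]).astype(np.uint8)


def fit_reference_segmenter(
    patches: Sequence[PatchRecord],
    seed: int = 0,
    max_pixels: int = 200_000,
) -> ReferenceSegmenter:
    """Fit the reference pixel classifier on ground-truth-labeled patches.

    ``patches`` must carry ``pixel_labels`` rasters (as produced by the
    phantom generator) covering at least two classes.  A random pixel
    subsample caps the training set at ``max_pixels``.  Deterministic for a
    fixed seed.
    """
    feats, labs = [], []
    for rec in patches:
        if rec.pixel_labels is None:
            raise ValueError("training patches must carry pixel_labels rasters")
        feats.append(_pixel_features(rec.image))
        labs.append(np.asarray(rec.pixel_labels).ravel())
    if not feats:
        raise ValueError("no training patches given")
    x = np.concatenate(feats)
    y = np.concatenate(labs)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class; need at least two")
    rng = np.random.default_rng(seed)
    if x.shape[0] > max_pixels:
        idx = rng.choice(x.shape[0], size=max_pixels, replace=False)
        x, y = x[idx], y[idx]
    clf = DecisionTreeClassifier(max_depth=10, random_state=int(rng.integers(2**31 - 1)))
    clf.fit(x, y)
    return ReferenceSegmenter(_clf=clf)


# ---------------------------------------------------------------------------
# TSR scoring

#: internal pixel class for "not graded stroma" in the scorer's classifier
_OTHER = 3


@dataclass
class ReferenceTSRScorer:
    """Pixel-grade classifier aggregated to a patch score.

    A patch's ground-truth TSR label is the *modal* grade over its stroma
    pixels, so the reference scorer mirrors that definition: it classifies
    pixels (on a subsampled grid) into grade 0/1/2 or "other" (tumor /
    background) by color and local variance, sums the grade probability
    mass over the patch, and reports the normalized mass as the class
    probabilities.  This stays accurate on patches that straddle grade
    bands, where whole-patch summary features are ambiguous.
    """

    criterion: str
    name: str = "reference-tsr-scorer"
    version: str = "2"
    subsample: int = 2
    _clf: DecisionTreeClassifier = field(default=None, repr=False)

    def score(self, image: np.ndarray, criterion: str) -> tuple[int, np.ndarray]:
        if self._clf is None:
            raise RuntimeError("scorer is not fitted")
        if criterion != self.criterion:
            raise ValueError(
                f"scorer was fitted for {self.criterion!r}, asked for {criterion!r}"
            )
        image = np.asarray(image)
        s = self.subsample
        sub = image[::s, ::s]
        feats = _pixel_features(sub)
        raw = self._clf.predict_proba(feats)
        mass = np.zeros(3, dtype=float)
        for col, cls in enumerate(self._clf.classes_):
            if int(cls) in (0, 1, 2):
                mass[int(cls)] = raw[:, col].sum()
        total = mass.sum()
        if total <= 0:  # no graded-stroma evidence anywhere in the patch
            probs = np.full(3, 1.0 / 3.0)
        else:
            probs = mass / total
        return int(probs.argmax()), probs


def fit_reference_tsr_scorer(
    patches: Sequence[PatchRecord],
    criterion: str,
    seed: int = 0,
    max_pixels: int = 200_000,
) -> ReferenceTSRScorer:
    """Fit the reference TSR scorer for one criterion.

    Training patches must carry ``pixel_scores`` rasters (per-pixel grade,
    255 off-stroma, as the phantom generator produces).  All three grade
    classes must be represented among the stroma pixels; non-stroma pixels
    train an internal "other" class so tumor and glass never contribute
    grade mass at inference.
    """
    feats, labs = [], []
    for rec in patches:
        if rec.pixel_scores is None or criterion not in rec.pixel_scores:
            continue
        grades = np.asarray(rec.pixel_scores[criterion]).ravel()
        f = _pixel_features(rec.image)
        y = np.where(grades <= 2, grades, _OTHER)
        feats.append(f)
        labs.append(y)
    if not feats:
        raise ValueError(f"no patches carry {criterion!r} pixel grades")
    x = np.concatenate(feats)
    y = np.concatenate(labs)
    present = set(np.unique(y).tolist())
    missing = [s for s in SCORES if s not in present]
    if missing:
        raise ValueError(
            f"score class {missing[0]} missing from {criterion!r} training labels"
        )
    rng = np.random.default_rng(seed)
    if x.shape[0] > max_pixels:
        idx = rng.choice(x.shape[0], size=max_pixels, replace=False)
        x, y = x[idx], y[idx]
    clf = DecisionTreeClassifier(max_depth=10, random_state=int(rng.integers(2**31 - 1)))
    clf.fit(x, y)
    return ReferenceTSRScorer(criterion=criterion, _clf=clf)


# ---------------------------------------------------------------------------
# slide-level inference

@dataclass
class PatchPrediction:
    """Model output for one tile: label raster, dominant class, and (for
    stroma-dominant tiles) per-criterion scores and probabilities."""

    slide_id: str
    x: int
    y: int
    size: int
    class_mask: np.ndarray
    dominant_class: int
    tsr_scores: Optional[dict[str, int]] = None
    tsr_probs: Optional[dict[str, np.ndarray]] = None


def dominant_class(class_mask: np.ndarray) -> int:
    """Majority label over tissue pixels; ties break toward stroma, which is
    conservative for interface detection.  All-background tiles return
    background."""
    n_tumor = int((class_mask == TUMOR).sum())
    n_stroma = int((class_mask == STROMA).sum())
    if n_tumor == 0 and n_stroma == 0:
        return BACKGROUND
    return STROMA if n_stroma >= n_tumor else TUMOR


def _check_segment_output(labels: np.ndarray, image: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != image.shape[:2]:
        raise BackendContractError(
            f"segmenter returned shape {labels.shape}, expected {image.shape[:2]}"
        )
    if not np.isin(labels, list(VALID_LABELS)).all():
        raise BackendContractError("segmenter emitted labels outside {0,1,2}")
    return labels


def _check_score_output(pred: int, probs: np.ndarray) -> None:
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (3,) or (probs < 0).any():
        raise BackendContractError("scorer probabilities must be a nonnegative 3-vector")
    if abs(float(probs.sum()) - 1.0) > 1e-6:
        raise BackendContractError("scorer probabilities must sum to 1 within 1e-6")
    if int(np.argmax(probs)) != int(pred):
        raise BackendContractError("scorer argmax inconsistent with predicted score")


def predict_slide(
    patches: Sequence[PatchRecord],
    segmenter: SegmenterBackend,
    scorers: dict[str, TSRScorerBackend],
) -> list[PatchPrediction]:
    """Run backends patch by patch.

    Each surviving tile gets a segmentation raster and a dominant class;
    TSR scores are attached only to tiles whose dominant class is stroma
    (scores on tumor-dominant tissue are not meaningful).  Contract
    violations raise :class:`BackendContractError` rather than being
    silently corrected.  Patches are processed strictly sequentially, so
    results are independent of batching.
    """
    results: list[PatchPrediction] = []
    for rec in patches:
        labels = _check_segment_output(segmenter.segment(rec.image), rec.image)
        dom = dominant_class(labels)
        pred = PatchPrediction(
            slide_id=rec.slide_id,
            x=rec.x,
            y=rec.y,
            size=rec.size,
            class_mask=labels,
            dominant_class=dom,
        )
        if dom == STROMA and scorers:
            pred.tsr_scores, pred.tsr_probs = {}, {}
            for crit, scorer in scorers.items():
                s, p = scorer.score(rec.image, crit)
                _check_score_output(s, p)
                pred.tsr_scores[crit] = int(s)
                pred.tsr_probs[crit] = np.asarray(p, dtype=float)
        results.append(pred)
    return results


def predictions_to_frame(preds: Sequence[PatchPrediction]):
    """Serialize predictions to a manifest-style DataFrame (one row per
    patch: origin, dominant class, scores, probabilities)."""
    import pandas as pd

    rows = []
    for p in preds:
        row = {
            "slide_id": p.slide_id,
            "x": p.x,
            "y": p.y,
            "size": p.size,
            "class": LABEL_NAMES[p.dominant_class],
        }
        if p.tsr_scores:
            for crit, s in p.tsr_scores.items():
                row[crit] = s
                for k in SCORES:
                    row[f"{crit}_p{k}"] = float(p.tsr_probs[crit][k])
        rows.append(row)
    return pd.DataFrame(rows)
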