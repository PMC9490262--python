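"""Slide-mask stitching and tumor-stroma interface detection.

Patch-level segmentation results are down-sampled (default r = 1/128) and
stitched back to their original locations to form a slide-level multilabel
mask (background / tumor / stroma).  The tumor-stroma interface — the band
of stroma hugging the invasive tumor front — is then identified by a fixed
composition of binary morphology:

    Tumor_core  = closing(I_T, S)
    Stroma_core = closing(I_S, S)
    interface   = (dilate(Stroma_core, S) XOR erode(Stroma_core, S))
                  AND Stroma_core AND dilate(Tumor_core, S)

where I_T / I_S are the tumor and stroma indicator rasters and S is the
structuring element.  The XOR term is the morphological gradient band of the
stroma core (its boundary zone); intersecting with the stroma core keeps the
inner half of that band, and intersecting with the dilated tumor core keeps
only boundary stroma that actually touches tumor.  All operators treat
pixels outside the image as empty (border_value 0).

The largest connected components of the interface mask (8-connected by
default) are the representative sub-regions used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, footprint_rectangle

from .patch_models import BACKGROUND, STROMA, TUMOR, PatchPrediction


@dataclass(frozen=True)
class StructuringElement:
    """Neighborhood shape for the morphological operators.

    ``radius`` is in mask-scale pixels; at the default r = 1/128 a radius-2
    disk corresponds to roughly 512 full-resolution pixels, a band a few
    patches wide.
    """

    shape: str = "disk"
    radius: int = 2

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "square"):
            raise ValueError("shape must be 'disk' or 'square'")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    def footprint(self) -> np.ndarray:
        if self.shape == "disk":
            return disk(self.radius).astype(bool)
        side = 2 * self.radius + 1
        return footprint_rectangle((side, side)).astype(bool)


@dataclass
class SlideMask:
    """Multilabel raster (0 background, 1 tumor, 2 stroma) at scale ``r``."""

    labels: np.ndarray
    r: float
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        if not (0 < self.r <= 1):
            raise ValueError("scale r must be in (0, 1]")

    @property
    def tumor(self) -> np.ndarray:
        return self.labels == TUMOR

    @property
    def stroma(self) -> np.ndarray:
        return self.labels == STROMA


@dataclass
class InterfaceResult:
    """Interface mask plus its connected components, sorted by size
    descending (ties broken by scan-order component id)."""

    interface_mask: np.ndarray
    components: list[tuple[int, int, tuple[int, int, int, int]]]
    component_labels: np.ndarray


def stitch_patches(
    preds: Sequence[PatchPrediction],
    slide_shape: tuple[int, int],
    r: float = 1.0 / 128.0,
    slide_id: str = "slide",
) -> SlideMask:
    """Down-sample patch predictions and stitch them into a slide mask.

    Each patch paints its dominant class over its down-scaled footprint
    (e.g. a 256 px patch covers a 2x2 block at r = 1/128).  Patches must not
    overlap at the mask scale — inference tiling uses stride = patch size —
    and uncovered area stays background.
    """
    h, w = slide_shape
    out_h, out_w = int(np.ceil(h * r)), int(np.ceil(w * r))
    labels = np.full((out_h, out_w), BACKGROUND, dtype=np.uint8)
    covered = np.zeros((out_h, out_w), dtype=bool)
    for p in preds:
        y0 = int(round(p.y * r))
        x0 = int(round(p.x * r))
        y1 = min(int(round((p.y + p.size) * r)), out_h)
        x1 = min(int(round((p.x + p.size) * r)), out_w)
        block = (slice(y0, y1), slice(x0, x1))
        if covered[block].any():
            raise ValueError(
                f"patch at ({p.x},{p.y}) overlaps a previously stitched patch "
                "at the mask scale; stitching requires non-overlapping tiling"
            )
        covered[block] = True
        labels[block] = p.dominant_class
    return SlideMask(labels=labels, r=r, slide_id=slide_id)


def _fp(selem: StructuringElement | np.ndarray) -> np.ndarray:
    if isinstance(selem, StructuringElement):
        return selem.footprint()
    return np.asarray(selem, dtype=bool)


def dilate(mask: np.ndarray, selem: StructuringElement | np.ndarray) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=_fp(selem), border_value=0)


def erode(mask: np.ndarray, selem: StructuringElement | np.ndarray) -> np.ndarray:
    return ndimage.binary_erosion(mask, structure=_fp(selem), border_value=0)


def closing(mask: np.ndarray, selem: StructuringElement | np.ndarray) -> np.ndarray:
    # dilation followed by erosion, both with empty exterior
    return erode(dilate(mask, selem), selem)


def _label_components(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    return ndimage.label(mask, structure=structure)


def detect_interface(
    mask: SlideMask,
    selem: StructuringElement = StructuringElement(),
    connectivity: int = 8,
    closing_selem: StructuringElement | None = None,
) -> InterfaceResult:
    """Apply the morphological interface formula to a slide mask.

    ``closing_selem`` optionally overrides the element used for the two
    closings (the same S is used everywhere by default).  An empty tumor or
    stroma mask yields an empty interface, not an error.
    """
    if not np.isin(mask.labels, [BACKGROUND, TUMOR, STROMA]).all():
        raise ValueError("slide mask contains labels outside {0,1,2}")
    s_close = closing_selem if closing_selem is not None else selem
    tumor_core = closing(mask.tumor, s_close)
    stroma_core = closing(mask.stroma, s_close)
    band = dilate(stroma_core, selem) ^ erode(stroma_core, selem)
    interface = band & stroma_core & dilate(tumor_core, selem)

    labeled, n = _label_components(interface, connectivity)
    comps = []
    if n:
        sizes = np.bincount(labeled.ravel())[1:]
        objs = ndimage.find_objects(labeled)
        for cid in range(1, n + 1):
            sl = objs[cid - 1]
            bbox = (sl[1].start, sl[0].start, sl[1].stop, sl[0].stop)  # x0,y0,x1,y1
            comps.append((cid, int(sizes[cid - 1]), bbox))
        comps.sort(key=lambda c: (-c[1], c[0]))
    return InterfaceResult(
        interface_mask=interface, components=comps, component_labels=labeled
    )


def top_k_components(
    result: InterfaceResult, k: int = 5
) -> list[tuple[int, int, tuple[int, int, int, int]]]:
    """The ``min(k, count)`` largest components; size ties resolve to the
    smaller (scan-order) component id, stable across runs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return result.components[:k]


def boundary_band(mask: SlideMask, selem: StructuringElement = StructuringElement()) -> np.ndarray:
    """Ground-truth interface band of a labeled mask: stroma pixels within
    one structuring-element radius of tumor (stroma AND dilate(tumor, S))."""
    return mask.stroma & dilate(mask.tumor, selem)


def band_recovery(
    interface_mask: np.ndarray,
    truth: SlideMask,
    selem: StructuringElement = StructuringElement(),
) -> tuple[float, float]:
    """Evaluate a detected interface against a ground-truth mask.

    Returns ``(recovery, far_field_rate)``: the fraction of the true
    boundary band covered by the detection, and the fraction of far-field
    stroma (beyond one element radius of tumor) wrongly included.  Either is
    NaN when its reference set is empty.
    """
    band = boundary_band(truth, selem)
    far = truth.stroma & ~band
    recovery = float((interface_mask & band).sum() / band.sum()) if band.any() else float("nan")
    far_rate = float((interface_mask & far).sum() / far.sum()) if far.any() else float("nan")
    return recovery, far_rate
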