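"""Foreground detection, sliding-window patch extraction, and raster I/O.

Whole-slide images are bright-field scans: tissue is darker than the glass
background, so foreground is detected by thresholding the L (lightness)
channel of the CIELAB color space.  Patches are enumerated on a stride
lattice in row-major order; coordinates are 0-based, x right / y down, with
half-open pixel intervals ``[origin, origin + size)``.  Partial tiles at the
right/bottom edges are dropped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2lab

#: Fallback L-channel threshold (CIELAB lightness, 0-100).  Glass background
#: on a bright-field scan sits near L=95; stained tissue well below 85.
DEFAULT_L_THRESHOLD = 85.0


@dataclass(frozen=True)
class TilingConfig:
    """Sliding-window parameters.

    ``stride`` defaults to 128 (half-overlapping windows, used to enlarge
    training sets).  For inference tiling pass ``stride=patch_size`` so
    tiles do not overlap.  ``fg_downsample`` is the integer factor at which
    the slide-level foreground mask is computed; ``max_background_frac`` is
    the exclusion rule: a patch whose background fraction (recomputed at
    full resolution) exceeds it is dropped.
    """

    patch_size: int = 256
    stride: int = 128
    fg_downsample: int = 128
    max_background_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if not (0 < self.stride <= self.patch_size):
            raise ValueError("stride must satisfy 0 < stride <= patch_size")
        if self.fg_downsample < 1:
            raise ValueError("fg_downsample must be >= 1")
        if not (0 < self.max_background_frac <= 1):
            raise ValueError("max_background_frac must be in (0, 1]")


@dataclass
class PatchRecord:
    """One extracted tile and its bookkeeping.

    ``x``/``y`` are the level-0 pixel origin of the tile.  ``background_frac``
    is the fraction of tile pixels classified as background by the L-channel
    rule at full resolution.  Optional fields are filled by the synthetic
    generator (ground-truth labels) or by model inference (predictions).
    """

    slide_id: str
    x: int
    y: int
    size: int
    image: np.ndarray
    background_frac: float
    label: Optional[str] = None
    tsr_labels: Optional[dict] = None
    pixel_labels: Optional[np.ndarray] = None
    pixel_scores: Optional[dict] = None
    predictions: Optional[dict] = field(default=None)


def lightness(image: np.ndarray) -> np.ndarray:
    """CIELAB L channel (0-100) of an RGB image (uint8 or float in [0,1])."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    if image.size == 0:
        raise ValueError("empty image")
    return rgb2lab(image)[..., 0]


def _resolve_threshold(lab_l: np.ndarray, method: str, threshold: Optional[float]) -> float:
    if method == "fixed":
        return DEFAULT_L_THRESHOLD if threshold is None else float(threshold)
    if method == "otsu":
        from skimage.filters import threshold_otsu

        # A (near-)constant image has no bimodal split; fall back to the
        # fixed default so uniform glass reads as background and uniform
        # tissue as foreground.
        if float(lab_l.max() - lab_l.min()) < 1e-6:
            return DEFAULT_L_THRESHOLD if threshold is None else float(threshold)
        return float(threshold_otsu(lab_l))
    raise ValueError(f"unknown foreground method: {method!r}")


def detect_foreground(
    image: np.ndarray,
    method: str = "otsu",
    threshold: Optional[float] = None,
) -> np.ndarray:
    """Binary tissue mask: a pixel is foreground iff its L value is below
    the threshold.

    ``method='otsu'`` picks the threshold automatically from the L
    histogram (with a fixed fallback for degenerate, single-mode images);
    ``method='fixed'`` uses ``threshold`` (default ``DEFAULT_L_THRESHOLD``).
    """
    lab_l = lightness(image)
    thr = _resolve_threshold(lab_l, method, threshold)
    return lab_l < thr


def extract_patches(
    image: np.ndarray,
    config: TilingConfig,
    slide_id: str = "slide",
    fg_mask: Optional[np.ndarray] = None,
    method: str = "otsu",
    threshold: Optional[float] = None,
) -> list[PatchRecord]:
    """Tile a slide and keep patches that are mostly tissue.

    Grid positions are enumerated row-major with the configured stride;
    partial tiles at the right/bottom edges are dropped.  Each tile's
    background fraction is recomputed at full patch resolution with the same
    L-threshold rule used for slide-level foreground detection (one
    threshold, resolved once per slide).  ``fg_mask``, when given at the
    ``fg_downsample`` scale, is only a pre-filter: tiles whose coarse
    footprint contains no foreground are skipped without decoding.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    ps, st = config.patch_size, config.stride
    if ps > h or ps > w:
        raise ValueError(f"patch_size {ps} exceeds slide dims {w}x{h}")

    lab_l = lightness(image)
    thr = _resolve_threshold(lab_l, method, threshold)
    background = lab_l >= thr

    f = config.fg_downsample
    records: list[PatchRecord] = []
    for y in range(0, h - ps + 1, st):
        for x in range(0, w - ps + 1, st):
            if fg_mask is not None:
                coarse = fg_mask[y // f : -(-(y + ps) // f), x // f : -(-(x + ps) // f)]
                if coarse.size and not coarse.any():
                    continue
            bg_frac = float(background[y : y + ps, x : x + ps].mean())
            if bg_frac > config.max_background_frac:
                continue
            records.append(
                PatchRecord(
                    slide_id=slide_id,
                    x=x,
                    y=y,
                    size=ps,
                    image=image[y : y + ps, x : x + ps],
                    background_frac=bg_frac,
                )
            )
    return records


# ---------------------------------------------------------------------------
# raster and manifest I/O (lossless formats only)

def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF image as a numpy array (RGB kept as uint8)."""
    with Image.open(path) as im:
        return np.asarray(im)


def write_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write an RGB or single-channel raster as PNG/TIFF (lossless)."""
    Image.fromarray(np.asarray(image)).save(path)


def write_mask_png(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_mask_png(path: str | os.PathLike) -> np.ndarray:
    """Read a {0, 255} PNG back to a boolean mask."""
    return read_image(path) > 127


def patch_filename(record: PatchRecord) -> str:
    return f"{record.slide_id}_{record.x}_{record.y}.png"


def write_patches(records: Sequence[PatchRecord], out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write patch PNGs named ``{slide}_{x}_{y}.png`` plus a CSV manifest;
    returns the manifest frame."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in records:
        name = patch_filename(rec)
        write_image(os.path.join(out_dir, name), rec.image)
        rows.append(
            {
                "slide_id": rec.slide_id,
                "x": rec.x,
                "y": rec.y,
                "size": rec.size,
                "background_frac": rec.background_frac,
                "filename": name,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "patch_manifest.csv"), index=False)
    return manifest


def read_patches(manifest_dir: str | os.PathLike) -> list[PatchRecord]:
    """Rebuild PatchRecords from a directory written by :func:`write_patches`."""
    manifest = pd.read_csv(os.path.join(manifest_dir, "patch_manifest.csv"))
    records = []
    for row in manifest.itertuples(index=False):
        img = read_image(os.path.join(manifest_dir, row.filename))
        records.append(
            PatchRecord(
                slide_id=row.slide_id,
                x=int(row.x),
                y=int(row.y),
                size=int(row.size),
                image=img,
                background_frac=float(row.background_frac),
            )
        )
    return records
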