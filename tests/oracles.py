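"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes quantities from first principles (exhaustive
neighborhood scans, flood fill, threshold enumeration, per-pixel polygon
tests) without touching the package's own code paths.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# binary morphology by exhaustive neighborhood scan (outside image = empty)

def _offsets(footprint: np.ndarray) -> list[tuple[int, int]]:
    fh, fw = footprint.shape
    cy, cx = fh // 2, fw // 2
    return [
        (i - cy, j - cx)
        for i in range(fh)
        for j in range(fw)
        if footprint[i, j]
    ]


def _shift(mask: np.ndarray, dy: int, dx: int, fill: bool) -> np.ndarray:
    """Translate a mask by (dy, dx), filling vacated cells with ``fill``."""
    h, w = mask.shape
    out = np.full((h, w), fill, dtype=bool)
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = mask[ys_src, xs_src]
    return out


def brute_dilate(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """dilate(M)[p] = any M[p - o] over the explicit footprint offsets o
    (symmetric footprints make the reflection irrelevant); out-of-image
    counts as empty."""
    out = np.zeros(mask.shape, dtype=bool)
    for dy, dx in _offsets(footprint):
        out |= _shift(mask, dy, dx, fill=False)
    return out


def brute_erode(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """erode(M)[p] = all M[p + o]; out-of-image counts as empty, so the
    image border erodes."""
    out = np.ones(mask.shape, dtype=bool)
    for dy, dx in _offsets(footprint):
        out &= _shift(mask, -dy, -dx, fill=False)
    return out


def brute_close(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return brute_erode(brute_dilate(mask, footprint), footprint)


def brute_interface(tumor: np.ndarray, stroma: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """The interface formula composed from the brute-force operators."""
    tumor_core = brute_close(tumor, footprint)
    stroma_core = brute_close(stroma, footprint)
    band = brute_dilate(stroma_core, footprint) ^ brute_erode(stroma_core, footprint)
    return band & stroma_core & brute_dilate(tumor_core, footprint)


# ---------------------------------------------------------------------------
# connected components by flood fill

def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> list[int]:
    """Component pixel counts in scan order (first-seen order)."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    sizes = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                stack = [(y, x)]
                seen[y, x] = True
                count = 0
                while stack:
                    cy, cx = stack.pop()
                    count += 1
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                sizes.append(count)
    return sizes


# ---------------------------------------------------------------------------
# average precision by exhaustive threshold enumeration

def brute_average_precision(scores: np.ndarray, truth: np.ndarray) -> float:
    """Walk the distinct thresholds from high to low; at each, classify
    score >= t as positive, record (precision, recall); AP is the sum of
    precision * recall increments."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    n_pos = truth.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores.tolist()), reverse=True):
        pred = scores >= t
        tp = (pred & truth).sum()
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return float(ap)


# ---------------------------------------------------------------------------
# tile-by-tile extraction oracle

def brute_surviving_tiles(
    background: np.ndarray, patch_size: int, stride: int, max_bg: float
) -> list[tuple[int, int]]:
    """Enumerate every full tile and apply the background-fraction rule."""
    h, w = background.shape
    keep = []
    for y in range(0, h - patch_size + 1, stride):
        for x in range(0, w - patch_size + 1, stride):
            frac = background[y : y + patch_size, x : x + patch_size].mean()
            if frac <= max_bg:
                keep.append((x, y))
    return keep


# ---------------------------------------------------------------------------
# point-in-polygon by per-pixel even-odd ray casting

def brute_polygon_mask(
    polygon: list[tuple[float, float]], shape: tuple[int, int], origin: tuple[int, int] = (0, 0)
) -> np.ndarray:
    """Even-odd rule applied to every pixel center, one crossing test at a
    time (no geometry library)."""
    h, w = shape
    x0, y0 = origin
    out = np.zeros((h, w), dtype=bool)
    n = len(polygon)
    for iy in range(h):
        py = iy + y0 + 0.5
        for ix in range(w):
            px = ix + x0 + 0.5
            inside = False
            for i in range(n):
                x1, y1 = polygon[i]
                x2, y2 = polygon[(i + 1) % n]
                if (y1 > py) != (y2 > py):
                    xcross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < xcross:
                        inside = not inside
            out[iy, ix] = inside
    return out
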