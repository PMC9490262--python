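"""Polygon ROI annotations with TSR sub-scores.

Pathologist annotations are exchanged as a GeoJSON FeatureCollection (the
format QuPath exports), one feature per polygon:

* a feature with ``properties.kind == "boundary"`` is the outline of one
  region of interest (ROI), identified by ``properties.roi_id``;
* a feature with ``properties.kind == "score_region"`` is a homogeneous
  sub-region of that ROI carrying ``properties.criterion`` (fibrosis,
  cellularity or orientation) and ``properties.score`` (0, 1 or 2).

Coordinates are level-0 pixel positions (x right, y down).  Rasterization
tests pixel *centers* against each polygon (even-odd rule, unambiguous for
the simple polygons this module requires); when scored sub-regions overlap,
later features overwrite earlier ones (file order, last wins) with a
warning.

The training-mask algebra mirrors the study design: stroma is the union of
all scored sub-regions (any criterion, any score), and tumor is the
remaining tissue inside the ROI.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon
from shapely import contains_xy

from .synthetic_data import CRITERIA, TSR_UNDEFINED

VALID_SCORES = (0, 1, 2)


class AnnotationError(ValueError):
    """A malformed or inconsistent annotation file."""


@dataclass(frozen=True)
class SubRegion:
    polygon: tuple[tuple[float, float], ...]
    criterion: str
    score: int


@dataclass
class ROIAnnotation:
    """One ROI: its boundary polygon plus scored sub-regions."""

    roi_id: str
    boundary: tuple[tuple[float, float], ...]
    sub_regions: list[SubRegion] = field(default_factory=list)

    def bounding_box(self) -> tuple[int, int, int, int]:
        """Integer pixel bounding box (x0, y0, x1, y1), half-open."""
        xs = [p[0] for p in self.boundary]
        ys = [p[1] for p in self.boundary]
        return (
            math.floor(min(xs)),
            math.floor(min(ys)),
            math.ceil(max(xs)),
            math.ceil(max(ys)),
        )


def _validate_polygon(coords: Sequence[Sequence[float]], roi_id: str, what: str) -> Polygon:
    if len(coords) < 3:
        raise AnnotationError(f"ROI {roi_id!r}: {what} polygon has fewer than 3 vertices")
    poly = Polygon(coords)
    if not poly.is_valid or not poly.is_simple:
        raise AnnotationError(f"ROI {roi_id!r}: {what} polygon is self-intersecting")
    if poly.area <= 0:
        raise AnnotationError(f"ROI {roi_id!r}: {what} polygon has zero area")
    return poly


def parse_annotations(source: str | os.PathLike | dict) -> list[ROIAnnotation]:
    """Parse a GeoJSON FeatureCollection into validated ROI annotations.

    ``source`` is a file path or an already-loaded GeoJSON dict.  Unknown
    criterion names, scores outside {0,1,2} and self-intersecting polygons
    raise :class:`AnnotationError` naming the offending roi_id.  Sub-region
    file order is preserved (it defines overlap precedence).
    """
    if isinstance(source, dict):
        doc = source
    else:
        with open(source) as fh:
            doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise AnnotationError("expected a GeoJSON FeatureCollection")

    rois: dict[str, ROIAnnotation] = {}
    pending: list[tuple[str, SubRegion]] = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        geom = feat.get("geometry", {})
        roi_id = str(props.get("roi_id", ""))
        if not roi_id:
            raise AnnotationError("feature without a roi_id property")
        if geom.get("type") != "Polygon":
            raise AnnotationError(f"ROI {roi_id!r}: only Polygon geometry is supported")
        coords = [tuple(map(float, pt)) for pt in geom["coordinates"][0]]
        if coords and coords[0] == coords[-1]:
            coords = coords[:-1]  # drop GeoJSON ring closure
        kind = props.get("kind")
        if kind == "boundary":
            _validate_polygon(coords, roi_id, "boundary")
            if roi_id in rois:
                raise AnnotationError(f"duplicate boundary for ROI {roi_id!r}")
            rois[roi_id] = ROIAnnotation(roi_id=roi_id, boundary=tuple(coords))
        elif kind == "score_region":
            criterion = props.get("criterion")
            if criterion not in CRITERIA:
                raise AnnotationError(
                    f"ROI {roi_id!r}: unknown criterion {criterion!r}"
                )
            score = props.get("score")
            if score not in VALID_SCORES:
                raise AnnotationError(
                    f"ROI {roi_id!r}: score {score!r} outside {{0,1,2}}"
                )
            _validate_polygon(coords, roi_id, f"{criterion} sub-region")
            pending.append(
                (roi_id, SubRegion(polygon=tuple(coords), criterion=criterion, score=int(score)))
            )
        else:
            raise AnnotationError(f"ROI {roi_id!r}: unknown feature kind {kind!r}")

    for roi_id, sub in pending:
        if roi_id not in rois:
            raise AnnotationError(f"sub-region references unknown ROI {roi_id!r}")
        rois[roi_id].sub_regions.append(sub)
    return list(rois.values())


def write_annotations(rois: Sequence[ROIAnnotation], path: str | os.PathLike) -> None:
    """Serialize ROIs back to the GeoJSON dialect (round-trip exact)."""
    features = []
    for roi in rois:
        ring = [list(pt) for pt in roi.boundary] + [list(roi.boundary[0])]
        features.append(
            {
                "type": "Feature",
                "properties": {"roi_id": roi.roi_id, "kind": "boundary"},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
        for sub in roi.sub_regions:
            ring = [list(pt) for pt in sub.polygon] + [list(sub.polygon[0])]
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "roi_id": roi.roi_id,
                        "kind": "score_region",
                        "criterion": sub.criterion,
                        "score": sub.score,
                    },
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _fill_polygon(
    mask: np.ndarray,
    value,
    polygon: Sequence[tuple[float, float]],
    origin: tuple[int, int],
) -> np.ndarray:
    """Set mask pixels whose centers fall inside the polygon; returns the
    boolean inside-mask."""
    x0, y0 = origin
    poly = Polygon(polygon)
    minx, miny, maxx, maxy = poly.bounds
    cx0 = max(int(math.floor(minx - x0)), 0)
    cy0 = max(int(math.floor(miny - y0)), 0)
    cx1 = min(int(math.ceil(maxx - x0)) + 1, mask.shape[1])
    cy1 = min(int(math.ceil(maxy - y0)) + 1, mask.shape[0])
    inside_full = np.zeros(mask.shape, dtype=bool)
    if cx1 <= cx0 or cy1 <= cy0:
        return inside_full
    yy, xx = np.mgrid[cy0:cy1, cx0:cx1]
    inside = contains_xy(poly, xx + x0 + 0.5, yy + y0 + 0.5)
    inside_full[cy0:cy1, cx0:cx1] = inside
    mask[inside_full] = value
    return inside_full


def rasterize_scores(roi: ROIAnnotation, criterion: str) -> np.ndarray:
    """Integer score mask over the ROI bounding box.

    Pixel value = score of the containing sub-region for ``criterion``;
    pixels in no sub-region hold the sentinel :data:`TSR_UNDEFINED`.
    Later sub-regions overwrite earlier ones on overlap (with a warning).
    """
    if criterion not in CRITERIA:
        raise AnnotationError(f"unknown criterion {criterion!r}")
    subs = [s for s in roi.sub_regions if s.criterion == criterion]
    if not subs:
        raise AnnotationError(
            f"ROI {roi.roi_id!r}: no sub-regions for criterion {criterion!r}"
        )
    x0, y0, x1, y1 = roi.bounding_box()
    mask = np.full((y1 - y0, x1 - x0), TSR_UNDEFINED, dtype=np.uint8)
    painted = np.zeros(mask.shape, dtype=bool)
    for sub in subs:
        inside = _fill_polygon(mask, sub.score, sub.polygon, (x0, y0))
        if (inside & painted).any():
            warnings.warn(
                f"ROI {roi.roi_id!r}: overlapping {criterion} sub-regions; "
                "later polygon wins",
                stacklevel=2,
            )
        painted |= inside
    return mask


def derive_tumor_stroma(
    roi: ROIAnnotation, tissue_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Training masks over the ROI bounding box.

    Stroma is the union of all scored sub-regions (any criterion, any
    score) clipped to tissue inside the ROI; tumor is the remaining tissue
    inside the ROI.  The two masks are disjoint by construction.
    """
    x0, y0, x1, y1 = roi.bounding_box()
    shape = (y1 - y0, x1 - x0)
    if tissue_mask.shape != shape:
        raise AnnotationError(
            f"tissue_mask shape {tissue_mask.shape} does not cover the ROI "
            f"bounding box {shape}"
        )
    roi_mask = np.zeros(shape, dtype=bool)
    _fill_polygon(roi_mask, True, roi.boundary, (x0, y0))
    stroma_union = np.zeros(shape, dtype=bool)
    for sub in roi.sub_regions:
        _fill_polygon(stroma_union, True, sub.polygon, (x0, y0))
    tissue_roi = np.asarray(tissue_mask, dtype=bool) & roi_mask
    stroma = stroma_union & tissue_roi
    tumor = tissue_roi & ~stroma
    return tumor, stroma
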