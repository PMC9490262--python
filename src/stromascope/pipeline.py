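"""End-to-end slide pipeline: tile -> predict -> stitch -> interface -> summarize.

Convenience wrappers chaining the module-level operations in the order a
whole-slide run uses them, plus the ground-truth counterpart for phantoms
(used to evaluate interface recovery at the scale the pipeline operates
on: the stitched mask is patch-granular, so its truth is the dominant
ground-truth class of each tile stitched the same way).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly_interface import (
    InterfaceResult,
    SlideMask,
    StructuringElement,
    detect_interface,
    stitch_patches,
)
from .patch_models import (
    BACKGROUND,
    STROMA,
    TUMOR,
    PatchPrediction,
    SegmenterBackend,
    TSRScorerBackend,
    predict_slide,
)
from .summarization import SlideFeatureRow, summarize_slide
from .synthetic_data import PhantomSlide, generate_labeled_patches
from .tiling_io import TilingConfig, extract_patches


@dataclass
class SlidePipelineResult:
    predictions: list[PatchPrediction]
    slide_mask: SlideMask
    interface: InterfaceResult
    features: SlideFeatureRow


def run_slide(
    image: np.ndarray,
    segmenter: SegmenterBackend,
    scorers: dict[str, TSRScorerBackend],
    tile_config: TilingConfig | None = None,
    r: float = 1.0 / 128.0,
    selem: StructuringElement = StructuringElement(),
    slide_id: str = "slide",
) -> SlidePipelineResult:
    """Run the whole per-slide chain on an RGB slide image.

    Inference tiling is non-overlapping (stride = patch size) so that
    stitched blocks tile the mask exactly.
    """
    if tile_config is None:
        tile_config = TilingConfig(stride=256)
    if tile_config.stride != tile_config.patch_size:
        raise ValueError("inference tiling requires stride == patch_size")
    # Fixed L threshold: the automatic bimodal threshold can split the wrong
    # valley when tissue itself is strongly multimodal (dark tumor + light
    # stroma), misreading pale stroma as glass.
    patches = extract_patches(image, tile_config, slide_id=slide_id, method="fixed")
    preds = predict_slide(patches, segmenter, scorers)
    mask = stitch_patches(preds, image.shape[:2], r=r, slide_id=slide_id)
    interface = detect_interface(mask, selem)
    features = summarize_slide(preds, interface.interface_mask, r, slide_id=slide_id)
    return SlidePipelineResult(
        predictions=preds, slide_mask=mask, interface=interface, features=features
    )


def ground_truth_slide_mask(
    slide: PhantomSlide,
    tile_config: TilingConfig | None = None,
    r: float = 1.0 / 128.0,
) -> SlideMask:
    """Stitch the *ground-truth* dominant class of each tile into a slide
    mask — the patch-granular truth against which the stitched prediction
    and its interface are judged."""
    if tile_config is None:
        tile_config = TilingConfig(stride=256)
    if tile_config.stride != tile_config.patch_size:
        raise ValueError("inference tiling requires stride == patch_size")
    records = generate_labeled_patches(slide, tile_config)
    preds = []
    for rec in records:
        if rec.background_frac > tile_config.max_background_frac:
            dom = BACKGROUND  # same exclusion rule the extraction applies
        else:
            dom = {"background": BACKGROUND, "tumor": TUMOR, "stroma": STROMA}[rec.label]
        preds.append(
            PatchPrediction(
                slide_id=slide.slide_id,
                x=rec.x,
                y=rec.y,
                size=rec.size,
                class_mask=rec.pixel_labels,
                dominant_class=dom,
            )
        )
    return stitch_patches(preds, slide.tumor_mask.shape, r=r, slide_id=slide.slide_id)
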