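"""Slide-level TSR feature summarization.

Interface region sizes vary from slide to slide, so per-slide descriptors
are scale-free: the normalized distribution of predicted TSR scores
(ratio_0/1/2) over interface patches, plus the mean and population standard
deviation of the {0,1,2} scores, for each criterion.  Every interface patch
carries equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .patch_models import STROMA, PatchPrediction
from .synthetic_data import CRITERIA


@dataclass
class SlideFeatureRow:
    """Per-slide TSR summary.

    ``features[criterion]`` holds ratio_0, ratio_1, ratio_2, mean_score and
    sd_score.  When no stroma patch overlaps the interface the row is
    emitted with ``valid=False`` and NaN features rather than silent zeros.
    """

    slide_id: str
    n_interface_patches: int
    valid: bool
    features: dict = field(default_factory=dict)

    def to_flat_dict(self) -> dict:
        out = {"slide_id": self.slide_id, "n_interface_patches": self.n_interface_patches,
               "valid": self.valid}
        for crit, f in self.features.items():
            for key, val in f.items():
                out[f"{crit}_{key}"] = val
        return out


def _patch_in_interface(
    pred: PatchPrediction, interface: np.ndarray, r: float, min_overlap: float
) -> bool:
    y0 = int(round(pred.y * r))
    x0 = int(round(pred.x * r))
    y1 = min(int(round((pred.y + pred.size) * r)), interface.shape[0])
    x1 = min(int(round((pred.x + pred.size) * r)), interface.shape[1])
    block = interface[y0:y1, x0:x1]
    if block.size == 0:
        return False
    frac = float(block.mean())
    if min_overlap <= 0:
        return frac > 0.0
    return frac >= min_overlap


def summarize_slide(
    preds: Sequence[PatchPrediction],
    interface_mask: np.ndarray,
    r: float,
    slide_id: str | None = None,
    min_overlap: float = 0.0,
    criteria: Sequence[str] = CRITERIA,
) -> SlideFeatureRow:
    """Summarize scored stroma patches inside the interface into one row.

    A patch is "within the interface" iff the fraction of its down-sampled
    footprint intersecting ``interface_mask`` exceeds ``min_overlap`` (any
    overlap by default).  Only stroma-dominant patches carry scores, so only
    those are counted.
    """
    scored = [
        p
        for p in preds
        if p.dominant_class == STROMA
        and p.tsr_scores is not None
        and _patch_in_interface(p, interface_mask, r, min_overlap)
    ]
    if slide_id is None:
        slide_id = preds[0].slide_id if preds else "slide"
    n = len(scored)
    row = SlideFeatureRow(slide_id=slide_id, n_interface_patches=n, valid=n > 0)
    for crit in criteria:
        if n == 0:
            row.features[crit] = {
                k: float("nan")
                for k in ("ratio_0", "ratio_1", "ratio_2", "mean_score", "sd_score")
            }
            continue
        scores = np.array([p.tsr_scores[crit] for p in scored], dtype=float)
        counts = np.bincount(scores.astype(int), minlength=3)[:3]
        ratios = counts / n
        row.features[crit] = {
            "ratio_0": float(ratios[0]),
            "ratio_1": float(ratios[1]),
            "ratio_2": float(ratios[2]),
            "mean_score": float(scores.mean()),
            "sd_score": float(scores.std()),  # population SD
        }
    return row


def rows_to_frame(rows: Sequence[SlideFeatureRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_flat_dict() for r in rows])


def build_cohort_table(
    rows: Sequence[SlideFeatureRow] | pd.DataFrame,
    clinical: pd.DataFrame,
    mapping: dict[str, str] | None = None,
    aggregate: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Join slide features onto the clinical table.

    ``mapping`` maps slide id -> case id (identity by default).  Multiple
    slides per case are rejected unless ``aggregate='mean'`` averages their
    numeric features.  Returns the inner-joined table plus a report of
    unmatched slide and case ids.
    """
    feats = rows if isinstance(rows, pd.DataFrame) else rows_to_frame(rows)
    feats = feats.copy()
    if mapping is not None:
        feats["case_id"] = feats["slide_id"].map(mapping)
    else:
        feats["case_id"] = feats["slide_id"]
    unmatched_slides = feats.loc[
        ~feats["case_id"].isin(clinical["case_id"]), "slide_id"
    ].tolist()
    feats = feats[feats["case_id"].isin(clinical["case_id"])]

    dup = feats["case_id"].duplicated()
    if dup.any():
        if aggregate is None:
            dups = sorted(feats.loc[dup, "case_id"].unique())
            raise ValueError(
                f"multiple slides map to case(s) {dups}; pass aggregate='mean' to average"
            )
        if aggregate != "mean":
            raise ValueError(f"unsupported aggregation {aggregate!r}")
        numeric = feats.select_dtypes(include="number").columns
        feats = feats.groupby("case_id", as_index=False)[list(numeric)].mean()

    joined = clinical.merge(feats, on="case_id", how="inner")
    unmatched_cases = clinical.loc[
        ~clinical["case_id"].isin(feats["case_id"]), "case_id"
    ].tolist()
    report = {"unmatched_slides": unmatched_slides, "unmatched_cases": unmatched_cases}
    return joined, report
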