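"""Synthetic phantom slides and cohorts with known ground truth.

Real tumor-stroma reaction (TSR) studies need annotated H&E whole-slide
images, survival follow-up, and tumor transcriptomes.  This module
fabricates all three with *planted* structure so that every downstream
stage — tiling, segmentation, TSR scoring, interface detection,
summarization, association — can be tested against a known answer:

* **Phantom slides** contain smooth tumor blobs surrounded by stroma inside
  an elliptical tissue region on a bright background.  The two tissue
  classes and the three stroma TSR grades are rendered with deliberately
  disjoint base-color ranges (plus grade-dependent stripe/dot texture) so a
  classical color/texture classifier can succeed; a narrower "hard" mode is
  available for robustness experiments.
* **TSR grading is spatial**: each stroma pixel's score decays with
  Euclidean distance from the nearest tumor blob (2 near, then 1, then 0),
  which creates a true desmoplastic band hugging the tumor border — the
  ground-truth tumor-stroma interface.
* **Case classes** mimic the study design: carcinoma-like slides (HGSOC
  role) carry the graded reaction; borderline-like slides (SBOT role) have
  tumor and stroma but a TSR score identically 0, serving as negative
  controls.
* **Synthetic cohorts** pair per-case survival (exponential, with a planted
  log hazard ratio for the fibrosis-high half) with a genes x cases
  expression matrix in which a chosen fraction of genes depends linearly on
  the case fibrosis score and the rest are independent noise.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter, zoom

from .tiling_io import PatchRecord, TilingConfig, write_image, write_mask_png

CRITERIA = ("fibrosis", "cellularity", "orientation")

#: sentinel for "TSR score undefined" (non-stroma pixels) in score rasters
TSR_UNDEFINED = 255

HGSOC_LIKE = "HGSOC-like"
SBOT_LIKE = "SBOT-like"


@dataclass(frozen=True)
class TextureParams:
    """Rendering parameters for one (class, grade) texture."""

    base_rgb: tuple[int, int, int]
    noise_amp: float = 7.0
    stripe_freq: float = 0.0     # cycles / pixel, orientation grading
    stripe_angle: float = 0.0    # radians
    stripe_amp: float = 0.0
    dot_density: float = 0.0     # dots / pixel, cellularity grading
    fiber_density: float = 0.0   # fiber segments / pixel, fibrosis grading


#: Default textures: disjoint base-color ranges by construction
#: (noise_amp 7 keeps each class within +-21 of its base after smoothing).
DEFAULT_TUMOR_TEXTURE = TextureParams(base_rgb=(112, 62, 152))
DEFAULT_STROMA_TEXTURES = {
    0: TextureParams(base_rgb=(233, 190, 208)),
    1: TextureParams(
        base_rgb=(212, 140, 176), stripe_freq=0.06, stripe_amp=6.0,
        dot_density=0.002, fiber_density=0.001,
    ),
    2: TextureParams(
        base_rgb=(182, 88, 142), stripe_freq=0.12, stripe_amp=10.0,
        dot_density=0.006, fiber_density=0.003,
    ),
}

#: "hard mode": narrower color separation for robustness testing
HARD_STROMA_TEXTURES = {
    0: TextureParams(base_rgb=(226, 178, 200), noise_amp=12.0),
    1: TextureParams(base_rgb=(214, 158, 186), noise_amp=12.0, stripe_freq=0.06, stripe_amp=4.0),
    2: TextureParams(base_rgb=(200, 138, 170), noise_amp=12.0, stripe_freq=0.12, stripe_amp=6.0),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one phantom slide.

    ``score2_dist``/``score1_dist`` are the Euclidean-distance thresholds
    (pixels from the nearest tumor pixel) below which a stroma pixel is
    graded 2 and 1 respectively; beyond ``score1_dist`` the grade is 0.
    """

    width: int = 1024
    height: int = 1024
    label: str = HGSOC_LIKE
    tumor_blob_count: int = 3
    blob_radius_frac: tuple[float, float] = (0.10, 0.16)  # of min(width, height)
    blob_center_frac: tuple[float, float] = (0.32, 0.68)  # center placement range
    score2_dist: float = 80.0
    score1_dist: float = 200.0
    tumor_texture: TextureParams = DEFAULT_TUMOR_TEXTURE
    stroma_textures: dict = field(default_factory=lambda: dict(DEFAULT_STROMA_TEXTURES))
    background_rgb: tuple[int, int, int] = (244, 244, 244)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 512 or self.height < 512:
            raise ValueError("phantom slides must be at least 512x512 pixels")
        if self.label not in (HGSOC_LIKE, SBOT_LIKE):
            raise ValueError(f"unknown case class {self.label!r}")
        if self.label == HGSOC_LIKE and self.tumor_blob_count < 1:
            raise ValueError("a carcinoma-like slide needs at least one tumor blob")
        if not (0 < self.score2_dist < self.score1_dist):
            raise ValueError("need 0 < score2_dist < score1_dist")


@dataclass
class PhantomSlide:
    """A rendered phantom plus its ground truth.

    ``tsr_maps[criterion]`` is a uint8 raster holding scores {0,1,2} on
    stroma pixels and :data:`TSR_UNDEFINED` elsewhere.
    """

    image: np.ndarray
    tumor_mask: np.ndarray
    stroma_mask: np.ndarray
    tsr_maps: dict[str, np.ndarray]
    label: str
    seed: int
    slide_id: str = "phantom"


def _smooth_noise(
    shape: tuple[int, int],
    sigma: float,
    rng: np.random.Generator,
    coarse: int = 4,
) -> np.ndarray:
    """Smooth correlated noise normalized to max |.| = 1.

    Generated on a ``coarse``-times-smaller grid and bilinearly upsampled,
    which is visually indistinguishable for the sigmas used here and keeps
    large slides cheap.
    """
    h, w = shape
    ch = max(-(-h // coarse), 4)
    cw = max(-(-w // coarse), 4)
    field = gaussian_filter(
        rng.standard_normal((ch, cw)).astype(np.float32), sigma=max(sigma / coarse, 0.5)
    )
    field = zoom(field, (h / ch, w / cw), order=1)[:h, :w]
    return field / max(np.abs(field).max(), 1e-9)


def _tissue_mask(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Elliptical tissue region with a gently irregular boundary."""
    yy = np.arange(h, dtype=np.float32)[:, None]
    xx = np.arange(w, dtype=np.float32)[None, :]
    cy, cx = h / 2, w / 2
    ry, rx = 0.46 * h, 0.46 * w
    r = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    wobble = _smooth_noise((h, w), min(h, w) / 10, rng, coarse=16)
    return r + 0.08 * wobble < 1.0


def _tumor_mask(cfg: PhantomConfig, tissue: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    h, w = tissue.shape
    mask = np.zeros((h, w), dtype=bool)
    rmin, rmax = cfg.blob_radius_frac
    scale = min(h, w)
    c_lo, c_hi = cfg.blob_center_frac
    for _ in range(cfg.tumor_blob_count):
        cy = rng.uniform(c_lo * h, c_hi * h)
        cx = rng.uniform(c_lo * w, c_hi * w)
        radius = rng.uniform(rmin, rmax) * scale
        # low-frequency radial perturbation keeps blobs smooth but not circular
        n_h = 3
        amp = rng.uniform(0.05, 0.12, size=n_h)
        phase = rng.uniform(0, 2 * np.pi, size=n_h)
        # rasterize only inside the blob's bounding box
        rmax_px = radius * (1.0 + amp.sum())
        y0, y1 = max(int(cy - rmax_px - 1), 0), min(int(cy + rmax_px + 2), h)
        x0, x1 = max(int(cx - rmax_px - 1), 0), min(int(cx + rmax_px + 2), w)
        yy = np.arange(y0, y1, dtype=np.float32)[:, None] - cy
        xx = np.arange(x0, x1, dtype=np.float32)[None, :] - cx
        theta = np.arctan2(yy, xx)
        pert = sum(a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amp, phase)))
        mask[y0:y1, x0:x1] |= np.hypot(yy, xx) < radius * (1.0 + pert)
    return mask & tissue


def _render_texture(
    out: np.ndarray,
    region: np.ndarray,
    tex: TextureParams,
    rng: np.random.Generator,
) -> None:
    """Paint ``region`` pixels of ``out`` (uint8 HxWx3) with a texture."""
    if not region.any():
        return
    h, w = region.shape
    base = np.array(tex.base_rgb, dtype=np.float32)
    # smooth correlated noise, shared across channels with per-channel jitter
    noise = _smooth_noise((h, w), 2.0, rng, coarse=2)
    field3 = np.empty((h, w, 3), dtype=np.float32)
    for c in range(3):
        jitter = _smooth_noise((h, w), 1.0, rng, coarse=2)
        field3[..., c] = base[c] + tex.noise_amp * (0.7 * noise + 0.3 * jitter)
    if tex.stripe_amp > 0 and tex.stripe_freq > 0:
        yy = np.arange(h, dtype=np.float32)[:, None]
        xx = np.arange(w, dtype=np.float32)[None, :]
        phase = 2 * np.pi * tex.stripe_freq * (
            np.cos(tex.stripe_angle) * xx + np.sin(tex.stripe_angle) * yy
        )
        stripes = tex.stripe_amp * np.sin(phase + rng.uniform(0, 2 * np.pi))
        field3 -= stripes[..., None].astype(np.float32)
    if tex.dot_density > 0:
        n_dots = rng.poisson(tex.dot_density * h * w)
        if n_dots:
            dy = rng.integers(0, h, n_dots)
            dx = rng.integers(0, w, n_dots)
            dots = np.zeros((h, w), dtype=np.float32)
            dots[dy, dx] = 1.0
            dots = gaussian_filter(dots, sigma=1.2)
            dots /= max(dots.max(), 1e-9)
            field3 -= 35.0 * dots[..., None]
    vals = np.clip(field3, 0, 255).astype(np.uint8)
    out[region] = vals[region]


def generate_phantom_slide(config: PhantomConfig, slide_id: str = "phantom") -> PhantomSlide:
    """Render one phantom slide with ground-truth masks and TSR score maps.

    Tumor is placed as smooth blobs inside an elliptical tissue region;
    stroma fills the remaining tissue.  TSR scores decay with distance from
    the nearest tumor pixel, so grade 2 concentrates at the tumor border.
    Borderline-like (negative control) slides get all-zero score maps.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width

    tissue = _tissue_mask(h, w, rng)
    tumor = _tumor_mask(config, tissue, rng)
    stroma = tissue & ~tumor

    if config.label == SBOT_LIKE:
        score = np.zeros((h, w), dtype=np.uint8)
    else:
        dist = distance_transform_edt(~tumor)
        score = np.zeros((h, w), dtype=np.uint8)
        score[dist <= config.score1_dist] = 1
        score[dist <= config.score2_dist] = 2

    tsr_maps = {}
    for crit in CRITERIA:
        m = np.full((h, w), TSR_UNDEFINED, dtype=np.uint8)
        m[stroma] = score[stroma]
        tsr_maps[crit] = m

    image = np.empty((h, w, 3), dtype=np.uint8)
    image[:] = np.array(config.background_rgb, dtype=np.uint8)
    _render_texture(image, tumor, config.tumor_texture, rng)
    for grade, tex in sorted(config.stroma_textures.items()):
        _render_texture(image, stroma & (score == grade), tex, rng)

    return PhantomSlide(
        image=image,
        tumor_mask=tumor,
        stroma_mask=stroma,
        tsr_maps=tsr_maps,
        label=config.label,
        seed=config.seed,
        slide_id=slide_id,
    )


def generate_labeled_patches(slide: PhantomSlide, tile: TilingConfig) -> list[PatchRecord]:
    """Tile a phantom on the stride lattice and attach ground-truth labels.

    Each patch is labeled tumor/stroma by majority pixel class (ties break
    toward stroma); its TSR label per criterion is the modal score over the
    patch's stroma pixels (absent when the patch has none).  Partial edge
    tiles are dropped, matching the extraction convention.  Patches also
    carry full ground-truth rasters for training pixel-level reference
    backends: ``pixel_labels`` (0 background, 1 tumor, 2 stroma) and
    ``pixel_scores[criterion]`` (grade per pixel, 255 off-stroma).
    """
    h, w = slide.tumor_mask.shape
    ps, st = tile.patch_size, tile.stride
    if ps > h or ps > w:
        raise ValueError("tile size exceeds slide dims")

    pixel_labels = np.zeros((h, w), dtype=np.uint8)
    pixel_labels[slide.tumor_mask] = 1
    pixel_labels[slide.stroma_mask] = 2

    records: list[PatchRecord] = []
    for y in range(0, h - ps + 1, st):
        for x in range(0, w - ps + 1, st):
            lab = pixel_labels[y : y + ps, x : x + ps]
            n_tumor = int((lab == 1).sum())
            n_stroma = int((lab == 2).sum())
            n_bg = lab.size - n_tumor - n_stroma
            if n_tumor == 0 and n_stroma == 0:
                cls = "background"
            else:
                cls = "tumor" if n_tumor > n_stroma else "stroma"
            tsr_labels = None
            pixel_scores = None
            if n_stroma > 0:
                tsr_labels, pixel_scores = {}, {}
                sub = slide.stroma_mask[y : y + ps, x : x + ps]
                for crit in CRITERIA:
                    grades = slide.tsr_maps[crit][y : y + ps, x : x + ps]
                    counts = np.bincount(grades[sub], minlength=3)[:3]
                    tsr_labels[crit] = int(counts.argmax())
                    pixel_scores[crit] = grades
            records.append(
                PatchRecord(
                    slide_id=slide.slide_id,
                    x=x,
                    y=y,
                    size=ps,
                    image=slide.image[y : y + ps, x : x + ps],
                    background_frac=n_bg / lab.size,
                    label=cls,
                    tsr_labels=tsr_labels,
                    pixel_labels=lab,
                    pixel_scores=pixel_scores,
                )
            )
    return records


def cohort_slide_config(seed: int, label: str = HGSOC_LIKE) -> PhantomConfig:
    """Study-scale phantom for end-to-end cohort runs.

    Large enough (3072 px square) that the default 1/128 stitched mask
    resolves the peritumoral band, with tumor blobs placed centrally so the
    stroma ring around them stays several structuring-element radii thick —
    the interface formula cannot recover band pixels where the stroma strip
    between tumor and glass is thinner than the element.  TSR grade
    distances scale with the blob size.
    """
    return PhantomConfig(
        width=3072,
        height=3072,
        label=label,
        tumor_blob_count=2,
        blob_radius_frac=(0.16, 0.20),
        blob_center_frac=(0.40, 0.60),
        score2_dist=160.0,
        score1_dist=400.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# synthetic cohort (survival + expression)

@dataclass
class SyntheticCohort:
    """Clinical table, expression matrix (genes x cases), and the planted truth."""

    clinical: pd.DataFrame
    expression: pd.DataFrame
    planted_genes: list[str]
    planted_log_hr: float


def generate_cohort(
    n_cases: int = 200,
    n_genes: int = 1000,
    planted_log_hr: float = 0.69,
    planted_gene_frac: float = 0.10,
    seed: int = 0,
    baseline_hazard: float = 1.0 / 40.0,
    censor_time: float = 150.0,
    gene_slope: float = 0.7,
) -> SyntheticCohort:
    """Simulate a cohort with a planted fibrosis hazard and gene signal.

    Each case gets a continuous fibrosis score (uniform on [0, 2], the scale
    of a mean 0/1/2 TSR score).  The fibrosis-high half (top half of the
    score) has its exponential survival hazard multiplied by
    ``exp(planted_log_hr)``; follow-up is administratively censored at
    ``censor_time`` months.  A ``planted_gene_frac`` fraction of genes
    depends linearly (positive slope) on the standardized score plus unit
    Gaussian noise; the rest are independent standard normals.  Age, stage
    (III/IV) and debulking status are drawn independently with realistic
    advanced-carcinoma frequencies.
    """
    if n_cases < 20:
        raise ValueError("n_cases must be >= 20")
    if not (0 <= planted_gene_frac < 1):
        raise ValueError("planted_gene_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)

    case_ids = [f"case{i:04d}" for i in range(n_cases)]
    score = rng.uniform(0.0, 2.0, n_cases)
    order = np.argsort(score, kind="stable")
    high = np.zeros(n_cases, dtype=bool)
    high[order[n_cases // 2 :]] = True  # top half of the score

    hazard = baseline_hazard * np.exp(planted_log_hr * high)
    t_event = rng.exponential(1.0 / hazard)
    time = np.minimum(t_event, censor_time)
    event = (t_event <= censor_time).astype(int)
    time = np.maximum(time, 1e-3)  # strictly positive follow-up

    age = np.clip(rng.normal(63.3, 11.2, n_cases), 24, 89)
    stage = np.where(rng.uniform(size=n_cases) < 0.746, 3, 4)
    debulking = np.where(rng.uniform(size=n_cases) < 0.759, "optimal", "suboptimal")

    clinical = pd.DataFrame(
        {
            "case_id": case_ids,
            "time": time,
            "event": event,
            "age": age,
            "stage": stage,
            "debulking": debulking,
            "fibrosis_score": score,
            "fibrosis_group": np.where(high, "high", "low"),
        }
    )

    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    n_planted = int(round(planted_gene_frac * n_genes))
    planted = gene_ids[:n_planted]
    z = (score - score.mean()) / max(score.std(), 1e-9)
    expr = rng.standard_normal((n_genes, n_cases))
    if n_planted:
        expr[:n_planted] += gene_slope * z[None, :]
    expression = pd.DataFrame(expr, index=gene_ids, columns=case_ids)

    return SyntheticCohort(
        clinical=clinical,
        expression=expression,
        planted_genes=list(planted),
        planted_log_hr=planted_log_hr,
    )


# ---------------------------------------------------------------------------
# on-disk forms

def write_phantom(slide: PhantomSlide, out_dir: str | os.PathLike) -> None:
    """Write image (PNG), binary masks ({0,255} PNG) and TSR score maps
    ({0,1,2} with 255 = undefined, PNG)."""
    os.makedirs(out_dir, exist_ok=True)
    write_image(os.path.join(out_dir, f"{slide.slide_id}.png"), slide.image)
    write_mask_png(os.path.join(out_dir, f"{slide.slide_id}_tumor.png"), slide.tumor_mask)
    write_mask_png(os.path.join(out_dir, f"{slide.slide_id}_stroma.png"), slide.stroma_mask)
    for crit, m in slide.tsr_maps.items():
        write_image(os.path.join(out_dir, f"{slide.slide_id}_tsr_{crit}.png"), m)


def write_cohort(cohort: SyntheticCohort, out_dir: str | os.PathLike) -> None:
    """Clinical table as CSV; expression as TSV with genes in rows."""
    os.makedirs(out_dir, exist_ok=True)
    cohort.clinical.to_csv(os.path.join(out_dir, "clinical.csv"), index=False)
    cohort.expression.to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t")
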