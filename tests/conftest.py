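import pytest

from stromascope.synthetic_data import (
    CRITERIA,
    SBOT_LIKE,
    PhantomConfig,
    generate_labeled_patches,
    generate_phantom_slide,
)
from stromascope.tiling_io import TilingConfig
from stromascope.patch_models import fit_reference_segmenter, fit_reference_tsr_scorer


@pytest.fixture(scope="session")
def hgsoc_slide():
    return generate_phantom_slide(PhantomConfig(seed=11), slide_id="hg11")


@pytest.fixture(scope="session")
def sbot_slide():
    return generate_phantom_slide(
        PhantomConfig(seed=12, label=SBOT_LIKE), slide_id="sb12"
    )


@pytest.fixture(scope="session")
def training_patches():
    """Labeled patches from three carcinoma-like and two borderline-like
    phantoms (stride 128 to enlarge the set)."""
    tile = TilingConfig(stride=128)
    patches = []
    for seed in range(3):
        s = generate_phantom_slide(PhantomConfig(seed=seed), slide_id=f"tr{seed}")
        patches += generate_labeled_patches(s, tile)
    for seed in (100, 101):
        s = generate_phantom_slide(
            PhantomConfig(seed=seed, label=SBOT_LIKE), slide_id=f"trs{seed}"
        )
        patches += generate_labeled_patches(s, tile)
    return patches


@pytest.fixture(scope="session")
def heldout_patches():
    tile = TilingConfig(stride=128)
    patches = []
    for seed in (50, 51):
        s = generate_phantom_slide(PhantomConfig(seed=seed), slide_id=f"te{seed}")
        patches += generate_labeled_patches(s, tile)
    s = generate_phantom_slide(PhantomConfig(seed=52, label=SBOT_LIKE), slide_id="te52")
    patches += generate_labeled_patches(s, tile)
    return patches


@pytest.fixture(scope="session")
def segmenter(training_patches):
    return fit_reference_segmenter(training_patches, seed=0)


@pytest.fixture(scope="session")
def scorers(training_patches):
    return {c: fit_reference_tsr_scorer(training_patches, c, seed=0) for c in CRITERIA}
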