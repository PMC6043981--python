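import numpy as np
import pytest

from stemct.imaging import CalibratedSlice, SegmentationConfig
from stemct.phantom import PhantomSpec, PhantomStemSpec, generate_stack


@pytest.fixture
def circle_cfg() -> SegmentationConfig:
    """Segmentation config that keeps near-circular regions (the usual
    operating mode for stem cross-sections)."""
    return SegmentationConfig(eccentricity_mode="exclude_above", eccentricity_cutoff=0.9)


@pytest.fixture
def single_stem():
    """One noise-free stem: outer radius 20 px, rind 5 px, 30% pithy."""
    spec = PhantomSpec(
        stems=[
            PhantomStemSpec(
                grid_cell=(2, 2),
                outer_radius_mm=20 * (1 / 1.024),
                rind_thickness_mm=5 * (1 / 1.024),
                pithy_fraction_true=0.3,
            )
        ],
        n_slices=1,
        seed=123,
    )
    slices, truth = generate_stack(spec)
    return spec, slices, truth


def make_slice(pixels: np.ndarray, spacing: float = 1.0, thickness: float = 0.6,
               z: int = 0) -> CalibratedSlice:
    return CalibratedSlice(
        pixels=np.asarray(pixels, dtype=np.uint8),
        pixel_spacing=spacing,
        slice_thickness=thickness,
        z_index=z,
    )
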