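import numpy as np
import pytest

from perfpaint import (
    ImageGrid,
    PhantomSpec,
    StructureMask,
    classify_perfusion,
    derive_targets,
    extract_gtv_h,
    generate_phantom,
)

# Desk-scale grid: same 3 mm slices as the acquisition-scale default, 2 mm
# in-plane, small enough that a full phantom + three plans runs in seconds.
SMALL_GRID = ImageGrid(shape=(96, 96, 40), spacing_mm=(2.0, 2.0, 3.0))


def small_spec(**overrides) -> PhantomSpec:
    defaults = dict(
        seed=7,
        grid=SMALL_GRID,
        brain_semiaxes_mm=(60.0, 70.0, 50.0),
        tumor_semiaxes_mm=(20.0, 15.0, 10.0),
        noise_sd=0.0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def phantom():
    """Noise-free default phantom: (spec, cbf, structures)."""
    spec = small_spec()
    cbf, structures = generate_phantom(spec)
    return spec, cbf, structures


@pytest.fixture(scope="session")
def segmented(phantom):
    """(spec, cbf, structures, labels, gtv_h) for the noise-free phantom."""
    spec, cbf, structures = phantom
    labels = classify_perfusion(cbf, structures["gtv"])
    gtv_h = extract_gtv_h(labels)
    return spec, cbf, structures, labels, gtv_h


@pytest.fixture(scope="session")
def targets(segmented):
    spec, cbf, structures, labels, gtv_h = segmented
    return derive_targets(structures["gtv"], gtv_h, brain=structures["brain"])


def make_mask(grid: ImageGrid, member: np.ndarray, name: str = "mask") -> StructureMask:
    return StructureMask(grid, name, member)


def block_mask(grid: ImageGrid, n_voxels: int, name: str = "block") -> StructureMask:
    """A contiguous raster-order block of exactly n_voxels."""
    flat = np.zeros(int(np.prod(grid.shape)), dtype=bool)
    flat[:n_voxels] = True
    return StructureMask(grid, name, flat.reshape(grid.shape))
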