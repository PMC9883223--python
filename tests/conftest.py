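import numpy as np
import pytest

from terracemark import (
    binarize_soft_tissue,
    extract_isosurface,
    face_phantom_spec,
    generate_phantom,
)

#: cohort seed used by the agreement tests (any seed works; fixed for speed
#: so the session-scoped fixture is computed once)
COHORT_SEED = 11
COHORT_SIZE = 10


@pytest.fixture(scope="session")
def cohort_cc_table():
    """CC1/CC2 digitizations of a randomized phantom cohort."""
    from terracemark.synthetic import cohort_cc_series

    return cohort_cc_series(COHORT_SIZE, seed=COHORT_SEED, shape=160)


@pytest.fixture(scope="session")
def base_phantom():
    """Canonical six-bump face phantom at 160^3: (spec, volume, truth)."""
    spec = face_phantom_spec(160)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def base_mask(base_phantom):
    _, vol, _ = base_phantom
    return binarize_soft_tissue(vol)


@pytest.fixture(scope="session")
def base_mesh(base_mask):
    return extract_isosurface(base_mask)


@pytest.fixture(scope="session")
def ball_mask():
    """Digitized solid ball of radius 20 voxels, fully interior."""
    x, y, z = np.indices((50, 50, 50))
    return (x - 25.0) ** 2 + (y - 25.0) ** 2 + (z - 25.0) ** 2 <= 20.0 ** 2


@pytest.fixture(scope="session")
def step_pyramid_mask():
    """Flat-topped step pyramid: stacked squares shrinking with height.

    Terraces are two voxels tall so the first terrace below the top plateau
    sits exactly 2 px lower along +z.
    """
    mask = np.zeros((40, 40, 12), dtype=bool)
    for level, half in enumerate((18, 14, 11, 8)):
        lo, hi = 20 - half, 20 + half
        mask[lo:hi, lo:hi, 2 * level + 1:2 * level + 3] = True
    return mask
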