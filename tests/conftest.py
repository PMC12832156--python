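import numpy as np
import pytest

from pgcvol.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Small noiseless phantom with one calcified blob fully inside the ROI."""
    spec = PhantomSpec(
        shape=(48, 48, 32),
        spacing_mm=(0.49, 0.49, 1.5),
        ventricle_center_mm=(11.5, 16.0, 23.0),
        ventricle_semiaxes_mm=(3.0, 4.0, 4.0),
        calc_blobs=[((11.5, 3.0, 23.0), 2.0, 150.0)],
        noise_sd_HU=0.0,
        seed=0,
    )
    # ROI center sits 20 mm posterior of the ventricle centroid (y ~ -4),
    # so the blob at y=3 lies well inside the 12 mm sphere.
    return make_phantom(spec)


def brute_force_sphere(shape, affine, center, radius):
    """Triple-loop voxel-center sphere membership, the exhaustive oracle."""
    out = np.zeros(shape, dtype=bool)
    A = np.asarray(affine)
    cx, cy, cz = center
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                w = A[:3, :3] @ (i, j, k) + A[:3, 3]
                if (w[0] - cx) ** 2 + (w[1] - cy) ** 2 + (w[2] - cz) ** 2 <= radius ** 2:
                    out[i, j, k] = True
    return out
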