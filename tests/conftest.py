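import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from contourqa.io import ImageGrid, StructureMask

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def mask_from_indices(indices, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), name="m"):
    """Build a StructureMask with the given voxel index triples set."""
    vox = np.zeros(shape, dtype=bool)
    for idx in indices:
        vox[tuple(idx)] = True
    return StructureMask(ImageGrid(shape, spacing), vox, name)


def random_mask(rng, shape=(8, 8, 8), density=0.3):
    """Non-empty random occupancy on a small grid."""
    while True:
        vox = rng.random(shape) < density
        if vox.any():
            return vox


# ---------------------------------------------------------------------------
# O(n^2) brute-force surface-distance oracle, independent of the EDT path


def brute_surface_indices(vox):
    """Voxels with at least one unset (or out-of-bounds) face neighbour."""
    shape = vox.shape
    out = []
    for i, j, k in np.argwhere(vox):
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            inside = 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]
            if not inside or not vox[ni, nj, nk]:
                out.append((i, j, k))
                break
    return np.asarray(out, dtype=float)


def brute_directed_min_distances(from_idx, to_idx, spacing):
    diffs = (from_idx[:, None, :] - to_idx[None, :, :]) * np.asarray(spacing)
    return np.sqrt((diffs**2).sum(axis=-1)).min(axis=1)


def brute_hd_msd(vox_a, vox_b, spacing):
    sa = brute_surface_indices(vox_a)
    sb = brute_surface_indices(vox_b)
    d_ab = brute_directed_min_distances(sa, sb, spacing)
    d_ba = brute_directed_min_distances(sb, sa, spacing)
    hd = max(d_ab.max(), d_ba.max())
    msd = (d_ab.mean() + d_ba.mean()) / 2.0
    return hd, msd


@pytest.fixture
def small_grid():
    return ImageGrid((8, 8, 8), (1.0, 1.0, 1.0))
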