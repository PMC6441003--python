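import numpy as np
import pytest
from scipy import ndimage

from fibroquant.fish import NucleusRecord


def random_blob_mask(rng: np.random.Generator, size: int = 48, min_area: int = 30) -> np.ndarray:
    """A random 4-connected blob mask that does not touch the array border."""
    while True:
        noise = rng.normal(size=(size, size))
        smooth = ndimage.gaussian_filter(noise, sigma=size / 8)
        mask = smooth > np.quantile(smooth, 0.72)
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
        labels, n = ndimage.label(mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        if n == 0:
            continue
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        mask = labels == largest
        if mask.sum() >= min_area:
            return mask


def record_from_mask(mask: np.ndarray, label: int = 1) -> NucleusRecord:
    rows, cols = np.nonzero(mask)
    r0, c0, r1, c1 = rows.min(), cols.min(), rows.max() + 1, cols.max() + 1
    return NucleusRecord(
        label=label,
        bbox=(int(r0), int(c0), int(r1), int(c1)),
        mask=mask[r0:r1, c0:c1],
        area=int(mask.sum()),
        centroid=(float(rows.mean()), float(cols.mean())),
    )


def boundary_distance(mask: np.ndarray) -> np.ndarray:
    """Distance-to-background used as the shared geometric input of the shell
    oracle tests (the ordering/partition logic under test is independent)."""
    return ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1] * mask


def brute_force_shell_assignment(mask: np.ndarray, n_shells: int) -> np.ndarray:
    """Sort-free shell labels: per-pixel rank by explicit pairwise comparison
    of (distance, row, col), then a cumulative-size quantile lookup."""
    dist = boundary_distance(mask)
    rows, cols = np.nonzero(mask)
    d = dist[rows, cols]
    area = len(rows)
    ranks = np.empty(area, dtype=int)
    for i in range(area):
        less = d < d[i]
        tie = (d == d[i]) & (
            (rows < rows[i]) | ((rows == rows[i]) & (cols < cols[i]))
        )
        ranks[i] = int(less.sum() + tie.sum())
    base, rem = divmod(area, n_shells)
    sizes = np.full(n_shells, base)
    sizes[:rem] += 1
    cum = np.cumsum(sizes)
    out = np.zeros(mask.shape, dtype=int)
    out[rows, cols] = np.searchsorted(cum, ranks, side="right") + 1
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_field():
    from fibroquant.synthetic import FieldSpec, generate_nucleus_field

    return generate_nucleus_field(
        FieldSpec(width=384, height=384, n_nuclei=12, seed=11)
    )
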