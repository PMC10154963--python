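import numpy as np
import pytest

import lungct as lc


@pytest.fixture(scope="session")
def default_phantom():
    """Healthy-mouse phantom at the default 128x128x192 scale."""
    spec = lc.PhantomSpec(seed=0)
    vol, truth, true_volume = lc.generate_phantom(spec)
    return spec, vol, truth, true_volume


@pytest.fixture(scope="session")
def fibrotic_phantom():
    spec = lc.fibrotic_spec(seed=0)
    vol, truth, true_volume = lc.generate_phantom(spec)
    return spec, vol, truth, true_volume


@pytest.fixture(scope="session")
def segmented_default(default_phantom):
    """Automated lung mask of the default phantom (default parameters)."""
    spec, vol, truth, true_volume = default_phantom
    params = lc.SegmentationParams(base_slice=spec.default_base_slice)
    return lc.segment_lung(vol, params)


@pytest.fixture(scope="session")
def small_phantom():
    """A quick 48x48x72 phantom for I/O and CLI round trips."""
    spec = lc.PhantomSpec(dims=(48, 48, 72), seed=3)
    vol, truth, true_volume = lc.generate_phantom(spec)
    return spec, vol, truth, true_volume


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Independent BFS flood-fill oracle: set of components as voxel sets."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                   if (i, j, k) != (0, 0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    nx, ny, nz = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            v = queue.pop()
            comp.append(v)
            for di, dj, dk in offsets:
                w = (v[0] + di, v[1] + dj, v[2] + dk)
                if 0 <= w[0] < nx and 0 <= w[1] < ny and 0 <= w[2] < nz \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(frozenset(comp))
    return comps
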