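import numpy as np
import pytest

from kymodwell import ImagingParams, Kymograph, MicrotubuleExtent


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_imaging():
    """Imaging geometry small enough for fast rendered-image tests."""
    return ImagingParams(n_frames=300, n_pixels=128, seed=5)


def make_gfp_kymograph(
    gfp: np.ndarray, frame_interval: float = 1 / 2.7, pixel_size: float = 160.0
) -> Kymograph:
    """Kymograph with the given GFP channel and a flat rhodamine channel."""
    gfp = np.asarray(gfp, dtype=float)
    return Kymograph(np.zeros_like(gfp), gfp, frame_interval, pixel_size)


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """Brute-force 8-connected components by BFS; oracle for segmentation."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    nrows, ncols = mask.shape
    for r0 in range(nrows):
        for c0 in range(ncols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < nrows
                            and 0 <= cc < ncols
                            and mask[rr, cc]
                            and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(comp)
    return comps


@pytest.fixture
def extent_10_50():
    return MicrotubuleExtent(10, 50, 1.0)
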