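import numpy as np
import pytest

from fazmetrics.shapes import make_circle, make_faz_blob, rasterize


@pytest.fixture(scope="session")
def blob_contours():
    """Ten seeded FAZ-like blobs of varying size and irregularity."""
    out = []
    for i in range(10):
        out.append(
            make_faz_blob(
                seed=100 + i,
                mean_radius=20.0 + 6.0 * i,
                irregularity=0.05 + 0.03 * (i % 5),
            )
        )
    return out


@pytest.fixture(scope="session")
def blob_masks(blob_contours):
    return [rasterize(c) for c in blob_contours]


@pytest.fixture(scope="session")
def circle_mask_r50():
    return rasterize(make_circle(50.0))
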