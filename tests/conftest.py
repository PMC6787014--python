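import numpy as np
import pandas as pd
import pytest


def disk_mask(shape, center, radius_px):
    """Rasterized disk: pixel centers within radius of the given center."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


@pytest.fixture
def single_disk_mask():
    # r = 20 um at 0.5 um/px in an image wide enough for 180-um annuli
    return disk_mask((1000, 1000), (500, 500), 40)


@pytest.fixture
def cells_frame():
    def make(coords, marker="CD3"):
        return pd.DataFrame(
            {
                "x_px": [c[0] for c in coords],
                "y_px": [c[1] for c in coords],
                "marker": marker,
            }
        )

    return make
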