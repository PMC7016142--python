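import numpy as np
import pytest


@pytest.fixture
def disk_mask():
    """Rasterized disk mask factory: disk_mask(radius, size) -> bool array."""

    def _make(radius: float, size: int | None = None) -> np.ndarray:
        size = size or int(2 * radius + 7)
        c = size / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2

    return _make
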