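import numpy as np
import pytest

# RGB triples with their exact hue degree and saturation on the 0-255 scale
COMMON_COLORS = {
    "black": ((0, 0, 0), 0, 0),
    "gray50": ((127, 127, 127), 0, 0),
    "white": ((255, 255, 255), 0, 0),
    "red": ((255, 0, 0), 0, 255),
    "green": ((0, 255, 0), 120, 255),
    "blue": ((0, 0, 255), 240, 255),
    "yellow": ((255, 255, 0), 60, 255),
    "magenta": ((255, 0, 255), 300, 255),
    "cyan": ((0, 255, 255), 180, 255),
}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def uniform_image(color, shape=(10, 10)):
    img = np.empty(shape + (3,), dtype=np.uint8)
    img[:] = color
    return img


def naive_hue_spectrum(image, tv=0.05):
    """Per-pixel double-loop transliteration of the published histogram
    algorithm; the independent oracle for the vectorized implementation."""
    import math

    height, width, layers = image.shape
    assert layers == 3
    fc, fs = [], []
    for i in range(height):
        for j in range(width):
            pr, pg, pb = (float(v) for v in image[i, j])
            dx = pr - pg / 2.0 - pb / 2.0
            dy = (pg - pb) * math.sqrt(3.0) / 2.0
            s = math.sqrt(dx * dx + dy * dy) / 255.0
            h = math.atan2(dy, dx) * 180.0 / math.pi
            if h < 0:
                h += 360.0
            if s > tv:
                d = int(math.floor(h + 0.5))  # round half away from zero, h >= 0
                if d == 0:
                    d = 360
                fc.append(d)
                fs.append(s)
    rv = np.zeros(360)
    n = len(fc)
    if n > 1:
        for d, s in zip(fc, fs):
            rv[d - 1] += s
        rv /= n
    return rv, n
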