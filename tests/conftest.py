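import numpy as np
import pytest

from pseudodect.containers import CTImage
from pseudodect.physics import attenuation_coefficient
from pseudodect.tomography import forward_project, make_geometry


@pytest.fixture(scope="session")
def water_disk():
    """Uniform water disk (mu at 60 keV) on a 128-px, 2-mm grid."""
    n, sp, r, ss = 128, 2.0, 60.0, 8
    x = (np.arange(n * ss) + 0.5) * (sp / ss) - n * sp / 2
    xx, yy = np.meshgrid(x, x)
    frac = (xx ** 2 + yy ** 2 <= r ** 2).reshape(n, ss, n, ss).mean(axis=(1, 3))
    mu = attenuation_coefficient("water", 60.0)
    img = CTImage(mu * frac, sp, "mm^-1", 60.0)
    return img, r, mu


@pytest.fixture(scope="session")
def water_disk_sinogram(water_disk):
    img, r, mu = water_disk
    geom = make_geometry(img.shape[0], img.spacing, 360)
    return forward_project(img, geom), img, r, mu
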