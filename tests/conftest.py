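import numpy as np
import pytest

from fwpenumbra.synthcohort import (
    Ellipsoid,
    make_gradient_scheme,
    make_phantom,
)


@pytest.fixture(scope="session")
def scheme64():
    """The acquisition used throughout: 64 directions at b=1000 plus one b0."""
    return make_gradient_scheme(64, 1000.0, 1, seed=7)


@pytest.fixture(scope="session")
def small_phantom():
    """A 20-cube phantom with one central lesion, FW decaying outward and
    FA peaking in the second rim."""
    fw_profile = lambda d: 0.15 + 0.25 * np.exp(-np.asarray(d) / 4.0)
    fa_profile = lambda d: 0.30 + 0.25 * np.exp(-(((np.asarray(d) - 3.2) / 1.2) ** 2))
    return make_phantom(
        (20, 20, 20),
        [Ellipsoid((10, 10, 10), (2.5, 2.0, 2.0))],
        fw_profile,
        fa_profile,
        seed=11,
    )
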