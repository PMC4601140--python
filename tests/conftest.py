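import numpy as np
import pytest

from acer import (
    CoilModel,
    PhantomSpec,
    apply_precalibration_correction,
    make_phantom,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def phantom_bundle():
    """Canonical small phantom: ground truth, uncorrected and corrected images."""
    spec = PhantomSpec.small(seed=1)
    coil = CoilModel()
    g = make_phantom(spec)
    unc = simulate_acquisition(g, coil, spec.sigma0, 1)
    cor = apply_precalibration_correction(unc, coil)
    return {"spec": spec, "coil": coil, "g": g, "unc": unc, "cor": cor}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
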