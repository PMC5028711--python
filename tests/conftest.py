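import numpy as np
import pytest

from asoct.core import DeviceModel
from asoct.phantom import PhantomSpec, make_phantom_spec, render_bscan


@pytest.fixture(scope="session")
def device():
    return DeviceModel()


@pytest.fixture(scope="session")
def flat_spec_factory():
    """Phantoms with horizontal (or uniformly tilted) plane boundaries:
    the closed-form reference geometry for the optics tests."""

    def make(acb=300.0, asb=438.0, psb=1143.0, tilt=0.0, **overrides):
        knots = np.linspace(0.0, 16000.0, 17)
        ramp = np.tan(np.radians(tilt)) * knots
        return PhantomSpec(
            seed=0,
            meridian="nasal",
            knots_x=knots,
            acb_knots=np.full_like(knots, acb) + ramp,
            asb_knots=np.full_like(knots, asb) + ramp,
            psb_knots=np.full_like(knots, psb) + ramp,
            spur_x=2500.0,
            **overrides,
        )

    return make


@pytest.fixture(scope="session")
def nasal_spec():
    return make_phantom_spec(1, "nasal")


@pytest.fixture(scope="session")
def rendered_scan(device):
    """One rendered noisy phantom with its image-space ground truth."""
    spec = make_phantom_spec(7, "nasal")
    image, truth = render_bscan(spec, device)
    return spec, image, truth
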