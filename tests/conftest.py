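import numpy as np
import pytest

from csxrf import (
    DetectorModel,
    ElementSpec,
    Phantom,
    PhantomConfig,
    RegionSpec,
    generate_phantom,
    roi_for_element,
    three_element_demo,
)


@pytest.fixture
def demo():
    """Built-in 5x5 three-element specimen (grey substrate, blue disk, red rectangle)."""
    return three_element_demo()


@pytest.fixture
def demo_rois(demo):
    return {e.name: roi_for_element(demo.detector, e) for e in demo.elements}


@pytest.fixture
def small_detector():
    return DetectorModel(n_channels=8, gain=0.5, offset=0.0, background_rate=0.0)


def make_two_phase_phantom(shape, n_element_pixels, *, conc=20.0, dwell_detector=None,
                           transmission_inside=0.3, yield_scale=10.0):
    """Substrate-only grid with the first ``n_element_pixels`` (row-major)
    carrying the element "Na" and a reduced transmission.

    Used for conditional/dynamic fixtures where an exact pixel fraction of
    the grid must carry the signal.
    """
    rows, cols = shape
    det = dwell_detector or DetectorModel(n_channels=16, gain=0.2, offset=0.0)
    elements = [
        ElementSpec("sub", line_energy=0.5, peak_sigma=0.1, yield_scale=yield_scale),
        ElementSpec("Na", line_energy=2.2, peak_sigma=0.1, yield_scale=yield_scale),
    ]
    conc_sub = np.full(shape, 1.0)
    conc_na = np.zeros(shape)
    transmission = np.ones(shape)
    flat = np.arange(rows * cols).reshape(shape)
    inside = flat < n_element_pixels
    conc_na[inside] = conc
    transmission[inside] = transmission_inside
    return Phantom(elements=elements, detector=det,
                   concentration={"sub": conc_sub, "Na": conc_na},
                   transmission=transmission)


@pytest.fixture
def disk_config():
    """20x20 single Si disk on a faint substrate, for generation tests."""
    det = DetectorModel(n_channels=32, gain=0.1, offset=0.0, background_rate=0.0)
    elements = (
        ElementSpec("C", line_energy=0.28, peak_sigma=0.05, yield_scale=5.0),
        ElementSpec("Si", line_energy=1.74, peak_sigma=0.05, yield_scale=20.0),
    )
    return PhantomConfig(
        shape=(20, 20),
        detector=det,
        elements=elements,
        substrate_element="C",
        substrate_concentration=0.5,
        substrate_transmission=0.95,
        regions=(
            RegionSpec("disk", "Si", concentration=4.0, transmission=0.4,
                       center=(10.0, 10.0), radius=5.0),
        ),
    )
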