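"""Shared fixtures: small phantoms reused across test modules.

Phantom image sizes are scaled down (128-256 px, a handful of frames)
so the whole suite runs in minutes on one CPU; the physics parameters
(protocol timing, pixel size, displacement amplitudes) keep their
defaults.
"""

import warnings

import numpy as np
import pytest

from nucleostrain import (NucleolusSpec, PhantomSpec, make_texture,
                          multipass_piv, nucleus_mask, render_sequence)

PEAK_INDEX = 119  # last stimulation frame, t = 29.75 s at 4 fps


@pytest.fixture(scope="session")
def small_spec():
    """128 px phantom nucleus, default protocol, no substructures."""
    return PhantomSpec(image_shape=(128, 128), nucleus_radius_um=6.5)


@pytest.fixture(scope="session")
def texture(small_spec):
    return make_texture(small_spec).frames[0]


@pytest.fixture(scope="session")
def rendered_pair():
    """256 px phantom rendered at t=0 and peak deformation, with truth."""
    spec = PhantomSpec(image_shape=(256, 256), nucleus_radius_um=12.0,
                       amplitude_um=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack, truth = render_sequence(spec, frame_indices=[0, PEAK_INDEX])
    return spec, stack, truth


@pytest.fixture(scope="session")
def peak_field(rendered_pair):
    """Default-config PIV field of the rendered pair at peak deformation."""
    spec, stack, _ = rendered_pair
    return multipass_piv(stack.frames[0], stack.frames[1],
                         mask=nucleus_mask(spec),
                         pixel_size=spec.pixel_size)


@pytest.fixture(scope="session")
def nucleolus_spec():
    return PhantomSpec(
        image_shape=(256, 256), nucleus_radius_um=12.0, amplitude_um=1.0,
        nucleolus=NucleolusSpec(center_px=(128.0, 128.0), radius_um=2.0,
                                mobile=False, ramp_um=1.5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
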