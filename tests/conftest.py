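import numpy as np
import pytest

from staphycurve import Orientation, RpeProfile


def make_profile(
    a=0.0,
    tilt=0.0,
    bump=0.0,
    bump_sigma=150.0,
    orientation=Orientation.HORIZONTAL,
    spacing=50.0,
    half_span=3300.0,
    axial_length=29.5,
    scaled=True,
    noise_sd=0.0,
    rng=None,
):
    """Hand-built quadratic-plus-perturbation profile (independent of the
    package's own geometry generator)."""
    x = np.arange(-half_span, half_span + spacing / 2, spacing)
    z = a * x**2 + tilt * x
    if bump:
        z = z + bump * np.exp(-(x**2) / (2 * bump_sigma**2)) - bump
    if noise_sd:
        rng = rng or np.random.default_rng(0)
        z = z + rng.normal(0, noise_sd, len(x))
    return RpeProfile(
        orientation=orientation,
        x=x,
        z=z,
        axial_length_mm=axial_length,
        scaled=scaled,
    )


@pytest.fixture
def parabola_pair():
    """Identical horizontal/vertical parabolas with a = 7e-5 µm⁻¹."""
    return (
        make_profile(a=7e-5, orientation=Orientation.HORIZONTAL),
        make_profile(a=7e-5, orientation=Orientation.VERTICAL),
    )


def parabola_index_closed_form(a: float, half_span: float = 3000.0) -> float:
    """Closed-form arc/chord index of z = a x^2 over ±half_span.

    arc = (1/2a)[u sqrt(1+u^2) + asinh(u)] with u = 2 a X; chord = 2X
    (the endpoints share the same elevation).
    """
    u = 2.0 * a * half_span
    if u == 0:
        return 1.0
    arc = (u * np.sqrt(1 + u * u) + np.arcsinh(u)) / (2 * a)
    return arc / (2 * half_span)
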