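"""Axial-length magnification correction for OCT lateral measurements.

Lateral distances on an OCT B-scan are magnified in long eyes.  The
correction used here converts an on-image measurement ``s`` to the actual
dimension ``t`` with

    t = 3.382 x 0.01306 x (axial_length_mm - 1.82) x s

which is the Bennett-type single-variable formula widely used for Cirrus
HD-OCT images.  The factor is exactly 1 at an axial length of about
24.46 mm and grows linearly (slope 3.382 x 0.01306 per mm).

Only the lateral (x) coordinate is corrected: OCT axial sampling is set by
the interferometer, not by ocular optics, so elevations are taken as true
after 1:1 µm conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .core import RpeProfile
from .errors import DomainError, StateError

SCALE_SLOPE_PER_MM = 3.382 * 0.01306
SCALE_OFFSET_MM = 1.82


@dataclass(frozen=True)
class ScaleResult:
    """Magnification-correction factor for one eye."""

    factor: float
    axial_length_mm: float


def scale_factor(axial_length_mm: float) -> ScaleResult:
    """Return the lateral magnification-correction factor for an eye.

    Raises
    ------
    DomainError
        If ``axial_length_mm <= 1.82`` mm, where the formula degenerates.
    """
    if not axial_length_mm > SCALE_OFFSET_MM:
        raise DomainError(
            f"axial length must exceed {SCALE_OFFSET_MM} mm, got {axial_length_mm}"
        )
    return ScaleResult(
        factor=SCALE_SLOPE_PER_MM * (axial_length_mm - SCALE_OFFSET_MM),
        axial_length_mm=axial_length_mm,
    )


def rescale_profile(profile: RpeProfile) -> RpeProfile:
    """Apply magnification correction to the lateral coordinate of a profile.

    Multiplies ``x`` by the eye's scale factor, leaves ``z`` untouched, and
    marks the profile as scaled.  Calling it on an already-scaled profile is
    an error so the correction can never be applied twice.
    """
    if profile.scaled:
        raise StateError("profile is already magnification-corrected")
    factor = scale_factor(profile.axial_length_mm).factor
    return replace(profile, x=profile.x * factor, scaled=True)
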