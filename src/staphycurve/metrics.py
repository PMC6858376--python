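"""Per-eye curvature and severity measures computed from scaled RPE profiles.

Three curvature parameters are computed from each pair of fovea-centered
horizontal/vertical profiles:

* **Staphyloma heights** — signed elevation of the RPE at ±3 mm from the
  fovea relative to the subfoveal RPE, one per side (nasal, temporal,
  superior, inferior), plus their horizontal/vertical sums and total.
  A height is negative when the peripheral RPE lies posterior to the
  subfoveal RPE.
* **Coefficient a** — leading coefficient of the ordinary least-squares
  quadratic ``a x^2 + b x + c`` fitted to the profile resampled on the
  fixed 21-point grid −3000, −2700, …, +3000 µm (300 µm intervals).
  Larger a means a steeper staphyloma.
* **Curvature index** — length of the RPE polyline between the two points
  ±3 mm from the fovea divided by the straight (chord) distance between
  those points.  The chord is the full Euclidean distance (lateral and
  elevation components), so the index is ≥ 1 with equality only for a
  straight segment.

The arc length is measured on the full-resolution polyline; the 300 µm
grid is used only for the polynomial fit — the two procedures are distinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import MIN_HALF_SPAN_UM, CurvatureMetrics, Orientation, RpeProfile
from .errors import SpanError, StateError, ValidationError

#: Landmark distance from the fovea (µm) for heights and the index.
LANDMARK_UM = 3000.0
#: Resampling interval (µm) for the quadratic fit.
FIT_INTERVAL_UM = 300.0


@dataclass(frozen=True)
class QuadFit:
    """Ordinary least-squares quadratic fit ``a x^2 + b x + c``."""

    a: float
    b: float
    c: float
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValidationError("a quadratic fit needs at least 3 points")
        if self.rss < 0:
            raise ValidationError("rss must be >= 0")


@dataclass(frozen=True)
class StaphylomaHeights:
    """Signed staphyloma heights (µm) and their sums."""

    h_nasal: float
    h_temporal: float
    h_superior: float
    h_inferior: float

    @property
    def h_horizontal(self) -> float:
        return self.h_nasal + self.h_temporal

    @property
    def h_vertical(self) -> float:
        return self.h_superior + self.h_inferior

    @property
    def h_total(self) -> float:
        return self.h_horizontal + self.h_vertical


def _require_scaled_span(profile: RpeProfile, half_span: float = LANDMARK_UM) -> None:
    if not profile.scaled:
        raise StateError("profile must be magnification-corrected first")
    lo, hi = profile.span
    if lo > -half_span or hi < half_span:
        raise SpanError(
            f"{profile.orientation.value} profile spans [{lo:.0f}, {hi:.0f}] µm; "
            f"metrics need at least ±{half_span:.0f} µm"
        )


def elevation_at(profile: RpeProfile, x: float) -> float:
    """Linearly interpolated RPE elevation (µm) at lateral position ``x``.

    Exact at sample points; never extrapolates.
    """
    if not profile.scaled:
        raise StateError("profile must be magnification-corrected first")
    lo, hi = profile.span
    if x < lo or x > hi:
        raise SpanError(f"x={x} µm outside profile span [{lo:.0f}, {hi:.0f}]")
    return float(np.interp(x, profile.x, profile.z))


def staphyloma_heights(
    horizontal: RpeProfile, vertical: RpeProfile
) -> StaphylomaHeights:
    """Signed heights of the RPE at ±3 mm relative to the subfoveal RPE.

    On horizontal scans negative x is nasal; on vertical scans negative x
    is inferior.
    """
    if horizontal.orientation is not Orientation.HORIZONTAL:
        raise ValidationError("first profile must be horizontal")
    if vertical.orientation is not Orientation.VERTICAL:
        raise ValidationError("second profile must be vertical")
    _require_scaled_span(horizontal)
    _require_scaled_span(vertical)
    z0_h = elevation_at(horizontal, 0.0)
    z0_v = elevation_at(vertical, 0.0)
    return StaphylomaHeights(
        h_nasal=elevation_at(horizontal, -LANDMARK_UM) - z0_h,
        h_temporal=elevation_at(horizontal, LANDMARK_UM) - z0_h,
        h_superior=elevation_at(vertical, LANDMARK_UM) - z0_v,
        h_inferior=elevation_at(vertical, -LANDMARK_UM) - z0_v,
    )


def fit_coefficient_a(profile: RpeProfile, x_unit_scale: float = 1.0) -> QuadFit:
    """Least-squares quadratic fit on the fixed 300 µm resampling grid.

    The profile is resampled by linear interpolation at the 21 grid points
    −3000, −2700, …, +3000 µm and ``a x^2 + b x + c`` is fitted by ordinary
    least squares.  ``x_unit_scale`` rescales the abscissa before fitting
    (a is in (µm · x_unit_scale)⁻¹); the default 1.0 keeps x in µm so a is
    in µm⁻¹.  Deterministic.
    """
    _require_scaled_span(profile)
    grid = np.arange(-LANDMARK_UM, LANDMARK_UM + FIT_INTERVAL_UM / 2, FIT_INTERVAL_UM)
    z = np.interp(grid, profile.x, profile.z)
    xs = grid * x_unit_scale
    design = np.column_stack([xs**2, xs, np.ones_like(xs)])
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    resid = z - design @ coef
    return QuadFit(
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        rss=float(resid @ resid),
        n_points=len(grid),
    )


def curvature_index(profile: RpeProfile) -> float:
    """Arc length of the RPE polyline over ±3 mm divided by its chord.

    The polyline is clipped to [−3000, +3000] µm with linearly interpolated
    endpoints; the arc is the summed segment length and the chord the
    Euclidean distance between the two endpoints (lateral and elevation
    components).  Always ≥ 1.
    """
    _require_scaled_span(profile)
    x0, x1 = -LANDMARK_UM, LANDMARK_UM
    inside = (profile.x > x0) & (profile.x < x1)
    xs = np.concatenate(([x0], profile.x[inside], [x1]))
    zs = np.concatenate(
        ([elevation_at(profile, x0)], profile.z[inside], [elevation_at(profile, x1)])
    )
    arc = float(np.sum(np.hypot(np.diff(xs), np.diff(zs))))
    chord = math.hypot(x1 - x0, float(zs[-1] - zs[0]))
    return arc / chord


def compute_metrics(
    horizontal: RpeProfile, vertical: RpeProfile, x_unit_scale: float = 1.0
) -> CurvatureMetrics:
    """All curvature parameters for one eye from its two scaled profiles."""
    heights = staphyloma_heights(horizontal, vertical)
    a_h = fit_coefficient_a(horizontal, x_unit_scale).a
    a_v = fit_coefficient_a(vertical, x_unit_scale).a
    ci_h = curvature_index(horizontal)
    ci_v = curvature_index(vertical)
    return CurvatureMetrics(
        h_nasal=heights.h_nasal,
        h_temporal=heights.h_temporal,
        h_superior=heights.h_superior,
        h_inferior=heights.h_inferior,
        h_horizontal=heights.h_horizontal,
        h_vertical=heights.h_vertical,
        h_total=heights.h_total,
        coef_a_horizontal=a_h,
        coef_a_vertical=a_v,
        coef_a_average=0.5 * (a_h + a_v),
        ci_horizontal=ci_h,
        ci_vertical=ci_v,
        ci_average=0.5 * (ci_h + ci_v),
    )


def foveoschisis_height(
    ilm: RpeProfile,
    rpe: RpeProfile,
    hole: Optional[tuple[float, float]] = None,
) -> float:
    """Foveoschisis height: ILM-to-RPE distance at the foveal center (µm).

    With a full-thickness macular hole, ``hole=(x_lo, x_hi)`` gives the
    lateral extent of the hole; the ILM elevation at the fovea is then the
    straight-line bridge between the ILM at the two hole edges.

    Raises
    ------
    ValidationError
        If the resulting height is negative (layers crossed) or the hole
        interval does not straddle the fovea.
    """
    rpe0 = elevation_at(rpe, 0.0)
    if hole is None:
        ilm0 = elevation_at(ilm, 0.0)
    else:
        lo, hi = hole
        if not (lo < 0.0 < hi):
            raise ValidationError("macular-hole interval must straddle x=0")
        z_lo = elevation_at(ilm, lo)
        z_hi = elevation_at(ilm, hi)
        ilm0 = z_lo + (z_hi - z_lo) * (0.0 - lo) / (hi - lo)
    fsh = ilm0 - rpe0
    if fsh < 0:
        raise ValidationError(
            f"negative foveoschisis height ({fsh:.1f} µm): ILM posterior to RPE"
        )
    return float(fsh)


def average_sct(sct_horizontal_um: float, sct_vertical_um: float) -> float:
    """Subfoveal choroidal thickness averaged over the two scan orientations."""
    if sct_horizontal_um < 0 or sct_vertical_um < 0:
        raise ValidationError("choroidal thickness must be >= 0")
    return 0.5 * (sct_horizontal_um + sct_vertical_um)
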