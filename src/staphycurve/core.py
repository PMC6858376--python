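"""Core domain types: RPE profiles, per-eye curvature metrics, eye records, cohorts.

Conventions
-----------
Elevation ``z`` increases *anteriorly* (toward the vitreous) and is centered
so that the subfoveal RPE sits at ``z = 0``.  A posterior staphyloma is
therefore an upward-opening curve: peripheral elevations are positive when
the peripheral RPE lies anterior to the subfoveal RPE, and a staphyloma
height is negative exactly when the peripheral RPE lies posterior to the
subfoveal RPE.

Lateral position ``x`` is in micrometres with the fovea at 0.  Negative x is
nasal on horizontal scans and inferior on vertical scans; right and left
eyes are normalized to this convention at read time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

#: Minimum half-span (µm) a scaled profile must cover for curvature metrics.
MIN_HALF_SPAN_UM = 3000.0


class Orientation(str, enum.Enum):
    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"


class Eye(str, enum.Enum):
    OD = "OD"
    OS = "OS"


class Group(str, enum.Enum):
    MTM = "MTM"
    MCNV = "mCNV"
    CONTROL = "control"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class StaphylomaType(str, enum.Enum):
    WIDE_MACULAR = "wide_macular"
    NARROW_MACULAR = "narrow_macular"
    OTHER = "other"


class Provenance(str, enum.Enum):
    MEASURED = "measured"
    SYNTHETIC_METRICS = "synthetic_metrics"
    SYNTHETIC_GEOMETRY = "synthetic_geometry"


@dataclass(frozen=True)
class RpeProfile:
    """One oriented RPE polyline extracted from a fovea-centered B-scan.

    Parameters
    ----------
    orientation
        Scan orientation (horizontal or vertical).
    x
        Lateral positions in µm, strictly increasing, fovea at 0.
    z
        RPE elevations in µm, same length as ``x``, increasing anteriorly.
    axial_length_mm
        Axial length of the eye, used for magnification correction.
    scaled
        True once lateral magnification correction has been applied.
    """

    orientation: Orientation
    x: np.ndarray
    z: np.ndarray
    axial_length_mm: float
    scaled: bool = False

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        if x.ndim != 1 or z.ndim != 1:
            raise ValidationError("x and z must be one-dimensional")
        if len(x) != len(z):
            raise ValidationError(
                f"x and z lengths differ: {len(x)} vs {len(z)}"
            )
        if len(x) < 2:
            raise ValidationError("a profile needs at least two samples")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z))):
            raise ValidationError("profile contains non-finite values")
        if np.any(np.diff(x) <= 0):
            bad = int(np.argmax(np.diff(x) <= 0))
            raise ValidationError(
                f"x must be strictly increasing (violated at index {bad + 1},"
                f" x={x[bad]!r} followed by x={x[bad + 1]!r})"
            )
        if not (math.isfinite(self.axial_length_mm) and self.axial_length_mm > 0):
            raise ValidationError("axial_length_mm must be a positive real")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    def covers(self, half_span_um: float = MIN_HALF_SPAN_UM) -> bool:
        return self.x[0] <= -half_span_um and self.x[-1] >= half_span_um

    def centered(self) -> "RpeProfile":
        """Return a copy with z shifted so the sample nearest x=0 is 0."""
        i = int(np.argmin(np.abs(self.x)))
        return replace(self, z=self.z - self.z[i])

    def allclose(self, other: "RpeProfile", tol: float = 1e-9) -> bool:
        return (
            self.orientation == other.orientation
            and self.scaled == other.scaled
            and abs(self.axial_length_mm - other.axial_length_mm) <= tol
            and len(self.x) == len(other.x)
            and np.allclose(self.x, other.x, rtol=0, atol=tol)
            and np.allclose(self.z, other.z, rtol=0, atol=tol)
        )


_IDENT_TOL = 1e-6


@dataclass(frozen=True)
class CurvatureMetrics:
    """Per-eye staphyloma curvature parameter set.

    Heights are signed µm.  ``coef_a_*`` is the leading coefficient of the
    least-squares quadratic fit (inverse length, internal units: µm⁻¹ when x
    is in µm).  ``ci_*`` is the dimensionless arc/chord curvature index
    (always ≥ 1).  Averages are arithmetic means of the horizontal and
    vertical values; sums satisfy the height identities exactly.
    """

    h_nasal: float
    h_temporal: float
    h_superior: float
    h_inferior: float
    h_horizontal: float
    h_vertical: float
    h_total: float
    coef_a_horizontal: float
    coef_a_vertical: float
    coef_a_average: float
    ci_horizontal: float
    ci_vertical: float
    ci_average: float

    def __post_init__(self) -> None:
        for name in self.field_names():
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} is not finite")
        if abs(self.h_horizontal - (self.h_nasal + self.h_temporal)) > _IDENT_TOL:
            raise ValidationError("h_horizontal != h_nasal + h_temporal")
        if abs(self.h_vertical - (self.h_superior + self.h_inferior)) > _IDENT_TOL:
            raise ValidationError("h_vertical != h_superior + h_inferior")
        if abs(self.h_total - (self.h_horizontal + self.h_vertical)) > _IDENT_TOL:
            raise ValidationError("h_total != sum of the four heights")
        for name in ("ci_horizontal", "ci_vertical", "ci_average"):
            if getattr(self, name) < 1.0 - 1e-12:
                raise ValidationError(f"{name} < 1")
        if abs(self.ci_average - 0.5 * (self.ci_horizontal + self.ci_vertical)) > _IDENT_TOL:
            raise ValidationError("ci_average is not the H/V mean")
        if abs(
            self.coef_a_average - 0.5 * (self.coef_a_horizontal + self.coef_a_vertical)
        ) > _IDENT_TOL * max(1.0, abs(self.coef_a_average)):
            raise ValidationError("coef_a_average is not the H/V mean")

    @staticmethod
    def field_names() -> tuple[str, ...]:
        return (
            "h_nasal", "h_temporal", "h_superior", "h_inferior",
            "h_horizontal", "h_vertical", "h_total",
            "coef_a_horizontal", "coef_a_vertical", "coef_a_average",
            "ci_horizontal", "ci_vertical", "ci_average",
        )

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self.field_names()}


@dataclass
class EyeRecord:
    """Clinical metadata, optional profiles, and optional metrics for one eye."""

    patient_id: str
    eye: Eye
    group: Group
    age_years: float
    sex: Sex
    bcva_logmar: float
    axial_length_mm: float
    refractive_error_d: float
    pseudophakic: bool
    staphyloma_type: StaphylomaType
    metapm_category: int
    sct_um: float
    fsh_um: Optional[float] = None
    cnv_size_da: Optional[float] = None
    profile_h: Optional[RpeProfile] = None
    profile_v: Optional[RpeProfile] = None
    metrics: Optional[CurvatureMetrics] = None

    def __post_init__(self) -> None:
        self.eye = Eye(self.eye)
        self.group = Group(self.group)
        self.sex = Sex(self.sex)
        self.staphyloma_type = StaphylomaType(self.staphyloma_type)
        if int(self.metapm_category) not in (1, 2, 3, 4):
            raise ValidationError(
                f"metapm_category must be 1-4, got {self.metapm_category!r}"
            )
        self.metapm_category = int(self.metapm_category)
        if self.fsh_um is not None and self.group is not Group.MTM:
            raise ValidationError(
                f"fsh_um is an MTM-only field (eye {self.patient_id})"
            )
        if self.cnv_size_da is not None and self.group is not Group.MCNV:
            raise ValidationError(
                f"cnv_size_da is an mCNV-only field (eye {self.patient_id})"
            )
        if self.fsh_um is not None and self.fsh_um < 0:
            raise ValidationError("fsh_um must be >= 0")
        if self.cnv_size_da is not None and self.cnv_size_da < 0:
            raise ValidationError("cnv_size_da must be >= 0")
        if self.sct_um < 0:
            raise ValidationError("sct_um must be >= 0")

    @property
    def key(self) -> tuple[str, str]:
        return (self.patient_id, self.eye.value)


@dataclass
class Cohort:
    """A sequence of eye records with a provenance tag and optional seed."""

    records: list[EyeRecord] = field(default_factory=list)
    provenance: Provenance = Provenance.MEASURED
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.provenance = Provenance(self.provenance)
        self.validate()

    def validate(self, one_eye_per_patient: bool = False) -> None:
        seen: set[tuple[str, str]] = set()
        patients: set[str] = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValidationError(
                    f"duplicate record for patient {rec.patient_id} eye {rec.eye.value}"
                )
            seen.add(rec.key)
            if one_eye_per_patient and rec.patient_id in patients:
                raise ValidationError(
                    f"patient {rec.patient_id} contributes more than one eye"
                )
            patients.add(rec.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def by_group(self) -> dict[Group, list[EyeRecord]]:
        out: dict[Group, list[EyeRecord]] = {g: [] for g in Group}
        for rec in self.records:
            out[rec.group].append(rec)
        return out
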