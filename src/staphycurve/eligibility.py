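"""Study inclusion/exclusion rules as testable filters.

Inclusion requires high myopia — axial length ≥ 26.5 mm or a spherical
equivalent of −6.0 D or more myopic (pseudophakic eyes never qualify via
refraction, since their refraction no longer reflects the native eye).

A dome-shaped macula — an inward (anterior) bulge of the macular RPE of
more than 50 µm above a line tangent to the RPE at the bottom of the
staphyloma — is an exclusion.  The tangent is operationalized as the lower
convex hull of the RPE polyline: for a purely staphylomatous (convex)
profile every sample lies on the hull and the bulge is zero; a central
dome lifts samples above the hull segment bridging it, and the bulge is
the maximum elevation of the profile above that hull.

Remaining exclusions (prior treatment, scleral buckle, coexisting
exudative disease, poor image quality, both MTM and mCNV, staphyloma not
involving the fovea) are clinical judgements carried as input flags.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields

import numpy as np

from .core import Cohort, Eye, EyeRecord, RpeProfile
from .metrics import _require_scaled_span

#: Dome-shaped-macula bulge threshold (µm); the rule is a strict ">".
DOME_THRESHOLD_UM = 50.0
HIGH_MYOPIA_AXIAL_LENGTH_MM = 26.5
HIGH_MYOPIA_REFRACTION_D = -6.0


class ExclusionReason(str, enum.Enum):
    NOT_HIGH_MYOPIA = "not_high_myopia"
    DOME_SHAPED_MACULA = "dome_shaped_macula"
    STAPHYLOMA_NOT_FOVEAL = "staphyloma_not_foveal"
    BOTH_MTM_AND_MCNV = "both_mtm_and_mcnv"
    PRIOR_TREATMENT = "prior_treatment"
    PRIOR_BUCKLE = "prior_buckle"
    OTHER_EXUDATIVE_DISEASE = "other_exudative_disease"
    POOR_IMAGE_QUALITY = "poor_image_quality"
    DUPLICATE_EYE = "duplicate_eye"


@dataclass(frozen=True)
class ScreeningOutcome:
    reasons: tuple[ExclusionReason, ...] = ()

    @property
    def eligible(self) -> bool:
        return not self.reasons


@dataclass(frozen=True)
class ExclusionFlags:
    """Chart-review exclusion flags that cannot be computed from profiles."""

    staphyloma_not_foveal: bool = False
    both_mtm_and_mcnv: bool = False
    prior_treatment: bool = False
    prior_buckle: bool = False
    other_exudative_disease: bool = False
    poor_image_quality: bool = False

    def reasons(self) -> list[ExclusionReason]:
        return [
            ExclusionReason(f.name) for f in fields(self) if getattr(self, f.name)
        ]


def is_high_myopia(
    axial_length_mm: float, refractive_error_d: float, pseudophakic: bool
) -> bool:
    """High-myopia inclusion rule (boundary values inclusive)."""
    if axial_length_mm >= HIGH_MYOPIA_AXIAL_LENGTH_MM:
        return True
    return (not pseudophakic) and refractive_error_d <= HIGH_MYOPIA_REFRACTION_D


def _lower_hull(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull of a function graph (monotone chain)."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # drop k if it lies on or above segment j->i
            cross = (x[k] - x[j]) * (z[i] - z[j]) - (z[k] - z[j]) * (x[i] - x[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def _bulge(profile: RpeProfile) -> float:
    """Maximum elevation of the profile above its lower convex hull (µm)."""
    x, z = profile.x, profile.z
    hull = _lower_hull(x, z)
    base = np.interp(x, x[hull], z[hull])
    return float(np.max(z - base))


def dome_shaped_macula(
    horizontal: RpeProfile,
    vertical: RpeProfile,
    threshold_um: float = DOME_THRESHOLD_UM,
) -> bool:
    """True if either orientation shows an RPE bulge strictly above threshold."""
    _require_scaled_span(horizontal)
    _require_scaled_span(vertical)
    return max(_bulge(horizontal), _bulge(vertical)) > threshold_um


def screen_eye(
    record: EyeRecord,
    flags: ExclusionFlags = ExclusionFlags(),
    dome_threshold_um: float = DOME_THRESHOLD_UM,
) -> ScreeningOutcome:
    """Aggregate the inclusion rule, the dome rule, and the metadata flags."""
    reasons: list[ExclusionReason] = []
    if not is_high_myopia(
        record.axial_length_mm, record.refractive_error_d, record.pseudophakic
    ):
        reasons.append(ExclusionReason.NOT_HIGH_MYOPIA)
    if record.profile_h is not None and record.profile_v is not None:
        if dome_shaped_macula(record.profile_h, record.profile_v, dome_threshold_um):
            reasons.append(ExclusionReason.DOME_SHAPED_MACULA)
    reasons.extend(flags.reasons())
    return ScreeningOutcome(reasons=tuple(reasons))


def one_eye_per_patient(cohort: Cohort) -> Cohort:
    """Keep one eye per patient: the right eye whenever both are eligible."""
    by_patient: dict[str, list[EyeRecord]] = {}
    for rec in cohort.records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    kept: list[EyeRecord] = []
    for recs in by_patient.values():
        if len(recs) == 1:
            kept.append(recs[0])
        else:
            od = [r for r in recs if r.eye is Eye.OD]
            kept.append(od[0] if od else recs[0])
    return Cohort(records=kept, provenance=cohort.provenance, seed=cohort.seed)


@dataclass
class ScreeningReport:
    """Per-eye outcomes plus the surviving cohort."""

    outcomes: dict[tuple[str, str], ScreeningOutcome] = field(default_factory=dict)
    eligible: Cohort = field(default_factory=Cohort)


def screen_cohort(
    cohort: Cohort,
    flags: dict[tuple[str, str], ExclusionFlags] | None = None,
    dome_threshold_um: float = DOME_THRESHOLD_UM,
) -> ScreeningReport:
    """Screen every eye, then apply the one-eye-per-patient rule."""
    flags = flags or {}
    outcomes: dict[tuple[str, str], ScreeningOutcome] = {}
    survivors: list[EyeRecord] = []
    for rec in cohort.records:
        outcome = screen_eye(
            rec, flags.get(rec.key, ExclusionFlags()), dome_threshold_um
        )
        outcomes[rec.key] = outcome
        if outcome.eligible:
            survivors.append(rec)
    eligible = one_eye_per_patient(
        Cohort(records=survivors, provenance=cohort.provenance, seed=cohort.seed)
    )
    kept_keys = {r.key for r in eligible.records}
    for key, outcome in outcomes.items():
        if outcome.eligible and key not in kept_keys:
            outcomes[key] = ScreeningOutcome(
                reasons=(ExclusionReason.DUPLICATE_EYE,)
            )
    return ScreeningReport(outcomes=outcomes, eligible=eligible)
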