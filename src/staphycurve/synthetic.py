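"""Synthetic cohorts with the statistical structure the analysis assumes.

No patient-level OCT dataset is publicly deposited for this kind of study,
so the package ships two generators:

* **Metric-level** (:func:`sample_cohort_metrics`) — draws per-eye clinical
  variables and curvature parameters directly from configured group
  distributions (defaults: the published three-group summary statistics).
  Physically bounded variables (curvature index ≥ 1, coefficient a ≥ 0,
  thicknesses ≥ 0) use lower-truncated Gaussians whose underlying location
  and scale are solved so that the *truncated* distribution has exactly
  the configured mean and SD — the configured numbers are observed sample
  moments, so the generator must reproduce them as realized moments, not
  as pre-truncation parameters.  The three curvature parameters share a
  Gaussian copula with a configurable positive correlation.
* **Geometry-level** (:func:`synthesize_profile`,
  :func:`generate_group_geometry`) — builds RPE polylines
  ``z(x) = a x^2 + tilt x + bump`` plus measurement noise, for end-to-end
  tests of the measurement pipeline with internally consistent shapes.

The two levels are deliberately separate: the published coefficient-a
magnitudes and staphyloma heights are not mutually consistent under a
single parabola in micrometre units (the original plot-export units are
unknown), so metric-level cohorts reproduce the printed statistics while
geometry-level cohorts feed the pipeline self-consistent shapes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .core import (
    Cohort,
    CurvatureMetrics,
    Eye,
    EyeRecord,
    Group,
    Orientation,
    Provenance,
    RpeProfile,
    Sex,
    StaphylomaType,
)
from .errors import ConfigError

logger = logging.getLogger(__name__)

#: Scale of the stored coefficient-a group parameters (the published
#: tables print coefficient a x 10^4).
COEF_A_PRINT_SCALE = 1e-4


@dataclass(frozen=True)
class GroupDistribution:
    """Generative distribution of one study group.

    Continuous fields are ``(mean, sd)`` pairs; ``coef_a_avg`` is on the
    printed x10^4 scale.  ``height_fractions`` splits the total staphyloma
    height into (nasal, temporal, superior, inferior).  ``coef_a_delta`` and
    ``ci_delta`` are the half-differences (horizontal - vertical)/2 used to
    split an average into its two orientations.  Frequencies must sum to 1.
    """

    n: int
    age: tuple[float, float]
    bcva: tuple[float, float]
    axial_length: tuple[float, float]
    refractive_error: tuple[float, float]
    sct: tuple[float, float]
    h_total: tuple[float, float]
    coef_a_avg: tuple[float, float]
    ci_avg: tuple[float, float]
    height_fractions: tuple[float, float, float, float]
    coef_a_delta: float
    ci_delta: float
    sex_freq: dict[str, float]
    staphyloma_type_freq: dict[str, float]
    metapm_freq: dict[int, float]
    pseudophakic_p: float
    fsh: Optional[tuple[float, float]] = None
    cnv_size: Optional[tuple[float, float]] = None
    curvature_rho: float = 0.65

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError("group size must be >= 0")
        for name in ("age", "bcva", "axial_length", "refractive_error", "sct",
                     "h_total", "coef_a_avg", "ci_avg"):
            if getattr(self, name)[1] < 0:
                raise ConfigError(f"{name} SD must be >= 0")
        for name in ("sex_freq", "staphyloma_type_freq", "metapm_freq"):
            freqs = getattr(self, name)
            if abs(sum(freqs.values()) - 1.0) > 1e-9 or min(freqs.values()) < 0:
                raise ConfigError(f"{name} must be nonnegative and sum to 1")
        if not -1.0 < self.curvature_rho < 1.0:
            raise ConfigError("curvature_rho must lie in (-1, 1)")
        rho = self.curvature_rho
        corr = np.full((3, 3), rho) + (1 - rho) * np.eye(3)
        if np.linalg.eigvalsh(corr).min() < -1e-12:
            raise ConfigError("curvature correlation matrix is not PSD")


def _freq(pairs: list[tuple[object, float]], total: int) -> dict:
    return {k: v / total for k, v in pairs}


def default_group_distributions() -> dict[Group, GroupDistribution]:
    """Published three-group summary statistics as generator defaults.

    The foveoschisis-height and CNV-size distributions are not published as
    group summaries; clinically plausible values are used (FSH ~ 350 ± 150
    µm; CNV area ~ 1.2 ± 0.8 disc areas, both truncated at 0).
    """
    mtm = GroupDistribution(
        n=72,
        age=(60.7, 9.1), bcva=(0.73, 0.54), axial_length=(29.8, 1.7),
        refractive_error=(-12.6, 3.7), sct=(39.1, 19.7),
        h_total=(2614.0, 944.3), coef_a_avg=(4.33, 2.35), ci_avg=(1.066, 0.048),
        height_fractions=_normed(599.3, 727.0, 852.8, 434.8),
        coef_a_delta=(4.47 - 4.21) / 2, ci_delta=(1.064 - 1.069) / 2,
        sex_freq=_freq([("M", 17), ("F", 55)], 72),
        staphyloma_type_freq=_freq(
            [("wide_macular", 31), ("narrow_macular", 36), ("other", 5)], 72),
        metapm_freq=_freq([(1, 8), (2, 34), (3, 29), (4, 1)], 72),
        pseudophakic_p=10 / 72,
        fsh=(350.0, 150.0),
    )
    mcnv = GroupDistribution(
        n=58,
        age=(60.0, 10.6), bcva=(0.80, 0.39), axial_length=(30.0, 1.4),
        refractive_error=(-12.4, 2.7), sct=(34.0, 17.8),
        h_total=(2030.7, 879.6), coef_a_avg=(3.11, 1.39), ci_avg=(1.044, 0.027),
        height_fractions=_normed(257.2, 736.7, 658.9, 377.9),
        coef_a_delta=(2.96 - 3.25) / 2, ci_delta=(1.044 - 1.043) / 2,
        sex_freq=_freq([("M", 11), ("F", 47)], 58),
        staphyloma_type_freq=_freq(
            [("wide_macular", 29), ("narrow_macular", 27), ("other", 2)], 58),
        metapm_freq=_freq([(1, 5), (2, 27), (3, 26), (4, 0)], 58),
        pseudophakic_p=6 / 58,
        cnv_size=(1.2, 0.8),
    )
    control = GroupDistribution(
        n=69,
        age=(52.3, 9.1), bcva=(0.54, 0.41), axial_length=(29.5, 1.5),
        refractive_error=(-11.9, 2.8), sct=(37.9, 18.5),
        h_total=(2042.2, 771.1), coef_a_avg=(3.14, 1.56), ci_avg=(1.042, 0.021),
        height_fractions=_normed(382.8, 627.4, 597.2, 434.9),
        coef_a_delta=(3.21 - 3.07) / 2, ci_delta=(1.043 - 1.041) / 2,
        sex_freq=_freq([("M", 20), ("F", 49)], 69),
        staphyloma_type_freq=_freq(
            [("wide_macular", 28), ("narrow_macular", 39), ("other", 2)], 69),
        metapm_freq=_freq([(1, 12), (2, 33), (3, 24), (4, 0)], 69),
        pseudophakic_p=5 / 69,
    )
    return {Group.MTM: mtm, Group.MCNV: mcnv, Group.CONTROL: control}


def _normed(*values: float) -> tuple[float, float, float, float]:
    total = sum(values)
    return tuple(v / total for v in values)  # type: ignore[return-value]


@lru_cache(maxsize=256)
def _matched_truncnorm(mean: float, sd: float, lower: float):
    """Underlying (mu, sigma) of a lower-truncated normal whose truncated
    moments equal ``(mean, sd)``.  Returns None when truncation is
    negligible (> 8 sd below the mean)."""
    if sd == 0:
        if mean < lower:
            raise ConfigError(f"degenerate mean {mean} below bound {lower}")
        return None
    if (mean - lower) / sd > 8:
        return None

    def residual(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        alpha = (lower - mu) / sigma
        m = stats.truncnorm.mean(alpha, np.inf, loc=mu, scale=sigma)
        s = stats.truncnorm.std(alpha, np.inf, loc=mu, scale=sigma)
        return [m - mean, s - sd]

    sol = optimize.root(residual, x0=[mean, math.log(sd)], tol=1e-12)
    if not sol.success:
        raise ConfigError(
            f"cannot match a truncated normal to mean={mean}, sd={sd}, lower={lower}"
        )
    mu, sigma = float(sol.x[0]), float(math.exp(sol.x[1]))
    logger.info(
        "truncation at %g active for mean=%g sd=%g: underlying mu=%.6g sigma=%.6g",
        lower, mean, sd, mu, sigma,
    )
    return mu, sigma


def _draw(z: np.ndarray, mean: float, sd: float, lower: Optional[float]) -> np.ndarray:
    """Transform standard-normal draws to the configured margin."""
    if sd == 0:
        if lower is not None and mean < lower:
            raise ConfigError(f"degenerate mean {mean} below bound {lower}")
        return np.full_like(z, mean)
    if lower is None:
        return mean + sd * z
    matched = _matched_truncnorm(mean, sd, lower)
    if matched is None:
        return mean + sd * z
    mu, sigma = matched
    alpha = (lower - mu) / sigma
    u = stats.norm.cdf(z)
    return stats.truncnorm.ppf(u, alpha, np.inf, loc=mu, scale=sigma)


def _choices(rng: np.random.Generator, freq: dict, size: int) -> np.ndarray:
    keys = list(freq.keys())
    p = np.array([freq[k] for k in keys], dtype=float)
    idx = rng.choice(len(keys), size=size, p=p / p.sum())
    return np.array([keys[i] for i in idx], dtype=object)


def sample_cohort_metrics(
    groups: Optional[dict[Group, GroupDistribution]] = None,
    seed: int = 0,
) -> Cohort:
    """Draw a metric-level synthetic cohort from per-group distributions.

    The three curvature parameters (total height, average coefficient a,
    average curvature index) are drawn through a shared Gaussian copula
    with pairwise correlation ``curvature_rho``; all other continuous
    variables are independent.  Reproducible for a fixed seed.
    """
    groups = groups if groups is not None else default_group_distributions()
    rng = np.random.default_rng(seed)
    records: list[EyeRecord] = []
    for group in (Group.MTM, Group.MCNV, Group.CONTROL):
        if group not in groups:
            continue
        dist = groups[group]
        n = dist.n
        if n == 0:
            continue
        rho = dist.curvature_rho
        corr = np.full((3, 3), rho) + (1 - rho) * np.eye(3)
        chol = np.linalg.cholesky(corr)
        latent = rng.standard_normal((n, 3)) @ chol.T
        h_total = _draw(latent[:, 0], *dist.h_total, lower=None)
        coef_a = _draw(latent[:, 1], *dist.coef_a_avg, lower=0.0)
        ci = _draw(latent[:, 2], *dist.ci_avg, lower=1.0)

        age = _draw(rng.standard_normal(n), *dist.age, lower=0.0)
        bcva = _draw(rng.standard_normal(n), *dist.bcva, lower=None)
        al = _draw(rng.standard_normal(n), *dist.axial_length, lower=None)
        refr = _draw(rng.standard_normal(n), *dist.refractive_error, lower=None)
        sct = _draw(rng.standard_normal(n), *dist.sct, lower=0.0)
        fsh = (
            _draw(rng.standard_normal(n), *dist.fsh, lower=0.0)
            if dist.fsh is not None else [None] * n
        )
        cnv = (
            _draw(rng.standard_normal(n), *dist.cnv_size, lower=0.0)
            if dist.cnv_size is not None else [None] * n
        )
        sex = _choices(rng, dist.sex_freq, n)
        stype = _choices(rng, dist.staphyloma_type_freq, n)
        metapm = _choices(rng, dist.metapm_freq, n)
        pseudo = rng.random(n) < dist.pseudophakic_p
        eyes = np.where(rng.random(n) < 0.5, Eye.OD.value, Eye.OS.value)

        fn, ft, fs, fi = dist.height_fractions
        for i in range(n):
            ci_i = float(ci[i])
            d_ci = math.copysign(min(abs(dist.ci_delta), ci_i - 1.0), dist.ci_delta)
            a_avg = float(coef_a[i]) * COEF_A_PRINT_SCALE
            d_a = dist.coef_a_delta * COEF_A_PRINT_SCALE
            if abs(d_a) > abs(a_avg):  # keep both orientations nonnegative
                d_a = math.copysign(abs(a_avg), d_a)
            metrics = CurvatureMetrics(
                h_nasal=fn * h_total[i],
                h_temporal=ft * h_total[i],
                h_superior=fs * h_total[i],
                h_inferior=fi * h_total[i],
                h_horizontal=(fn + ft) * h_total[i],
                h_vertical=(fs + fi) * h_total[i],
                h_total=float(h_total[i]),
                coef_a_horizontal=a_avg + d_a,
                coef_a_vertical=a_avg - d_a,
                coef_a_average=a_avg,
                ci_horizontal=ci_i + d_ci,
                ci_vertical=ci_i - d_ci,
                ci_average=ci_i,
            )
            records.append(
                EyeRecord(
                    patient_id=f"{group.value}-{i + 1:03d}",
                    eye=Eye(eyes[i]),
                    group=group,
                    age_years=float(age[i]),
                    sex=Sex(sex[i]),
                    bcva_logmar=float(bcva[i]),
                    axial_length_mm=float(al[i]),
                    refractive_error_d=float(refr[i]),
                    pseudophakic=bool(pseudo[i]),
                    staphyloma_type=StaphylomaType(stype[i]),
                    metapm_category=int(metapm[i]),
                    sct_um=float(sct[i]),
                    fsh_um=None if fsh[i] is None else float(fsh[i]),
                    cnv_size_da=None if cnv[i] is None else float(cnv[i]),
                    metrics=metrics,
                )
            )
    return Cohort(records=records, provenance=Provenance.SYNTHETIC_METRICS, seed=seed)


# ---------------------------------------------------------------------------
# Geometry-level generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryParams:
    """Shape parameters of one synthetic eye's RPE geometry.

    ``a_*`` are parabola coefficients (µm⁻¹), ``tilt_*`` dimensionless
    slopes, the bump a Gaussian dome perturbation (amplitude µm, width µm),
    ``noise_sd_um`` i.i.d. tracing noise added per sample.
    """

    a_h: float = 7e-5
    a_v: float = 7e-5
    tilt_h: float = 0.0
    tilt_v: float = 0.0
    bump_amplitude_um: float = 0.0
    bump_sigma_um: float = 150.0
    noise_sd_um: float = 0.0
    sample_spacing_um: float = 50.0
    half_span_um: float = 3300.0
    axial_length_mm: float = 29.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sample_spacing_um <= 0:
            raise ConfigError("sample_spacing_um must be > 0")
        if self.noise_sd_um < 0:
            raise ConfigError("noise_sd_um must be >= 0")
        if self.half_span_um < 3000:
            raise ConfigError("half_span_um must cover the ±3000 µm landmarks")


def synthesize_profile(
    params: GeometryParams,
    orientation: Orientation,
    rng: Optional[np.random.Generator] = None,
) -> RpeProfile:
    """Build one RPE polyline from geometry parameters.

    ``z(x) = a x^2 + tilt x + bump exp(-x^2 / 2 sigma^2)``, centered so that
    z(0) = 0 before noise is added; the profile is marked as already
    magnification-corrected (its x are actual µm).
    """
    orientation = Orientation(orientation)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    a, tilt = (
        (params.a_h, params.tilt_h)
        if orientation is Orientation.HORIZONTAL
        else (params.a_v, params.tilt_v)
    )
    x = np.arange(
        -params.half_span_um,
        params.half_span_um + params.sample_spacing_um / 2,
        params.sample_spacing_um,
    )
    z = a * x**2 + tilt * x
    if params.bump_amplitude_um:
        z = z + params.bump_amplitude_um * np.exp(
            -(x**2) / (2 * params.bump_sigma_um**2)
        )
        z = z - params.bump_amplitude_um  # recenter: z(0) = 0 before noise
    if params.noise_sd_um:
        z = z + rng.normal(0.0, params.noise_sd_um, size=len(x))
    return RpeProfile(
        orientation=orientation,
        x=x,
        z=z,
        axial_length_mm=params.axial_length_mm,
        scaled=True,
    )


@dataclass(frozen=True)
class GeometryRanges:
    """Uniform sampling ranges for per-eye geometry parameters."""

    a: tuple[float, float] = (5e-5, 1e-4)
    tilt: tuple[float, float] = (-0.05, 0.05)
    bump_amplitude: tuple[float, float] = (0.0, 0.0)
    bump_sigma: tuple[float, float] = (100.0, 200.0)
    noise_sd_um: float = 5.0
    sample_spacing_um: float = 50.0
    half_span_um: float = 3300.0

    def sample(self, rng: np.random.Generator, axial_length_mm: float) -> GeometryParams:
        return GeometryParams(
            a_h=rng.uniform(*self.a),
            a_v=rng.uniform(*self.a),
            tilt_h=rng.uniform(*self.tilt),
            tilt_v=rng.uniform(*self.tilt),
            bump_amplitude_um=rng.uniform(*self.bump_amplitude),
            bump_sigma_um=rng.uniform(*self.bump_sigma),
            noise_sd_um=self.noise_sd_um,
            sample_spacing_um=self.sample_spacing_um,
            half_span_um=self.half_span_um,
            axial_length_mm=axial_length_mm,
        )


def generate_group_geometry(
    n: int,
    ranges: GeometryRanges = GeometryRanges(),
    seed: int = 0,
    group: Group = Group.CONTROL,
    dist: Optional[GroupDistribution] = None,
) -> Cohort:
    """Cohort of ``n`` eyes with sampled geometry and sampled metadata.

    Profiles are attached; curvature metrics are left to the measurement
    pipeline.  Metadata (age, sex, axial length, ...) is drawn from the
    given :class:`GroupDistribution` (default: the group's published
    distribution).
    """
    if dist is None:
        dist = default_group_distributions()[group]
    rng = np.random.default_rng(seed)
    records: list[EyeRecord] = []
    for i in range(n):
        al = float(_draw(rng.standard_normal(1), *dist.axial_length, lower=None)[0])
        params = ranges.sample(rng, axial_length_mm=al)
        prof_h = synthesize_profile(params, Orientation.HORIZONTAL, rng)
        prof_v = synthesize_profile(params, Orientation.VERTICAL, rng)
        records.append(
            EyeRecord(
                patient_id=f"{group.value}-G{i + 1:03d}",
                eye=Eye.OD if rng.random() < 0.5 else Eye.OS,
                group=group,
                age_years=float(_draw(rng.standard_normal(1), *dist.age, lower=0.0)[0]),
                sex=Sex(_choices(rng, dist.sex_freq, 1)[0]),
                bcva_logmar=float(
                    _draw(rng.standard_normal(1), *dist.bcva, lower=None)[0]
                ),
                axial_length_mm=al,
                refractive_error_d=float(
                    _draw(rng.standard_normal(1), *dist.refractive_error, lower=None)[0]
                ),
                pseudophakic=bool(rng.random() < dist.pseudophakic_p),
                staphyloma_type=StaphylomaType(
                    _choices(rng, dist.staphyloma_type_freq, 1)[0]
                ),
                metapm_category=int(_choices(rng, dist.metapm_freq, 1)[0]),
                sct_um=float(_draw(rng.standard_normal(1), *dist.sct, lower=0.0)[0]),
                fsh_um=(
                    float(_draw(rng.standard_normal(1), *dist.fsh, lower=0.0)[0])
                    if dist.fsh is not None else None
                ),
                cnv_size_da=(
                    float(_draw(rng.standard_normal(1), *dist.cnv_size, lower=0.0)[0])
                    if dist.cnv_size is not None else None
                ),
                profile_h=prof_h,
                profile_v=prof_v,
            )
        )
    return Cohort(records=records, provenance=Provenance.SYNTHETIC_GEOMETRY, seed=seed)
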