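import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from staphycurve import (
    Orientation,
    RpeProfile,
    SpanError,
    StateError,
    ValidationError,
    average_sct,
    compute_metrics,
    curvature_index,
    elevation_at,
    fit_coefficient_a,
    foveoschisis_height,
    staphyloma_heights,
)

from conftest import make_profile, parabola_index_closed_form


class TestElevationAt:
    def test_exact_at_sample_points(self):
        prof = make_profile(a=7e-5)
        i = 10
        assert elevation_at(prof, float(prof.x[i])) == prof.z[i]

    def test_midpoint_is_mean_of_neighbours(self):
        prof = RpeProfile(
            Orientation.HORIZONTAL, [-3000.0, 0.0, 3000.0], [630.0, 0.0, 630.0],
            29.0, scaled=True,
        )
        assert elevation_at(prof, 1500.0) == pytest.approx(315.0)

    def test_dense_parabola_matches_analytic(self):
        a = 8e-5
        prof = make_profile(a=a, spacing=5.0)
        for x in (-2345.6, -17.0, 910.3, 2999.9):
            assert elevation_at(prof, x) == pytest.approx(a * x * x, abs=a * 25)

    def test_out_of_span_rejected(self):
        prof = make_profile(a=7e-5, half_span=3300)
        with pytest.raises(SpanError):
            elevation_at(prof, 3300.1)

    def test_unscaled_profile_rejected(self):
        prof = make_profile(a=7e-5, scaled=False)
        with pytest.raises(StateError):
            elevation_at(prof, 0.0)


class TestStaphylomaHeights:
    def test_parabola_heights(self, parabola_pair):
        # H = a * 3000^2 = 630 µm on every side
        h = staphyloma_heights(*parabola_pair)
        for side in (h.h_nasal, h.h_temporal, h.h_superior, h.h_inferior):
            assert side == pytest.approx(630.0, abs=1e-9)
        assert h.h_total == pytest.approx(2520.0, abs=1e-9)

    def test_flat_profiles(self):
        h = staphyloma_heights(
            make_profile(), make_profile(orientation=Orientation.VERTICAL)
        )
        assert h.h_total == 0.0

    def test_pure_tilt_signed_heights_cancel(self):
        # z = 0.1 x: nasal RPE sits posterior to the fovea -> negative height
        h = staphyloma_heights(
            make_profile(tilt=0.1),
            make_profile(tilt=0.1, orientation=Orientation.VERTICAL),
        )
        assert h.h_nasal == pytest.approx(-300.0)
        assert h.h_temporal == pytest.approx(300.0)
        assert h.h_horizontal == pytest.approx(0.0, abs=1e-9)

    def test_reflection_swaps_sides(self):
        prof_h = make_profile(a=5e-5, tilt=0.03)
        prof_v = make_profile(a=5e-5, tilt=0.02, orientation=Orientation.VERTICAL)
        h = staphyloma_heights(prof_h, prof_v)
        mirrored = staphyloma_heights(
            RpeProfile(Orientation.HORIZONTAL, -prof_h.x[::-1], prof_h.z[::-1],
                       prof_h.axial_length_mm, scaled=True),
            RpeProfile(Orientation.VERTICAL, -prof_v.x[::-1], prof_v.z[::-1],
                       prof_v.axial_length_mm, scaled=True),
        )
        assert mirrored.h_nasal == pytest.approx(h.h_temporal)
        assert mirrored.h_temporal == pytest.approx(h.h_nasal)
        assert mirrored.h_superior == pytest.approx(h.h_inferior)

    def test_short_span_rejected(self):
        short = make_profile(a=7e-5, half_span=2000.0)
        with pytest.raises(SpanError, match="2000"):
            staphyloma_heights(short, make_profile(orientation=Orientation.VERTICAL))

    def test_orientation_mix_up_rejected(self):
        with pytest.raises(ValidationError):
            staphyloma_heights(
                make_profile(orientation=Orientation.VERTICAL), make_profile()
            )


class TestFitCoefficientA:
    def test_exact_quadratic_recovery(self):
        # the fit grid samples the parabola exactly, so OLS must return it
        a = 4.45e-4
        prof = make_profile(a=a, spacing=300.0)
        fit = fit_coefficient_a(prof)
        assert fit.a == pytest.approx(a, rel=1e-12)
        assert fit.n_points == 21

    def test_straight_line(self):
        fit = fit_coefficient_a(make_profile(tilt=0.05))
        assert fit.a == pytest.approx(0.0, abs=1e-18)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.floats(min_value=-3e-4, max_value=3e-4),
        b=st.floats(min_value=-0.2, max_value=0.2),
        c=st.floats(min_value=-500, max_value=500),
    )
    def test_any_exact_quadratic_reproduced(self, a, b, c):
        x = np.arange(-3300.0, 3301.0, 50.0)
        prof = RpeProfile(
            Orientation.HORIZONTAL, x, a * x**2 + b * x + c, 29.0, scaled=True
        )
        fit = fit_coefficient_a(prof)
        scale = max(1.0, abs(a))
        assert fit.a == pytest.approx(a, rel=1e-12, abs=1e-12 * scale)
        assert fit.b == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_x_unit_scale_changes_units(self):
        # with x in mm the coefficient grows by 1e6
        prof = make_profile(a=7e-5)
        fit_um = fit_coefficient_a(prof, x_unit_scale=1.0)
        fit_mm = fit_coefficient_a(prof, x_unit_scale=1e-3)
        assert fit_mm.a == pytest.approx(fit_um.a * 1e6, rel=1e-9)

    def test_noisy_fit_unbiased_and_rss_estimates_variance(self):
        # least-squares theory: E[a_hat] = a, E[rss/(n-3)] = sigma^2
        a, sigma = 7e-5, 8.0
        rng = np.random.default_rng(11)
        x = np.arange(-3000.0, 3001.0, 300.0)
        a_hats, rsss = [], []
        for _ in range(400):
            z = a * x**2 + rng.normal(0, sigma, len(x))
            prof = RpeProfile(Orientation.HORIZONTAL, x, z, 29.0, scaled=True)
            fit = fit_coefficient_a(prof)
            a_hats.append(fit.a)
            rsss.append(fit.rss)
        assert np.mean(a_hats) == pytest.approx(a, rel=0.02)
        assert np.mean(rsss) / 18 == pytest.approx(sigma**2, rel=0.15)


class TestCurvatureIndex:
    def test_straight_segment_is_exactly_one(self):
        assert curvature_index(make_profile(tilt=0.07)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_parabola_matches_closed_form(self):
        # u = 2 a X; index = [u sqrt(1+u^2) + asinh(u)] / (2u)
        a = 7.07e-5
        prof = make_profile(a=a, spacing=5.0)
        expected = parabola_index_closed_form(a)
        assert expected == pytest.approx(1.0292, abs=5e-4)
        assert curvature_index(prof) == pytest.approx(expected, rel=1e-6)

    def test_closed_form_agrees_with_quadrature(self):
        a = 9e-5
        arc, _ = quad(lambda x: np.sqrt(1 + (2 * a * x) ** 2), -3000, 3000)
        assert parabola_index_closed_form(a) == pytest.approx(arc / 6000, rel=1e-10)

    def test_chord_includes_elevation_component(self):
        # tilted parabola: endpoints differ in z, chord > 6000
        prof = make_profile(a=7e-5, tilt=0.0775, spacing=5.0)
        dz = elevation_at(prof, 3000.0) - elevation_at(prof, -3000.0)
        chord = np.hypot(6000.0, dz)
        assert chord > 6000.0
        arc, _ = quad(
            lambda x: np.sqrt(1 + (2 * 7e-5 * x + 0.0775) ** 2), -3000, 3000
        )
        assert curvature_index(prof) == pytest.approx(arc / chord, rel=1e-5)

    def test_grid_endpoints_interpolated_not_extrapolated(self):
        # samples straddle ±3000 without landing on them
        x = np.arange(-3290.0, 3300.0, 70.0)
        a = 6e-5
        prof = RpeProfile(Orientation.HORIZONTAL, x, a * x**2, 29.0, scaled=True)
        assert curvature_index(prof) == pytest.approx(
            parabola_index_closed_form(a), rel=1e-4
        )

    @settings(max_examples=40, deadline=None)
    @given(
        a=st.floats(min_value=-2e-4, max_value=2e-4),
        tilt=st.floats(min_value=-0.1, max_value=0.1),
        shift=st.floats(min_value=-500, max_value=500),
    )
    def test_index_at_least_one_and_translation_invariant(self, a, tilt, shift):
        prof = make_profile(a=a, tilt=tilt)
        ci = curvature_index(prof)
        assert ci >= 1.0 - 1e-12
        shifted = RpeProfile(
            prof.orientation, prof.x, prof.z + shift, prof.axial_length_mm,
            scaled=True,
        )
        assert curvature_index(shifted) == pytest.approx(ci, rel=1e-12)
        assert fit_coefficient_a(shifted).a == pytest.approx(
            fit_coefficient_a(prof).a, rel=1e-9, abs=1e-15
        )

    def test_equality_iff_collinear(self):
        assert curvature_index(make_profile(tilt=0.05)) == pytest.approx(1.0, abs=1e-12)
        assert curvature_index(make_profile(a=1e-6)) > 1.0 + 1e-9

    def test_discretization_bound_on_fit_grid(self):
        # 21-point polyline underestimates the true arc by < 0.1% for a <= 2e-4
        for a in (5e-5, 1e-4, 2e-4):
            coarse = make_profile(a=a, spacing=300.0, half_span=3000.0)
            truth = parabola_index_closed_form(a)
            approx = curvature_index(coarse)
            assert approx <= truth + 1e-12
            assert (truth - approx) / truth < 1e-3


class TestComputeMetrics:
    def test_identical_orientations_average_to_either(self, parabola_pair):
        m = compute_metrics(*parabola_pair)
        assert m.ci_average == pytest.approx(m.ci_horizontal)
        assert m.coef_a_average == pytest.approx(m.coef_a_horizontal)

    def test_average_strictly_between_unequal_orientations(self):
        h = make_profile(a=9e-5)
        v = make_profile(a=5e-5, orientation=Orientation.VERTICAL)
        m = compute_metrics(h, v)
        assert m.coef_a_vertical < m.coef_a_average < m.coef_a_horizontal
        assert m.ci_vertical < m.ci_average < m.ci_horizontal

    def test_fixture_eye_composition(self, parabola_pair):
        m = compute_metrics(*parabola_pair)
        assert m.h_total == pytest.approx(2520.0, abs=1e-9)
        assert m.coef_a_average == pytest.approx(7e-5, rel=1e-10)
        assert m.ci_average == pytest.approx(
            parabola_index_closed_form(7e-5), rel=1e-5
        )

    def test_metrics_comonotone_in_steepness(self):
        # all three parameters increase strictly with the parabola coefficient
        values = []
        for a in (3e-5, 6e-5, 9e-5, 1.2e-4):
            m = compute_metrics(
                make_profile(a=a),
                make_profile(a=a, orientation=Orientation.VERTICAL),
            )
            values.append((m.h_total, m.coef_a_average, m.ci_average))
        for i in range(3):
            col = [v[i] for v in values]
            assert all(x < y for x, y in zip(col, col[1:]))

    def test_parabola_height_identity(self):
        # for a pure parabola h_horizontal = 2 a X^2 exactly
        for a in (4e-5, 7e-5, 1.1e-4):
            m = compute_metrics(
                make_profile(a=a),
                make_profile(a=a, orientation=Orientation.VERTICAL),
            )
            assert m.h_horizontal == pytest.approx(2 * a * 3000**2, rel=1e-12)
            assert m.h_horizontal == pytest.approx(
                2 * m.coef_a_horizontal * 3000**2, rel=1e-9
            )


class TestSeverityMeasures:
    def _layers(self, ilm_z0=300.0):
        x = np.arange(-1000.0, 1001.0, 50.0)
        rpe = RpeProfile(Orientation.HORIZONTAL, x, np.zeros_like(x), 29.0, scaled=True)
        ilm = RpeProfile(
            Orientation.HORIZONTAL, x, np.full_like(x, ilm_z0), 29.0, scaled=True
        )
        return ilm, rpe

    def test_simple_fsh(self):
        ilm, rpe = self._layers(300.0)
        assert foveoschisis_height(ilm, rpe) == pytest.approx(300.0)

    def test_macular_hole_bridge(self):
        x = np.arange(-1000.0, 1001.0, 50.0)
        rpe = RpeProfile(Orientation.HORIZONTAL, x, np.zeros_like(x), 29.0, scaled=True)
        # ILM rises linearly 250 -> 350 across the hole edges at ±500
        ilm = RpeProfile(Orientation.HORIZONTAL, x, 300.0 + 0.1 * x, 29.0, scaled=True)
        fsh = foveoschisis_height(ilm, rpe, hole=(-500.0, 500.0))
        assert fsh == pytest.approx(300.0)

    def test_coincident_layers(self):
        ilm, rpe = self._layers(0.0)
        assert foveoschisis_height(ilm, rpe) == 0.0

    def test_crossed_layers_rejected(self):
        ilm, rpe = self._layers(-10.0)
        with pytest.raises(ValidationError, match="negative"):
            foveoschisis_height(ilm, rpe)

    def test_hole_must_straddle_fovea(self):
        ilm, rpe = self._layers()
        with pytest.raises(ValidationError, match="straddle"):
            foveoschisis_height(ilm, rpe, hole=(100.0, 500.0))

    def test_average_sct(self):
        assert average_sct(30.0, 50.0) == 40.0
        assert average_sct(37.0, 37.0) == 37.0
        rng = np.random.default_rng(5)
        pairs = rng.uniform(0, 400, size=(1000, 2))
        got = np.array([average_sct(a, b) for a, b in pairs])
        np.testing.assert_allclose(got, pairs.mean(axis=1), rtol=1e-12)

    def test_negative_sct_rejected(self):
        with pytest.raises(ValidationError):
            average_sct(-1.0, 30.0)
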