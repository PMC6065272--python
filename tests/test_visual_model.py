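from itertools import permutations

import numpy as np
import pytest

from sticklevision.color_metrics import OpsinProfile
from sticklevision.spectra_io import STANDARD_GRID, Spectrum
from sticklevision.visual_model import (
    DEFAULT_LAMBDA_MAX,
    LWS_LAMBDA_MAX,
    VisualSystem,
    delta_S,
    male_contrast,
    orange_red_sensitivity,
    pigment_absorbance,
    quantum_catch,
    receptor_contrast,
    receptor_noise,
    retina_weighted_absorbance,
    von_kries,
)

EQUAL_ETA = OpsinProfile(0.25, 0.25, 0.25, 0.25)


def rnl_general_oracle(df, e):
    """Brute-force n-receptor RNL contrast.

    The RNL distance is the noise-metric norm of the receptor-contrast
    vector projected orthogonally to the achromatic (all-ones) direction:
    with W = diag(1/e^2),
        dS^2 = df' (W - W 1 1' W / (1' W 1)) df.
    """
    df = np.asarray(df, dtype=float)
    w = 1.0 / np.asarray(e, dtype=float) ** 2
    W = np.diag(w)
    ones = np.ones_like(df)
    M = W - np.outer(w, w) / w.sum()
    return float(np.sqrt(df @ M @ df))


class TestPigmentTemplates:
    @pytest.mark.parametrize("lmax", [373.5, 437.5, 530.0, 566.0, 602.0, 638.0])
    def test_peak_location_and_height(self, lmax):
        tpl = pigment_absorbance(lmax)
        peak_at = STANDARD_GRID[np.argmax(tpl.values)]
        assert abs(peak_at - lmax) <= 1.0
        assert abs(tpl.values.max() - 1.0) <= 0.02

    def test_long_wavelength_tail_monotone(self):
        tpl = pigment_absorbance(602.0)
        sel = STANDARD_GRID >= 607
        assert np.all(np.diff(tpl.values[sel]) < 0)

    def test_lws_variants_cross_once(self):
        lo = pigment_absorbance(566.0).values
        hi = pigment_absorbance(638.0).values
        between = (STANDARD_GRID > 566) & (STANDARD_GRID < 638)
        signs = np.sign(lo[between] - hi[between])
        crossings = np.sum(np.diff(signs[signs != 0]) != 0)
        assert crossings == 1

    def test_a2_template_red_shifted_tail(self):
        a1 = pigment_absorbance(602.0, "A1")
        a2 = pigment_absorbance(602.0, "A2")
        tail = STANDARD_GRID >= 660
        assert np.all(a2.values[tail] > a1.values[tail])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="validity"):
            pigment_absorbance(250.0)


class TestQuantumCatch:
    def test_zero_reflectance_zero_catch(self, flat_spectrum, clean_field):
        tpl = pigment_absorbance(530.0)
        dark = flat_spectrum.with_values(np.zeros_like(STANDARD_GRID))
        assert quantum_catch(tpl, dark, clean_field.surface) == 0.0

    def test_linear_in_irradiance(self, flat_spectrum, clean_field):
        tpl = pigment_absorbance(530.0)
        irr = clean_field.surface
        q1 = quantum_catch(tpl, flat_spectrum, irr)
        q2 = quantum_catch(tpl, flat_spectrum, irr.with_values(2 * irr.values))
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    def test_unit_everything_gives_interval_width(self, flat_spectrum):
        ones = Spectrum(STANDARD_GRID, np.ones_like(STANDARD_GRID), "irradiance")
        tpl = pigment_absorbance(530.0)
        unit_tpl = type(tpl)(530.0, "A1", flat_spectrum.with_values(
            np.ones_like(STANDARD_GRID), kind="absorbance"))
        assert quantum_catch(unit_tpl, flat_spectrum, ones) == pytest.approx(400.0)


class TestVonKries:
    def test_unit_template_unit_background(self, flat_spectrum):
        tpl = pigment_absorbance(530.0)
        unit = type(tpl)(530.0, "A1", flat_spectrum.with_values(
            np.ones_like(STANDARD_GRID), kind="absorbance"))
        ones = Spectrum(STANDARD_GRID, np.ones_like(STANDARD_GRID), "irradiance")
        q = von_kries([400.0], [unit], ones)  # k = 1/400
        assert q[0] == pytest.approx(1.0, rel=1e-12)

    def test_white_under_own_adapting_light(self, flat_spectrum, clean_field):
        templates = [pigment_absorbance(l) for l in (373.5, 437.5, 530.0, 602.0)]
        irr = clean_field.surface
        Q = [quantum_catch(t, flat_spectrum, irr) for t in templates]
        q = von_kries(Q, templates, irr)
        np.testing.assert_allclose(q, 1.0, atol=1e-10)

    def test_joint_rescale_invariance(self, flat_spectrum, clean_field):
        templates = [pigment_absorbance(l) for l in (373.5, 437.5, 530.0, 602.0)]
        irr = clean_field.surface
        Q = np.array([quantum_catch(t, flat_spectrum, irr) for t in templates])
        q1 = von_kries(Q, templates, irr)
        scaled = irr.with_values(irr.values * 17.0)
        Q2 = np.array([quantum_catch(t, flat_spectrum, scaled) for t in templates])
        q2 = von_kries(Q2, templates, scaled)
        np.testing.assert_allclose(q1, q2, atol=1e-12)

    def test_zero_adapting_catch_rejected(self):
        tpl = pigment_absorbance(530.0)
        dark = Spectrum(STANDARD_GRID, np.zeros_like(STANDARD_GRID), "irradiance")
        with pytest.raises(ValueError, match="adaptation undefined"):
            von_kries([1.0], [tpl], dark)


class TestReceptorContrastAndNoise:
    def test_log_ratio_values(self):
        np.testing.assert_allclose(receptor_contrast([1.0], [1.0]), [0.0])
        np.testing.assert_allclose(
            receptor_contrast([np.e], [1.0]), [1.0], atol=1e-15
        )

    def test_antisymmetry(self):
        a, b = np.array([0.3, 2.0]), np.array([1.1, 0.7])
        np.testing.assert_allclose(
            receptor_contrast(a, b), -receptor_contrast(b, a), atol=1e-15
        )

    @pytest.mark.parametrize("eta,expected", [(1.0, 0.05), (0.25, 0.10)])
    def test_weber_scaling(self, eta, expected):
        assert receptor_noise(0.05, eta) == pytest.approx(expected, rel=1e-12)

    def test_noise_decreasing_in_density(self):
        etas = np.linspace(0.05, 1.0, 20)
        noise = [receptor_noise(0.05, h) for h in etas]
        assert np.all(np.diff(noise) < 0)

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError, match="dropped"):
            receptor_noise(0.05, 0.0)


class TestDeltaS:
    def test_achromatic_shift_is_zero(self):
        for c in (-2.0, 0.0, 3.7):
            assert delta_S([c] * 4, [0.05] * 4) == 0.0

    def test_matches_general_oracle_on_axis_case(self):
        df = np.array([0.0, 0.0, 0.0, 0.8])
        e = np.array([0.05] * 4)
        assert delta_S(df, e) == pytest.approx(rnl_general_oracle(df, e), abs=1e-12)

    def test_matches_general_oracle_random(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            df = rng.normal(size=4)
            e = rng.uniform(0.02, 0.3, size=4)
            assert delta_S(df, e) == pytest.approx(
                rnl_general_oracle(df, e), abs=1e-12
            )

    def test_receptor_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        df = rng.normal(size=4)
        e = rng.uniform(0.02, 0.3, size=4)
        ref = delta_S(df, e)
        for perm in permutations(range(4)):
            assert delta_S(df[list(perm)], e[list(perm)]) == pytest.approx(
                ref, abs=1e-12
            )

    @pytest.mark.parametrize("n", [2, 3])
    def test_reduced_systems_match_oracle(self, n):
        rng = np.random.default_rng(n)
        df = rng.normal(size=n)
        e = rng.uniform(0.02, 0.3, size=n)
        assert delta_S(df, e) == pytest.approx(rnl_general_oracle(df, e), abs=1e-12)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            delta_S([0, 0, 0, 1], [0.05, 0.05, 0.0, 0.05])


class TestRetinalAbsorbance:
    def test_pure_lws_equals_template(self):
        vs = VisualSystem(eta=EQUAL_ETA)
        pure = OpsinProfile(0.0, 0.0, 0.0, 1.0)
        weighted = retina_weighted_absorbance(pure, vs)
        np.testing.assert_array_equal(
            weighted.values, pigment_absorbance(602.0).values
        )

    def test_equal_weights_are_mean(self):
        vs = VisualSystem(eta=EQUAL_ETA)
        weighted = retina_weighted_absorbance(EQUAL_ETA, vs)
        mean = vs.template_matrix().mean(axis=0)
        np.testing.assert_allclose(weighted.values, mean, atol=1e-14)

    def test_convex_combination_bounds(self, small_study):
        vs = VisualSystem(eta=EQUAL_ETA)
        tm = vs.template_matrix()
        for male in small_study.males:
            w = retina_weighted_absorbance(male.opsin, vs).values
            assert np.all(w <= tm.max(axis=0) + 1e-12)
            assert np.all(w >= tm.min(axis=0) - 1e-12)

    def test_integral_between_template_integrals(self):
        vs = VisualSystem(eta=EQUAL_ETA)
        tm = vs.template_matrix()
        integrals = np.trapezoid(tm, STANDARD_GRID, axis=1)
        w = retina_weighted_absorbance(EQUAL_ETA, vs)
        total = np.trapezoid(w.values, STANDARD_GRID)
        assert integrals.min() <= total <= integrals.max()


class TestOrangeRedSensitivity:
    def test_zero_spectrum(self):
        zero = Spectrum(STANDARD_GRID, np.zeros_like(STANDARD_GRID), "absorbance")
        assert orange_red_sensitivity(zero) == 0.0

    def test_uv_only_viewer_near_zero(self):
        vs = VisualSystem(eta=EQUAL_ETA)
        uv = OpsinProfile(1.0, 0.0, 0.0, 0.0)
        total = orange_red_sensitivity(retina_weighted_absorbance(uv, vs))
        # 61 grid points x a deep template tail
        assert total < 0.5

    def test_increasing_in_lws_share(self):
        vs = VisualSystem(eta=EQUAL_ETA)
        values = []
        for lws in np.linspace(0.1, 0.9, 9):
            rest = (1 - lws) / 3
            prof = OpsinProfile(rest, rest, rest, lws)
            values.append(
                orange_red_sensitivity(retina_weighted_absorbance(prof, vs))
            )
        assert np.all(np.diff(values) > 0)


class TestMaleContrast:
    def test_target_proportional_to_background_invisible(self, clean_field):
        side = clean_field.entries[1.0]["side"]
        down = clean_field.entries[1.0]["down"]
        # reflectance chosen so reflected light is proportional to sidewelling
        refl = Spectrum(
            STANDARD_GRID, 0.5 * side.values / down.values, "reflectance"
        )
        res = male_contrast(refl, EQUAL_ETA, 1.0, clean_field,
                            VisualSystem(eta=EQUAL_ETA))
        assert res.delta_s == pytest.approx(0.0, abs=1e-10)

    def test_illumination_scale_invariance(self, clean_field, flat_spectrum):
        from sticklevision.spectra_io import IrradianceField

        vs = VisualSystem(eta=EQUAL_ETA)
        refl = flat_spectrum.with_values(
            0.2 + 0.6 * (STANDARD_GRID - 300) / 400
        )
        res1 = male_contrast(refl, EQUAL_ETA, 1.5, clean_field, vs)
        scaled = IrradianceField(
            {
                d: {
                    k: s.with_values(s.values * 9.0)
                    for k, s in pair.items()
                }
                for d, pair in clean_field.entries.items()
            },
            clean_field.surface.with_values(clean_field.surface.values * 9.0),
        )
        res2 = male_contrast(refl, EQUAL_ETA, 1.5, scaled, vs)
        assert res2.delta_s == pytest.approx(res1.delta_s, abs=1e-10)

    def test_depth_outside_span_rejected(self, clean_field, flat_spectrum):
        with pytest.raises(ValueError, match="span"):
            male_contrast(flat_spectrum, EQUAL_ETA, 99.0, clean_field,
                          VisualSystem(eta=EQUAL_ETA))

    def test_straight_line_reimplementation_oracle(self, clean_field):
        """The pipeline equals a direct transcription of the five model steps."""
        vs = VisualSystem(eta=EQUAL_ETA)
        red_step = Spectrum(
            STANDARD_GRID,
            np.where(STANDARD_GRID >= 600, 0.8, 0.1).astype(float),
            "reflectance",
        )
        depth = 2.0
        res = male_contrast(red_step, EQUAL_ETA, depth, clean_field, vs)

        # independent straight-line script
        wl = STANDARD_GRID
        down = clean_field.entries[depth]["down"].values
        side = clean_field.entries[depth]["side"].values
        A = np.stack([pigment_absorbance(l).values for l in (373.5, 437.5, 530.0, 602.0)])
        Qt = np.array([np.trapezoid(a * red_step.values * down, wl) for a in A])
        Qb = np.array([np.trapezoid(a * 1.0 * side, wl) for a in A])
        k = np.array([1.0 / np.trapezoid(a * side, wl) for a in A])
        df = np.log((k * Qt) / (k * Qb))
        e = 0.05 / np.sqrt(np.array([0.25] * 4))
        num = (
            (e[0] * e[1]) ** 2 * (df[3] - df[2]) ** 2
            + (e[0] * e[2]) ** 2 * (df[3] - df[1]) ** 2
            + (e[0] * e[3]) ** 2 * (df[2] - df[1]) ** 2
            + (e[1] * e[2]) ** 2 * (df[3] - df[0]) ** 2
            + (e[1] * e[3]) ** 2 * (df[2] - df[0]) ** 2
            + (e[2] * e[3]) ** 2 * (df[1] - df[0]) ** 2
        )
        den = (
            (e[0] * e[1] * e[2]) ** 2
            + (e[0] * e[1] * e[3]) ** 2
            + (e[0] * e[2] * e[3]) ** 2
            + (e[1] * e[2] * e[3]) ** 2
        )
        assert res.delta_s == pytest.approx(np.sqrt(num / den), abs=1e-10)

    def test_higher_lws_viewer_sees_red_target_better(self, clean_field):
        vs = VisualSystem(eta=EQUAL_ETA)
        red_step = Spectrum(
            STANDARD_GRID,
            np.where(STANDARD_GRID >= 600, 0.8, 0.1).astype(float),
            "reflectance",
        )
        low = OpsinProfile(0.3, 0.3, 0.3, 0.1)
        high = OpsinProfile(0.2, 0.2, 0.2, 0.4)
        ds_low = male_contrast(red_step, low, 0.5, clean_field, vs).delta_s
        ds_high = male_contrast(red_step, high, 0.5, clean_field, vs).delta_s
        assert ds_high >= ds_low
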