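"""Section selection, similarity transforms, registration, averaging,
leakage quantification, and compartment means."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ichmap.datatypes import SectionImage
from ichmap.histology import (
    SimilarityTransform,
    average_intensity_map,
    compartment_mask,
    compartment_mean_intensity,
    estimate_registration,
    quantify_leakage,
    select_standard_sections,
    warp_to_template,
)
from ichmap.synthetic import template_section


class TestSectionSelection:
    def test_sixteen_section_stack_yields_eight(self):
        positions = [300 + 60 * i for i in range(16)]
        idx = select_standard_sections(positions, start_um=300,
                                       step_sections=2, n_sections=8)
        assert idx == [0, 2, 4, 6, 8, 10, 12, 14]

    def test_start_skips_anterior_sections(self):
        positions = [120, 180, 240, 300, 360, 420, 480]
        idx = select_standard_sections(positions, start_um=300,
                                       step_sections=2, n_sections=2)
        assert idx == [3, 5]

    def test_single_section_at_start(self):
        idx = select_standard_sections([100, 300, 360], start_um=300,
                                       step_sections=2, n_sections=1)
        assert idx == [1]

    def test_short_stack_error_names_shortfall(self):
        positions = [300 + 60 * i for i in range(10)]
        with pytest.raises(ValueError, match="need 15"):
            select_standard_sections(positions, start_um=300,
                                     step_sections=2, n_sections=8)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            select_standard_sections([300, 240, 360])


class TestSimilarityTransform:
    def test_apply_then_inverse_is_identity(self):
        tf = SimilarityTransform.from_params(12.0, 1.07, (4.0, -2.5),
                                             (50.0, 50.0))
        pts = np.array([[10.0, 20.0], [75.0, 5.0], [50.0, 50.0]])
        back = tf.inverse().apply(tf.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-6)

    def test_params_recovered_about_center(self):
        tf = SimilarityTransform.from_params(-8.0, 0.93, (3.0, 6.0),
                                             (30.0, 40.0))
        rot, scale, (ty, tx) = tf.params_about((30.0, 40.0))
        assert rot == pytest.approx(-8.0)
        assert scale == pytest.approx(0.93)
        assert (ty, tx) == pytest.approx((3.0, 6.0))

    def test_compose_matches_sequential_application(self):
        a = SimilarityTransform.from_params(5.0, 1.1, (1.0, 2.0))
        b = SimilarityTransform.from_params(-3.0, 0.9, (-2.0, 0.5))
        pts = np.array([[3.0, 4.0]])
        np.testing.assert_allclose(
            a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-9
        )

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            SimilarityTransform.from_params(scale=0.0)


@pytest.fixture(scope="module")
def template():
    return template_section(192, 50.0)


def _jittered(template, rot, shift, scale):
    center = ((template.labels.shape[0] - 1) / 2,) * 2
    tf = SimilarityTransform.from_params(rot, scale, shift, center)
    labs = tf.warp(template.labels.astype(float), order=0,
                   fill=0.0).astype(np.uint16)
    return SectionImage(
        channels={}, labels=labs, label_table=template.label_table,
        px_size_um=template.px_size_um, section_position_um=0.0,
        animal="a", time_h=None, genotype="wildtype",
    ), tf


class TestRegistration:
    def test_template_to_itself_is_identity(self, template):
        tform, residual, low = estimate_registration(template, template)
        rot, scale, (ty, tx) = tform.params_about((95.5, 95.5))
        assert abs(rot) < 1e-3
        assert scale == pytest.approx(1.0, abs=1e-6)
        assert abs(ty) < 1e-3 and abs(tx) < 1e-3
        assert not low

    def test_planted_rotation_shift_recovered(self, template):
        sec, tf = _jittered(template, 10.0, (5.0, -3.0), 1.0)
        est, _, _ = estimate_registration(sec, template)
        center = ((template.labels.shape[0] - 1) / 2,) * 2
        r_est, s_est, t_est = est.params_about(center)
        r_true, s_true, t_true = tf.inverse().params_about(center)
        assert r_est == pytest.approx(r_true, abs=0.5)
        assert np.hypot(t_est[0] - t_true[0],
                        t_est[1] - t_true[1]) < 0.5
        assert s_est == pytest.approx(s_true, abs=0.01)

    def test_planted_scale_recovered_within_one_percent(self, template):
        sec, tf = _jittered(template, 0.0, (0.0, 0.0), 1.1)
        est, _, _ = estimate_registration(sec, template)
        assert est.scale == pytest.approx(1.0 / 1.1, rel=0.01)

    def test_recovery_rate_over_random_transforms(self, template):
        """>= 95% of 100 random similarity jitters recovered within
        0.5 deg / 0.5 px / 1%."""
        rng = np.random.default_rng(17)
        center = ((template.labels.shape[0] - 1) / 2,) * 2
        ok = 0
        for _ in range(100):
            rot = rng.uniform(-15, 15)
            shift = tuple(rng.uniform(-10, 10, 2))
            scale = rng.uniform(0.9, 1.1)
            sec, tf = _jittered(template, rot, shift, scale)
            est, _, _ = estimate_registration(sec, template)
            r_e, s_e, t_e = est.params_about(center)
            r_t, s_t, t_t = tf.inverse().params_about(center)
            if (abs(r_e - r_t) <= 0.5
                    and abs(s_e / s_t - 1) <= 0.01
                    and np.hypot(t_e[0] - t_t[0], t_e[1] - t_t[1]) <= 0.5):
                ok += 1
        assert ok >= 95

    def test_missing_outline_raises(self, template):
        empty = SectionImage(
            channels={}, labels=np.zeros_like(template.labels),
            label_table=template.label_table, px_size_um=50.0,
            section_position_um=0.0, animal="a", time_h=None,
            genotype="wildtype",
        )
        with pytest.raises(ValueError, match="outline"):
            estimate_registration(empty, template)


class TestWarp:
    def test_identity_transform_preserves_image(self, rng):
        img = rng.normal(size=(40, 40))
        out = warp_to_template(img, SimilarityTransform.identity(),
                               (40, 40))
        np.testing.assert_allclose(out, img, atol=1e-9)

    def test_constant_image_stays_constant_on_coverage(self):
        img = np.full((50, 50), 7.0)
        tf = SimilarityTransform.from_params(8.0, 1.0, (2.0, 1.0),
                                             (24.5, 24.5))
        out = warp_to_template(img, tf, (50, 50))
        cov = np.isfinite(out)
        assert cov.any()
        np.testing.assert_allclose(out[cov], 7.0, atol=1e-9)

    def test_smooth_roundtrip_small_error(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = np.sin(yy / 10.0) + np.cos(xx / 13.0)
        tf = SimilarityTransform.from_params(7.0, 1.0, (3.0, -2.0),
                                             (31.5, 31.5))
        fwd = warp_to_template(img, tf, (64, 64))
        fwd_filled = np.where(np.isfinite(fwd), fwd, 0.0)
        back = warp_to_template(fwd_filled, tf.inverse(), (64, 64))
        ok = np.isfinite(back)
        # stay away from the border where fill values bleed in
        ok[:8] = ok[-8:] = ok[:, :8] = ok[:, -8:] = False
        err = np.abs(back - img)[ok].mean()
        assert err < 0.01 * (img.max() - img.min())


def _flat_section(template, value, animal="a", channel="CD45"):
    img = np.full(template.labels.shape, float(value))
    return SectionImage(
        channels={channel: img}, labels=template.labels.copy(),
        label_table=template.label_table, px_size_um=template.px_size_um,
        section_position_um=300.0, animal=animal, time_h=24.0,
        genotype="wildtype",
    )


class TestAveraging:
    def test_single_section_map_equals_its_image(self, template):
        sec = _flat_section(template, 10.0)
        m = average_intensity_map([sec], "CD45", template,
                                  normalize=False, register=False)
        ok = m.coverage > 0
        np.testing.assert_allclose(m.image[ok], 10.0)
        assert m.n_sections == 1 and m.n_animals == 1

    def test_two_constant_sections_average(self, template):
        secs = [_flat_section(template, 10.0, "a"),
                _flat_section(template, 20.0, "b")]
        m = average_intensity_map(secs, "CD45", template,
                                  normalize=False, register=False)
        np.testing.assert_allclose(m.image[m.coverage == 2], 15.0)
        assert m.n_animals == 2

    def test_averaging_linearity(self, template, rng):
        a = rng.uniform(1, 5, size=template.labels.shape)
        b = rng.uniform(1, 5, size=template.labels.shape)
        mk = lambda img: SectionImage(
            channels={"CD45": img}, labels=template.labels.copy(),
            label_table=template.label_table,
            px_size_um=template.px_size_um, section_position_um=300.0,
            animal="a", time_h=24.0, genotype="wildtype",
        )
        m_ab = average_intensity_map([mk(2 * a + 3 * b)], "CD45", template,
                                     normalize=False, register=False)
        m_a = average_intensity_map([mk(a)], "CD45", template,
                                    normalize=False, register=False)
        m_b = average_intensity_map([mk(b)], "CD45", template,
                                    normalize=False, register=False)
        np.testing.assert_allclose(
            m_ab.image, 2 * m_a.image + 3 * m_b.image, atol=1e-9
        )

    def test_normalization_divides_by_contralateral_median(self, template):
        sec = _flat_section(template, 8.0)
        m = average_intensity_map([sec], "CD45", template,
                                  normalize=True, register=False)
        np.testing.assert_allclose(m.image[m.coverage > 0], 1.0)


class TestLeakage:
    def _background(self, shape, rng, mean=10.0, sd=2.0):
        return rng.normal(mean, sd, size=shape)

    def test_uniform_image_zero_area(self, rng):
        img = self._background((100, 100), rng)
        bg = np.zeros((100, 100), dtype=bool)
        bg[:20, :20] = True
        area, inten = quantify_leakage(img, (50, 50), bg, px_size_um=20.0)
        assert area == 0.0
        assert np.isnan(inten)

    def test_disc_area_and_intensity_analytic(self, rng):
        """Disc of radius 25 px at plateau 100 over N(10,2) background:
        recovered area within 5% of pi r^2, intensity ~ 100."""
        img = self._background((200, 200), rng)
        yy, xx = np.mgrid[0:200, 0:200]
        disc = (yy - 100) ** 2 + (xx - 100) ** 2 <= 25 ** 2
        img[disc] = 100.0
        bg = np.zeros_like(disc)
        bg[:40, :40] = True
        area, inten = quantify_leakage(img, (100, 100), bg, px_size_um=20.0,
                                       k_sigma=3.0)
        expected = np.pi * 25 ** 2 * (20.0 / 1000) ** 2
        assert area == pytest.approx(expected, rel=0.05)
        assert inten == pytest.approx(100.0, rel=0.02)

    def test_only_component_near_site_counted(self, rng):
        img = self._background((200, 200), rng)
        yy, xx = np.mgrid[0:200, 0:200]
        near = (yy - 100) ** 2 + (xx - 100) ** 2 <= 8 ** 2
        far = (yy - 30) ** 2 + (xx - 170) ** 2 <= 20 ** 2
        img[near | far] = 100.0
        bg = np.zeros_like(near)
        bg[:40, :40] = True
        area, _ = quantify_leakage(img, (100, 100), bg, px_size_um=20.0,
                                   site_radius_um=200.0)
        assert area == pytest.approx(near.sum() * (20.0 / 1000) ** 2,
                                     rel=0.1)

    def test_area_monotone_nonincreasing_in_k_sigma(self, rng):
        img = self._background((150, 150), rng)
        yy, xx = np.mgrid[0:150, 0:150]
        blob = (yy - 75) ** 2 + (xx - 75) ** 2 <= 20 ** 2
        img[blob] += np.linspace(5, 60, blob.sum())
        bg = np.zeros_like(blob)
        bg[:30, :30] = True
        areas = [
            quantify_leakage(img, (75, 75), bg, px_size_um=20.0,
                             k_sigma=k)[0]
            for k in (1.0, 2.0, 3.0, 4.0, 5.0)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestCompartmentMeans:
    def test_constant_image_every_compartment_equal(self, template):
        sec = _flat_section(template, 5.0)
        out = compartment_mean_intensity(
            sec, "CD45", ["CP_ipsi", "CP_contra", "CP_third",
                          "perilesional_STR", "hemisphere_ipsi"],
            normalize=False,
        )
        for v in out.values():
            assert v == pytest.approx(5.0)

    def test_checkerboard_mean_is_half(self, template):
        img = np.zeros(template.labels.shape)
        img[::2, :] = 100.0
        sec = _flat_section(template, 0.0)
        sec.channels["CD45"] = img
        out = compartment_mean_intensity(sec, "CD45", ["hemisphere_contra"],
                                         normalize=False)
        assert out["hemisphere_contra"] == pytest.approx(50.0, abs=1.0)

    def test_empty_compartment_is_nan(self, template):
        sec = _flat_section(template, 5.0)
        sec.labels = np.where(
            compartment_mask(sec.labels, sec.label_table, "lesion"),
            0, sec.labels,
        ).astype(np.uint16)
        out = compartment_mean_intensity(sec, "CD45", ["lesion"],
                                         normalize=False)
        assert np.isnan(out["lesion"])

    def test_dextran_cp_ordering_at_2h(self, histology_cfg):
        """Planted 2 h dextran: CP_ipsi > CP_third > CP_contra."""
        from ichmap.pipeline import (
            _iter_standard_sections,
            _section_measurements,
        )
        from ichmap.synthetic import CohortDesign

        design = CohortDesign(time_points_h=(2.0,),
                              animals_per_timepoint=1, seed=5)
        rows = []
        for sec in _iter_standard_sections(design, ["dextran70"],
                                           histology_cfg):
            rows.extend(_section_measurements(sec, ["dextran70"],
                                              histology_cfg))
        df = pd.DataFrame(rows).mean(numeric_only=True)
        assert (df["mean_CP_ipsi"] > df["mean_CP_third"]
                > df["mean_CP_contra"])
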