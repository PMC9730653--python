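"""Generator contracts: layout invariants, planted folds, determinism,
and fixture round-trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ichmap.datatypes import GeneSetCatalog
from ichmap.io import read_gmt, read_spatial_bundle, write_gmt
from ichmap.synthetic import (
    CohortDesign,
    TemporalProgram,
    build_layout,
    default_baseline,
    default_gene_sets,
    default_programs,
    default_spot_design,
    generate_section_cohort,
    generate_spot_cohort,
    spot_grid,
    write_fixture_bundle,
)
from ichmap.synthetic.layout import REGIONS
from ichmap.synthetic.programs import ERYTHROCYTE_GENES


@pytest.fixture(scope="module")
def layout():
    return build_layout(140, 20.0)


class TestLayout:
    def test_masks_disjoint_and_inside_outline(self, layout):
        total = np.zeros(layout.shape, dtype=int)
        for name in REGIONS:
            total += layout.region_masks[name]
        assert total.max() == 1
        assert not (total.astype(bool) & ~layout.outline).any()

    def test_lesion_inside_ipsilateral_striatum(self, layout):
        lesion = layout.region_masks["lesion"]
        assert lesion.any()
        # ipsilateral = high column index
        _, cols = np.nonzero(lesion)
        assert cols.min() > layout.width_px / 2

    def test_every_region_nonempty(self, layout):
        for name in REGIONS:
            assert layout.region_masks[name].any(), name

    def test_validate_rejects_overlap(self, layout):
        bad = {k: v.copy() for k, v in layout.region_masks.items()}
        bad["TH"] = bad["TH"] | bad["STR"]
        broken = build_layout(140, 20.0)
        broken.region_masks = bad
        with pytest.raises(ValueError, match="overlap"):
            broken.validate()


class TestTemporalProgram:
    def test_fold_is_one_at_control_and_peaks_at_peak(self):
        prog = TemporalProgram("p", ["g"], ("CP",), peak_time_h=12.0,
                               amplitude=6.0)
        assert prog.fold(None) == 1.0
        times = [2.0, 12.0, 24.0, 48.0, 96.0]
        folds = [prog.fold(t) for t in times]
        assert folds[times.index(12.0)] == pytest.approx(6.0)
        assert np.argmax(folds) == times.index(12.0)

    def test_biphasic_has_two_humps(self):
        prog = TemporalProgram("p", ["g"], ("CP",), peak_time_h=24.0,
                               amplitude=4.0, width_log=0.4,
                               second_peak_time_h=96.0, second_amplitude=5.0)
        f = [prog.fold(t) for t in [2.0, 12.0, 24.0, 48.0, 96.0]]
        assert f[2] > f[1] and f[2] > f[3]  # 24 h bump
        assert f[4] > f[3]  # rising again toward 96 h

    def test_amplitude_below_one_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            TemporalProgram("p", ["g"], ("CP",), peak_time_h=12.0,
                            amplitude=0.5)

    def test_off_grid_peak_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            TemporalProgram("p", ["g"], ("CP",), peak_time_h=17.0,
                            amplitude=2.0)


class TestSpotCohort:
    def test_deterministic_given_seed(self, layout):
        design = CohortDesign(time_points_h=(None, 12.0), seed=5)
        a = generate_spot_cohort(layout, design, default_programs(),
                                 default_baseline())
        b = generate_spot_cohort(layout, design, default_programs(),
                                 default_baseline())
        for sa, sb in zip(a.samples, b.samples):
            np.testing.assert_array_equal(sa.counts, sb.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_planted_fold_recovered_in_mean_ratio(self, layout):
        """One STR program of amplitude 4 at its peak shifts the mean
        count of its gene by a factor of ~4 against control."""
        prog = TemporalProgram("solo", ["Hk0010"], ("STR", "lesion"),
                               peak_time_h=96.0, amplitude=4.0)
        design = CohortDesign(time_points_h=(None, 96.0), seed=11)
        cohort = generate_spot_cohort(layout, design, [prog],
                                      default_baseline())
        gi = cohort.samples[0].genes.index("Hk0010")
        means = {}
        for ds in cohort.samples:
            in_str = cohort.truth[
                (cohort.truth.sample_id == ds.meta["sample_id"])
                & (cohort.truth.region5 == "STR")
            ].index
            rows = cohort.truth.loc[in_str, "barcode"]
            sel = [ds.barcodes.index(b) for b in rows]
            means[ds.meta["time_h"]] = ds.counts[sel, gi].mean()
        ratio = means[96.0] / means[None]
        # NB sampling error at ~500 spots per group
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_no_program_means_no_temporal_signal(self, layout):
        """With all amplitudes at 1 the per-gene two-sample test is
        non-significant for at least 99% of genes at alpha = 0.01."""
        design = CohortDesign(time_points_h=(None, 24.0), seed=13)
        cohort = generate_spot_cohort(layout, design, [], default_baseline())
        a, b = cohort.samples
        # lesion spots are relabeled STR in the control, so drop them to
        # compare identically distributed populations
        keep = (cohort.truth[cohort.truth.sample_id
                             == b.meta["sample_id"]]["region"]
                != "lesion").to_numpy()
        _, p = stats.mannwhitneyu(a.counts[keep], b.counts[keep], axis=0)
        assert (p < 0.01).mean() <= 0.01

    def test_erythrocyte_score_peaks_at_2h(self, spot_cohort):
        """Hemoglobin/Alas2 mean counts in blood-exposed regions are
        maximal at the 2 h time point."""
        truth = spot_cohort.truth
        gi = [spot_cohort.samples[0].genes.index(g)
              for g in ERYTHROCYTE_GENES]
        by_time = {}
        for ds in spot_cohort.samples:
            t = ds.meta["time_h"]
            sel = truth[(truth.sample_id == ds.meta["sample_id"])
                        & truth.region5.isin(["CP", "STR"])]
            idx = [ds.barcodes.index(b) for b in sel["barcode"]]
            by_time[t] = ds.counts[np.ix_(idx, gi)].mean()
        assert max(by_time, key=by_time.get) == 2.0

    def test_knockout_suppresses_cp_programs_only(self, layout):
        design = CohortDesign(time_points_h=(12.0,), genotypes=("TLR4ko",),
                              seed=3)
        cohort = generate_spot_cohort(layout, design, default_programs(),
                                      default_baseline())
        tr = cohort.truth
        cp_folds = tr.loc[tr.region == "CP", "fold_cp_inflammatory_wave"]
        str_folds = tr.loc[tr.region == "STR", "fold_erythrocyte_pulse"]
        assert (cp_folds == 1.0).all()
        assert (str_folds > 1.0).all()

    def test_spot_grid_has_positions_and_truth(self, layout):
        grid = spot_grid(layout)
        assert {"array_row", "array_col", "pxl_row_in_fullres",
                "pxl_col_in_fullres", "region"} <= set(grid.columns)
        assert (~grid.region.str.startswith("ventricle")).all()


class TestSectionCohort:
    def test_unknown_channel_rejected(self):
        design = CohortDesign(time_points_h=(24.0,), seed=0)
        with pytest.raises(ValueError, match="unknown channel"):
            list(generate_section_cohort(design, ["nope"], size_px=64))

    def test_sham_icam1_is_background(self):
        design = CohortDesign(time_points_h=(24.0,), genotypes=("sham",),
                              seed=4)
        secs = list(generate_section_cohort(design, ["ICAM1"], size_px=128,
                                            px_size_um=80.0, n_stack=1,
                                            jitter=False))
        sec = secs[0]
        from ichmap.histology import compartment_mask

        cp = compartment_mask(sec.labels, sec.label_table, "CP")
        tissue = (sec.labels > 0) & ~cp
        img = sec.channels["ICAM1"]
        # CP mean within a few noise SDs of the general tissue mean
        assert abs(img[cp].mean() - img[tissue].mean()) < 60.0

    def test_wildtype_dextran_area_maximal_at_48h(self):
        from ichmap.synthetic import leakage_area_factor

        factors = {t: leakage_area_factor(t) for t in (24.0, 48.0, 96.0)}
        assert max(factors, key=factors.get) == 48.0

    def test_jitter_displaces_mask_centroid_as_planted(self):
        """Planted similarity transform moves the outline centroid to
        exactly the analytically transformed position."""
        from ichmap.histology import SimilarityTransform
        from ichmap.synthetic import template_section

        template = template_section(128, 80.0)
        center = (63.5, 63.5)
        tf = SimilarityTransform.from_params(10.0, 1.0, (5.0, -3.0), center)
        warped = tf.warp(template.labels.astype(float), order=0,
                         fill=0.0).astype(np.uint16)
        ys, xs = np.nonzero(template.labels > 0)
        c0 = np.array([[ys.mean(), xs.mean()]])
        expect = tf.apply(c0)[0]
        ys, xs = np.nonzero(warped > 0)
        got = np.array([ys.mean(), xs.mean()])
        assert np.hypot(*(got - expect)) < 0.5  # mask discretization

    def test_deterministic_given_seed(self):
        design = CohortDesign(time_points_h=(12.0,), seed=9)
        a = list(generate_section_cohort(design, ["CD45"], size_px=96,
                                         px_size_um=100.0, n_stack=2))
        b = list(generate_section_cohort(design, ["CD45"], size_px=96,
                                         px_size_um=100.0, n_stack=2))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.channels["CD45"],
                                          sb.channels["CD45"])
            np.testing.assert_array_equal(sa.labels, sb.labels)


class TestFixtureBundle:
    def test_counts_round_trip_bit_exact(self, tmp_path, layout):
        design = CohortDesign(time_points_h=(None, 2.0), seed=21)
        cohort = generate_spot_cohort(layout, design, default_programs(),
                                      default_baseline())
        out = write_fixture_bundle(cohort, default_gene_sets(),
                                   tmp_path / "bundle")
        for ds in cohort.samples:
            back = read_spatial_bundle(out / ds.meta["sample_id"])
            np.testing.assert_array_equal(back.counts, ds.counts)
            assert back.genes == ds.genes
            assert back.barcodes == ds.barcodes

    def test_mtx_header_has_genes_by_spots(self, tmp_path, layout):
        design = CohortDesign(time_points_h=(None,), seed=22)
        cohort = generate_spot_cohort(layout, design, [], default_baseline())
        out = write_fixture_bundle(cohort, default_gene_sets(),
                                   tmp_path / "bundle")
        sid = cohort.samples[0].meta["sample_id"]
        header = None
        with open(out / sid / "matrix.mtx") as fh:
            for line in fh:
                if not line.startswith("%"):
                    header = line.split()
                    break
        n_genes, n_spots = int(header[0]), int(header[1])
        assert (n_genes, n_spots) == (cohort.samples[0].n_genes,
                                      cohort.samples[0].n_spots)

    def test_refuses_nonempty_outdir_without_force(self, tmp_path, layout):
        design = CohortDesign(time_points_h=(None,), seed=23)
        cohort = generate_spot_cohort(layout, design, [], default_baseline())
        out = tmp_path / "bundle"
        out.mkdir()
        (out / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_fixture_bundle(cohort, default_gene_sets(), out)
        write_fixture_bundle(cohort, default_gene_sets(), out, force=True)

    def test_gmt_round_trip_preserves_member_order(self, tmp_path):
        cat = GeneSetCatalog(
            sets={"CP_markers": ["Ttr", "Folr1", "Clic6"]},
            universe=["Ttr", "Folr1", "Clic6", "Other"],
        )
        path = tmp_path / "sets.gmt"
        write_gmt(cat, path)
        back = read_gmt(path)
        assert back.sets["CP_markers"] == ["Ttr", "Folr1", "Clic6"]
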