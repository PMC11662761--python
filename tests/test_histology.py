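import numpy as np
import pytest

from eaequant.histology import (
    AxonRecord,
    ImageWithMasks,
    eyfp_percent_transection,
    eyfp_standardized_ratio,
    gratio_records,
    nr_percent_wm_loss,
    remyelination_summary,
)
from eaequant.synthetic import AxonSimParams, EyfpSimParams, gen_axon_field, gen_eyfp_image


def _image(gm_level, wm_level, shape=(40, 60)):
    img = np.zeros(shape)
    gm = np.zeros(shape, dtype=bool)
    wm = np.zeros(shape, dtype=bool)
    gm[:, :20] = True
    wm[:, 30:] = True
    img[gm] = gm_level
    img[wm] = wm_level
    return ImageWithMasks(
        intensity=img, wm_mask=wm, gm_mask=gm, healthy_wm_mask=wm.copy(), name="t"
    )


class TestEyfpRatio:
    def test_equal_means_give_unit_ratio(self):
        assert eyfp_standardized_ratio([_image(50.0, 50.0)]) == pytest.approx(1.0)

    def test_cohort_mean_of_per_image_ratios(self):
        imgs = [_image(100.0, 120.0), _image(100.0, 140.0)]
        assert eyfp_standardized_ratio(imgs) == pytest.approx(1.3)

    def test_seeded_cohort_recovers_construction_ratio(self):
        imgs = [
            gen_eyfp_image(EyfpSimParams(seed=s, noise_sd_frac=0.05))[0]
            for s in range(8)
        ]
        assert eyfp_standardized_ratio(imgs) == pytest.approx(1.25, abs=0.02)

    def test_empty_mask_is_fatal(self):
        img = _image(50.0, 60.0)
        img.healthy_wm_mask[:] = False
        with pytest.raises(ValueError, match="healthy_wm_mask"):
            eyfp_standardized_ratio([img])


class TestEyfpPercent:
    def test_uniform_healthy_wm_is_zero_percent(self):
        img = _image(100.0, 100.0)
        res = eyfp_percent_transection(img, ratio=1.0, factor=1.5)
        assert res.percent_transection == 0.0

    def test_constructed_fraction_recovered_exactly(self):
        img, true_pct = gen_eyfp_image(
            EyfpSimParams(puncta_fraction=0.10, noise_sd_frac=0.0, seed=2)
        )
        ratio = eyfp_standardized_ratio([img])
        res = eyfp_percent_transection(img, ratio)
        assert res.percent_transection == pytest.approx(true_pct, abs=1e-12)

    def test_global_intensity_scaling_invariance(self):
        img, _ = gen_eyfp_image(EyfpSimParams(puncta_fraction=0.07, seed=3))
        scaled = ImageWithMasks(
            intensity=img.intensity * 3.0, wm_mask=img.wm_mask, gm_mask=img.gm_mask,
            healthy_wm_mask=img.healthy_wm_mask, name="x3",
        )
        r1 = eyfp_standardized_ratio([img])
        r2 = eyfp_standardized_ratio([scaled])
        p1 = eyfp_percent_transection(img, r1).percent_transection
        p2 = eyfp_percent_transection(scaled, r2).percent_transection
        assert p1 == pytest.approx(p2, abs=1e-9)


class TestNrWmLoss:
    def _rgb(self, shape=(30, 30)):
        rgb = np.zeros(shape + (3,))
        rgb[..., 2] = 200.0  # EC blue everywhere
        wm = np.ones(shape, dtype=bool)
        return rgb, wm

    def test_blue_white_matter_is_zero(self):
        rgb, wm = self._rgb()
        assert nr_percent_wm_loss(rgb, wm) == 0.0

    def test_quarter_lesion_is_25_percent(self):
        rgb, wm = self._rgb((20, 20))
        rgb[:10, :10, 0] = 255.0
        rgb[:10, :10, 2] = 50.0
        assert nr_percent_wm_loss(rgb, wm) == pytest.approx(25.0)

    def test_fully_red_is_100_percent(self):
        rgb, wm = self._rgb()
        rgb[..., 0] = 255.0
        rgb[..., 2] = 50.0
        assert nr_percent_wm_loss(rgb, wm) == pytest.approx(100.0)

    def test_grayscale_image_is_fatal(self):
        with pytest.raises(ValueError):
            nr_percent_wm_loss(np.zeros((10, 10)), np.ones((10, 10), dtype=bool))


def _disk_annulus(r_in, r_out, size=None):
    size = size or int(2 * r_out + 10)
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    axon = (d2 <= r_in**2).astype(np.uint16)
    myelin = ((d2 <= r_out**2) & (d2 > r_in**2)).astype(np.uint16)
    return axon, myelin


class TestGratio:
    def test_concentric_disks_match_radius_ratio(self):
        axon, myelin = _disk_annulus(40, 50)
        (rec,) = gratio_records(axon, myelin, pixel_size_um=0.01)
        assert rec.g == pytest.approx(0.8, abs=0.01)

    def test_unmyelinated_axon_has_unit_g(self):
        axon, _ = _disk_annulus(20, 25)
        (rec,) = gratio_records(axon, np.zeros_like(axon), pixel_size_um=0.01)
        assert rec.g == 1.0
        assert not rec.myelinated

    def test_matches_pixel_count_oracle_on_seeded_annuli(self):
        """Area-equivalent g from the pipeline equals a naive per-pixel count."""
        n_checked = 0
        for seed in range(2):
            axon, myelin, truth, _ = gen_axon_field(
                AxonSimParams(seed=seed, n_axons=25)
            )
            recs = {r.label: r for r in gratio_records(axon, myelin, 0.02)}
            for lab in truth["label"]:
                n_ax = int(np.count_nonzero(axon == lab))
                n_my = int(np.count_nonzero(myelin == lab))
                g_oracle = np.sqrt(n_ax / (n_ax + n_my))
                assert recs[lab].g == pytest.approx(g_oracle, abs=1e-12)
                n_checked += 1
        assert n_checked >= 50

    @pytest.mark.parametrize("r", [10, 20, 40, 80])
    def test_disk_discretization_error_shrinks(self, r):
        R = int(round(r / 0.8))
        axon, myelin = _disk_annulus(r, R)
        (rec,) = gratio_records(axon, myelin, pixel_size_um=0.01)
        assert abs(rec.g - r / R) < 2.0 / r

    def test_border_touching_axons_excluded(self):
        axon, myelin = _disk_annulus(20, 25, size=48)  # annulus clips the border
        assert gratio_records(axon, myelin, 0.01) == []

    def test_orphan_myelin_warns_and_is_skipped(self):
        axon, myelin = _disk_annulus(20, 25)
        myelin[myelin > 0] = 7  # label with no matching axon
        with pytest.warns(UserWarning, match="no matching axon"):
            recs = gratio_records(axon, myelin, 0.01)
        assert [r.label for r in recs] == [1]

    def test_shape_mismatch_fatal(self):
        with pytest.raises(ValueError):
            gratio_records(np.zeros((5, 5)), np.zeros((6, 6)), 0.01)


def _record(g, myelinated=True, label=1):
    my = 0.0 if g == 1.0 else (1.0 / g**2 - 1.0)
    return AxonRecord(
        label=label, axon_area_um2=1.0, myelin_area_um2=my, g=g,
        myelinated=myelinated, remyelinating=myelinated and g > 0.8,
    )


class TestRemyelinationSummary:
    def test_counting_above_cutoff(self):
        recs = [_record(g, label=i) for i, g in enumerate((0.75, 0.85, 0.90), 1)]
        s = remyelination_summary(recs, field_area_um2=100.0)
        assert s.n_remyelinating == 2
        assert s.percent_remyelinating == pytest.approx(66.67, abs=0.01)

    def test_exactly_at_cutoff_not_remyelinating(self):
        s = remyelination_summary([_record(0.8)], field_area_um2=10.0)
        assert s.n_remyelinating == 0

    def test_density(self):
        recs = [_record(0.9, label=i) for i in range(1, 5)]
        recs += [_record(0.7, label=i) for i in range(5, 11)]
        s = remyelination_summary(recs, field_area_um2=100.0)
        assert s.n_axons == 10
        assert s.density_remyelinating == pytest.approx(0.04)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        recs = [_record(g, label=i) for i, g in enumerate(rng.uniform(0.6, 0.95, 30), 1)]
        s1 = remyelination_summary(recs, 50.0)
        rng.shuffle(recs)
        s2 = remyelination_summary(recs, 50.0)
        assert (s1.n_remyelinating, s1.percent_remyelinating) == (
            s2.n_remyelinating, s2.percent_remyelinating
        )

    def test_empty_records_warn(self):
        with pytest.warns(UserWarning):
            s = remyelination_summary([], 10.0)
        assert s.n_axons == 0
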