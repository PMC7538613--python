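"""Noise estimation, SNR thresholding, patency scoring and MIP measurements."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pcoma as pc


class TestEstimateNoise:
    def test_rayleigh_background_recovers_channel_sigma(self, rayleigh_volume):
        """SD(Rayleigh)/0.6551 recovers the Gaussian channel sigma within 2%."""
        full = pc.RoiMask(np.ones(rayleigh_volume.shape, bool))
        assert rayleigh_volume.intensities.size >= 10**5
        assert pc.estimate_noise(rayleigh_volume, full) == pytest.approx(1.0, rel=0.02)

    def test_sigma_scales_homogeneously(self, rayleigh_volume):
        full = pc.RoiMask(np.ones(rayleigh_volume.shape, bool))
        base = pc.estimate_noise(rayleigh_volume, full)
        scaled = pc.estimate_noise(rayleigh_volume.scaled(3.5), full)
        assert scaled == pytest.approx(3.5 * base, rel=1e-12)

    def test_constant_background_rejected(self):
        volume = pc.AngioVolume(np.ones((8, 8, 8)))
        with pytest.raises(ValueError, match="zero variance"):
            pc.estimate_noise(volume, pc.RoiMask(np.ones((8, 8, 8), bool)))

    def test_empty_mask_rejected(self, rayleigh_volume):
        with pytest.raises(ValueError, match="empty"):
            pc.estimate_noise(rayleigh_volume, pc.RoiMask(np.zeros(rayleigh_volume.shape, bool)))

    def test_corner_fallback_is_unbiased_on_pure_noise(self, rayleigh_volume):
        assert pc.estimate_noise(rayleigh_volume) == pytest.approx(1.0, rel=0.05)


class TestSnrMap:
    def test_definitional_values(self):
        volume = pc.AngioVolume(np.full((4, 4, 4), 40.0))
        assert pc.snr_map(volume, 4.0).values[0, 0, 0] == pytest.approx(10.0)
        assert pc.snr_map(volume, 40.0).values[0, 0, 0] == pytest.approx(1.0)

    def test_scale_invariance(self, rayleigh_volume):
        a = pc.snr_map(rayleigh_volume, 1.3)
        b = pc.snr_map(rayleigh_volume.scaled(7.0), 1.3 * 7.0)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_nonpositive_sigma_rejected(self, rayleigh_volume):
        with pytest.raises(ValueError, match="sigma"):
            pc.snr_map(rayleigh_volume, 0.0)


class TestThresholdMap:
    def test_cutoff_is_fraction_of_dataset_max(self):
        values = np.linspace(0, 40, 64).reshape(4, 4, 4)
        out = pc.threshold_map(pc.SnrMap(values, sigma=1.0), 0.1)
        assert out.threshold == pytest.approx(4.0)
        assert np.isnan(out.values[values < 4.0]).all()
        assert np.isfinite(out.values[values >= 4.0]).all()

    def test_uniform_map_retains_all_voxels(self):
        out = pc.threshold_map(pc.SnrMap(np.full((3, 3, 3), 5.0), sigma=1.0), 0.1)
        assert np.isfinite(out.values).all()

    def test_idempotent_on_random_grids(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            snr = pc.SnrMap(rng.random((8, 8, 8)) * 30, sigma=1.0)
            once = pc.threshold_map(snr, 0.1)
            twice = pc.threshold_map(once, 0.1)
            np.testing.assert_array_equal(once.values, twice.values)
            assert once.threshold == pytest.approx(twice.threshold)

    def test_fraction_out_of_range_rejected(self):
        snr = pc.SnrMap(np.ones((2, 2, 2)), sigma=1.0)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="fraction"):
                pc.threshold_map(snr, bad)


class TestPcomaScore:
    @staticmethod
    def _score_phantom(volume, side="left", fraction=0.1):
        sigma = pc.estimate_noise(volume)
        thresholded = pc.threshold_map(pc.snr_map(volume, sigma), fraction)
        return pc.pcoma_score(thresholded, pc.pcoma_corridor(side=side), pc.pcoma_slab())

    def test_all_subthreshold_roi_scores_zero_with_flag(self):
        values = np.full((8, 8, 12), 1.0)
        values[0, 0, 0] = 100.0  # bright voxel far from the ROI drives the cutoff
        thresholded = pc.threshold_map(pc.SnrMap(values, sigma=1.0), 0.5)
        roi = np.zeros((8, 8, 12), bool)
        roi[4:6, 4:6, 2:8] = True
        result = pc.pcoma_score(thresholded, pc.RoiMask(roi), pc.SliceSlab(2, 7))
        assert result.score == 0.0
        assert result.no_signal

    def test_empty_roi_slab_intersection_is_an_error(self):
        snr = pc.SnrMap(np.ones((8, 8, 12)), sigma=1.0)
        roi = np.zeros((8, 8, 12), bool)
        roi[:, :, 0] = True  # ROI only on slice 0, slab starts at 2
        with pytest.raises(ValueError, match="intersect"):
            pc.pcoma_score(snr, pc.RoiMask(roi), pc.SliceSlab(2, 7))

    def test_planted_intensity_recovered_within_ten_percent(self, phantom_batch):
        """Mean recovered score over 5 phantoms within ±10% of the planted SNR 12."""
        scores = [float(self._score_phantom(volume).score) for _, volume, _ in phantom_batch]
        assert np.mean(scores) == pytest.approx(12.0, rel=0.10)

    def test_score_monotone_in_planted_intensity(self):
        """Score is nondecreasing over a grid of 5 planted intensities x 3 seeds."""
        for seed in range(3):
            scores = []
            for snr in (0.0, 3.0, 6.0, 9.0, 12.0):
                config = pc.willis_phantom_config(seed=seed, pcoma_snr=(snr, snr))
                volume, _ = pc.make_angiophantom(config)
                scores.append(float(self._score_phantom(volume).score))
            assert all(b >= a - 0.5 for a, b in zip(scores, scores[1:]))

    def test_enlarging_roi_never_decreases_score(self):
        rng = np.random.default_rng(5)
        values = pc.SnrMap(rng.random((10, 10, 12)) * 20, sigma=1.0)
        small = np.zeros((10, 10, 12), bool)
        small[3:5, 3:5, 2:10] = True
        large = small.copy()
        large[2:8, 2:8, 2:10] = True
        slab = pc.SliceSlab(2, 9)
        assert (
            pc.pcoma_score(values, pc.RoiMask(large), slab).score
            >= pc.pcoma_score(values, pc.RoiMask(small), slab).score
        )

    def test_end_to_end_score_scale_invariant(self, default_phantom):
        """Rescaling all intensities by c > 0 leaves the score unchanged."""
        _, volume, _ = default_phantom
        base = self._score_phantom(volume)
        for c in (0.01, 3.7, 250.0):
            scaled = self._score_phantom(volume.scaled(c))
            assert scaled.score == pytest.approx(base.score, rel=1e-9)

    def test_thresholding_preserves_nonzero_scores(self, default_phantom):
        """score(thresholded) == score(raw) whenever the raw score clears the cutoff."""
        _, volume, _ = default_phantom
        sigma = pc.estimate_noise(volume)
        raw = pc.snr_map(volume, sigma)
        thresholded = pc.threshold_map(raw, 0.1)
        roi, slab = pc.pcoma_corridor(side="left"), pc.pcoma_slab()
        raw_score = pc.pcoma_score(raw, roi, slab).score
        assert raw_score >= thresholded.threshold
        assert pc.pcoma_score(thresholded, roi, slab).score == pytest.approx(raw_score)


class TestMip:
    def test_constant_volume_projects_constant(self):
        image = pc.mip(pc.AngioVolume(np.full((5, 6, 7), 2.5)))
        assert image.shape == (5, 6)
        assert (image == 2.5).all()

    def test_single_bright_voxel_projects_to_one_pixel(self):
        data = np.zeros((5, 6, 7))
        data[2, 3, 4] = 9.0
        image = pc.mip(pc.AngioVolume(data), axis=2)
        assert image[2, 3] == 9.0
        assert (image > 0).sum() == 1

    def test_phantom_vessels_visible_on_projection(self, default_phantom):
        """Every planted vessel's projected footprint rises above background."""
        _, volume, truth = default_phantom
        image = pc.mip(volume, axis=2)
        background = np.median(image)
        for name, vessel in truth.vessels.items():
            footprint = vessel.mask.any(axis=2)
            assert image[footprint].max() > 3 * background, name


class TestVesselDiameter:
    def test_box_profile_fwhm_equals_width(self):
        image = np.zeros((40, 40))
        image[:, 17:22] = 1.0  # 5-pixel-wide band
        width = pc.vessel_diameter(image, point=(20, 19.5), direction=(0, 1), pixel_size=0.1)
        assert width == pytest.approx(0.5, abs=1e-6)

    def test_phantom_cylinder_diameter_recovered(self):
        """FWHM of a 0.20 mm cylinder on the MIP is within ±1 pixel of truth."""
        vessel = pc.VesselSpec("v", np.array([[1.0, 4.0, 2.0], [7.0, 4.0, 2.0]]), 0.20, 400.0)
        config = pc.PhantomConfig(grid_shape=(80, 80, 40), vessels=(vessel,),
                                  noise_sigma=2.0, seed=2)
        volume, _ = pc.make_angiophantom(config)
        image = pc.mip(volume, axis=2)
        width = pc.vessel_diameter(image, point=(40, 40), direction=(0, 1), pixel_size=0.1)
        assert width == pytest.approx(0.20, abs=0.1)

    def test_pure_noise_profile_raises_no_vessel(self):
        rng = np.random.default_rng(8)
        image = np.hypot(rng.normal(0, 1, (40, 40)), rng.normal(0, 1, (40, 40)))
        with pytest.raises(pc.NoVesselError):
            pc.vessel_diameter(image, point=(20, 20), direction=(0, 1), pixel_size=0.1)

    def test_percent_of_basilar(self):
        assert pc.diameter_percent_basilar(0.12, 0.20) == pytest.approx(60.0)
        assert pc.diameter_percent_basilar(0.20, 0.20) == pytest.approx(100.0)
        assert pc.diameter_percent_basilar(0.0, 0.20) == 0.0
        with pytest.raises(ValueError, match="basilar"):
            pc.diameter_percent_basilar(0.1, 0.0)


class TestPhenotypes:
    @pytest.mark.parametrize(
        "left,right,expected",
        [(True, True, "complete"), (False, True, "unilateral"),
         (True, False, "unilateral"), (False, False, "absent")],
    )
    def test_classification(self, left, right, expected):
        assert pc.classify_phenotype(left, right) == expected

    def test_missing_side_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            pc.classify_phenotype(True, None)

    def test_cohort_percentages_match_printed_counts(self):
        """Counts 9/23/11 of 43 give 21%, 53% and 26%."""
        summary = pc.PhenotypeSummary.from_counts(complete=9, unilateral=23, absent=11)
        assert summary.n == 43
        assert summary.percentages == {"complete": 21, "unilateral": 53, "absent": 26}

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
    def test_counts_partition_cohort(self, calls):
        summary = pc.summarize_phenotypes(calls)
        assert sum(summary.counts.values()) == len(calls)
        assert sum(summary.fractions.values()) == pytest.approx(1.0)


class TestAggregateRatings:
    def test_mean_per_subject(self):
        means = pc.aggregate_ratings(np.array([[3, 0, 1], [3, 1, 1], [3, 2, 1]]))
        assert means.n_raters == 3
        np.testing.assert_allclose(means.mean_ratings.to_numpy(), [3.0, 1.0, 1.0])

    def test_single_rater_identity(self):
        means = pc.aggregate_ratings(np.array([[0, 1, 2, 3]]))
        np.testing.assert_allclose(means.mean_ratings.to_numpy(), [0, 1, 2, 3])

    def test_out_of_range_names_rater_and_subject(self):
        import pandas as pd

        frame = pd.DataFrame([[1, 2], [1, 4]], index=["anna", "ben"], columns=["m1", "m2"])
        with pytest.raises(ValueError, match="ben.*m2"):
            pc.aggregate_ratings(frame)
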