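"""Phantom generator: geometry, contrast, determinism, calibrated excesses."""

import numpy as np
import pytest

from lymphmap import phantom as ph
from lymphmap.exceptions import ContrastError, GeometryError
from lymphmap.segmentation import Tissue
from lymphmap.compartments import Compartment
from lymphmap.volume_io import upper_arm_mark

from conftest import small_arm_spec


class TestGenerateArm:
    def test_noise_free_voxels_carry_exact_tissue_means(self, noise_free_arm):
        stack, gt = noise_free_arm
        feats = stack.features().reshape(gt.labels.shape + (3,))
        for name, code in (("background", Tissue.NOISE), ("muscle", Tissue.MUSCLE),
                           ("fat", Tissue.FAT), ("fluid", Tissue.FLUID)):
            sel = gt.labels == code
            assert sel.any()
            np.testing.assert_array_equal(
                feats[sel], np.broadcast_to(ph.DEFAULT_TISSUE_MEANS[name],
                                            (sel.sum(), 3)))

    def test_deterministic_given_seed(self):
        spec = small_arm_spec(seed=5, noise_fraction=0.1)
        s1, g1 = ph.generate_arm(spec)
        s2, g2 = ph.generate_arm(spec)
        np.testing.assert_array_equal(s1.stir.data, s2.stir.data)
        np.testing.assert_array_equal(g1.labels, g2.labels)

    def test_label_counts_partition_volume(self, noise_free_arm):
        _, gt = noise_free_arm
        counts = [int((gt.labels == t).sum())
                  for t in (Tissue.NOISE, Tissue.MUSCLE, Tissue.FAT, Tissue.FLUID)]
        assert sum(counts) == gt.labels.size

    def test_true_volumes_are_voxel_counts_over_extent(self, noise_free_arm):
        _, gt = noise_free_arm
        stop = gt.analysis_stop
        lab, comp = gt.labels[:stop], gt.compartments[:stop]
        assert gt.true_volumes["fluid_epifascial"] == pytest.approx(
            0.001 * ((lab == Tissue.FLUID)
                     & (comp == Compartment.EPIFASCIAL)).sum())
        assert gt.true_volumes["total_arm"] == pytest.approx(
            0.001 * (comp != Compartment.OUTSIDE).sum())

    def test_spherical_blob_matches_brute_force_voxel_count(self):
        # independent voxel-centre enumeration of the discretized sphere,
        # intersected with the internal epifascial band
        spec = ph.PhantomSpec(
            n_slices=40, in_plane_size=64, arm_radius=24.0, muscle_radius=12.0,
            elbow_slice=22,
            fluid_pockets=[ph.FluidPocket(center_slice=20, extent_mm=10,
                                          shape="blob", angle_deg=0,
                                          layer="internal")])
        _, gt = ph.generate_arm(spec)
        c = (64 - 1) / 2.0
        mid = (24.0 + 12.0) / 2.0
        rc = 0.5 * (12.0 + mid)
        px, py, rad = c + rc, c, 5.0
        count = 0
        for z in range(40):
            for y in range(64):
                for x in range(64):
                    if (z - 20) ** 2 + (y - py) ** 2 + (x - px) ** 2 <= rad ** 2:
                        r = np.hypot(y - c, x - c)
                        if 12.0 < r <= mid:
                            count += 1
        assert int((gt.labels == Tissue.FLUID).sum()) == count

    def test_noise_free_feature_space_is_separable(self, noise_free_arm):
        stack, _ = noise_free_arm
        assert np.unique(stack.features(), axis=0).shape[0] == 4

    def test_ground_truth_tissue_compartment_consistency(self, noise_free_arm):
        _, gt = noise_free_arm
        fluid = gt.labels == Tissue.FLUID
        fat = gt.labels == Tissue.FAT
        muscle = gt.labels == Tissue.MUSCLE
        assert np.all(gt.compartments[fluid | fat] == Compartment.EPIFASCIAL)
        assert np.all(gt.compartments[muscle] == Compartment.SUBFASCIAL)

    def test_subfascial_pocket_can_be_injected(self):
        spec = small_arm_spec()
        spec.fluid_pockets = [ph.FluidPocket(center_slice=30, extent_mm=6,
                                             shape="blob", layer="subfascial")]
        _, gt = ph.generate_arm(spec)
        sub_fluid = (gt.labels == Tissue.FLUID) & (gt.compartments == Compartment.SUBFASCIAL)
        assert sub_fluid.sum() > 0
        assert gt.true_volumes["fluid_epifascial"] == 0.0

    def test_honeycomb_interleaves_fluid_with_fat(self):
        spec = small_arm_spec()
        spec.fluid_pockets = [ph.FluidPocket(center_slice=30, extent_mm=16,
                                             shape="annulus-sector", width_deg=90,
                                             honeycomb=True)]
        _, gt = ph.generate_arm(spec)
        fluid = gt.labels == Tissue.FLUID
        assert fluid.sum() > 0
        # period-2 lattice: no two fluid voxels are 6-neighbours
        for axis in range(3):
            shifted = np.roll(fluid, 1, axis=axis)
            assert not np.any(fluid & shifted)

    def test_bias_field_stays_within_amplitude(self):
        spec = small_arm_spec()
        spec.bias_amplitude = 0.2
        stack, gt = ph.generate_arm(spec)
        fat = gt.labels == Tissue.FAT
        vals = stack.fat.data[fat] / ph.DEFAULT_TISSUE_MEANS["fat"][1]
        assert vals.min() >= 0.8 - 1e-9 and vals.max() <= 1.2 + 1e-9
        assert vals.std() > 0          # the field actually varies


class TestSpecValidation:
    def test_muscle_must_fit_inside_arm(self):
        with pytest.raises(GeometryError):
            ph.PhantomSpec(n_slices=20, in_plane_size=64,
                           arm_radius=15.0, muscle_radius=16.0)

    def test_contrast_dominance_enforced(self):
        means = dict(ph.DEFAULT_TISSUE_MEANS)
        means["muscle"] = (5.0, 10.0, 25.0)     # water no longer dominant
        with pytest.raises(ContrastError):
            ph.PhantomSpec(n_slices=20, in_plane_size=64, arm_radius=15.0,
                           muscle_radius=9.0, tissue_means=means)

    def test_arm_must_leave_background_margin(self):
        with pytest.raises(GeometryError):
            ph.PhantomSpec(n_slices=20, in_plane_size=64, arm_radius=31.0,
                           muscle_radius=20.0)


class TestGeneratePair:
    def test_zero_excess_gives_identical_truths(self):
        spec = small_arm_spec(seed=2)
        (_, ga), (_, gu) = ph.generate_pair(
            spec, ph.ExcessSpec(fat_excess_ml=0, fluid_excess_ml=0))
        np.testing.assert_array_equal(ga.labels, gu.labels)
        assert ga.true_volumes == gu.true_volumes

    def test_injected_targets_hit_within_voxelization_error(self):
        spec = ph.PhantomSpec(n_slices=120, in_plane_size=96,
                              arm_radius=(24.0, 32.0), muscle_radius=(15.0, 20.0),
                              seed=4)
        (_, ga), (_, gu) = ph.generate_pair(
            spec, ph.ExcessSpec(fat_excess_ml=100.0, fluid_excess_ml=50.0,
                                fluid_span_mm=60.0))
        d_fat = ga.true_volumes["fat_epifascial"] - gu.true_volumes["fat_epifascial"]
        d_fluid = ga.true_volumes["fluid_epifascial"] - gu.true_volumes["fluid_epifascial"]
        assert d_fat == pytest.approx(100.0, abs=1.0)
        assert d_fluid == pytest.approx(50.0, abs=0.5)
        assert ga.true_volumes["muscle_subfascial"] == gu.true_volumes["muscle_subfascial"]

    def test_fat_fluid_ratio_scenario(self):
        # the headline composition scenario: fat excess 2.1x the fluid excess
        spec = ph.PhantomSpec(n_slices=120, in_plane_size=96,
                              arm_radius=(24.0, 32.0), muscle_radius=(15.0, 20.0),
                              seed=6)
        (_, ga), (_, gu) = ph.generate_pair(
            spec, ph.ExcessSpec(fat_excess_ml=105.0, fluid_excess_ml=50.0,
                                fluid_span_mm=60.0))
        d_fat = ga.true_volumes["fat_epifascial"] - gu.true_volumes["fat_epifascial"]
        d_fluid = ga.true_volumes["fluid_epifascial"] - gu.true_volumes["fluid_epifascial"]
        assert d_fat / d_fluid == pytest.approx(2.1, rel=0.02)

    def test_muscle_excess_injection(self):
        spec = small_arm_spec(seed=8)
        (_, ga), (_, gu) = ph.generate_pair(
            spec, ph.ExcessSpec(fat_excess_ml=4.0, fluid_excess_ml=2.0,
                                muscle_excess_ml=2.0, fluid_span_mm=30.0))
        d_mus = ga.true_volumes["muscle_subfascial"] - gu.true_volumes["muscle_subfascial"]
        assert d_mus == pytest.approx(2.0, abs=0.1)

    def test_capacity_violation_raises(self):
        spec = small_arm_spec()
        with pytest.raises(GeometryError):
            ph.generate_pair(spec, ph.ExcessSpec(fat_excess_ml=5000.0,
                                                 fluid_excess_ml=0.0))

    def test_elbow_aligned_landmarks_shared(self):
        spec = small_arm_spec(seed=1)
        (_, ga), (_, gu) = ph.generate_pair(spec, ph.ExcessSpec(4.0, 2.0))
        assert ga.landmarks == gu.landmarks
        assert ga.analysis_stop == upper_arm_mark(ga.landmarks) + 1


class TestGenerateCohort:
    LIGHT = ph.CohortParams(n_slices=40, in_plane_size=96,
                            shoulder_radius_mean=28.0, shoulder_radius_sd=1.5,
                            fat_excess_mean=15.0, fat_excess_sd=5.0,
                            fluid_noise_sd=2.1, fat_floor_ml=3.0,
                            fluid_floor_ml=0.5, fluid_span_mm=999.0)

    def test_truth_pearson_positive_in_most_seeds(self):
        positive = 0
        for seed in range(100):
            _, df = ph.generate_cohort(13, self.LIGHT, seed=seed)
            r = np.corrcoef(df.fat_excess_ml, df.fluid_excess_ml)[0, 1]
            positive += r > 0
        assert positive >= 95

    def test_reproducible_given_seed(self):
        _, df1 = ph.generate_cohort(5, self.LIGHT, seed=3)
        _, df2 = ph.generate_cohort(5, self.LIGHT, seed=3)
        assert df1.equals(df2)

    def test_degenerate_variance_rejected(self):
        params = ph.CohortParams(fat_excess_sd=0.0)
        with pytest.raises(GeometryError):
            ph.generate_cohort(5, params, seed=0)

    def test_minimum_cohort_size(self):
        with pytest.raises(Exception):
            ph.generate_cohort(1, self.LIGHT, seed=0)

    def test_materialized_pair_matches_truth_table(self):
        subs, df = ph.generate_cohort(2, self.LIGHT, seed=7, materialize=True)
        (_, ga), (_, gu) = subs[0]["pair"]
        d_fat = ga.true_volumes["fat_epifascial"] - gu.true_volumes["fat_epifascial"]
        assert d_fat == pytest.approx(df.fat_excess_ml.iloc[0], abs=1e-9)
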