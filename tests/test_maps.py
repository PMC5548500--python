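"""Longitudinal profiles, elbow alignment, segment maps, radial maps."""

import numpy as np
import pytest

from lymphmap import maps
from lymphmap import phantom as ph
from lymphmap.compartments import Compartment
from lymphmap.exceptions import LymphmapError
from lymphmap.volume_io import Landmarks


def truth_profile(gt: ph.GroundTruth) -> maps.LongitudinalProfile:
    stop = gt.analysis_stop
    return maps.longitudinal_profile(gt.labels[:stop], gt.compartments[:stop],
                                     Landmarks(0, gt.landmarks.elbow_slice,
                                               gt.landmarks.shoulder_tip_slice))


class TestLongitudinalProfile:
    def test_uniform_cylinder_gives_flat_profiles(self):
        spec = ph.PhantomSpec(n_slices=30, in_plane_size=64, arm_radius=20.0,
                              muscle_radius=12.0, elbow_slice=16)
        _, gt = ph.generate_arm(spec)
        p = truth_profile(gt)
        assert np.ptp(p.total) == 0 and np.ptp(p.muscle) == 0
        # per-slice value equals the cross-sectional voxel count in mL
        assert p.total[0] == pytest.approx(
            0.001 * (gt.compartments[0] != Compartment.OUTSIDE).sum())

    def test_tapered_slices_match_analytic_disc_area(self):
        spec = ph.PhantomSpec(n_slices=40, in_plane_size=96, arm_radius=(20.0, 36.0),
                              muscle_radius=(12.0, 20.0))
        _, gt = ph.generate_arm(spec)
        p = truth_profile(gt)
        radii = spec.arm_profile()[:gt.analysis_stop]
        np.testing.assert_allclose(p.total, 0.001 * np.pi * radii ** 2, rtol=0.02)

    def test_profile_sums_equal_measured_volumes(self, noise_free_result):
        res, _ = noise_free_result
        v = res.volumes
        assert res.profile.muscle.sum() == pytest.approx(v.muscle_subfascial, abs=1e-9)
        assert res.profile.fat.sum() == pytest.approx(v.fat_epifascial, abs=1e-9)
        assert res.profile.fluid.sum() == pytest.approx(v.fluid_epifascial, abs=1e-9)
        assert res.profile.total.sum() == pytest.approx(v.total_arm, abs=1e-9)

    def test_per_slice_total_bounds_tissue_sum(self, noise_free_result):
        res, _ = noise_free_result
        p = res.profile
        assert np.all(p.total + 1e-12 >= p.muscle + p.fat + p.fluid)


def make_profile(n, elbow, fill=1.0):
    arr = np.full(n, fill, dtype=float)
    return maps.LongitudinalProfile(muscle=arr.copy(), fat=arr.copy(),
                                    fluid=arr.copy(), epifascial=arr.copy(),
                                    total=arr.copy(), elbow_index=elbow)


class TestAlignPair:
    def test_identity_for_matching_profiles(self):
        a, u = make_profile(50, 20), make_profile(50, 20)
        al = maps.align_pair_at_elbow(a, u)
        assert al.n_slices == 50 and al.elbow_index == 20
        assert al.range_affected == (0, 50) and al.range_unaffected == (0, 50)

    def test_offset_elbows_trimmed_to_common_extent(self):
        al = maps.align_pair_at_elbow(make_profile(200, 80), make_profile(200, 90))
        assert al.n_slices == 190
        assert al.elbow_index == 80
        assert al.range_affected == (0, 190)
        assert al.range_unaffected == (10, 200)

    def test_random_offsets_match_span_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            na, nu = rng.integers(20, 300, size=2)
            ea, eu = rng.integers(1, na), rng.integers(1, nu)
            al = maps.align_pair_at_elbow(make_profile(na, ea), make_profile(nu, eu))
            assert al.n_slices == min(ea, eu) + min(na - ea, nu - eu)


class TestSegmentBounds:
    def test_remainder_distributed_from_distal_end(self):
        bounds = maps.segment_bounds(62 + 40, 62)
        forearm = [hi - lo for lo, hi in bounds[:6]]
        assert forearm == [11, 11, 10, 10, 10, 10]

    def test_bounds_partition_extent(self):
        bounds = maps.segment_bounds(137, 83)
        assert bounds[0][0] == 0 and bounds[-1][1] == 137
        assert all(b[1] == c[0] for b, c in zip(bounds, bounds[1:]))

    def test_too_few_slices_rejected(self):
        with pytest.raises(LymphmapError):
            maps.segment_bounds(8, 4)


class TestLongitudinalExcessMap:
    def test_identical_arms_give_all_zero_map(self):
        al = maps.align_pair_at_elbow(make_profile(60, 30), make_profile(60, 30))
        m = maps.longitudinal_excess_map(al)
        assert np.all(m.fluid_excess == 0) and np.all(m.fat_excess == 0)
        assert np.all(m.epifascial_increase_pct == 0)
        assert np.all(m.normalized("fluid_excess") == 0)

    def test_segment_sums_equal_global_excess(self, small_pair_result):
        m = small_pair_result.longitudinal_map
        c = small_pair_result.comparison
        assert m.fluid_excess.sum() == pytest.approx(
            c.excess["fluid_epifascial"], abs=1e-9)
        assert m.fat_excess.sum() == pytest.approx(
            c.excess["fat_epifascial"], abs=1e-9)

    def test_localized_fluid_lands_in_single_segment(self):
        # inject all fluid excess into one forearm segment (ground-truth path)
        spec = ph.PhantomSpec(n_slices=100, in_plane_size=96,
                              arm_radius=(24.0, 32.0), muscle_radius=(15.0, 20.0),
                              elbow_slice=60)
        ex = ph.ExcessSpec(fat_excess_ml=10.0, fluid_excess_ml=4.0,
                           fluid_center_slice=5, fluid_span_mm=8.0)
        (_, ga), (_, gu) = ph.generate_pair(spec, ex)
        al = maps.align_pair_at_elbow(truth_profile(ga), truth_profile(gu))
        m = maps.longitudinal_excess_map(al)
        assert m.fluid_excess[0] == pytest.approx(4.0, abs=0.1)
        assert np.all(np.abs(m.fluid_excess[1:]) < 1e-9)

    def test_normalization_peaks(self, small_pair_result):
        m = small_pair_result.longitudinal_map
        for measure in ("fluid_excess", "fat_excess", "epifascial_increase_pct"):
            norm = m.normalized(measure)
            vals = norm[~np.isnan(norm)]
            assert np.all(np.abs(vals) <= 1 + 1e-12)
            if m.peaks[measure] > 0:
                assert np.max(np.abs(vals)) == pytest.approx(1.0)


class TestSplitLayers:
    def test_concentric_boundary_at_mid_radius(self):
        spec = ph.PhantomSpec(n_slices=8, in_plane_size=100, arm_radius=40.0,
                              muscle_radius=20.0, elbow_slice=4)
        _, gt = ph.generate_arm(spec)
        sub = maps.split_epifascial_layers(gt.compartments)
        r2d, _ = ph._grids(100)
        epi = gt.compartments[0] == Compartment.EPIFASCIAL
        internal = (sub[0] == 1)[epi]
        rr = r2d[epi]
        assert rr[internal].max() <= 30.0 + 1.0
        assert rr[~internal].min() >= 30.0 - 1.0

    def test_one_voxel_shell_ties_to_internal(self):
        # straight-band geometry: every shell voxel is exactly 1 voxel from
        # both the fascia and the exterior, so the tie rule decides
        comp = np.zeros((1, 30, 30), dtype=np.uint8)
        comp[0, 10:20, :] = Compartment.SUBFASCIAL
        comp[0, 9, :] = Compartment.EPIFASCIAL
        comp[0, 20, :] = Compartment.EPIFASCIAL
        sub = maps.split_epifascial_layers(comp)
        shell = comp[0] == Compartment.EPIFASCIAL
        assert np.all(sub[0][shell] == 1)

    def test_matches_brute_force_nearest_boundary(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            size = 40
            cy, cx = rng.uniform(16, 24, size=2)
            mus = rng.uniform(4, 9)
            arm = mus + rng.uniform(3, 9)
            r = np.hypot(*(np.indices((size, size))
                           - np.array([cy, cx])[:, None, None]))
            comp = np.zeros((1, size, size), dtype=np.uint8)
            comp[0][r <= arm] = Compartment.EPIFASCIAL
            comp[0][r <= mus] = Compartment.SUBFASCIAL
            sub = maps.split_epifascial_layers(comp)

            # brute force: explicit nearest-voxel distances
            sl = comp[0]
            epi_pts = np.argwhere(sl == Compartment.EPIFASCIAL)
            sub_pts = np.argwhere(sl == Compartment.SUBFASCIAL)
            out_pts = np.argwhere(sl == Compartment.OUTSIDE)
            for y, x in epi_pts:
                d_f = np.min(((sub_pts - (y, x)) ** 2).sum(axis=1))
                d_s = np.min(((out_pts - (y, x)) ** 2).sum(axis=1))
                expected = 1 if d_f <= d_s else 2
                assert sub[0, y, x] == expected

    def test_no_epifascial_region_rejected(self):
        comp = np.zeros((1, 10, 10), dtype=np.uint8)
        with pytest.raises(LymphmapError):
            maps.split_epifascial_layers(comp)


class TestRadialMap:
    @pytest.fixture(scope="class")
    def annulus(self):
        spec = ph.PhantomSpec(
            n_slices=60, in_plane_size=96, arm_radius=32.0, muscle_radius=20.0,
            elbow_slice=33,
            fluid_pockets=[ph.FluidPocket(center_slice=30, extent_mm=1000,
                                          shape="annulus-sector", width_deg=360,
                                          layer="external")])
        return ph.generate_arm(spec)[1]

    def test_uniform_annulus_fills_sectors_equally(self, annulus):
        hist = maps.radial_fluid_histogram(annulus.labels, annulus.compartments,
                                           "right", sublayers=annulus.sublayers)
        ext = hist[1]
        assert (ext.max() - ext.min()) / ext.mean() <= 0.02
        assert hist[0].sum() == pytest.approx(0.0, abs=1e-9)

    def test_mirrored_left_arm_matches_right_arm(self, annulus):
        spec_pockets = [ph.FluidPocket(center_slice=30, extent_mm=1000,
                                       shape="annulus-sector", width_deg=120,
                                       angle_deg=30, layer="external")]
        spec = ph.PhantomSpec(n_slices=40, in_plane_size=96, arm_radius=30.0,
                              muscle_radius=18.0, elbow_slice=22,
                              fluid_pockets=spec_pockets)
        _, gt = ph.generate_arm(spec)
        flip = lambda a: np.ascontiguousarray(a[:, :, ::-1])
        h_right = maps.radial_fluid_histogram(gt.labels, gt.compartments, "right")
        h_left = maps.radial_fluid_histogram(flip(gt.labels),
                                             flip(gt.compartments), "left")
        np.testing.assert_allclose(h_left, h_right, atol=1e-12)

    def test_sector_pocket_rotated_by_45_degrees_shifts_bins(self):
        def hist_for(angle):
            spec = ph.PhantomSpec(
                n_slices=20, in_plane_size=96, arm_radius=30.0, muscle_radius=18.0,
                elbow_slice=11,
                fluid_pockets=[ph.FluidPocket(center_slice=10, extent_mm=1000,
                                              shape="annulus-sector", width_deg=44,
                                              angle_deg=angle, layer="external")])
            _, gt = ph.generate_arm(spec)
            return maps.radial_fluid_histogram(gt.labels, gt.compartments, "right",
                                               sublayers=gt.sublayers)

        h0, h45 = hist_for(22.5), hist_for(67.5)
        np.testing.assert_allclose(np.roll(h0[1], 1), h45[1],
                                   rtol=0.02, atol=1e-9)

    def test_sixteen_bin_sum_equals_global_fluid_excess(self, small_pair_result):
        r = small_pair_result.radial_map
        c = small_pair_result.comparison
        assert r.excess.sum() == pytest.approx(c.excess["fluid_epifascial"],
                                               abs=1e-9)

    def test_zero_excess_pair_gives_blank_map(self):
        spec = ph.PhantomSpec(n_slices=40, in_plane_size=64, arm_radius=(18.0, 24.0),
                              muscle_radius=(11.0, 15.0))
        _, gt = ph.generate_arm(spec)
        r = maps.radial_excess_map(gt.labels, gt.compartments, "left",
                                   gt.labels, gt.compartments, "right")
        # symmetric anatomy: mirroring is an involution, map stays zero
        assert np.allclose(r.excess, 0.0, atol=1e-12)


class TestRendering:
    def test_figures_written(self, small_pair_result, tmp_path):
        p = small_pair_result
        f1 = maps.render_longitudinal_profiles(p.aligned.affected,
                                               p.aligned.unaffected,
                                               str(tmp_path / "prof.png"))
        f2 = maps.render_longitudinal_excess_map(p.longitudinal_map,
                                                 str(tmp_path / "lmap.png"))
        f3 = maps.render_radial_excess_map(p.radial_map,
                                           str(tmp_path / "rmap.png"))
        f4 = maps.render_cohort_array([p.longitudinal_map], [p.radial_map],
                                      ["S01"], str(tmp_path / "array.png"))
        for f in (f1, f2, f3, f4):
            assert (tmp_path / f.split("/")[-1]).stat().st_size > 0
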