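"""3-D distribution analysis: histogram, contribution CDF, fit, segmentation."""

import numpy as np
import pytest

from fibersims.io import IonCube
from fibersims.voxel3d import (
    IntensityHistogram,
    LogisticFit,
    contribution_cdf,
    distribution_stats,
    fit_logistic,
    fraction_above,
    histogram,
    segment_domains,
    solve_quantile,
    surface_connectivity,
)

from conftest import make_random_cube
from oracles import (
    bisect_quantile,
    brute_components,
    brute_contribution_cdf,
    brute_fraction_above,
    brute_histogram,
)

# parameters of the reference log-logistic contribution curve
REF_A, REF_X0, REF_B = 1.0089, 17.990, 2.3693


def hist_from_counts(counts: dict[int, int]) -> IntensityHistogram:
    x_max = max(counts)
    arr = np.zeros(x_max + 1, dtype=np.int64)
    for x, n in counts.items():
        arr[x] = n
    return IntensityHistogram(
        counts=arr,
        total_voxels=int(arr.sum()),
        total_intensity=int(np.sum(arr * np.arange(x_max + 1))),
    )


class TestHistogram:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_tally(self, seed):
        cube = make_random_cube(seed, shape=(5, 5, 2), high=21)
        h = histogram(cube)
        expected = brute_histogram(cube.intensities)
        for x in range(h.x_max + 1):
            assert h.counts[x] == expected.get(x, 0)
        assert h.total_voxels == cube.n_voxels
        assert int(h.counts.sum()) == h.total_voxels

    def test_all_zero_cube(self):
        cube = IonCube(np.zeros((3, 3, 2), int), 0.2, np.array([0.0, 0.1]))
        h = histogram(cube)
        assert h.counts[0] == 18
        assert h.total_intensity == 0


class TestDistributionStats:
    def test_hand_enumerated_histogram(self):
        stats = distribution_stats(hist_from_counts({0: 1, 10: 3}))
        assert (stats.mode, stats.median) == (10, 10)
        assert stats.mean == pytest.approx(7.5)

    def test_single_voxel(self):
        stats = distribution_stats(hist_from_counts({7: 1}))
        assert (stats.mode, stats.median, stats.mean) == (7, 7, 7.0)

    def test_mode_tie_breaks_to_smallest(self):
        stats = distribution_stats(hist_from_counts({2: 5, 9: 5}))
        assert stats.mode == 2


class TestContributionCdf:
    def test_single_level_reaches_one(self):
        cdf = contribution_cdf(hist_from_counts({1: 10}))
        assert cdf.cumulative_fraction[1] == 1.0

    def test_two_level_hand_arithmetic(self):
        cdf = contribution_cdf(hist_from_counts({1: 10, 3: 10}))
        assert cdf.cumulative_fraction[1] == pytest.approx(0.25)
        assert cdf.cumulative_fraction[3] == 1.0

    @pytest.mark.parametrize("seed", [3, 4])
    def test_monotone_final_one_and_matches_brute_force(self, seed):
        cube = make_random_cube(seed)
        cdf = contribution_cdf(histogram(cube))
        assert cdf.cumulative_fraction[-1] == 1.0
        assert np.all(np.diff(cdf.cumulative_fraction) >= 0)
        expected = brute_contribution_cdf(cube.intensities)
        for x, frac in expected.items():
            assert cdf.cumulative_fraction[x] == pytest.approx(frac, abs=1e-12)

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError):
            contribution_cdf(hist_from_counts({0: 5}))

    @pytest.mark.parametrize("seed", [5, 6])
    def test_threshold_consistency_with_fraction_above(self, seed):
        cube = make_random_cube(seed)
        h = histogram(cube)
        cdf = contribution_cdf(h)
        for t in range(1, h.x_max + 1):
            assert fraction_above(h, t) + cdf.cumulative_fraction[t - 1] == (
                pytest.approx(1.0, abs=1e-12))


class TestLogisticFit:
    def test_recovers_exact_reference_curve(self):
        x = np.arange(0, 126)
        y = REF_A / (1.0 + (np.maximum(x, 1e-9) / REF_X0) ** (-REF_B))
        y[0] = 0.0
        from fibersims.voxel3d import ContributionCDF

        fit = fit_logistic(ContributionCDF(x=x, cumulative_fraction=y))
        assert fit.a == pytest.approx(REF_A, rel=1e-6)
        assert fit.x0 == pytest.approx(REF_X0, rel=1e-6)
        assert fit.b == pytest.approx(REF_B, rel=1e-6)
        assert fit.r2 > 1 - 1e-9

    def test_midpoint_identity(self):
        fit = LogisticFit(a=REF_A, x0=REF_X0, b=REF_B, r2=1.0)
        assert fit(REF_X0) == pytest.approx(REF_A / 2.0)

    def test_too_few_points_rejected(self):
        from fibersims.voxel3d import ContributionCDF

        with pytest.raises(ValueError):
            fit_logistic(ContributionCDF(x=np.array([1, 2]),
                                         cumulative_fraction=np.array([0.5, 1.0])))


class TestSolveQuantile:
    def test_median_is_scale_parameter(self):
        fit = LogisticFit(a=REF_A, x0=REF_X0, b=REF_B, r2=1.0)
        assert solve_quantile(fit, 0.5) == pytest.approx(REF_X0)

    def test_reference_curve_half_load_intensity(self):
        """The printed curve puts half the Cl load at ~18 intensity counts
        (reported as 18.1); the unnormalised convention gives ~17.9."""
        fit = LogisticFit(a=REF_A, x0=REF_X0, b=REF_B, r2=1.0)
        assert solve_quantile(fit, 0.5, normalized=True) == pytest.approx(17.990,
                                                                          abs=1e-9)
        assert solve_quantile(fit, 0.5, normalized=False) == pytest.approx(17.86,
                                                                           abs=0.01)

    @pytest.mark.parametrize("normalized", [True, False])
    def test_agrees_with_bisection_oracle(self, normalized):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x0 = rng.uniform(1.0, 100.0)
            b = rng.uniform(0.5, 5.0)
            a = rng.uniform(0.9, 1.1)
            q = rng.uniform(0.05, min(0.95, a - 0.05) if not normalized else 0.95)
            fit = LogisticFit(a=a, x0=x0, b=b, r2=1.0)
            closed = solve_quantile(fit, q, normalized=normalized)
            ref = bisect_quantile(a, x0, b, q, normalized=normalized)
            assert closed == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_quantile_domain(self, q):
        fit = LogisticFit(a=1.0, x0=10.0, b=2.0, r2=1.0)
        with pytest.raises(ValueError):
            solve_quantile(fit, q)


class TestFractionAbove:
    def test_trivial_thresholds(self):
        h = hist_from_counts({1: 10, 3: 10})
        assert fraction_above(h, 0) == 1.0
        assert fraction_above(h, 4) == 0.0
        assert fraction_above(h, 2) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", [8, 9])
    def test_matches_brute_force(self, seed):
        cube = make_random_cube(seed)
        h = histogram(cube)
        for t in [0, 1, 5, 13, 29]:
            assert fraction_above(h, t) == pytest.approx(
                brute_fraction_above(cube.intensities, t), abs=1e-12)


def box_cube(boxes, shape=(12, 12, 5), low=1, high=90):
    """Cube with `high` intensity inside the given index boxes, else `low`."""
    arr = np.full(shape, low, dtype=np.int64)
    for (r0, r1, c0, c1, k0, k1) in boxes:
        arr[r0:r1, c0:c1, k0:k1] = high
    return IonCube(arr, 0.2, np.arange(shape[2]) * 0.15)


class TestSegmentDomains:
    def test_cube_below_threshold_has_no_domains(self):
        cube = box_cube([])
        seg = segment_domains(cube, 50)
        assert seg.n_domains == 0
        assert seg.total_volume_fraction == 0.0

    def test_three_disjoint_boxes(self):
        boxes = [(0, 2, 0, 2, 0, 2), (5, 8, 5, 9, 1, 3), (9, 12, 0, 3, 3, 5)]
        cube = box_cube(boxes)
        seg = segment_domains(cube, 50)
        assert seg.n_domains == 3
        expected = sorted((r1 - r0) * (c1 - c0) * (k1 - k0)
                          for r0, r1, c0, c1, k0, k1 in boxes)
        assert sorted(d.voxel_count for d in seg.domains) == expected
        assert seg.total_volume_fraction == pytest.approx(sum(expected) / cube.n_voxels)
        assert sum(d.intensity_fraction for d in seg.domains) < 1.0

    @pytest.mark.parametrize("seed", [10, 11, 12])
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_components_match_bfs_oracle(self, seed, connectivity):
        cube = make_random_cube(seed, shape=(8, 8, 4), high=30)
        threshold = 20
        seg = segment_domains(cube, threshold, connectivity=connectivity)
        mask = cube.intensities >= threshold
        expected = brute_components(mask, connectivity)
        got = []
        for d in seg.domains:
            coords = zip(*np.nonzero(seg.label_volume == d.label))
            got.append(frozenset(coords))
        assert set(got) == set(expected)
        assert sum(d.voxel_count for d in seg.domains) == int(mask.sum())

    def test_min_voxels_discards_speckle(self):
        boxes = [(0, 4, 0, 4, 0, 3)]  # 48-voxel domain
        cube = box_cube(boxes)
        arr = np.array(cube.intensities)
        arr[10, 10, 4] = 90  # isolated suprathreshold voxel
        cube2 = IonCube(arr, cube.pixel_size_um, cube.level_depths_um)
        assert segment_domains(cube2, 50).n_domains == 2
        seg = segment_domains(cube2, 50, min_voxels=8)
        assert seg.n_domains == 1
        assert seg.domains[0].voxel_count == 48

    def test_physical_metrics_of_slab(self):
        # 1 x 10 x 1 voxel slab along columns: elongated along x
        cube = box_cube([(5, 6, 1, 11, 2, 3)])
        seg = segment_domains(cube, 50)
        d = seg.domains[0]
        assert d.voxel_count == 10
        ox, oy, oz = d.orientation
        assert abs(ox) == pytest.approx(1.0, abs=1e-9)
        assert d.axis_lengths_um[0] == pytest.approx(9 * 0.2)
        assert d.centroid_um[1] == pytest.approx(5.5 * 0.2)
        assert d.min_depth_um == pytest.approx(0.3)

    def test_volume_and_intensity_fractions_bounded(self):
        cube = make_random_cube(13, shape=(10, 10, 4), high=60)
        seg = segment_domains(cube, 30)
        assert 0.0 <= seg.total_volume_fraction <= 1.0
        assert 0.0 <= seg.total_intensity_fraction <= 1.0
        for d in seg.domains:
            assert 0.0 <= d.volume_fraction <= 1.0
            assert 0.0 <= d.intensity_fraction <= 1.0


class TestSurfaceConnectivity:
    def test_surface_spanning_domain_flagged(self):
        cube = box_cube([(0, 2, 0, 2, 0, 2)])
        seg = segment_domains(cube, 50)
        report = surface_connectivity(seg, depth_limit_um=0.5)
        assert report.n_surface_touching == 1

    def test_deep_domains_not_flagged(self):
        cube = box_cube([(0, 3, 0, 3, 4, 5), (6, 9, 6, 9, 4, 5)])
        seg = segment_domains(cube, 50)
        report = surface_connectivity(seg, depth_limit_um=0.5)
        assert report.n_surface_touching == 0
        assert set(report.surface_touching.values()) == {False}

    def test_flags_depend_only_on_depths(self):
        cube = box_cube([(0, 2, 0, 2, 0, 2), (6, 9, 6, 9, 4, 5)])
        seg = segment_domains(cube, 50)
        flags = surface_connectivity(seg, 0.5).surface_touching
        by_depth = {d.label: d.min_depth_um < 0.5 for d in seg.domains}
        assert flags == by_depth
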