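"""Synthetic signals, smoothed noise, and the coverage harness."""

import numpy as np
import pytest

from confsets import (
    DomainGrid,
    NoiseSpec,
    SignalSpec,
    SimConfig,
    assess_coverage_trial,
    make_noise,
    make_signal,
    make_truth,
    run_experiment,
    upper_cs_sensitivity,
)
from confsets.confidence_sets import ConfidenceSets
from confsets.simulate import FWHM_TO_SIGMA, smoothed_noise_sd


class TestSignals:
    def test_ramp_endpoints_and_linearity(self):
        f = make_signal(SignalSpec("ramp2d", (100, 100)))
        assert f.min() == 0.0 and f.max() == 1.0
        assert np.allclose(f[37, :], 37 / 99)
        assert np.allclose(np.diff(f[:, 0]), 1 / 99)

    def test_circle_center_value_and_no_rescale(self):
        f = make_signal(SignalSpec("circle2d", (100, 100)))
        # radius 30 disk is much wider than the kernel: plateau stays at 1
        assert f[49, 49] == pytest.approx(1.0, abs=1e-3)
        assert f.max() <= 1.0 + 1e-9

    def test_spheres_rescaled_to_unit_max(self):
        small = make_signal(SignalSpec("sphere3d_small", (32, 32, 32)))
        large = make_signal(SignalSpec("sphere3d_large", (32, 32, 32), radius=10))
        for f in (small, large):
            assert f.max() == pytest.approx(1.0, rel=1e-12)
        c = 15.5  # grid center for 32 voxels
        ctr = small[15:17, 15:17, 15:17].max()
        assert ctr == pytest.approx(1.0, abs=1e-6)

    def test_multi_sphere_each_center_at_unit_magnitude(self):
        centers = ((8.0, 8.0, 8.0), (8.0, 23.0, 23.0), (23.0, 8.0, 23.0))
        radii = (3.0, 4.0, 5.0)
        f = make_signal(
            SignalSpec("multi_sphere3d", (32, 32, 32), centers=centers, radii=radii)
        )
        assert f.max() <= 1.0 + 1e-12
        for (x, y, z) in centers:
            assert f[int(x), int(y), int(z)] == pytest.approx(1.0, abs=1e-6)

    def test_geometry_exceeding_grid_rejected(self):
        with pytest.raises(ValueError):
            make_signal(SignalSpec("circle2d", (20, 20), radius=30))
        with pytest.raises(ValueError):
            make_signal(SignalSpec("ramp2d", (10, 10, 10)))


class TestNoise:
    def test_pointwise_sd_matches_sd_field(self, rng):
        # standardization contract, checked against the sd over many subjects
        grid = DomainGrid((20, 20))
        for spec in (NoiseSpec(), NoiseSpec(sd="linear")):
            stack = make_noise(grid, spec, 4000, rng)
            sd = stack.data.std(axis=0, ddof=1)
            target = spec.sd_field(grid.shape)
            mc_rel = 3 / np.sqrt(2 * 3999)  # 3 MC SEs of a sample sd
            assert np.all(np.abs(sd / target - 1) < 4 * mc_rel + 0.02)

    def test_lag_correlation_matches_gaussian_kernel(self, rng):
        # away from edges the autocorrelation of FWHM-smoothed white noise is
        # exp(-lag^2 / (4 sigma^2))
        grid = DomainGrid((24, 24))
        stack = make_noise(grid, NoiseSpec(smoothing_fwhm=3.0), 6000, rng)
        sigma = 3.0 * FWHM_TO_SIGMA
        for lag in (1, 2):
            emp = np.corrcoef(
                stack.data[:, 12, 12], stack.data[:, 12, 12 + lag]
            )[0, 1]
            assert emp == pytest.approx(np.exp(-(lag**2) / (4 * sigma**2)), abs=0.05)

    def test_homogeneous_truth_equals_signal(self):
        mu = make_signal(SignalSpec("circle2d", (40, 40), radius=12))
        truth = make_truth(mu, NoiseSpec(), 0.8)
        assert np.array_equal(truth.d, mu)

    def test_linear_sd_field_profile(self):
        spec = NoiseSpec(sd="linear")
        f = spec.sd_field((5, 11))
        assert np.allclose(f[:, 0], 0.5) and np.allclose(f[:, -1], 1.5)
        assert np.allclose(np.diff(f[2]), 0.1)

    def test_smoothed_noise_sd_interior_closed_form(self):
        # in the grid interior the smoothed-white-noise sd is the l2 norm of
        # the separable kernel
        from confsets.simulate import _kernel1d

        k = _kernel1d(3.0)
        sd = smoothed_noise_sd((30, 30), 3.0)
        assert sd[15, 15] == pytest.approx(np.sqrt((k**2).sum()) ** 2, rel=1e-12)
        # edges lose kernel mass, so the sd is strictly smaller there
        assert sd[0, 0] < sd[15, 15]


def _fake_cs(grid, upper, lower, f_up=None, f_low=None):
    shape = grid.shape
    nan = np.full(shape, np.nan)
    return ConfidenceSets(
        grid=grid,
        upper=upper,
        lower=lower,
        point_estimate=upper.copy(),
        critical=None,
        c=0.8,
        alpha=0.05,
        algorithm=2,
        upper_decision=f_up if f_up is not None else np.where(upper, 1.0, -1.0),
        lower_decision=f_low if f_low is not None else np.where(lower, 1.0, -1.0),
        summary=None,
        degenerate=f_up is None and f_low is None,
    )


class TestCoverageAssessment:
    def test_vacuous_nesting_is_covered(self):
        grid = DomainGrid((6, 6))
        truth = make_truth(np.linspace(0, 1.2, 36).reshape(6, 6), NoiseSpec(), 0.8, grid)
        cs = _fake_cs(grid, np.zeros((6, 6), bool), np.ones((6, 6), bool))
        assert assess_coverage_trial(cs, truth)

    def test_single_upper_voxel_outside_truth_fails(self):
        grid = DomainGrid((6, 6))
        truth = make_truth(np.zeros((6, 6)), NoiseSpec(), 0.8, grid)
        upper = np.zeros((6, 6), bool)
        upper[3, 3] = True
        cs = _fake_cs(grid, upper, np.ones((6, 6), bool))
        assert not assess_coverage_trial(cs, truth)

    def test_true_set_escaping_lower_fails(self):
        grid = DomainGrid((6, 6))
        truth = make_truth(np.full((6, 6), 1.0), NoiseSpec(), 0.8, grid)
        cs = _fake_cs(grid, np.zeros((6, 6), bool), np.zeros((6, 6), bool))
        assert not assess_coverage_trial(cs, truth)

    def test_interpolated_near_miss_detected(self):
        # lattice checks pass, but at the interpolated true-boundary point
        # (w = 0.5 between the two voxels) the lower decision field dips
        # negative -> the trial must count as a miss
        grid = DomainGrid((1, 2))
        truth = make_truth(np.array([[0.7, 0.9]]), NoiseSpec(), 0.8, grid)
        assert truth.boundary_w[0] == pytest.approx(0.5)
        upper = np.zeros((1, 2), bool)
        lower = np.array([[False, True]])  # contains A_c = {voxel 1}
        f_up = np.array([[-2.0, -1.0]])  # never positive
        f_low = np.array([[-1.2, 1.0]])  # interpolates to -0.1 < 0 at w=.5
        cs = _fake_cs(grid, upper, lower, f_up, f_low)
        assert not assess_coverage_trial(cs, truth)
        # same lattice sets with a benign lower field: covered
        cs_ok = _fake_cs(grid, upper, lower, f_up, np.array([[-0.5, 1.0]]))
        assert assess_coverage_trial(cs_ok, truth)

    def test_sensitivity_counting(self):
        grid = DomainGrid((4, 4))
        d = np.zeros((4, 4))
        d[:2] = 1.0  # 8 true voxels
        truth = make_truth(d, NoiseSpec(), 0.8, grid)
        full = _fake_cs(grid, truth.a_c.copy(), np.ones((4, 4), bool))
        assert upper_cs_sensitivity(full, truth) == 1.0
        none = _fake_cs(grid, np.zeros((4, 4), bool), np.ones((4, 4), bool))
        assert upper_cs_sensitivity(none, truth) == 0.0
        half = truth.a_c.copy()
        half[0] = False  # drop 4 of 8
        assert upper_cs_sensitivity(_fake_cs(grid, half, np.ones((4, 4), bool)), truth) == 0.5

    def test_empty_truth_sensitivity_undefined(self):
        grid = DomainGrid((4, 4))
        truth = make_truth(np.zeros((4, 4)), NoiseSpec(), 0.8, grid)
        cs = _fake_cs(grid, np.zeros((4, 4), bool), np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="undefined"):
            upper_cs_sensitivity(cs, truth)


class TestRunExperiment:
    def test_single_trial_reproducible(self):
        cfg = SimConfig(n_trials=1, n_boot=120, sample_sizes=(20,), levels=(0.9,),
                        algorithms=(2,), seed=123, c=0.8)
        sig = SignalSpec("circle2d", (30, 30), radius=9)
        t1 = run_experiment(cfg, sig, NoiseSpec())
        t2 = run_experiment(cfg, sig, NoiseSpec())
        assert t1.equals(t2)
        row = t1.iloc[0]
        assert row["coverage"] in (0.0, 1.0)
        assert 0.0 <= row["sensitivity"] <= 1.0

    def test_algorithm1_at_least_as_conservative_as_algorithm2(self):
        # small-sample behavior on shared simulated samples
        cfg = SimConfig(n_trials=40, n_boot=200, sample_sizes=(30,), levels=(0.8,),
                        algorithms=(1, 2), seed=77, c=0.8)
        sig = SignalSpec("circle2d", (40, 40), radius=12)
        tab = run_experiment(cfg, sig, NoiseSpec())
        c1 = tab[tab.algorithm == 1].coverage.iloc[0]
        c2 = tab[tab.algorithm == 2].coverage.iloc[0]
        assert c1 >= c2

    def test_table_schema(self):
        cfg = SimConfig(n_trials=2, n_boot=120, sample_sizes=(16,), levels=(0.9,),
                        algorithms=(3,), seed=5, c=0.8)
        tab = run_experiment(cfg, SignalSpec("circle2d", (30, 30), radius=9), NoiseSpec(sd="linear"))
        assert list(tab.columns) == [
            "signal", "noise", "algorithm", "N", "level", "trials", "B",
            "coverage", "coverage_se", "sensitivity", "seed",
        ]
        assert tab.noise.iloc[0] == "linear"
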