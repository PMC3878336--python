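"""Inner fixed-point updates and the full reconstruction driver."""

import numpy as np
import pytest
from scipy import optimize as sopt

from attencorr import (
    ConeSpec,
    NoiseParams,
    PhantomSpec,
    RegularizerSpec,
    SolverConfig,
    TwoViewRecording,
    VolumeGrid,
    inner_fixed_point,
    make_dataset,
    reconstruct,
    reconstruct_baseline_ref7,
    simulate_two_views,
    update_beta,
    update_intensity,
)
from attencorr.energy import data_weight


def _edata(I, recs, C1, C2, beta2, noise):
    w1 = data_weight(recs.top, noise.m, noise.sigma)
    w2 = data_weight(recs.bottom, noise.m, noise.sigma)
    D1 = recs.top.values - I * C1**2
    D2 = recs.bottom.values - beta2 * I * C2**2
    return float(np.sum(w1 * D1**2) + np.sum(w2 * D2**2))


class TestUpdateIntensity:
    def test_identical_views_unit_cones_reproduce_value(self):
        v = np.full((3, 3, 3), 42.0)
        recs = TwoViewRecording(VolumeGrid(v.copy()), VolumeGrid(v.copy()))
        ones = np.ones_like(v)
        I = update_intensity(recs, ones, ones, 1.0, NoiseParams(0.0, 1.0))
        np.testing.assert_allclose(I, 42.0)

    def test_single_view_inversion_when_other_cone_is_dark(self, rng):
        rec1 = 100.0 * rng.random((3, 3, 3)) + 1.0
        recs = TwoViewRecording(VolumeGrid(rec1), VolumeGrid(np.zeros((3, 3, 3))))
        C1 = np.full((3, 3, 3), 0.7)
        C2 = np.zeros((3, 3, 3))
        I = update_intensity(recs, C1, C2, 0.8, NoiseParams(0.05, 10.0))
        np.testing.assert_allclose(I, rec1 / 0.49, rtol=1e-12)

    def test_matches_brute_force_scan(self, rng):
        """Per-voxel 1-D scan of the data energy over I confirms the
        closed-form argmin."""
        shape = (2, 2, 2)
        recs = TwoViewRecording(
            VolumeGrid(100 * rng.random(shape)), VolumeGrid(100 * rng.random(shape))
        )
        C1 = 0.3 + 0.7 * rng.random(shape)
        C2 = 0.3 + 0.7 * rng.random(shape)
        noise = NoiseParams(0.05, 10.0)
        beta2 = 0.8
        I_closed = update_intensity(recs, C1, C2, beta2, noise)
        grid = np.linspace(0.0, 1000.0, 10001)
        for idx in np.ndindex(shape):
            w1 = 1.0 / (0.0025 * recs.top.values[idx] + 100.0)
            w2 = 1.0 / (0.0025 * recs.bottom.values[idx] + 100.0)
            e = w1 * (recs.top.values[idx] - grid * C1[idx] ** 2) ** 2 + w2 * (
                recs.bottom.values[idx] - beta2 * grid * C2[idx] ** 2
            ) ** 2
            assert I_closed[idx] == pytest.approx(grid[np.argmin(e)], abs=0.2)


class TestUpdateBeta:
    def test_exact_recovery_from_noise_free_simulation(self):
        spec = PhantomSpec(shape=(24, 24, 24), seed=4)
        I_true, alpha_true, recs = make_dataset(spec, beta2=0.8, noise=None)
        from attencorr import cone_transmission

        C2 = cone_transmission(alpha_true.values, ConeSpec(view="bottom")).values
        beta = update_beta(recs, I_true.values, C2, NoiseParams(0.05, 10.0))
        assert beta == pytest.approx(0.8, rel=1e-9)

    def test_single_voxel_formula_collapse(self):
        recs = TwoViewRecording(
            VolumeGrid(np.full((1, 1, 1), 30.0)), VolumeGrid(np.full((1, 1, 1), 24.0))
        )
        beta = update_beta(recs, np.full((1, 1, 1), 50.0), np.full((1, 1, 1), 0.9),
                           NoiseParams(0.0, 1.0))
        assert beta == pytest.approx(24.0 / (50.0 * 0.81), rel=1e-12)

    def test_matches_brute_force_minimization(self, rng):
        shape = (3, 3, 3)
        recs = TwoViewRecording(
            VolumeGrid(100 * rng.random(shape)), VolumeGrid(100 * rng.random(shape))
        )
        I = 100 * rng.random(shape)
        C1 = np.ones(shape)
        C2 = 0.3 + 0.7 * rng.random(shape)
        noise = NoiseParams(0.05, 10.0)
        beta_closed = update_beta(recs, I, C2, noise)
        res = sopt.minimize_scalar(
            lambda b: _edata(I, recs, C1, C2, b, noise), bounds=(1e-6, 10.0),
            method="bounded", options={"xatol": 1e-10},
        )
        assert beta_closed == pytest.approx(res.x, rel=1e-6)

    def test_no_signal_leaves_beta_unchanged_with_warning(self):
        recs = TwoViewRecording(
            VolumeGrid(np.zeros((2, 2, 2))), VolumeGrid(np.zeros((2, 2, 2)))
        )
        with pytest.warns(UserWarning):
            beta = update_beta(recs, np.zeros((2, 2, 2)), np.ones((2, 2, 2)),
                               NoiseParams(0.0, 1.0), beta2_prev=0.7)
        assert beta == 0.7


class TestInnerFixedPoint:
    def test_bleaching_disabled_is_single_intensity_update(self, rng):
        shape = (3, 3, 3)
        recs = TwoViewRecording(
            VolumeGrid(100 * rng.random(shape)), VolumeGrid(100 * rng.random(shape))
        )
        C = 0.5 + 0.5 * rng.random(shape)
        noise = NoiseParams(0.05, 10.0)
        cfg = SolverConfig(estimate_bleaching=False)
        I, beta = inner_fixed_point(recs, C, C, 1.0, noise, cfg)
        np.testing.assert_array_equal(I, update_intensity(recs, C, C, 1.0, noise))
        assert beta == 1.0

    def test_converged_input_stable_in_one_sweep(self):
        spec = PhantomSpec(shape=(16, 16, 16), seed=5)
        I_true, alpha_true, recs = make_dataset(spec, beta2=0.8, noise=None)
        from attencorr import cone_transmission

        C1 = cone_transmission(alpha_true.values, ConeSpec(view="top")).values
        C2 = cone_transmission(alpha_true.values, ConeSpec(view="bottom")).values
        noise = NoiseParams(0.05, 10.0)
        I, beta = inner_fixed_point(recs, C1, C2, 0.8, noise, SolverConfig())
        assert beta == pytest.approx(0.8, rel=1e-6)

    def test_data_energy_never_increases(self, rng):
        """Each half-step is an exact coordinate minimizer."""
        shape = (4, 4, 4)
        for trial in range(5):
            recs = TwoViewRecording(
                VolumeGrid(200 * rng.random(shape)), VolumeGrid(200 * rng.random(shape))
            )
            C1 = 0.2 + 0.8 * rng.random(shape)
            C2 = 0.2 + 0.8 * rng.random(shape)
            noise = NoiseParams(0.05, 10.0)
            beta0 = 0.5 + rng.random()
            I0 = 100 * rng.random(shape)
            e_before = _edata(I0, recs, C1, C2, beta0, noise)
            I, beta = inner_fixed_point(recs, C1, C2, beta0, noise, SolverConfig())
            e_after = _edata(I, recs, C1, C2, beta, noise)
            assert e_after <= e_before + 1e-9 * abs(e_before)


class TestReconstruct:
    def test_noise_free_zero_attenuation_recovered(self, rng):
        """Global optimum at alpha = 0: intensities match the recordings to
        0.1% and the attenuation stays at (numerical) zero."""
        I = VolumeGrid(1000.0 * rng.random((12, 12, 12)) + 10.0)
        alpha0 = VolumeGrid(np.zeros((12, 12, 12)))
        recs = simulate_two_views(I, alpha0, beta2=1.0, noise=None)
        st = reconstruct(
            recs,
            reg=RegularizerSpec("tm", lam=0.0, mu=10.0),
            noise=NoiseParams(0.0, 1.0),
            solver=SolverConfig(max_outer_iterations=10, energy_tol=1e-12),
        )
        np.testing.assert_allclose(st.I.values, I.values, rtol=1e-3)
        assert st.alpha.values.max() < 1e-4

    def test_energy_trace_non_increasing(self, rng):
        spec = PhantomSpec(shape=(16, 16, 16), seed=6)
        _, _, recs = make_dataset(spec, beta2=0.8, noise=NoiseParams(0.05, 10.0, seed=6))
        st = reconstruct(
            recs,
            reg=RegularizerSpec("tm", lam=1e6, mu=100.0),
            noise=NoiseParams(0.05, 10.0),
            solver=SolverConfig(max_outer_iterations=8),
        )
        diffs = np.diff(st.energy_trace)
        assert np.all(diffs <= 1e-8 * np.abs(np.asarray(st.energy_trace[:-1])))

    def test_box_constraints_hold(self, rng):
        spec = PhantomSpec(shape=(16, 16, 16), seed=7)
        _, _, recs = make_dataset(spec, beta2=0.8, noise=NoiseParams(0.05, 10.0, seed=7))
        st = reconstruct(
            recs,
            reg=RegularizerSpec("tv", lam=5e4, mu=100.0),
            noise=NoiseParams(0.05, 10.0),
            solver=SolverConfig(max_outer_iterations=6),
        )
        assert st.alpha.values.min() >= 0.0
        assert st.I.values.min() >= 0.0
        assert st.beta2 > 0.0

    def test_bit_identical_reruns(self):
        """Identical inputs give bit-identical states (deterministic,
        single-threaded reductions)."""
        spec = PhantomSpec(shape=(12, 12, 12), seed=8)
        _, _, recs = make_dataset(spec, beta2=0.8, noise=NoiseParams(0.05, 10.0, seed=8))
        kwargs = dict(
            reg=RegularizerSpec("tm", lam=1e6, mu=100.0),
            noise=NoiseParams(0.05, 10.0),
            solver=SolverConfig(max_outer_iterations=5),
        )
        a = reconstruct(recs, **kwargs)
        b = reconstruct(recs, **kwargs)
        np.testing.assert_array_equal(a.alpha.values, b.alpha.values)
        np.testing.assert_array_equal(a.I.values, b.I.values)
        assert a.beta2 == b.beta2
        assert a.energy_trace == b.energy_trace


class TestBaselinePreset:
    def test_equals_reconstruct_with_explicit_parameters(self):
        spec = PhantomSpec(shape=(12, 12, 12), seed=9)
        _, _, recs = make_dataset(spec, beta2=0.8, noise=NoiseParams(0.05, 10.0, seed=9))
        solver = SolverConfig(max_outer_iterations=4)
        a = reconstruct_baseline_ref7(recs, lam=10.0, solver=solver)
        b = reconstruct(
            recs,
            reg=RegularizerSpec("tm", lam=10.0, mu=0.0),
            noise=NoiseParams(0.0, 1.0),
            solver=SolverConfig(max_outer_iterations=4, estimate_bleaching=False),
        )
        np.testing.assert_array_equal(a.alpha.values, b.alpha.values)
        np.testing.assert_array_equal(a.I.values, b.I.values)
        assert a.beta2 == b.beta2 == 1.0

    def test_energy_is_data_plus_weighted_smoothness(self):
        spec = PhantomSpec(shape=(12, 12, 12), seed=10)
        _, _, recs = make_dataset(spec, beta2=0.8, noise=NoiseParams(0.05, 10.0, seed=10))
        st = reconstruct_baseline_ref7(recs, lam=10.0,
                                       solver=SolverConfig(max_outer_iterations=3))
        bd = st.breakdown
        assert bd.e_total == pytest.approx(bd.e_data + 10.0 * bd.e_smooth)


class TestBleachingRecovery:
    def test_mean_beta_within_two_percent_over_seeds(self):
        """Parameter recovery across noise realizations on the sphere
        phantom simulated with beta_2 = 0.8."""
        betas = []
        for seed in range(5):
            spec = PhantomSpec(shape=(24, 24, 24), seed=seed)
            _, _, recs = make_dataset(spec, beta2=0.8,
                                      noise=NoiseParams(0.05, 10.0, seed=seed))
            st = reconstruct(
                recs,
                reg=RegularizerSpec("tm", lam=1e6, mu=100.0),
                noise=NoiseParams(0.05, 10.0),
                solver=SolverConfig(max_outer_iterations=8),
            )
            betas.append(st.beta2)
        assert np.mean(betas) == pytest.approx(0.8, abs=0.02)
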