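"""Forward model: stability, noise synthesis, neural dynamics, hemodynamics,
acquisition corruption."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longdcm.errors import StabilityError, ValidationError
from longdcm.simulate import (
    HemoParams,
    NoiseSpec,
    SessionSeries,
    balloon_bold,
    effective_matrix,
    is_stable,
    make_voxels,
    powerlaw_noise,
    sample_and_corrupt,
    simulate_bold,
    simulate_cohort_bold,
    simulate_neural,
)
from longdcm.simulate import _balloon_derivs
from longdcm.spdcm import self_rate


class TestStability:
    def test_decoupled_network_is_stable(self):
        assert is_stable(np.zeros((3, 3)))

    def test_strong_symmetric_pair_is_unstable(self):
        # 2x2 effective eigenvalues are -0.5 +/- 0.6
        a = np.array([[0.0, 0.6], [0.6, 0.0]])
        assert not is_stable(a)

    def test_agrees_with_eigenvalue_oracle(self, rng):
        for _ in range(50):
            a = 0.4 * rng.standard_normal((6, 6))
            eff = a.copy()
            np.fill_diagonal(eff, -0.5 * np.exp(np.diag(a)))
            oracle = np.all(np.linalg.eigvals(eff).real < 0)
            assert is_stable(a) == oracle

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            is_stable(np.array([[np.nan, 0.0], [0.0, 0.0]]))

    @pytest.mark.parametrize(
        "a_ii,expected", [(0.0, -0.5), (np.log(2.0), -1.0), (1.0, -1.3591409)]
    )
    def test_self_rate_convention(self, a_ii, expected):
        assert self_rate(a_ii) == pytest.approx(expected, abs=1e-6)

    def test_effective_matrix_applies_log_scale_diagonal(self):
        a = np.array([[0.3, 0.1], [-0.2, -0.4]])
        eff = effective_matrix(a)
        assert eff[0, 1] == 0.1 and eff[1, 0] == -0.2
        assert eff[0, 0] == pytest.approx(-0.5 * np.exp(0.3))


class TestNeuralSimulation:
    def test_powerlaw_noise_matches_target_spectrum(self, rng):
        v = powerlaw_noise(2**15, 0.1, 2.0, 1.0, rng, 1)[:, 0]
        spec = np.abs(np.fft.rfft(v)) ** 2 * 0.1 / v.size
        f = np.fft.rfftfreq(v.size, 0.1)
        band = (f > 0.05) & (f < 2.0)
        ratio = spec[band] / (2.0 * f[band] ** -1.0)
        assert np.mean(ratio) == pytest.approx(1.0, abs=0.1)

    def test_zero_noise_decays_monotonically(self):
        x = simulate_neural(
            np.zeros((2, 2)),
            NoiseSpec(state_amp=0.0, obs_amp=0.0, drift_amp=0.0),
            duration=64,
            dt=0.05,
            seed=0,
            burn_in=32,
            x0=np.array([1.0, -2.0]),
        )
        norms = np.linalg.norm(x, axis=1)
        assert np.all(np.diff(norms) <= 1e-12)
        assert norms[-1] < 1e-3 * norms[0]

    def test_ou_variance_matches_closed_form(self, rng):
        # white state noise, single node, a11=0: Var = amp / (2 * 0.5)
        amp = 0.04
        noise = NoiseSpec(state_amp=amp, state_exp=0.0, obs_amp=0.0, drift_amp=0.0)
        x = simulate_neural(np.zeros((1, 1)), noise, duration=6000, dt=0.05, seed=5)
        assert x.var() == pytest.approx(amp / (2 * 0.5), rel=0.1)

    def test_trajectory_spectrum_matches_shaped_input(self, quiet_noise):
        # spectrum of x should follow S_v(f) |i2pi f - A|^-2 for one node
        x = simulate_neural(np.zeros((1, 1)), quiet_noise, duration=4000, dt=0.05, seed=2)
        n = x.shape[0]
        spec = np.abs(np.fft.rfft(x[:, 0])) ** 2 * 0.05 / n
        f = np.fft.rfftfreq(n, 0.05)
        band = (f > 0.01) & (f < 0.3)
        analytic = (
            quiet_noise.state_amp * f[band] ** -1.0 / ((2 * np.pi * f[band]) ** 2 + 0.25)
        )
        ratio = spec[band] / analytic
        assert np.mean(ratio) == pytest.approx(1.0, abs=0.15)

    def test_unstable_matrix_raises(self):
        with pytest.raises(StabilityError):
            simulate_neural(
                np.array([[0.0, 0.6], [0.6, 0.0]]), NoiseSpec(), 100, 0.05, 0
            )

    def test_stationarity_split_halves(self, quiet_noise):
        x = simulate_neural(np.zeros((2, 2)), quiet_noise, 4000, 0.05, seed=9)
        half = x.shape[0] // 2
        v1, v2 = x[:half].var(axis=0), x[half:].var(axis=0)
        assert np.all(np.abs(v1 - v2) / v2 < 0.5)

    def test_seed_determinism(self, quiet_noise):
        a = simulate_neural(np.zeros((2, 2)), quiet_noise, 100, 0.05, seed=3)
        b = simulate_neural(np.zeros((2, 2)), quiet_noise, 100, 0.05, seed=3)
        assert np.array_equal(a, b)


class TestBalloon:
    def test_rest_maps_to_zero_signal(self):
        y = balloon_bold(np.zeros((100, 2)), dt=0.05)
        assert np.allclose(y, 0.0)

    def test_constant_drive_reaches_steady_state(self):
        h = HemoParams()
        x = np.full((int(120 / 0.05), 1), 0.02)
        balloon_bold(x, h, 0.05)  # integrate to t=120 s
        # re-integrate tracking the final state derivatives
        state = np.stack([np.zeros(1), np.ones(1), np.ones(1), np.ones(1)])
        dt = 0.05
        for k in range(x.shape[0]):
            u = x[k]
            k1 = _balloon_derivs(state, u, h)
            k2 = _balloon_derivs(state + 0.5 * dt * k1, u, h)
            k3 = _balloon_derivs(state + 0.5 * dt * k2, u, h)
            k4 = _balloon_derivs(state + dt * k3, u, h)
            state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        assert np.all(np.abs(_balloon_derivs(state, x[-1], h)) < 1e-6)

    def test_impulse_response_peak_against_fine_grid(self):
        # same piecewise-constant input integrated at dt and dt/25
        dt = 0.05
        T = int(30 / dt)
        x = np.zeros((T, 1))
        x[0, 0] = 1.0 / dt  # unit-area impulse held over one step
        y = balloon_bold(x, dt=dt)[:, 0]
        fine = np.repeat(x, 25, axis=0) / 1.0
        y_fine = balloon_bold(fine, dt=dt / 25)[::25, 0]
        t = np.arange(T) * dt
        peak, peak_fine = y.max(), y_fine.max()
        assert abs(peak - peak_fine) / peak_fine < 0.01
        t_peak = t[np.argmax(y)]
        assert 3.0 < t_peak < 8.0
        assert y[t > t_peak + 2].min() < 0  # post-peak undershoot

    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ValidationError):
            HemoParams(E0=1.5)
        with pytest.raises(ValidationError):
            HemoParams(tau=-1.0)


class TestAcquisition:
    def test_volume_count_matches_request(self, quiet_noise):
        bold = simulate_bold(np.zeros((2, 2)), quiet_noise, 330, 0.05, 1)
        ser, conf = sample_and_corrupt(bold, 2.0, 165, NoiseSpec(), seed=2, dt=0.05)
        assert ser.n_volumes == 165
        assert conf.shape == (165, 15)

    def test_noiseless_equals_decimated(self, quiet_noise):
        bold = simulate_bold(np.zeros((2, 2)), quiet_noise, 330, 0.05, 1)
        ser, _ = sample_and_corrupt(
            bold, 2.0, 165, quiet_noise, seed=2, dt=0.05, confound_leak=0.0
        )
        assert np.allclose(ser.data, bold[: 164 * 40 + 1 : 40])

    def test_confound_regression_reduces_error(self, quiet_noise):
        from longdcm.preprocess import regress_confounds

        bold = simulate_bold(np.zeros((2, 2)), quiet_noise, 330, 0.05, 4)
        clean = bold[: 164 * 40 + 1 : 40]
        noise = NoiseSpec(state_amp=3e-5, obs_amp=0.0, drift_amp=0.0)
        ser, conf = sample_and_corrupt(
            bold, 2.0, 165, noise, seed=5, dt=0.05, confound_leak=0.2
        )
        resid = regress_confounds(ser, conf).data
        mse_with = np.mean((resid - (clean - clean.mean(0))) ** 2)
        mse_without = np.mean((ser.data - clean.mean(0) - (clean - clean.mean(0))) ** 2)
        assert mse_with < mse_without

    def test_cohort_batch_shares_scale_with_single(self, quiet_noise):
        mats = [np.zeros((2, 2)), np.diag([0.1, -0.1])]
        batch = simulate_cohort_bold(mats, quiet_noise, 200, 0.05, seed=3)
        assert batch.shape == (2, int(200 / 0.05), 2)
        single = simulate_bold(mats[0], quiet_noise, 200, 0.05, seed=3)
        assert np.isclose(batch.std(), single.std(), rtol=0.5)


class TestVoxels:
    def test_unit_gains_no_noise_reproduce_series(self, quiet_noise):
        bold = simulate_bold(np.zeros((2, 2)), quiet_noise, 330, 0.05, 1)
        ser, _ = sample_and_corrupt(bold, 2.0, 165, quiet_noise, seed=0, dt=0.05,
                                    confound_leak=0.0)
        blocks = make_voxels(ser, 4, 0.0, seed=0, gains=np.ones(4))
        for j, name in enumerate(ser.region_names):
            assert np.allclose(blocks[name], ser.data[:, [j]])

    def test_two_voxel_rank_one_block(self, quiet_noise):
        bold = simulate_bold(np.zeros((2, 2)), quiet_noise, 330, 0.05, 1)
        ser, _ = sample_and_corrupt(bold, 2.0, 165, quiet_noise, seed=0, dt=0.05,
                                    confound_leak=0.0)
        blocks = make_voxels(ser, 2, 0.0, seed=0, gains=np.array([1.0, 2.0]))
        block = blocks[ser.region_names[0]]
        assert np.allclose(block[:, 1], 2 * block[:, 0])

    def test_minimum_voxels_enforced(self, quiet_noise):
        bold = simulate_bold(np.zeros((2, 2)), quiet_noise, 330, 0.05, 1)
        ser, _ = sample_and_corrupt(bold, 2.0, 165, quiet_noise, seed=0, dt=0.05)
        with pytest.raises(ValidationError):
            make_voxels(ser, 1, 0.1, seed=0)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_noise_spec_validation_is_total(seed):
    # any non-negative amplitudes and exponents in [0,2] are accepted
    rng = np.random.default_rng(seed)
    spec = NoiseSpec(
        state_amp=float(rng.uniform(0, 1)),
        state_exp=float(rng.uniform(0, 2)),
        obs_amp=float(rng.uniform(0, 1)),
        obs_exp=float(rng.uniform(0, 2)),
        drift_amp=float(rng.uniform(0, 1)),
    )
    assert spec.state_amp >= 0


def test_session_series_contract():
    with pytest.raises(ValidationError):
        SessionSeries(data=np.zeros((10, 2)), tr=2.0)  # too short
    with pytest.raises(ValidationError):
        SessionSeries(data=np.full((40, 2), np.nan), tr=2.0)
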