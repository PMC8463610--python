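"""Solver unit tests: linear theory, conservation structure, dealiasing."""

import numpy as np
import pytest
from scipy import fft as sfft

import vortexmelt as vm
from vortexmelt.solver import _workspace


def single_mode_state(params, k, amplitude):
    """State carrying amplitude*cos(k x) as the only vorticity mode."""
    x = np.arange(params.N) * params.dx
    omega = amplitude * np.cos(k * x)[:, None] * np.ones(params.N)[None, :]
    return vm.state_from_vorticity(omega, params)


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"beta": 0.0},
            {"beta": -0.01},
            {"N": 15},
            {"N": 14},
            {"L": -1.0},
            {"dt": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(lambda_adv=1.0, alpha=-0.8, beta=0.01, L=10.0, N=32, dt=0.01)
        base.update(kwargs)
        with pytest.raises(ValueError):
            vm.ModelParams(**base)


class TestLinearGrowthRate:
    def test_plug_in_values(self):
        assert vm.linear_growth_rate(1.0, -0.8) == pytest.approx(0.8)
        assert vm.linear_growth_rate(0.0, -0.8) == pytest.approx(-0.2)

    def test_most_unstable_wavelength_is_two_pi(self):
        k = np.linspace(0.0, 3.0, 30001)
        k_star = k[np.argmax(vm.linear_growth_rate(k, -0.8))]
        assert 2 * np.pi / k_star == pytest.approx(2 * np.pi, rel=1e-3)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            vm.linear_growth_rate(-0.5, -0.8)


class TestInitRandom:
    def test_zero_amplitude_gives_zero_field(self, small_params):
        st = vm.init_random(small_params, seed=0, amplitude=0.0)
        assert np.all(st.omega_hat == 0)
        assert np.all(st.mean_u == 0)

    def test_same_seed_bit_identical(self, small_params):
        a = vm.init_random(small_params, seed=42)
        b = vm.init_random(small_params, seed=42)
        assert np.array_equal(a.omega_hat, b.omega_hat)

    def test_band_limit(self, small_params):
        st = vm.init_random(small_params, seed=1, kmax_band=2.0)
        ws = _workspace(small_params)
        assert np.all(st.omega_hat[ws.k2 > 4.0] == 0)

    def test_rms_amplitude(self, small_params):
        st = vm.init_random(small_params, seed=1, amplitude=0.37)
        omega = vm.vorticity_grid(st, small_params)
        assert np.sqrt(np.mean(omega**2)) == pytest.approx(0.37, rel=1e-12)

    def test_nonpositive_band_rejected(self, small_params):
        with pytest.raises(ValueError):
            vm.init_random(small_params, seed=0, kmax_band=0.0)


class TestStep:
    def test_zero_field_is_fixed_point(self, small_params):
        st = vm.init_random(small_params, seed=0, amplitude=0.0)
        out = vm.step(st, small_params)
        assert np.all(out.omega_hat == 0)
        assert np.all(out.mean_u == 0)
        assert out.t == pytest.approx(small_params.dt)

    @pytest.mark.parametrize("kint", [6, 8, 10, 12, 14])
    def test_dispersion_oracle(self, kint):
        # seeded low-amplitude mode grows at sigma(k) = -(1-k^2)^2 - alpha
        alpha = -0.8
        p = vm.ModelParams(0.0, alpha, 0.01, 20 * np.pi, 64, 0.01)
        k = kint * 0.1
        st = single_mode_state(p, k, 1e-8)
        a0 = np.abs(st.omega_hat).max()
        for _ in range(100):
            st = vm.step(st, p)
        measured = np.log(np.abs(st.omega_hat).max() / a0)
        assert measured == pytest.approx(vm.linear_growth_rate(k, alpha), rel=1e-2)

    def test_mean_flow_fixed_point(self):
        # alpha < -1: |<u>| converges to sqrt(-(1+alpha)/beta)
        p = vm.ModelParams(0.0, -1.2, 0.01, 20 * np.pi, 16, 0.01)
        st = vm.SpectralState(
            np.zeros((16, 9), complex), np.array([1.0, 0.0]), 0.0
        )
        for _ in range(10000):  # t = 100
            st = vm.step(st, p)
        assert np.linalg.norm(st.mean_u) == pytest.approx(np.sqrt(20.0), rel=1e-6)

    def test_nonfinite_state_raises_with_diagnostic(self, small_params):
        st = vm.init_random(small_params, seed=0, amplitude=0.1)
        st.omega_hat[2, 2] = np.nan
        with pytest.raises(vm.BlowupError, match="omega_hat"):
            vm.step(st, small_params)
        st2 = vm.init_random(small_params, seed=0, amplitude=0.1)
        st2.mean_u[0] = np.inf
        with pytest.raises(vm.BlowupError, match="mean_u"):
            vm.step(st2, small_params)

    def test_determinism(self, small_params):
        p = vm.ModelParams(3.0, -0.8, 0.01, small_params.L, 32, 0.01)
        outs = []
        for _ in range(2):
            st = vm.init_random(p, seed=9, amplitude=0.5)
            for _ in range(50):
                st = vm.step(st, p)
            outs.append(st.omega_hat.copy())
        assert np.array_equal(outs[0], outs[1])

    def test_dealiasing_cubic_support(self):
        # with lambda = 0 the only nonlinearity is cubic: starting from
        # modes k1, k2, k3 the increment must live on sums of three of
        # (+-k1, +-k2, +-k3); aliased contributions would fall elsewhere.
        p = vm.ModelParams(0.0, -0.8, 0.01, 2 * np.pi, 32, 1e-4)
        x = np.arange(p.N) * p.dx
        X, Y = np.meshgrid(x, x, indexing="ij")
        omega = (
            np.cos(3 * X) + np.cos(4 * Y) + np.cos(5 * X + 5 * Y)
        )
        st = vm.state_from_vorticity(omega, p)
        n_omega, _, _ = vm.nonlinear_rhs(st, p)
        mags = np.abs(n_omega)
        seeds = [(3, 0), (0, 4), (5, 5)]
        allowed = set()
        for s1 in (1, -1):
            for s2 in (1, -1):
                for s3 in (1, -1):
                    for a in seeds:
                        for b in seeds:
                            for c in seeds:
                                kx = s1 * a[0] + s2 * b[0] + s3 * c[0]
                                ky = s1 * a[1] + s2 * b[1] + s3 * c[1]
                                allowed.add((kx % p.N, ky % p.N))
        tol = 1e-10 * mags.max()
        bad = []
        for i in range(p.N):
            for j in range(p.N // 2 + 1):
                if mags[i, j] > tol and (i, j) not in allowed:
                    # Hermitian partner of an allowed mode is allowed
                    if ((-i) % p.N, (-j) % p.N) not in allowed:
                        bad.append((i, j))
        assert bad == []


class TestRealityConstraint:
    def test_hermitian_symmetry_enforced_along_run(self):
        # the ky=0 column must stay exactly conjugate-symmetric: any
        # defect lives in an invisible subspace that grows at sigma(k)
        p = vm.ModelParams(7.0, -0.8, 0.01, 10 * np.pi, 32, 0.005)
        st = vm.init_random(p, seed=7, amplitude=0.5)
        for _ in range(400):
            st = vm.step(st, p)
        c0 = st.omega_hat[:, 0]
        defect = np.abs(c0 - np.conj(np.roll(c0[::-1], 1))).max()
        assert defect == 0.0

    def test_energy_stays_below_homogeneous_cap(self):
        # dE/dt <= -2 alpha E - beta <|u|^2>^2 caps E at -alpha/(2 beta)
        p = vm.ModelParams(7.0, -0.8, 0.01, 10 * np.pi, 32, 0.005)
        st = vm.init_random(p, seed=8, amplitude=0.5)
        cap = -p.alpha / (2 * p.beta)
        for _ in range(10):
            for _ in range(100):
                st = vm.step(st, p)
            u = vm.velocity_from_vorticity(st, p)
            assert vm.energy_density(u) < cap


class TestVelocityRecovery:
    def test_cos_x_gives_sin_x_flow(self):
        # omega = cos x  =>  u = (0, sin x) under omega = dx u_y - dy u_x
        p = vm.ModelParams(0.0, -0.8, 0.01, 2 * np.pi, 32, 0.01)
        st = single_mode_state(p, 1.0, 1.0)
        u = vm.velocity_from_vorticity(st, p)
        x = np.arange(p.N) * p.dx
        assert np.allclose(u[..., 0], 0.0, atol=1e-12)
        assert np.allclose(u[..., 1], np.sin(x)[:, None], atol=1e-12)

    def test_curl_roundtrip(self, small_params):
        st = vm.init_random(small_params, seed=3, amplitude=1.0)
        u = vm.velocity_from_vorticity(st, small_params)
        ux_hat = sfft.rfft2(u[..., 0])
        uy_hat = sfft.rfft2(u[..., 1])
        ws = _workspace(small_params)
        curl_hat = 1j * ws.KX * uy_hat - 1j * ws.KY * ux_hat
        omega_back = sfft.irfft2(curl_hat, s=(small_params.N, small_params.N))
        omega_in = vm.vorticity_grid(st, small_params)
        assert np.allclose(omega_back, omega_in, atol=1e-10)

    def test_mean_mode(self, small_params):
        st = vm.SpectralState(
            np.zeros((small_params.N, small_params.N // 2 + 1), complex),
            np.array([1.0, 2.0]),
        )
        u = vm.velocity_from_vorticity(st, small_params)
        assert np.allclose(u[..., 0], 1.0)
        assert np.allclose(u[..., 1], 2.0)

    def test_incompressibility(self, small_params):
        p = vm.ModelParams(3.0, -0.8, 0.01, small_params.L, 32, 0.01)
        st = vm.init_random(p, seed=11, amplitude=0.5)
        for _ in range(20):
            st = vm.step(st, p)
        u = vm.velocity_from_vorticity(st, p)
        ws = _workspace(p)
        div_hat = 1j * ws.KX * sfft.rfft2(u[..., 0]) + 1j * ws.KY * sfft.rfft2(
            u[..., 1]
        )
        div = sfft.irfft2(div_hat, s=(p.N, p.N))
        assert np.abs(div).max() < 1e-10


class TestEnergyDensity:
    def test_zero(self):
        assert vm.energy_density(np.zeros((8, 8, 2))) == 0.0

    def test_uniform(self):
        u = np.zeros((8, 8, 2))
        u[..., 0] = 2.0
        assert vm.energy_density(u) == pytest.approx(2.0)

    def test_sinusoidal(self):
        x = np.arange(64) * 2 * np.pi / 64
        u = np.zeros((64, 64, 2))
        u[..., 1] = np.sin(x)[:, None]
        assert vm.energy_density(u) == pytest.approx(0.25)


class TestRun:
    def test_sample_cadence(self, small_params):
        st = vm.init_random(small_params, seed=0, amplitude=0.1)
        n_steps = 20
        es, snaps = vm.run(
            small_params,
            st,
            T_end=n_steps * small_params.dt,
            sample_every=small_params.dt,
        )
        assert len(es.times) == n_steps + 1
        assert snaps[-1].t == pytest.approx(n_steps * small_params.dt)

    def test_invalid_T_end(self, small_params):
        st = vm.init_random(small_params, seed=0, amplitude=0.1)
        with pytest.raises(ValueError):
            vm.run(small_params, st, T_end=0.0, sample_every=0.1)

    def test_blowup_preserves_last_snapshot(self):
        # huge dt at finite amplitude trips the CFL guard
        p = vm.ModelParams(8.0, -0.8, 0.01, 20 * np.pi, 32, 5.0)
        st = vm.init_random(p, seed=0, amplitude=5.0)
        with pytest.raises(vm.BlowupError) as exc:
            vm.run(p, st, T_end=50.0, sample_every=5.0)
        assert exc.value.last_snapshot is not None
        assert np.all(np.isfinite(exc.value.last_snapshot.omega))


class TestUpscale:
    def test_pure_tiling_spectrum_support(self, small_params):
        st = vm.init_random(small_params, seed=4, amplitude=0.5)
        new_state, new_params = vm.upscale(st, small_params, 2, noise_scale=0.0)
        assert new_params.L == pytest.approx(2 * small_params.L)
        assert new_params.N == 2 * small_params.N
        oh = sfft.fft2(vm.vorticity_grid(new_state, new_params))
        mags = np.abs(oh)
        odd = np.ones(new_params.N, dtype=bool)
        odd[::2] = False
        assert mags[odd, :].max() < 1e-9 * mags.max()
        assert mags[:, odd].max() < 1e-9 * mags.max()

    def test_tiled_field_matches_input(self, small_params):
        st = vm.init_random(small_params, seed=4, amplitude=0.5)
        omega = vm.vorticity_grid(st, small_params)
        new_state, new_params = vm.upscale(st, small_params, 2, noise_scale=0.0)
        new_omega = vm.vorticity_grid(new_state, new_params)
        N = small_params.N
        assert np.allclose(new_omega[:N, :N], omega, atol=1e-12)
        assert np.allclose(new_omega[N:, N:], omega, atol=1e-12)

    def test_noise_profile_ratio(self):
        # A(k) = k exp(-(k-4)^2): A(4)/A(2) = 2 e^4
        assert vm.upscale_noise_profile(4.0) / vm.upscale_noise_profile(
            2.0
        ) == pytest.approx(2 * np.exp(4.0))

    def test_output_field_is_real(self, small_params):
        st = vm.init_random(small_params, seed=4, amplitude=0.5)
        new_state, new_params = vm.upscale(st, small_params, 2, noise_scale=0.05, seed=7)
        # irfft2 output is real by construction; verify full Hermitian
        # consistency by comparing against the full complex transform
        omega = vm.vorticity_grid(new_state, new_params)
        oh = sfft.fft2(omega)
        back = sfft.ifft2(oh)
        assert np.abs(back.imag).max() < 1e-12

    def test_negative_noise_rejected(self, small_params):
        st = vm.init_random(small_params, seed=4, amplitude=0.5)
        with pytest.raises(ValueError):
            vm.upscale(st, small_params, 2, noise_scale=-1.0)
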