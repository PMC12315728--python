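import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sgmfmri import (
    FrequencyGrid,
    SGMParams,
    build_laplacian,
    eigendecompose,
    gamma_transfer,
    model_csd,
    model_fc,
    model_psd,
    model_signal_spectrum,
    model_signal_spectrum_alt,
    network_diffusion_fc,
    normalize_connectome,
    simulate_time_domain,
)
from sgmfmri.forward import state_space_frequency_response
from conftest import random_connected_connectome


class TestGammaTransfer:
    def test_dc_gain_is_one(self):
        for tau in (0.5, 1.0, 3.0):
            assert np.isclose(gamma_transfer(0.0, tau), 1.0)

    def test_unit_point(self):
        assert np.isclose(abs(gamma_transfer(1.0, 1.0)), 0.5)

    def test_matches_numerical_fourier_transform(self):
        # trapezoidal integration of f(t) = (t/tau^2) exp(-t/tau), tau = 2
        tau = 2.0
        t = np.linspace(0, 200, 400001)
        f = t / tau**2 * np.exp(-t / tau)
        for omega in (0.1, 0.5, 2.0):
            num = np.trapezoid(f * np.exp(-1j * omega * t), t)
            assert abs(num - gamma_transfer(omega, tau)) < 1e-6

    def test_magnitude_nonincreasing(self):
        omega = np.linspace(0, 10, 200)
        mag = np.abs(gamma_transfer(omega, 1.7))
        assert np.all(np.diff(mag) <= 1e-15)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            gamma_transfer(1.0, 0.0)


class TestSignalSpectrum:
    def test_dense_solve_oracle(self, grid):
        sc = random_connected_connectome(10, seed=7)
        eig = eigendecompose(sc, 0.8)
        params = SGMParams(alpha=0.8, tau=2.0)
        x = model_signal_spectrum(eig, params, grid, include_first_mode=True)
        lap = build_laplacian(sc, 0.8)
        for i, om in enumerate(grid.omega):
            direct = np.linalg.solve(
                1j * om * np.eye(10) + gamma_transfer(om, 2.0) * lap / 2.0,
                np.ones(10),
            )
            assert np.abs(x[:, i] - direct).max() < 1e-10

    def test_linearity_in_driving(self, eig10, grid, params):
        p = np.full(10, 1.0)
        x1 = model_signal_spectrum(eig10, params, grid, driving=p)
        x2 = model_signal_spectrum(eig10, params, grid, driving=2 * p)
        assert np.allclose(x2, 2 * x1)

    def test_single_region_warns_and_returns_zero(self):
        sc = normalize_connectome([[0.0, 1.0], [1.0, 0.0]])
        eig = eigendecompose(sc, 0.5)
        grid = FrequencyGrid(np.array([0.05]))
        weights = np.zeros(2)  # nothing left after dropping the global mode
        with pytest.warns(UserWarning, match="no eigenmodes"):
            x = model_signal_spectrum(eig, SGMParams(alpha=0.5, tau=1.0), grid,
                                      weights=weights)
        assert np.all(x == 0)

    def test_dimension_mismatch(self, eig10, grid, params):
        with pytest.raises(ValueError):
            model_signal_spectrum(eig10, params, grid, weights=np.ones(4))
        with pytest.raises(ValueError):
            model_signal_spectrum(eig10, params, grid, driving=np.ones(7))


class TestThreeParamSpectrum:
    def test_reduces_to_two_param(self, eig10, grid, params):
        x2 = model_signal_spectrum(eig10, params, grid)
        x3 = model_signal_spectrum_alt(eig10, 2.0, 2.0, grid)
        assert np.allclose(x2, x3)

    def test_dense_solve_oracle_split_constants(self, grid):
        sc = random_connected_connectome(8, seed=11)
        tau1, tau2, alpha = 1.5, 3.0, 0.6
        eig = eigendecompose(sc, alpha)
        x = model_signal_spectrum_alt(eig, tau1, tau2, grid,
                                      include_first_mode=True)
        lap = build_laplacian(sc, alpha)
        for i, om in enumerate(grid.omega):
            direct = np.linalg.solve(
                1j * om * np.eye(8) + gamma_transfer(om, tau2) * lap / tau1,
                np.ones(8),
            )
            assert np.abs(x[:, i] - direct).max() < 1e-10

    def test_growing_response_time_attenuates_high_frequencies(self, eig10, grid):
        mags = []
        for tau2 in (1.0, 2.0, 4.0):
            x = model_signal_spectrum_alt(eig10, 2.0, tau2, grid)
            mags.append(np.abs(x[:, -1]).mean())  # highest grid frequency
        assert mags[0] > mags[1] > mags[2]


class TestCSD:
    def test_hermitian_psd_with_real_nonneg_diagonal(self, eig10, grid, params):
        csd = model_csd(eig10, params, grid)
        for i in range(len(grid)):
            sl = csd[:, :, i]
            assert np.abs(sl - sl.conj().T).max() < 1e-12
            assert np.min(np.real(np.diag(sl))) >= -1e-12
            assert np.linalg.eigvalsh(sl).min() > -1e-10

    def test_two_region_hand_computation(self, toy2):
        eig = eigendecompose(toy2, 1.0)
        params = SGMParams(alpha=1.0, tau=1.5)
        om = 2 * np.pi * 0.05
        grid = FrequencyGrid(np.array([0.05]))
        csd = model_csd(eig, params, grid)[:, :, 0]
        # only the k=2 (highest-lambda) mode survives: lambda = 1.5
        lam2 = 1.5
        gamma2 = 1.0 / (1j * om + lam2 * gamma_transfer(om, 1.5) / 1.5)
        u2 = eig.eigenvectors[:, 1]
        assert np.allclose(csd, abs(gamma2) ** 2 * np.outer(u2, u2), atol=1e-12)

    def test_sigma_scaling(self, eig10, grid):
        c1 = model_csd(eig10, SGMParams(alpha=0.8, tau=2.0, sigma=1.0), grid)
        c2 = model_csd(eig10, SGMParams(alpha=0.8, tau=2.0, sigma=2.0), grid)
        assert np.allclose(c2, 4 * c1)


class TestModelFC:
    def test_single_frequency_grid_returns_slice(self, eig10, params):
        grid = FrequencyGrid(np.array([0.05]))
        csd = model_csd(eig10, params, grid)
        fc = model_fc(csd, grid, mode="integral")
        assert np.allclose(fc, np.real(csd[:, :, 0]))

    def test_constant_csd_integrates_to_bandwidth(self):
        grid = FrequencyGrid(np.linspace(0.01, 0.11, 21))
        const = np.ones((3, 3))[:, :, None] * np.ones(21)
        fc = model_fc(const, grid, mode="integral")
        bandwidth = grid.omega[-1] - grid.omega[0]
        assert np.allclose(fc, bandwidth)

    def test_at_peak_requires_grid_point(self, eig10, grid, params):
        csd = model_csd(eig10, params, grid)
        fc = model_fc(csd, grid, mode="at_peak", omega0=grid.omega[5])
        assert np.allclose(fc, np.real(csd[:, :, 5]))
        with pytest.raises(ValueError):
            model_fc(csd, grid, mode="at_peak", omega0=999.0)
        with pytest.raises(ValueError):
            model_fc(csd, grid, mode="at_peak")

    def test_parseval_against_time_domain_covariance(self):
        # white-noise-driven 6-node simulation: zero-lag covariance matches
        # the frequency-integrated model CSD up to a global scale
        sc = random_connected_connectome(6, seed=21)
        from sgmfmri import scale_to_critical_coupling

        sc = scale_to_critical_coupling(sc)
        params = SGMParams(alpha=0.7, tau=1.5)
        eig = eigendecompose(sc, params.alpha)
        dt = 0.05
        x = simulate_time_domain(sc, params, duration=6000.0, dt=dt,
                                 noise_scale=1.0, seed=5, burn_in=60.0)
        # drop the k=1 mode from the data to match the model's mode set
        u1 = eig.eigenvectors[:, 0]
        x = x - np.outer(u1, u1 @ x)
        emp_cov = np.cov(x)
        grid = FrequencyGrid(np.linspace(1e-4, 0.5 / dt, 4001))
        fc = model_fc(model_csd(eig, params, grid), grid, mode="integral")
        iu = np.triu_indices(6, k=1)
        r = np.corrcoef(emp_cov[iu], fc[iu])[0, 1]
        assert r > 0.95


class TestModelPSD:
    def test_modes_nonnegative(self, eig10, grid, params):
        for mode in ("signal_magnitude", "csd_diagonal"):
            psd = model_psd(eig10, params, grid, mode=mode)
            assert psd.shape == (10, len(grid))
            assert np.all(psd >= 0)

    def test_csd_diagonal_expansion_oracle(self, toy2, grid):
        params = SGMParams(alpha=1.0, tau=2.0)
        eig = eigendecompose(toy2, 1.0)
        psd = model_psd(eig, params, grid, mode="csd_diagonal")
        csd = model_csd(eig, params, grid)
        assert np.allclose(psd, np.real(np.einsum("iif->if", csd)))

    def test_sign_flip_invariance(self, sc10, grid, params):
        eig = eigendecompose(sc10, 0.8)
        flipped = eig.with_alpha(0.8)
        flipped.eigenvectors = eig.eigenvectors * -1.0
        a = model_psd(eig, params, grid, mode="signal_magnitude")
        b = model_psd(flipped, params, grid, mode="signal_magnitude")
        assert np.allclose(a, b)

    def test_unknown_mode(self, eig10, grid, params):
        with pytest.raises(ValueError):
            model_psd(eig10, params, grid, mode="nope")


class TestNetworkDiffusion:
    def test_zero_depth_is_identity(self, sc10):
        assert np.allclose(network_diffusion_fc(sc10, 0.0, alpha=0.8), np.eye(10))

    def test_two_node_closed_form(self, toy2):
        t = 0.7
        eig = eigendecompose(toy2, 1.0)
        fc = network_diffusion_fc(eig, t)
        u = eig.eigenvectors
        expected = u @ np.diag(np.exp(-t * np.array([0.5, 1.5]))) @ u.T
        assert np.allclose(fc, expected)

    def test_series_expansion_oracle(self, sc10):
        t = 0.9
        lap = build_laplacian(sc10, 0.8)
        series = np.zeros_like(lap)
        term = np.eye(10)
        for k in range(31):
            series += term
            term = term @ (-t * lap) / (k + 1)
        fc = network_diffusion_fc(sc10, t, alpha=0.8)
        assert np.abs(fc - series).max() < 1e-10

    def test_negative_depth_rejected(self, sc10):
        with pytest.raises(ValueError):
            network_diffusion_fc(sc10, -0.1)


class TestTimeDomain:
    def test_zero_noise_zero_state_stays_zero(self, sc10, params):
        x = simulate_time_domain(sc10, params, duration=5.0, dt=0.1,
                                 noise_scale=0.0, seed=0)
        assert np.all(x == 0)

    def test_frequency_response_probe(self, scaled_sc):
        params = SGMParams(alpha=0.8, tau=2.0)
        lap = build_laplacian(scaled_sc, 0.8)
        omega = 2 * np.pi * np.array([0.01, 0.05, 0.1, 0.2])
        h = state_space_frequency_response(lap, 2.0, omega)
        n = lap.shape[0]
        for i, om in enumerate(omega):
            direct = np.linalg.inv(
                1j * om * np.eye(n) + gamma_transfer(om, 2.0) * lap / 2.0
            )
            assert np.abs(h[:, :, i] - direct).max() < 1e-8

    def test_reproducible_given_seed(self, sc10, params):
        a = simulate_time_domain(sc10, params, 10.0, 0.1, seed=3)
        b = simulate_time_domain(sc10, params, 10.0, 0.1, seed=3)
        assert np.array_equal(a, b)

    def test_free_evolution_matches_matrix_exponential(self, sc10):
        # with the impulse response removed the dynamics reduce to network
        # diffusion dx/dt = -L x / tau, solvable in closed form
        tau = 2.0
        lap = build_laplacian(sc10, 0.8)
        rng = np.random.default_rng(0)
        x0 = rng.standard_normal(10)
        t_end = 3.0
        sol = solve_ivp(lambda t, x: -lap @ x / tau, (0, t_end), x0,
                        rtol=1e-10, atol=1e-12)
        eig = eigendecompose(sc10, 0.8)
        expected = (eig.eigenvectors *
                    np.exp(-t_end * eig.eigenvalues / tau)) @ (
                        eig.eigenvectors.T @ x0)
        assert np.abs(sol.y[:, -1] - expected).max() < 1e-6

    def test_unstable_configuration_reported(self, scaled_sc):
        with pytest.raises(ValueError, match="state eigenvalue|unstable"):
            simulate_time_domain(scaled_sc, SGMParams(alpha=1.3, tau=2.0),
                                 duration=5.0, dt=0.05, seed=0)


def test_region_permutation_equivariance(grid):
    """All model outputs commute with a relabeling of the regions."""
    sc = random_connected_connectome(8, seed=33)
    params = SGMParams(alpha=0.7, tau=2.0)
    rng = np.random.default_rng(1)
    perm = rng.permutation(8)
    from sgmfmri import StructuralConnectome

    sc_p = StructuralConnectome(sc.weights[np.ix_(perm, perm)])
    eig, eig_p = eigendecompose(sc, 0.7), eigendecompose(sc_p, 0.7)
    csd = model_csd(eig, params, grid)
    csd_p = model_csd(eig_p, params, grid)
    assert np.allclose(csd_p, csd[np.ix_(perm, perm)], atol=1e-10)
    psd = model_psd(eig, params, grid, mode="csd_diagonal")
    psd_p = model_psd(eig_p, params, grid, mode="csd_diagonal")
    assert np.allclose(psd_p, psd[perm], atol=1e-10)
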