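"""Closed-form forward model of regional BOLD spectra and frequency-resolved FC.

The signal model couples regional activity through the structural connectome's
Laplacian, filtered by a Gamma-shaped impulse response
``f(t) = (t / tau^2) exp(-t / tau)`` whose Fourier transform is

    F(omega) = 1 / (tau^2 (j omega + 1/tau)^2) = 1 / (1 + j omega tau)^2.

In the Fourier domain the steady-state solution is a sum over Laplacian
eigenmodes,

    X(omega) = sum_k  w_k u_k u_k^H P(omega) / (j omega + lambda_k F(omega)/tau),

with the single most-global (lowest-lambda) mode excluded, and the model
cross-spectral density is ``C_X(omega) = U |Gamma(omega)|^2 U^H`` with mode
gains ``gamma_k = sigma / (j omega + lambda_k F(omega)/tau)``.

A time-domain simulator realizes the same dynamics exactly as a 3N-dimensional
linear state space (the Gamma kernel is a critically damped second-order
filter), serving as the numerical oracle for the closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .connectome import LaplacianEigens, StructuralConnectome, eigendecompose

__all__ = [
    "SGMParams",
    "FrequencyGrid",
    "ModelPrediction",
    "gamma_transfer",
    "model_signal_spectrum",
    "model_signal_spectrum_alt",
    "model_csd",
    "model_fc",
    "model_psd",
    "network_diffusion_fc",
    "simulate_time_domain",
]


@dataclass
class SGMParams:
    """Global model parameters.

    alpha : global coupling constant (unitless, >= 0)
    tau : characteristic neural time constant in seconds (> 0)
    sigma : driving-noise scale (default 1; not identifiable under a
        correlation-based cost, exposed for forward simulation)
    variant : "two_param" or "three_param"
    tau1, tau2 : network-spread and cortical-response time constants for the
        three-parameter variant, seconds
    """

    alpha: float
    tau: float = 2.0
    sigma: float = 1.0
    variant: str = "two_param"
    tau1: float | None = None
    tau2: float | None = None

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.variant not in ("two_param", "three_param"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "two_param":
            if self.tau is None or self.tau <= 0:
                raise ValueError("tau must be > 0")
        else:
            if self.tau1 is None or self.tau2 is None:
                raise ValueError("three_param variant requires tau1 and tau2")
            if self.tau1 <= 0 or self.tau2 <= 0:
                raise ValueError("time constants must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def tau_spread(self) -> float:
        """Time constant of the network-spread (self-decay) term."""
        return self.tau if self.variant == "two_param" else self.tau1

    @property
    def tau_response(self) -> float:
        """Time constant of the Gamma impulse response."""
        return self.tau if self.variant == "two_param" else self.tau2


@dataclass
class FrequencyGrid:
    """Strictly increasing analysis frequencies, Hz, with ``omega = 2 pi f``."""

    frequencies_hz: np.ndarray
    band: tuple | None = None

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a nonempty 1-D array")
        if np.any(f < 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be nonnegative and strictly increasing")
        self.frequencies_hz = f

    @classmethod
    def from_band(cls, f_low: float, f_high: float, n: int = 64) -> "FrequencyGrid":
        return cls(np.linspace(f_low, f_high, n), band=(f_low, f_high))

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequencies_hz

    def __len__(self) -> int:
        return self.frequencies_hz.size

    def index_of(self, omega0: float) -> int:
        """Index of the grid point at angular frequency ``omega0``."""
        i = int(np.argmin(np.abs(self.omega - omega0)))
        if not np.isclose(self.omega[i], omega0, rtol=1e-6, atol=1e-12):
            raise ValueError(f"omega0={omega0} is not on the frequency grid")
        return i


@dataclass
class ModelPrediction:
    """Bundle of forward-model outputs on a frequency grid."""

    grid: FrequencyGrid
    signal_spectrum: np.ndarray | None = None  # complex (N, F)
    psd: np.ndarray | None = None              # (N, F), nonnegative
    csd: np.ndarray | None = None              # complex (N, N, F), Hermitian slices
    fc: np.ndarray | None = None               # (N, N)
    params: SGMParams | None = None
    extras: dict = field(default_factory=dict)


def gamma_transfer(omega, tau: float):
    """Fourier transform of the Gamma impulse response ``t/tau^2 e^(-t/tau)``.

    ``F(omega) = 1 / (1 + j omega tau)^2``; equals 1 at omega = 0 and its
    magnitude decreases monotonically with |omega|.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    omega = np.asarray(omega, dtype=float)
    out = 1.0 / (1.0 + 1j * omega * tau) ** 2
    return out if out.ndim else complex(out)


def _mode_gains(
    eigens: LaplacianEigens,
    tau_spread: float,
    tau_response: float,
    grid: FrequencyGrid,
):
    """Per-mode complex denominators ``j omega + lambda_k F(omega)/tau`` (K, F)."""
    omega = grid.omega[None, :]
    lam = eigens.eigenvalues[:, None]
    f_resp = gamma_transfer(grid.omega, tau_response)[None, :]
    return 1j * omega + lam * f_resp / tau_spread


def _prepare_weights(weights, n: int, include_first_mode: bool) -> np.ndarray:
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError(f"weights must have length {n}, got {w.shape}")
        if np.any(w < 0):
            raise ValueError("eigenmode weights must be >= 0")
        w = w.copy()
    if not include_first_mode:
        w[0] = 0.0  # drop the most-global, lowest-lambda mode
    return w


def _signal_spectrum(
    eigens: LaplacianEigens,
    tau_spread: float,
    tau_response: float,
    grid: FrequencyGrid,
    weights=None,
    driving=None,
    include_first_mode: bool = False,
) -> np.ndarray:
    n = eigens.n_regions
    u = eigens.eigenvectors
    w = _prepare_weights(weights, n, include_first_mode)
    if np.all(w == 0):
        warnings.warn(
            "no eigenmodes contribute to the signal spectrum (N=1 or all "
            "weights zero); returning zeros",
            stacklevel=3,
        )
        return np.zeros((n, len(grid)), dtype=complex)
    if driving is None:
        p = np.ones(n)
    else:
        p = np.asarray(driving)
        if p.shape not in ((n,), (n, len(grid))):
            raise ValueError(
                f"driving must have shape ({n},) or ({n}, {len(grid)})"
            )
    denom = _mode_gains(eigens, tau_spread, tau_response, grid)  # (K, F)
    proj = u.T @ p  # (K,) or (K, F)
    if proj.ndim == 1:
        proj = proj[:, None]
    return u @ (w[:, None] * proj / denom)


def model_signal_spectrum(
    eigens: LaplacianEigens,
    params: SGMParams,
    grid: FrequencyGrid,
    weights=None,
    driving=None,
    include_first_mode: bool = False,
) -> np.ndarray:
    """Closed-form eigenmode solution of the signal spectrum, complex (N, F).

    ``driving`` defaults to a vector of ones (uniform stimulation / white
    noise).  ``weights`` scales each mode's outer-product term; the lowest-
    lambda mode is excluded unless ``include_first_mode``.  The eigenvalues
    are re-evaluated at ``params.alpha`` (the eigenvectors do not depend on
    it).
    """
    eigens = eigens.with_alpha(params.alpha)
    return _signal_spectrum(
        eigens, params.tau_spread, params.tau_response, grid,
        weights=weights, driving=driving, include_first_mode=include_first_mode,
    )


def model_signal_spectrum_alt(
    eigens: LaplacianEigens,
    tau1: float,
    tau2: float,
    grid: FrequencyGrid,
    weights=None,
    driving=None,
    include_first_mode: bool = False,
) -> np.ndarray:
    """Three-parameter variant: spread constant ``tau1``, response ``tau2``.

    Reduces exactly to the two-parameter spectrum when ``tau1 == tau2``.
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("time constants must be > 0")
    return _signal_spectrum(
        eigens, tau1, tau2, grid,
        weights=weights, driving=driving, include_first_mode=include_first_mode,
    )


def _csd_mode_power(
    eigens: LaplacianEigens,
    params: SGMParams,
    grid: FrequencyGrid,
    weights=None,
    include_first_mode: bool = False,
) -> np.ndarray:
    """Per-mode CSD eigenvalues ``w_k^2 |gamma_k(omega)|^2`` (K, F)."""
    eigens = eigens.with_alpha(params.alpha)
    w = _prepare_weights(weights, eigens.n_regions, include_first_mode)
    denom = _mode_gains(eigens, params.tau_spread, params.tau_response, grid)
    return (w[:, None] ** 2) * (params.sigma**2) / np.abs(denom) ** 2


def model_csd(
    eigens: LaplacianEigens,
    params: SGMParams,
    grid: FrequencyGrid,
    weights=None,
    include_first_mode: bool = False,
) -> np.ndarray:
    """Model cross-spectral density stack, complex (N, N, F).

    Each frequency slice is ``U diag(w^2 |gamma|^2 sigma^2) U^T`` — Hermitian
    positive semidefinite with a real nonnegative diagonal.
    """
    u = eigens.eigenvectors
    g2 = _csd_mode_power(eigens, params, grid, weights, include_first_mode)
    return np.einsum("nk,kf,mk->nmf", u, g2, u, optimize=True).astype(complex)


def model_fc(
    csd_stack: np.ndarray,
    grid: FrequencyGrid,
    mode: str = "integral",
    omega0: float | None = None,
) -> np.ndarray:
    """Collapse a CSD stack to a single N-by-N FC matrix.

    mode="integral" : trapezoidal integral over omega of the real part (the
        zero-lag FC).  A single-frequency grid returns that slice unscaled.
    mode="at_peak" : real part of the slice at ``omega0`` (must lie on the
        grid), the subject's peak-energy frequency.
    """
    real = np.real(csd_stack)
    if mode == "at_peak":
        if omega0 is None:
            raise ValueError("mode='at_peak' requires omega0")
        return real[:, :, grid.index_of(omega0)]
    if mode == "integral":
        if len(grid) == 1:
            return real[:, :, 0]
        return np.trapezoid(real, x=grid.omega, axis=-1)
    raise ValueError(f"unknown FC mode {mode!r}")


def model_psd(
    eigens: LaplacianEigens,
    params: SGMParams,
    grid: FrequencyGrid,
    weights=None,
    mode: str = "signal_magnitude",
    include_first_mode: bool = False,
) -> np.ndarray:
    """Model power spectrum per region, (N, F), nonnegative.

    mode="signal_magnitude" : ``|X(omega)|`` under uniform driving P = 1
        (amplitude units; the best-performing definition).
    mode="csd_diagonal" : ``diag(C_X(omega))`` (power units).
    """
    if mode == "signal_magnitude":
        x = model_signal_spectrum(
            eigens, params, grid, weights=weights,
            include_first_mode=include_first_mode,
        )
        return np.abs(x)
    if mode == "csd_diagonal":
        g2 = _csd_mode_power(eigens, params, grid, weights, include_first_mode)
        return (eigens.eigenvectors**2) @ g2
    raise ValueError(f"unknown PSD mode {mode!r}")


def network_diffusion_fc(
    sc: StructuralConnectome | LaplacianEigens,
    t_over_tau: float,
    alpha: float = 1.0,
) -> np.ndarray:
    """Network-diffusion benchmark FC: ``exp(-t/tau * L(alpha))``.

    The diffusion depth ``t_crit / tau`` is a single lumped free parameter,
    empirically inferred.  Reduces to the identity at ``t_over_tau = 0``.
    """
    if t_over_tau < 0:
        raise ValueError("t_over_tau must be >= 0")
    if isinstance(sc, LaplacianEigens):
        eig = sc
    else:
        eig = eigendecompose(sc, alpha)
    u = eig.eigenvectors
    return (u * np.exp(-t_over_tau * eig.eigenvalues)) @ u.T


def _state_matrix(lap: np.ndarray, tau: float) -> np.ndarray:
    """3N-dimensional state matrix realizing the Gamma-kernel convolution.

    With y = f * (L x) (the kernel is a critically damped second-order
    filter), the dynamics are
        dx/dt = -y / tau + p
        dy/dt = v
        dv/dt = -(2/tau) v - y / tau^2 + (L x) / tau^2
    """
    n = lap.shape[0]
    z = np.zeros((n, n))
    i = np.eye(n)
    return np.block([
        [z, -i / tau, z],
        [z, z, i],
        [lap / tau**2, -i / tau**2, -2.0 * i / tau],
    ])


def state_space_frequency_response(
    lap: np.ndarray, tau: float, omega: np.ndarray
) -> np.ndarray:
    """Transfer p -> x of the 3N state space, (N, N, F).

    Equals ``(j omega I + F(omega) L / tau)^{-1}`` analytically; used to
    cross-check the realization.
    """
    n = lap.shape[0]
    a = _state_matrix(lap, tau)
    b = np.zeros((3 * n, n))
    b[:n, :] = np.eye(n)
    omega = np.atleast_1d(np.asarray(omega, float))
    out = np.empty((n, n, omega.size), dtype=complex)
    for i, w in enumerate(omega):
        h = np.linalg.solve(1j * w * np.eye(3 * n) - a, b)
        out[:, :, i] = h[:n, :]
    return out


def simulate_time_domain(
    sc: StructuralConnectome | LaplacianEigens,
    params: SGMParams,
    duration: float,
    dt: float,
    noise_scale: float = 1.0,
    seed=None,
    x0: np.ndarray | None = None,
    burn_in: float = 0.0,
) -> np.ndarray:
    """Integrate the stochastic signal model; returns x sampled at dt, (N, T).

    The convolutional dynamics are realized exactly as a 3N-dimensional linear
    state space advanced by the matrix exponential ``expm(A dt)`` per step,
    with white driving noise of standard deviation ``noise_scale`` injected
    into the x-block (exponential-Euler scheme, first-order accurate in the
    noise).  Deterministic given ``seed``.
    """
    if params.variant != "two_param":
        raise NotImplementedError("time-domain simulator covers the two-parameter model")
    if isinstance(sc, LaplacianEigens):
        lap = sc.with_alpha(params.alpha).laplacian()
    else:
        lap = eigendecompose(sc, params.alpha).laplacian()
    tau = params.tau
    a = _state_matrix(lap, tau)
    eig_a = np.linalg.eigvals(a)
    worst = eig_a[np.argmax(eig_a.real)]
    if worst.real > 1e-9:
        raise ValueError(
            f"unstable configuration: state eigenvalue {worst} has positive real part"
        )
    n = lap.shape[0]
    ad = expm(a * dt)
    rng = np.random.default_rng(seed)
    n_burn = int(round(burn_in / dt))
    n_keep = int(round(duration / dt))
    z = np.zeros(3 * n)
    if x0 is not None:
        z[:n] = np.asarray(x0, float)
    out = np.empty((n, n_keep))
    amp = noise_scale * np.sqrt(dt)
    for t in range(n_burn + n_keep):
        z = ad @ z
        if noise_scale > 0:
            z[:n] += amp * rng.standard_normal(n)
        if not np.isfinite(z[0]):
            raise ValueError(
                f"simulation diverged at step {t}; slowest-decaying state "
                f"eigenvalue {worst}"
            )
        if t >= n_burn:
            out[:, t - n_burn] = z[:n]
    return out
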