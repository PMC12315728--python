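"""Synthetic connectomes and BOLD cohorts with known ground truth.

The generator emulates the two inputs the analysis consumes: (a) modular,
hemispherically organized weighted connectomes with log-normal edge weights
concentrated within modules (so several community eigenmodes sit near the
spectral radius, as in real streamline-weighted connectomes), and (b)
regional BOLD series produced by the model's own dynamics driven by white
noise, downsampled to a repetition time and corrupted by additive
observation noise.  Every draw is reproducible from a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import (
    StructuralConnectome,
    eigendecompose,
    normalize_connectome,
    scale_to_critical_coupling,
)
from .features import RegionalTimeSeries
from .forward import FrequencyGrid, SGMParams, model_signal_spectrum, simulate_time_domain

__all__ = [
    "SyntheticCohortSpec",
    "Cohort",
    "synthetic_connectome",
    "synthetic_bold",
    "fixture_cohort",
]


@dataclass
class SyntheticCohortSpec:
    """Stated world of the default synthetic cohort.

    Defaults: 30 regions in two hemispheres, 20 subjects, TR 0.6 s, 600
    samples — small enough for minutes-scale runs, long enough for Welch
    averaging.  Subject couplings are centered on the cohort-level values
    reported for real data (alpha ~ 0.8 of critical, tau ~ 2 s), with a
    ground-truth spread wide enough (alpha_sd 0.15) that a recovery
    regression across subjects is statistically meaningful, clipped to a
    stable simulator regime.  Observation noise is a fraction of each
    region's signal standard deviation (0.2, typical for ROI-level BOLD).
    """

    n_subjects: int = 20
    n_regions: int = 30
    module_count: int = 3           # modules per hemisphere
    p_within: float = 0.9
    p_between: float = 0.08
    weight_mu: float = 0.0          # log-normal location of background edges
    weight_sigma: float = 0.8
    module_boost: float = 1.5       # extra log-weight of within-module edges
    alpha_mean: float = 0.8
    alpha_sd: float = 0.15
    alpha_range: tuple = (0.4, 0.92)  # alpha >= 1 destabilizes the k=1 mode
    tau_mean: float = 2.0
    tau_sd: float = 0.5
    tau_range: tuple = (0.8, 4.0)
    tr: float = 0.6
    n_timepoints: int = 600
    noise_sd: float = 0.2           # fraction of per-region signal SD
    master_seed: int = 0

    def __post_init__(self):
        if self.n_regions < 6 or self.n_regions % 2:
            raise ValueError("n_regions must be even and >= 6")
        for p in (self.p_within, self.p_between):
            if not 0 < p <= 1:
                raise ValueError("edge densities must lie in (0, 1]")
        if self.alpha_sd < 0 or self.tau_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class Cohort:
    """Bundle of independent subject draws plus group-level summaries."""

    spec: SyntheticCohortSpec
    connectomes: list
    bold: list
    truth: pd.DataFrame          # subject, alpha, tau, seed
    group_sc: StructuralConnectome
    group_fc: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def synthetic_connectome(
    spec: SyntheticCohortSpec | None = None, seed=None
) -> StructuralConnectome:
    """Two-hemisphere modular weighted graph, connected and sum-normalized.

    Region ``i`` in the left hemisphere is homologous to ``i + N/2`` and
    shares its module; within-module edges are dense (``p_within``) and carry
    ``module_boost`` extra log-weight, so module eigenmodes dominate the
    spectrum as community structure does in real connectomes.  Homologous
    pairs are frequently connected; a weak spanning backbone guarantees
    a single component.
    """
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(seed)
    n = spec.n_regions
    half = n // 2
    modules = np.tile(np.arange(half) % spec.module_count, 2)
    hemi = np.repeat([0, 1], half)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same_hemi = hemi[i] == hemi[j]
            same_module = modules[i] == modules[j]
            if same_module:
                if same_hemi:
                    p, mu = spec.p_within, spec.weight_mu + spec.module_boost
                else:
                    p, mu = 0.5 * spec.p_within, spec.weight_mu + 0.7 * spec.module_boost
            elif same_hemi:
                p, mu = spec.p_between, spec.weight_mu
            else:
                p, mu = 0.3 * spec.p_between, spec.weight_mu
            if rng.random() < p:
                w[i, j] = w[j, i] = rng.lognormal(mu, spec.weight_sigma)
    homologs = [(i, i + half) for i in range(half)]
    for i, j in homologs:
        if rng.random() < 0.7:
            w[i, j] = w[j, i] = rng.lognormal(
                spec.weight_mu + spec.module_boost, spec.weight_sigma
            )
    # weak spanning backbone guarantees connectivity
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        if w[a, b] == 0:
            w[a, b] = w[b, a] = rng.lognormal(
                spec.weight_mu - 2.0, spec.weight_sigma
            )
    labels = [f"L{i}" for i in range(half)] + [f"R{i}" for i in range(half)]
    adjacency = [(i, i + 1) for i in range(half - 1)] + [
        (half + i, half + i + 1) for i in range(half - 1)
    ]
    return normalize_connectome(w, labels, homolog_map=homologs, adjacency_map=adjacency)


def synthetic_bold(
    sc: StructuralConnectome,
    params: SGMParams,
    tr: float,
    n_timepoints: int,
    noise_sd: float = 0.2,
    seed=None,
    oversample: int = 5,
    backend: str = "state_space",
    mode_weights=None,
) -> RegionalTimeSeries:
    """BOLD series generated by the model at known ground-truth parameters.

    The connectome is first scaled to unit spectral radius, so ``params.alpha``
    is a fraction of the critical coupling.  backend="state_space" integrates
    the stochastic differential model at ``dt = tr / oversample`` (burn-in of
    30 tau discarded) and decimates to the repetition time; it contains all
    eigenmodes including the global k=1 mode.  backend="spectral" synthesizes
    a stationary Gaussian series directly from the closed-form transfer
    function on the FFT grid — the only route that supports nonuniform
    eigenmode participation via ``mode_weights`` (the k=1 mode is excluded
    unless explicitly weighted).  i.i.d. observation noise with standard
    deviation ``noise_sd x per-region signal SD`` is added last.
    """
    rng = np.random.default_rng(seed)
    sc = scale_to_critical_coupling(sc)
    if backend == "state_space":
        if mode_weights is not None:
            raise ValueError("mode_weights require backend='spectral'")
        dt = tr / oversample
        x = simulate_time_domain(
            sc, params,
            duration=n_timepoints * tr,
            dt=dt,
            noise_scale=1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
            burn_in=30.0 * params.tau_spread,
        )
        data = x[:, ::oversample][:, :n_timepoints]
    elif backend == "spectral":
        data = _spectral_synthesis(sc, params, tr, n_timepoints, rng, mode_weights)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    if noise_sd > 0:
        sd = data.std(axis=1, keepdims=True)
        data = data + noise_sd * sd * rng.standard_normal(data.shape)
    return RegionalTimeSeries(data, tr, list(sc.region_labels))


def _spectral_synthesis(sc, params, tr, n_timepoints, rng, mode_weights):
    """Stationary Gaussian synthesis: X(omega) = H_w(omega) P(omega), irfft."""
    t_up = 4 * n_timepoints  # long circulant embedding, then crop
    freqs = np.fft.rfftfreq(t_up, d=tr)
    grid = FrequencyGrid(freqs[1:])  # omega=0 carries no power (zero mean)
    eig = eigendecompose(sc, params.alpha)
    n = sc.n_regions
    p = rng.standard_normal((n, len(grid))) + 1j * rng.standard_normal((n, len(grid)))
    x = model_signal_spectrum(eig, params, grid, weights=mode_weights, driving=p)
    spec = np.zeros((n, freqs.size), dtype=complex)
    spec[:, 1:] = x
    data = np.fft.irfft(spec, n=t_up, axis=1)
    data *= np.sqrt(t_up / (2.0 * tr))  # unit-density white driving
    start = rng.integers(0, t_up - n_timepoints)
    return data[:, start:start + n_timepoints]


def fixture_cohort(spec: SyntheticCohortSpec | None = None, mode_weights=None) -> Cohort:
    """Draw a full cohort: per-subject connectome, parameters, and BOLD.

    Also computes the group-mean connectome (renormalized element-wise mean)
    used for group-level graph Fourier weights, and a truth table of the
    generating ``(alpha, tau)`` per subject.  All randomness derives from
    ``spec.master_seed``.  Passing ``mode_weights`` switches generation to
    the spectral backend so eigenmode participation can be nonuniform.
    """
    spec = spec or SyntheticCohortSpec()
    root = np.random.default_rng(spec.master_seed)
    scs, bolds, rows = [], [], []
    for s in range(spec.n_subjects):
        seed_sc, seed_par, seed_bold = root.integers(0, 2**31 - 1, size=3)
        sc = synthetic_connectome(spec, seed=int(seed_sc))
        prng = np.random.default_rng(int(seed_par))
        # stability of the Gamma-filtered dynamics needs lambda = 1 - alpha*mu
        # < 2 for every eigenvalue; keep a margin below that critical alpha
        mu = np.linalg.eigvalsh(scale_to_critical_coupling(sc).weights)
        alpha_stable = 0.85 / abs(mu.min())
        alpha = float(np.clip(
            prng.normal(spec.alpha_mean, spec.alpha_sd),
            spec.alpha_range[0], min(spec.alpha_range[1], alpha_stable),
        ))
        tau = float(np.clip(
            prng.normal(spec.tau_mean, spec.tau_sd), *spec.tau_range
        ))
        params = SGMParams(alpha=alpha, tau=tau)
        backend = "spectral" if mode_weights is not None else "state_space"
        ts = synthetic_bold(
            sc, params, spec.tr, spec.n_timepoints,
            noise_sd=spec.noise_sd, seed=int(seed_bold),
            backend=backend, mode_weights=mode_weights,
        )
        scs.append(sc)
        bolds.append(ts)
        rows.append({"subject": s, "alpha": alpha, "tau": tau, "seed": int(seed_bold)})
    mean_w = np.mean([sc.weights for sc in scs], axis=0)
    group_sc = normalize_connectome(
        mean_w, scs[0].region_labels, scs[0].homolog_map, scs[0].adjacency_map
    )
    from .features import pearson_fc

    group_fc = np.mean([pearson_fc(ts) for ts in bolds], axis=0)
    return Cohort(
        spec=spec,
        connectomes=scs,
        bold=bolds,
        truth=pd.DataFrame(rows),
        group_sc=group_sc,
        group_fc=group_fc,
    )
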