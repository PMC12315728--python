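"""Empirical spectral and connectivity features of regional BOLD time series.

Everything the generative model is fit against lives here: bandpassed series,
Pearson functional connectivity, percolation-thresholded FC, Welch
cross-spectral density and PSD, the peak-energy frequency omega0, graph
Fourier weights of the FC matrix, and the cross-correlation lag profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.sparse.csgraph import connected_components

from .forward import FrequencyGrid

__all__ = [
    "RegionalTimeSeries",
    "SpectralFeatures",
    "EigenWeightsResult",
    "bandpass",
    "pearson_fc",
    "percolation_threshold",
    "cross_spectral_density",
    "peak_frequency",
    "graph_fourier_weights",
    "cross_correlation_profile",
    "remove_global_pc",
    "extract_features",
]


@dataclass
class RegionalTimeSeries:
    """BOLD series, regions by samples, with repetition time in seconds."""

    data: np.ndarray
    tr: float
    region_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be > 0 seconds")
        if self.data.shape[1] <= 2:
            raise ValueError("need more than 2 time points")
        if not self.region_labels:
            self.region_labels = [f"region_{i}" for i in range(self.n_regions)]

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr


@dataclass
class SpectralFeatures:
    """Model-facing empirical features of one subject's BOLD recording."""

    fc: np.ndarray                       # Pearson, (N, N)
    fc_thresholded: np.ndarray           # sub-threshold entries zeroed
    percolation_value: float
    csd: np.ndarray                      # Hermitian stack, (N, N, F)
    psd: np.ndarray                      # real diag of csd, (N, F)
    omega0: float                        # peak angular frequency, rad/s
    grid: FrequencyGrid
    fc_peak: np.ndarray | None = None            # real CSD slice at omega0
    fc_peak_thresholded: np.ndarray | None = None


@dataclass
class EigenWeightsResult:
    """Graph Fourier projection of FC and the per-mode weights derived from it."""

    projection: np.ndarray  # Q = U^H FC U
    gfw: np.ndarray         # |diag(Q)|, rescaled to max 1
    source: str             # "individual" | "group_mean"


def bandpass(ts: RegionalTimeSeries, f_low: float, f_high: float) -> RegionalTimeSeries:
    """Zero-phase Butterworth bandpass (order 2 per direction), mean removed.

    ``0 <= f_low < f_high <= Nyquist``; ``f_low = 0`` degenerates to a
    lowpass.  Constant series map to zero (DC removal).
    """
    nyq = ts.nyquist_hz
    if not (0 <= f_low < f_high):
        raise ValueError("need 0 <= f_low < f_high")
    if f_high > nyq + 1e-12:
        raise ValueError(
            f"f_high={f_high} Hz exceeds the Nyquist limit {nyq} Hz (tr={ts.tr} s)"
        )
    x = ts.data - ts.data.mean(axis=1, keepdims=True)
    if f_low > 0:
        sos = sps.butter(2, [f_low, f_high], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    else:
        sos = sps.butter(2, f_high, btype="lowpass", fs=1.0 / ts.tr, output="sos")
    return RegionalTimeSeries(
        sps.sosfiltfilt(sos, x, axis=1), ts.tr, list(ts.region_labels)
    )


def pearson_fc(ts: RegionalTimeSeries) -> np.ndarray:
    """Pearson correlation between regional time series, symmetric, diag 1."""
    sd = ts.data.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.region_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance region(s): {bad}")
    fc = np.corrcoef(ts.data)
    return 0.5 * (fc + fc.T)


def _is_connected(mask: np.ndarray) -> bool:
    return connected_components(mask, directed=False)[0] == 1


def percolation_threshold(fc: np.ndarray):
    """Largest edge-magnitude cutoff at which the FC graph stays connected.

    Operates on off-diagonal magnitudes ``|fc_ij|``; the threshold is the
    bottleneck weight of the maximum spanning tree, found here by bisection
    over the sorted distinct magnitudes with a connectivity check.  Returns
    ``(threshold, thresholded)`` where sub-threshold entries are zeroed,
    signed values at/above it kept, and the diagonal preserved.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError("FC must be square")
    if not np.allclose(fc, fc.T, atol=1e-10):
        raise ValueError("FC must be symmetric")
    mag = np.abs(fc).copy()
    np.fill_diagonal(mag, 0.0)
    if not _is_connected(mag > 0):
        raise ValueError("FC graph is disconnected before thresholding")
    levels = np.unique(mag[mag > 0])
    # connectivity at cutoff levels[i] is monotone: find last connected level
    lo, hi = 0, levels.size - 1
    if _is_connected(mag >= levels[hi]):
        lo = hi
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _is_connected(mag >= levels[mid]):
            lo = mid
        else:
            hi = mid - 1
    threshold = float(levels[lo])
    out = np.where(mag >= threshold, fc, 0.0)
    np.fill_diagonal(out, np.diag(fc))
    return threshold, out


def cross_spectral_density(
    ts: RegionalTimeSeries,
    segment_length: int | None = None,
    overlap: float = 0.5,
    band: tuple | None = None,
):
    """Welch-averaged cross-spectral density, Hann taper, (N, N, F) + grid.

    Defaults: ``segment_length = min(T, 64)`` samples, 50% overlap,
    per-segment mean removal.  One-sided density scaling, so the PSD
    integrates to the signal variance (Parseval).  ``band`` restricts the
    returned grid to ``(f_low, f_high)`` in Hz.
    """
    t = ts.n_samples
    if segment_length is None:
        segment_length = min(t, 64)
    if segment_length < 8:
        raise ValueError("segment_length must be >= 8 samples")
    if segment_length > t:
        raise ValueError(f"segment_length={segment_length} exceeds series length {t}")
    nover = int(overlap * segment_length)
    freqs, csd = sps.csd(
        ts.data[:, None, :],
        ts.data[None, :, :],
        fs=1.0 / ts.tr,
        window="hann",
        nperseg=segment_length,
        noverlap=nover,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    # enforce exact Hermitian symmetry of each slice
    csd = 0.5 * (csd + np.conj(np.swapaxes(csd, 0, 1)))
    if band is not None:
        keep = (freqs >= band[0]) & (freqs <= band[1])
        if not np.any(keep):
            raise ValueError(f"band {band} contains no Welch frequencies")
        freqs, csd = freqs[keep], csd[:, :, keep]
    return csd, FrequencyGrid(freqs, band=band)


def peak_frequency(csd: np.ndarray, grid: FrequencyGrid) -> float:
    """Angular frequency maximizing the pairwise (off-diagonal) sum of |CSD|.

    Ties resolve to the lowest frequency, where BOLD energy concentrates.
    """
    if csd.ndim != 3 or csd.shape[2] != len(grid):
        raise ValueError("csd stack and grid are inconsistent")
    n = csd.shape[0]
    iu = np.triu_indices(n, k=1)
    sums = np.abs(csd[iu[0], iu[1], :]).sum(axis=0)
    return float(grid.omega[int(np.argmax(sums))])


def graph_fourier_weights(fc, u: np.ndarray, rescale: bool = True) -> EigenWeightsResult:
    """Graph Fourier weights: project FC onto the Laplacian eigenbasis.

    ``Q = U^H FC U``; the magnitude of each diagonal entry measures how
    strongly that eigenmode participates in empirical FC.  Pass a list of FC
    matrices to use the cohort element-wise mean (with the mean SC's U) —
    the weights are stable across individuals, so group-mean weights are
    precomputed once and reused.  Rescaled to max 1 by default (only relative
    weights matter under a correlation cost).
    """
    if isinstance(fc, (list, tuple)):
        fc_mat = np.mean([np.asarray(f, float) for f in fc], axis=0)
        source = "group_mean"
    else:
        fc_mat = np.asarray(fc, dtype=float)
        source = "individual"
    if fc_mat.shape != (u.shape[0], u.shape[0]):
        raise ValueError(
            f"FC shape {fc_mat.shape} does not match eigenvector basis {u.shape}"
        )
    q = u.conj().T @ fc_mat @ u
    gfw = np.abs(np.diag(q))
    if rescale and gfw.max() > 0:
        gfw = gfw / gfw.max()
    return EigenWeightsResult(projection=q, gfw=gfw, source=source)


def cross_correlation_profile(ts: RegionalTimeSeries, max_lag: int):
    """Normalized cross-correlation over lags 0..max_lag, pooled over sign.

    For each region pair the profile at lag l is the larger of the two signed
    directions (the function is symmetric in expectation, so pooled |lag|
    captures the peak).  Returns ``(profiles (N, N, L+1), argmax-lag matrix,
    histogram of argmax lags over distinct pairs)``.
    """
    if max_lag >= ts.n_samples // 2:
        raise ValueError("max_lag must be < T/2")
    x = ts.data - ts.data.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.region_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance region(s): {bad}")
    x = x / sd[:, None]
    t = ts.n_samples
    n = ts.n_regions
    nfft = int(2 ** np.ceil(np.log2(2 * t)))
    fx = np.fft.rfft(x, n=nfft, axis=1)
    prof = np.empty((n, n, max_lag + 1))
    for i in range(n):
        cc = np.fft.irfft(fx[i][None, :] * np.conj(fx), n=nfft, axis=1) / t
        pos = cc[:, : max_lag + 1]            # x_i leads by l
        neg = np.concatenate([cc[:, :1], cc[:, -max_lag:][:, ::-1]], axis=1)
        prof[i] = np.maximum(pos, neg)
    argmax = prof.argmax(axis=2)
    iu = np.triu_indices(n, k=1)
    hist = np.bincount(argmax[iu], minlength=max_lag + 1)
    return prof, argmax, hist


def remove_global_pc(ts: RegionalTimeSeries) -> RegionalTimeSeries:
    """Remove the first principal component from all regions (GSR surrogate)."""
    x = ts.data - ts.data.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    pc = vt[0]
    x = x - np.outer(x @ pc, pc)
    return RegionalTimeSeries(x, ts.tr, list(ts.region_labels))


def extract_features(
    ts: RegionalTimeSeries,
    band: tuple = (0.01, 0.25),
    segment_length: int | None = None,
    overlap: float = 0.5,
    apply_bandpass: bool = True,
) -> SpectralFeatures:
    """Full feature set used by the fitting layer, from one BOLD recording."""
    f_high = min(band[1], ts.nyquist_hz)
    work = bandpass(ts, band[0], f_high) if apply_bandpass else ts
    fc = pearson_fc(work)
    thr, fc_thr = percolation_threshold(fc)
    csd, grid = cross_spectral_density(
        work, segment_length=segment_length, overlap=overlap, band=(band[0], f_high)
    )
    psd = np.real(np.einsum("iif->if", csd))
    omega0 = peak_frequency(csd, grid)
    fc_peak = np.real(csd[:, :, grid.index_of(omega0)])
    _, fc_peak_thr = percolation_threshold(0.5 * (fc_peak + fc_peak.T))
    return SpectralFeatures(
        fc=fc,
        fc_thresholded=fc_thr,
        percolation_value=thr,
        csd=csd,
        psd=psd,
        omega0=omega0,
        grid=grid,
        fc_peak=fc_peak,
        fc_peak_thresholded=fc_peak_thr,
    )
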