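"""Randomization controls: rewired connectomes and region-permuted series.

Two nulls probe whether model fits are specific to the structural network:
degree-preserving (Maslov-Sneppen) rewiring of the connectome with a
connectivity guarantee, and uniform random permutation of the BOLD region
ordering.  Fit-metric distributions under the nulls are compared with the
true fits by two-sample two-tailed t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .connectome import (
    StructuralConnectome,
    eigendecompose,
    normalize_connectome,
    scale_to_critical_coupling,
)
from .features import RegionalTimeSeries, SpectralFeatures
from .fitting import FitConfig, fit_subject

__all__ = [
    "NullEnsemble",
    "rewire_preserving_degree",
    "permute_regions",
    "null_comparison",
    "run_null_ensemble",
]


@dataclass
class NullEnsemble:
    """Fit metrics over an ensemble of randomized samples."""

    kind: str                   # "rewired_sc" | "permuted_regions"
    n_samples: int
    seeds: list = field(default_factory=list)
    fc_r: list = field(default_factory=list)
    spectral_r: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": np.arange(len(self.seeds)),
            "seed": self.seeds,
            "kind": self.kind,
            "fc_r": self.fc_r,
            "spectral_r": self.spectral_r,
        })


def rewire_preserving_degree(
    sc: StructuralConnectome,
    n_swaps_per_edge: int = 10,
    seed=None,
) -> StructuralConnectome:
    """Maslov-Sneppen double-edge swaps keeping the graph connected.

    Each swap exchanges the endpoints of two randomly chosen edges, with the
    edge weights travelling with their edges; a swap that would create a
    self-loop, a multi-edge, or disconnect the graph is rejected.  The binary
    degree sequence is preserved exactly.  Output is re-normalized to sum 1.
    """
    if n_swaps_per_edge < 1:
        raise ValueError("n_swaps_per_edge must be >= 1")
    rng = np.random.default_rng(seed)
    w = sc.weights.copy()
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = w[iu, ju] > 0
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    weights = {e: w[e] for e in edges}
    m = len(edges)
    if m < 2:
        raise ValueError("graph has fewer than 2 edges; cannot rewire")
    target = n_swaps_per_edge * m
    done = 0
    attempts = 0
    max_attempts = 200 * target
    while done < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.choice(m, size=2, replace=False)
        a, b = edges[e1]
        c, d = edges[e2]
        if len({a, b, c, d}) < 4:
            continue
        if rng.random() < 0.5:
            na = (min(a, d), max(a, d))
            nb = (min(c, b), max(c, b))
        else:
            na = (min(a, c), max(a, c))
            nb = (min(b, d), max(b, d))
        if na in weights or nb in weights:
            continue
        wa = weights.pop(edges[e1])
        wb = weights.pop(edges[e2])
        weights[na] = wa
        weights[nb] = wb
        adj = np.zeros((n, n), dtype=bool)
        ij = np.array(list(weights))
        adj[ij[:, 0], ij[:, 1]] = True
        adj |= adj.T
        if connected_components(adj, directed=False)[0] != 1:
            # revert
            del weights[na], weights[nb]
            weights[edges[e1]] = wa
            weights[edges[e2]] = wb
            continue
        edges[e1] = na
        edges[e2] = nb
        done += 1
    out = np.zeros_like(w)
    for (i, j), v in weights.items():
        out[i, j] = out[j, i] = v
    return normalize_connectome(
        out, sc.region_labels, sc.homolog_map, sc.adjacency_map
    )


def permute_regions(obj, seed=None, permutation=None):
    """Apply one uniform random permutation to the region ordering.

    Works on a ``RegionalTimeSeries`` (rows) or a square matrix (rows and
    columns, consistently).  Returns ``(permuted, permutation)`` so the
    inverse can be applied later.
    """
    rng = np.random.default_rng(seed)
    if isinstance(obj, RegionalTimeSeries):
        n = obj.n_regions
        perm = np.asarray(permutation) if permutation is not None else rng.permutation(n)
        out = RegionalTimeSeries(
            obj.data[perm], obj.tr, [obj.region_labels[i] for i in perm]
        )
        return out, perm
    mat = np.asarray(obj)
    n = mat.shape[0]
    perm = np.asarray(permutation) if permutation is not None else rng.permutation(n)
    if mat.ndim == 2 and mat.shape[1] == n:
        return mat[np.ix_(perm, perm)], perm
    return mat[perm], perm


def null_comparison(true_metrics, null_metrics) -> dict:
    """Two-sample two-tailed t-test between true and null fit metrics."""
    a = np.asarray(true_metrics, float)
    b = np.asarray(null_metrics, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            t_stat, p = 0.0, 1.0
        else:
            raise ValueError("zero pooled variance with unequal means")
    else:
        t_stat, p = stats.ttest_ind(a, b)
    return {
        "t": float(t_stat),
        "df": int(a.size + b.size - 2),
        "p": float(p),
        "mean_true": float(a.mean()),
        "sd_true": float(a.std(ddof=1)),
        "mean_null": float(b.mean()),
        "sd_null": float(b.std(ddof=1)),
        "n_true": int(a.size),
        "n_null": int(b.size),
    }


def run_null_ensemble(
    sc: StructuralConnectome,
    features: SpectralFeatures,
    kind: str,
    n_samples: int = 100,
    config: FitConfig | None = None,
    weights=None,
    seed: int = 0,
    n_swaps_per_edge: int = 10,
) -> NullEnsemble:
    """Fit the model ``n_samples`` times under one randomization scheme.

    kind="rewired_sc": refit with a rewired connectome against the true
    features.  kind="permuted_regions": refit the true connectome against
    region-permuted features (FC rows/columns and PSD rows permuted
    consistently; the spectra themselves are preserved, only reassigned).
    """
    config = config or FitConfig()
    ens = NullEnsemble(kind=kind, n_samples=n_samples)
    rng = np.random.default_rng(seed)
    for s in range(n_samples):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        ens.seeds.append(sub_seed)
        if kind == "rewired_sc":
            sc_null = rewire_preserving_degree(
                sc, n_swaps_per_edge=n_swaps_per_edge, seed=sub_seed
            )
            eig = eigendecompose(scale_to_critical_coupling(sc_null), 1.0)
            feats = features
        elif kind == "permuted_regions":
            perm = np.random.default_rng(sub_seed).permutation(sc.n_regions)
            feats = _permute_features(features, perm)
            eig = eigendecompose(scale_to_critical_coupling(sc), 1.0)
        else:
            raise ValueError(f"unknown null kind {kind!r}")
        res = fit_subject(eig, feats, config, weights=weights)
        ens.fc_r.append(res.fc_r)
        ens.spectral_r.append(res.spectral_r)
    return ens


def _permute_features(features: SpectralFeatures, perm: np.ndarray) -> SpectralFeatures:
    ix = np.ix_(perm, perm)
    return SpectralFeatures(
        fc=features.fc[ix],
        fc_thresholded=features.fc_thresholded[ix],
        percolation_value=features.percolation_value,
        csd=features.csd[ix[0], ix[1], :] if features.csd is not None else None,
        psd=features.psd[perm],
        omega0=features.omega0,
        grid=features.grid,
        fc_peak=None if features.fc_peak is None else features.fc_peak[ix],
        fc_peak_thresholded=(
            None if features.fc_peak_thresholded is None
            else features.fc_peak_thresholded[ix]
        ),
    )
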