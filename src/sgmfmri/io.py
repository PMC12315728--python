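"""Readers and writers for connectomes, time series, features, and results.

Delimited-text formats carry region labels in the first row/column; HDF5
containers store the same payloads plus metadata attributes.  All writers are
round-trippable: ``read(write(x)) == x`` within float tolerance.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectome import StructuralConnectome
from .features import RegionalTimeSeries, SpectralFeatures
from .forward import FrequencyGrid

__all__ = [
    "read_connectome_csv", "write_connectome_csv",
    "read_connectome_h5", "write_connectome_h5",
    "read_timeseries_csv", "write_timeseries_csv",
    "read_timeseries_h5", "write_timeseries_h5",
    "write_features_h5", "read_features_h5",
    "write_prediction_h5",
    "read_json", "write_json",
]


def write_connectome_csv(sc: StructuralConnectome, path) -> None:
    df = pd.DataFrame(sc.weights, index=sc.region_labels, columns=sc.region_labels)
    df.to_csv(path)


def read_connectome_csv(path, homolog_map=None, adjacency_map=None) -> StructuralConnectome:
    df = pd.read_csv(path, index_col=0)
    sep = "\t" if (df.shape[1] <= 1 and Path(path).suffix == ".tsv") else None
    if sep:
        df = pd.read_csv(path, index_col=0, sep=sep)
    return StructuralConnectome(
        weights=df.to_numpy(dtype=float),
        region_labels=[str(c) for c in df.columns],
        homolog_map=homolog_map,
        adjacency_map=adjacency_map,
    )


def write_connectome_h5(sc: StructuralConnectome, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=sc.weights)
        f.create_dataset(
            "labels", data=np.array(sc.region_labels, dtype=h5py.string_dtype())
        )
        if sc.homolog_map is not None:
            f.create_dataset("homolog_pairs", data=np.asarray(sc.homolog_map, dtype=int))
        if sc.adjacency_map is not None:
            f.create_dataset("adjacency_pairs", data=np.asarray(sc.adjacency_map, dtype=int))


def read_connectome_h5(path) -> StructuralConnectome:
    with h5py.File(path, "r") as f:
        weights = f["weights"][()]
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]]
        homolog = (
            [tuple(p) for p in f["homolog_pairs"][()]] if "homolog_pairs" in f else None
        )
        adjacency = (
            [tuple(p) for p in f["adjacency_pairs"][()]] if "adjacency_pairs" in f else None
        )
    return StructuralConnectome(weights, labels, homolog, adjacency)


def write_timeseries_csv(ts: RegionalTimeSeries, path) -> None:
    df = pd.DataFrame(
        ts.data,
        index=ts.region_labels,
        columns=[f"t{i}" for i in range(ts.n_samples)],
    )
    df.to_csv(path)


def read_timeseries_csv(path, tr: float) -> RegionalTimeSeries:
    df = pd.read_csv(path, index_col=0)
    return RegionalTimeSeries(df.to_numpy(dtype=float), tr, [str(i) for i in df.index])


def write_timeseries_h5(ts: RegionalTimeSeries, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=ts.data)
        d.attrs["tr"] = ts.tr
        f.create_dataset(
            "labels", data=np.array(ts.region_labels, dtype=h5py.string_dtype())
        )


def read_timeseries_h5(path) -> RegionalTimeSeries:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        tr = float(f["data"].attrs["tr"])
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]]
    return RegionalTimeSeries(data, tr, labels)


def write_features_h5(features: SpectralFeatures, path, json_summary=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frequencies_hz", data=features.grid.frequencies_hz)
        f.create_dataset("fc", data=features.fc)
        f.create_dataset("fc_thresholded", data=features.fc_thresholded)
        f.create_dataset("csd_real", data=np.real(features.csd))
        f.create_dataset("csd_imag", data=np.imag(features.csd))
        f.create_dataset("psd", data=features.psd)
        f.attrs["percolation_value"] = features.percolation_value
        f.attrs["omega0"] = features.omega0
        if features.fc_peak is not None:
            f.create_dataset("fc_peak", data=features.fc_peak)
        if features.fc_peak_thresholded is not None:
            f.create_dataset("fc_peak_thresholded", data=features.fc_peak_thresholded)
    if json_summary is not None:
        write_json(
            {
                "percolation_value": features.percolation_value,
                "omega0_hz": features.omega0 / (2 * np.pi),
            },
            json_summary,
        )


def read_features_h5(path) -> SpectralFeatures:
    with h5py.File(path, "r") as f:
        grid = FrequencyGrid(f["frequencies_hz"][()])
        return SpectralFeatures(
            fc=f["fc"][()],
            fc_thresholded=f["fc_thresholded"][()],
            percolation_value=float(f.attrs["percolation_value"]),
            csd=f["csd_real"][()] + 1j * f["csd_imag"][()],
            psd=f["psd"][()],
            omega0=float(f.attrs["omega0"]),
            grid=grid,
            fc_peak=f["fc_peak"][()] if "fc_peak" in f else None,
            fc_peak_thresholded=(
                f["fc_peak_thresholded"][()] if "fc_peak_thresholded" in f else None
            ),
        )


def write_prediction_h5(path, grid: FrequencyGrid, signal_spectrum=None,
                        psd=None, fc=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frequencies_hz", data=grid.frequencies_hz)
        if signal_spectrum is not None:
            f.create_dataset("signal_spectrum_real", data=np.real(signal_spectrum))
            f.create_dataset("signal_spectrum_imag", data=np.imag(signal_spectrum))
        if psd is not None:
            f.create_dataset("psd", data=psd)
        if fc is not None:
            f.create_dataset("fc", data=fc)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
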