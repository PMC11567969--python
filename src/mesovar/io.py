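"""HDF5 / CSV persistence for trial tensors and energy landscapes."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .network import TrialTensor
from .statespace import EnergyLandscape

__all__ = ["save_trials", "load_trials", "trials_to_frame", "save_landscape", "load_landscape"]


def save_trials(path, tensor: TrialTensor, params: dict | None = None) -> None:
    """Write a TrialTensor to HDF5 (datasets /data, /labels, /onset_idx,
    /offset_idx, optional /positions; attrs sample_rate and a params JSON)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=tensor.data, compression="gzip")
        fh.create_dataset("labels", data=np.asarray(tensor.labels, dtype=np.int64))
        fh.create_dataset("onset_idx", data=int(tensor.onset_idx))
        fh.create_dataset("offset_idx", data=int(tensor.offset_idx))
        if tensor.neuron_positions is not None:
            fh.create_dataset("positions", data=np.asarray(tensor.neuron_positions, dtype=float))
        fh.attrs["sample_rate"] = float(tensor.sample_rate)
        fh.attrs["params"] = json.dumps(params or {})


def load_trials(path) -> TrialTensor:
    with h5py.File(path, "r") as fh:
        return TrialTensor(
            data=fh["data"][...],
            sample_rate=float(fh.attrs["sample_rate"]),
            labels=fh["labels"][...],
            onset_idx=int(fh["onset_idx"][()]),
            offset_idx=int(fh["offset_idx"][()]),
            neuron_positions=fh["positions"][...] if "positions" in fh else None,
        )


def trials_to_frame(tensor: TrialTensor) -> pd.DataFrame:
    """Long-format view (trial, neuron, frame, time_s, label, value) for CSV export."""
    n_t, n, t = tensor.data.shape
    trial, neuron, frame = np.meshgrid(
        np.arange(n_t), np.arange(n), np.arange(t), indexing="ij"
    )
    labels = np.asarray(tensor.labels)
    return pd.DataFrame(
        {
            "trial": trial.ravel(),
            "neuron": neuron.ravel(),
            "frame": frame.ravel(),
            "time_s": frame.ravel() / tensor.sample_rate,
            "label": labels[trial.ravel()],
            "value": tensor.data.ravel(),
        }
    )


def save_landscape(path, landscape: EnergyLandscape) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("grid_x", data=landscape.grid_x)
        fh.create_dataset("grid_y", data=landscape.grid_y)
        fh.create_dataset("surface", data=landscape.surface)
        fh.create_dataset("sample_coords", data=landscape.sample_coords)
        fh.create_dataset("sample_energy", data=landscape.sample_energy)


def load_landscape(path) -> EnergyLandscape:
    with h5py.File(path, "r") as fh:
        return EnergyLandscape(
            grid_x=fh["grid_x"][...],
            grid_y=fh["grid_y"][...],
            surface=fh["surface"][...],
            sample_coords=fh["sample_coords"][...],
            sample_energy=fh["sample_energy"][...],
        )
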