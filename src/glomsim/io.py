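"""Serialization of trial results and waveforms.

Trial batches go to HDF5 (one group per trial: Vm, currents, spikes,
metadata including the seed); small runs and waveforms go to delimited
text.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .engine import BatchResult
from .neuron import TrialResult

__all__ = ["save_batch_hdf5", "load_trial_hdf5", "trace_to_csv"]


def save_batch_hdf5(batch: BatchResult, path: str | Path) -> None:
    """Write a batch of trials to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = batch.seed
        f.attrs["condition"] = batch.condition
        f.attrs["dt_ms"] = batch.dt
        f.create_dataset("time_ms", data=batch.time)
        for i in range(batch.vm.shape[0]):
            g = f.create_group(f"trial_{i:04d}")
            g.create_dataset("vm_mV", data=batch.vm[i])
            g.create_dataset("i_vdcc_pA", data=batch.i_vdcc[i])
            g.create_dataset("i_nmda_pA", data=batch.i_nmda[i])
            g.create_dataset("spike_times_ms", data=batch.spike_times[i])


def load_trial_hdf5(path: str | Path, trial: int = 0) -> TrialResult:
    """Read one trial back from an HDF5 container."""
    with h5py.File(path, "r") as f:
        g = f[f"trial_{trial:04d}"]
        return TrialResult(
            time=f["time_ms"][()],
            vm=g["vm_mV"][()].astype(float),
            spike_times=g["spike_times_ms"][()],
            i_vdcc=g["i_vdcc_pA"][()].astype(float),
            i_nmda=g["i_nmda_pA"][()].astype(float),
            seed=int(f.attrs["seed"]),
            condition=str(f.attrs["condition"]),
        )


def trace_to_csv(path: str | Path, time_ms: np.ndarray, **columns) -> None:
    """Write named traces sharing one time grid as CSV."""
    pd.DataFrame({"time_ms": time_ms, **columns}).to_csv(path, index=False)
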