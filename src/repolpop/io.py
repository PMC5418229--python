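"""Persistence: steady-state cache and trace export.

Steady states are stored in an HDF5 container with one dataset per model,
keyed by the hash of (scaling, block, perturbation, celltype, protocol
extras) from :func:`repolpop.ord_model.scenario_key`; a JSON sidecar records
the state-variable ordering so the cache is self-describing.  Traces export
to HDF5 (time, vm, currents, concentrations) or to a small CSV (time, vm).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .ord_model import N_STATE, OrdState, SimulationResult, STATE_NAMES

__all__ = ["StateCache", "export_trace_hdf5", "export_trace_csv"]


class StateCache:
    """HDF5-backed store of per-model steady states."""

    def __init__(self, path) -> None:
        self.path = Path(path)
        sidecar = self.path.with_suffix(self.path.suffix + ".schema.json")
        if not sidecar.exists():
            sidecar.parent.mkdir(parents=True, exist_ok=True)
            sidecar.write_text(json.dumps(
                {"state_order": list(STATE_NAMES)}, indent=2))

    def save(self, key: str, state: OrdState) -> None:
        with h5py.File(self.path, "a") as f:
            if key in f:
                del f[key]
            f.create_dataset(key, data=state.to_vector())

    def load(self, key: str) -> Optional[OrdState]:
        if not self.path.exists():
            return None
        with h5py.File(self.path, "r") as f:
            if key not in f:
                return None
            data = np.asarray(f[key])
        if data.shape != (N_STATE,):
            raise ValueError(f"cached state for {key!r} has wrong shape")
        return OrdState.from_vector(data)

    def __contains__(self, key: str) -> bool:
        if not self.path.exists():
            return False
        with h5py.File(self.path, "r") as f:
            return key in f


def export_trace_hdf5(result: SimulationResult, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=result.time)
        f.create_dataset("vm", data=result.vm)
        f.create_dataset("beat_boundaries", data=result.beat_boundaries)
        g = f.create_group("currents")
        for name, series in result.currents.items():
            g.create_dataset(name, data=series)
        g = f.create_group("concentrations")
        for name, series in result.concentrations.items():
            g.create_dataset(name, data=series)


def export_trace_csv(result: SimulationResult, path) -> None:
    pd.DataFrame({"time": result.time, "vm": result.vm}).to_csv(path,
                                                                index=False)
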