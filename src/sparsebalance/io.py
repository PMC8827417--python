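"""HDF5 / CSV persistence for weight matrices, trajectories and DMFT solutions."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import WeightMatrix, WeightSpec
from .dynamics import SimulationConfig, Trajectory
from .dmft import DMFTSolution

__all__ = [
    "save_weights",
    "load_weights",
    "save_trajectory",
    "load_trajectory",
    "save_dmft",
    "append_stats_csv",
    "weights_to_csv",
]


def save_weights(path: str | Path, W: WeightMatrix) -> None:
    """Dense weight matrix with its spec and seed as HDF5 attributes."""
    with h5py.File(path, "w") as h:
        d = h.create_dataset("values", data=W.values)
        d.attrs["seed"] = W.seed
        if W.spec is not None:
            for k, v in dataclasses.asdict(W.spec).items():
                d.attrs[k] = v
        if W.labels is not None:
            h.create_dataset("labels", data=np.char.encode(W.labels))


def load_weights(path: str | Path) -> WeightMatrix:
    with h5py.File(path, "r") as h:
        d = h["values"]
        values = d[...]
        attrs = dict(d.attrs)
        labels = None
        if "labels" in h:
            labels = np.char.decode(h["labels"][...])
    spec = None
    if "family" in attrs:
        spec = WeightSpec(
            family=str(attrs["family"]), J0=float(attrs["J0"]), g=float(attrs["g"]),
            nu=float(attrs["nu"]), K=int(attrs["K"]), N=int(attrs["N"]),
        )
    return WeightMatrix(values=values, spec=spec, seed=int(attrs["seed"]), labels=labels)


def weights_to_csv(path: str | Path, W: WeightMatrix) -> None:
    """Small fixtures only: plain CSV of the dense matrix."""
    np.savetxt(path, W.values, delimiter=",")


def save_trajectory(path: str | Path, traj: Trajectory) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("x", data=traj.x)
        h.create_dataset("phi", data=traj.phi)
        h.create_dataset("times", data=traj.times)
        if traj.eta is not None:
            h.create_dataset("eta", data=traj.eta)
        if traj.labels is not None:
            h.create_dataset("labels", data=np.char.encode(traj.labels))
        if traj.config is not None:
            for k, v in dataclasses.asdict(traj.config).items():
                if np.isscalar(v):
                    h.attrs[k] = v
        for k, v in (traj.meta or {}).items():
            if np.isscalar(v):
                h.attrs[f"meta_{k}"] = v


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as h:
        cfg_keys = {f.name for f in dataclasses.fields(SimulationConfig)}
        kw = {k: v for k, v in h.attrs.items() if k in cfg_keys and k != "dtype"}
        cfg = SimulationConfig(**{k: (int(v) if k in ("record_stride", "seed")
                                      else bool(v) if k == "record_eta" else float(v))
                                  for k, v in kw.items()}) if kw else None
        return Trajectory(
            x=h["x"][...],
            phi=h["phi"][...],
            times=h["times"][...],
            eta=h["eta"][...] if "eta" in h else None,
            labels=np.char.decode(h["labels"][...]) if "labels" in h else None,
            config=cfg,
            meta={k[5:]: v for k, v in h.attrs.items() if k.startswith("meta_")},
        )


def save_dmft(path: str | Path, sol: DMFTSolution) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("tau", data=sol.tau)
        h.create_dataset("sigma", data=sol.sigma)
        h.create_dataset("R_eta", data=sol.R_eta)
        for k in ("u", "m", "q", "sigma0", "quenched_var", "f", "beta",
                  "residual_u", "residual_q"):
            h.attrs[k] = getattr(sol, k)
        for k in ("J0", "g", "K", "I0", "order", "tau_max", "scaling"):
            h.attrs[f"param_{k}"] = getattr(sol.params, k)


def append_stats_csv(path: str | Path, df: pd.DataFrame) -> None:
    """Append sweep rows to a CSV, writing the header only when creating it."""
    path = Path(path)
    df.to_csv(path, mode="a", header=not path.exists(), index=False)
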