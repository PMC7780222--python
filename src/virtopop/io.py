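"""Persistence: JSON for small parameter objects, HDF5 for gridded arrays,
CSV for burden curves and biomarker samples."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .fields import LumpField, LumpPrior
from .growth import CellDensityPath, SpaceGrid

__all__ = [
    "save_lump_field",
    "load_lump_field",
    "save_lump_prior",
    "load_lump_prior",
    "save_density_path",
    "load_density_path",
    "save_burden_csv",
    "save_bundle",
]


def save_lump_field(field: LumpField, path) -> None:
    payload = {
        "centers": field.centers.tolist(),
        "amplitudes": field.amplitudes.tolist(),
        "lump_variance": field.lump_variance,
        "max_lumps": field.max_lumps,
    }
    Path(path).write_text(json.dumps(payload))


def load_lump_field(path) -> LumpField:
    d = json.loads(Path(path).read_text())
    return LumpField(
        np.asarray(d["centers"], dtype=float).reshape(-1, 2),
        np.asarray(d["amplitudes"], dtype=float),
        d["lump_variance"],
        d["max_lumps"],
    )


def save_lump_prior(prior: LumpPrior, path) -> None:
    payload = {
        "mean_lumps": prior.mean_lumps,
        "amplitude": prior.amplitude,
        "lump_variance": prior.lump_variance,
        "domain": [list(side) for side in prior.domain],
    }
    Path(path).write_text(json.dumps(payload))


def load_lump_prior(path) -> LumpPrior:
    d = json.loads(Path(path).read_text())
    return LumpPrior(
        d["mean_lumps"],
        d["amplitude"],
        d["lump_variance"],
        tuple(tuple(side) for side in d["domain"]),
    )


def save_density_path(path_obj: CellDensityPath, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=path_obj.values, compression="gzip")
        f.create_dataset("times", data=path_obj.times)
        f.attrs["nx"] = path_obj.grid.nx
        f.attrs["ny"] = path_obj.grid.ny
        f.attrs["box"] = np.asarray(path_obj.grid.box)
        f.attrs["clipped_nodes"] = path_obj.clipped_nodes


def load_density_path(path) -> CellDensityPath:
    with h5py.File(path, "r") as f:
        box = np.asarray(f.attrs["box"])
        grid = SpaceGrid(
            int(f.attrs["nx"]),
            int(f.attrs["ny"]),
            ((box[0, 0], box[0, 1]), (box[1, 0], box[1, 1])),
        )
        return CellDensityPath(
            f["values"][...],
            f["times"][...],
            grid,
            clipped_nodes=int(f.attrs["clipped_nodes"]),
        )


def save_burden_csv(times: np.ndarray, burdens: np.ndarray, path) -> None:
    """Burden curves to CSV: first column time (days), one column per member."""
    burdens = np.atleast_2d(burdens)
    table = np.column_stack([times, burdens.T])
    header = "time_days," + ",".join(f"member_{j}" for j in range(burdens.shape[0]))
    np.savetxt(path, table, delimiter=",", header=header, comments="")


def save_bundle(bundle: dict, outdir) -> None:
    """Persist an experiment artifact bundle under a run directory.

    Arrays go to ``arrays.h5``; scalars and the key inventory go to
    ``manifest.json``; burden curves additionally to CSV for inspection.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scalars = {}
    with h5py.File(outdir / "arrays.h5", "w") as f:
        for key, val in bundle.items():
            arr = np.asarray(val)
            if arr.ndim == 0:
                scalars[key] = arr.item()
            else:
                f.create_dataset(key, data=arr)
    manifest = {"scalars": scalars, "arrays": sorted(k for k in bundle if k not in scalars)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for key in ("vpp_mle_burden", "vpp_posterior_burden", "vpp_burden"):
        if key in bundle:
            save_burden_csv(bundle["prediction_times"], bundle[key], outdir / f"{key}.csv")
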