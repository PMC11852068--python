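"""Persistence of pipeline intermediates and results.

Epoch arrays and coherence tensors live in HDF5 containers keyed
``subject/band``; tables are CSV with header rows; run manifests are JSON
with sha256 checksums so a run's outputs are verifiable and each stage can
be re-run from the previous stage's artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .coherence import CoherenceTensor, WindowPlan
from .preprocess import BandSpec, EpochSet

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_tensors",
    "read_tensors",
    "write_sweep_csv",
    "sha256_of",
    "write_manifest",
]


def write_epochs(path: str | Path, epoch_sets: dict[str, dict[str, EpochSet]]) -> Path:
    """``epoch_sets[subject][band]`` → HDF5 groups ``subject/band``."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for subject, bands in epoch_sets.items():
            for band_name, es in bands.items():
                g = f.create_group(f"{subject}/{band_name}")
                g.create_dataset("data", data=es.data, compression="gzip", compression_opts=1)
                g.attrs["fs"] = es.fs
                g.attrs["event_sample"] = es.event_sample
                g.attrs["f_lo"] = es.band.f_lo
                g.attrs["f_hi"] = es.band.f_hi
                g.attrs["kept_trials"] = np.asarray(es.kept_trials, dtype=int)
    return path


def read_epochs(path: str | Path) -> dict[str, dict[str, EpochSet]]:
    out: dict[str, dict[str, EpochSet]] = {}
    with h5py.File(path, "r") as f:
        for subject in f:
            out[subject] = {}
            for band_name in f[subject]:
                g = f[subject][band_name]
                out[subject][band_name] = EpochSet(
                    band=BandSpec(band_name, float(g.attrs["f_lo"]), float(g.attrs["f_hi"])),
                    fs=float(g.attrs["fs"]),
                    data=g["data"][()],
                    event_sample=int(g.attrs["event_sample"]),
                    subject_id=subject,
                    kept_trials=[int(t) for t in g.attrs["kept_trials"]],
                )
    return out


def _plan_to_attrs(g: h5py.Group, plan: WindowPlan) -> None:
    g.attrs["win_len"] = plan.win_len
    g.attrs["step"] = plan.step
    g.attrs["starts"] = np.asarray(plan.starts, dtype=int)
    g.attrs["conditions"] = [c.encode() for c in plan.condition_of_window]
    g.attrs["event_sample"] = plan.event_sample


def _plan_from_attrs(g: h5py.Group) -> WindowPlan:
    conds = tuple(
        c.decode() if isinstance(c, bytes) else str(c) for c in g.attrs["conditions"]
    )
    return WindowPlan(
        win_len=int(g.attrs["win_len"]),
        step=int(g.attrs["step"]),
        starts=tuple(int(s) for s in g.attrs["starts"]),
        condition_of_window=conds,
        event_sample=int(g.attrs["event_sample"]),
    )


def write_tensors(path: str | Path, tensors: dict[str, dict[str, CoherenceTensor]]) -> Path:
    """``tensors[subject][band]`` → HDF5 groups ``subject/band``."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for subject, bands in tensors.items():
            for band_name, t in bands.items():
                g = f.create_group(f"{subject}/{band_name}")
                g.create_dataset("values", data=t.values, compression="gzip", compression_opts=1)
                g.attrs["f_lo"] = t.band.f_lo
                g.attrs["f_hi"] = t.band.f_hi
                _plan_to_attrs(g, t.window_plan)
    return path


def read_tensors(path: str | Path) -> dict[str, dict[str, CoherenceTensor]]:
    out: dict[str, dict[str, CoherenceTensor]] = {}
    with h5py.File(path, "r") as f:
        for subject in f:
            out[subject] = {}
            for band_name in f[subject]:
                g = f[subject][band_name]
                out[subject][band_name] = CoherenceTensor(
                    subject_id=subject,
                    band=BandSpec(band_name, float(g.attrs["f_lo"]), float(g.attrs["f_hi"])),
                    values=g["values"][()],
                    window_plan=_plan_from_attrs(g),
                )
    return out


def write_sweep_csv(path: str | Path, sweep) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "threshold": sweep.thresholds,
            "mean_surprise": sweep.mean_surprise,
            "mean_lcc_fraction": sweep.lcc_fraction,
        }
    ).to_csv(path, index=False)
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, artifacts: list[Path], extra: dict) -> Path:
    path = Path(path)
    manifest = dict(extra)
    manifest["artifacts"] = [
        {"path": str(Path(a).name), "sha256": sha256_of(a)} for a in artifacts
    ]
    path.write_text(json.dumps(manifest, indent=2))
    return path
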