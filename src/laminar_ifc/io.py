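"""HDF5 and tidy-table serialization for synthetic runs and feature maps."""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from laminar_ifc.synthetic_data import DepthRunSeries, GroundTruth

__all__ = [
    "write_subject_runs",
    "read_subject_runs",
    "write_maps",
    "read_maps",
    "maps_to_frame",
    "tuning_to_frame",
]


def write_subject_runs(path: str, runs: list, gt: GroundTruth,
                       subject: int, attrs: dict | None = None) -> None:
    """One HDF5 per synthetic subject: /runs/<id>/..., /truth/*."""
    by_run: dict = {}
    for r in runs:
        by_run.setdefault(r.run_id, []).append(r)
    with h5py.File(path, "w") as f:
        f.attrs["subject"] = subject
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
        for run_id, depth_runs in sorted(by_run.items()):
            depth_runs = sorted(depth_runs, key=lambda r: r.depth)
            g = f.create_group(f"runs/{run_id}")
            g.attrs["direction"] = depth_runs[0].direction
            g.attrs["tr"] = depth_runs[0].tr
            g.attrs["depths"] = [r.depth for r in depth_runs]
            g.create_dataset("data", data=np.stack([r.data for r in depth_runs]))
            g.create_dataset("nuisance", data=depth_runs[0].nuisance)
        t = f.create_group("truth")
        t.create_dataset("logf", data=gt.logf)
        t.create_dataset("tuning_width_oct", data=gt.tuning_width_oct)
        t.create_dataset("core_mask", data=gt.core_mask)
        t.create_dataset("snr", data=gt.snr)
        t.attrs["rho0"] = gt.rho0
        t.attrs["noise_sd"] = gt.noise_sd
        t.attrs["delay"] = gt.delays[subject]
        lam = t.create_group("lambda")
        for depth, tab in gt.lambda_table.items():
            for region, value in tab.items():
                lam.attrs[f"{depth}/{region}"] = value


def read_subject_runs(path: str) -> list:
    """Read back the runs written by :func:`write_subject_runs`."""
    runs = []
    with h5py.File(path, "r") as f:
        subject = int(f.attrs["subject"])
        for run_id in sorted(f["runs"]):
            g = f[f"runs/{run_id}"]
            data = g["data"][()]
            nuisance = g["nuisance"][()]
            for i, depth in enumerate(g.attrs["depths"]):
                runs.append(DepthRunSeries(
                    subject=subject, depth=float(depth), run_id=run_id,
                    direction=str(g.attrs["direction"]), data=data[i],
                    tr=float(g.attrs["tr"]), nuisance=nuisance))
    return runs


def write_maps(path: str, all_maps: dict, all_tuning: dict,
               attrs: dict | None = None) -> None:
    """Activation and tuning maps: /subject/<id>/depth/<nd>/{...}."""
    with h5py.File(path, "w") as f:
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
        for subject, maps in all_maps.items():
            for depth, amap in maps.items():
                g = f.create_group(f"subject/{subject}/depth/{depth}")
                g.create_dataset("z", data=amap.z)
                g.create_dataset("fisher_z", data=amap.fisher_z)
                g.create_dataset("phase", data=amap.phi_avg)
                g.create_dataset("latency", data=amap.latency)
                g.create_dataset("logf", data=amap.logf)
                g.create_dataset("valid", data=amap.valid)
                tmap = all_tuning.get(subject, {}).get(depth)
                if tmap is not None:
                    g.create_dataset("tw_oct", data=tmap.width_oct)
                    g.create_dataset("tw_r2", data=tmap.r2)
                    g.create_dataset("tw_valid", data=tmap.valid)


def read_maps(path: str) -> tuple:
    """Inverse of :func:`write_maps`; returns (maps, tuning) nested dicts."""
    from laminar_ifc.phase_mapping import ActivationMap
    from laminar_ifc.tuning import TuningMap

    all_maps: dict = {}
    all_tuning: dict = {}
    with h5py.File(path, "r") as f:
        for s_key in f["subject"]:
            subject = int(s_key)
            for d_key in f[f"subject/{s_key}/depth"]:
                depth = float(d_key)
                g = f[f"subject/{s_key}/depth/{d_key}"]
                all_maps.setdefault(subject, {})[depth] = ActivationMap(
                    z=g["z"][()], fisher_z=g["fisher_z"][()],
                    phi_avg=g["phase"][()], latency=g["latency"][()],
                    logf=g["logf"][()], valid=g["valid"][()].astype(bool),
                    depth=depth)
                if "tw_oct" in g:
                    all_tuning.setdefault(subject, {})[depth] = TuningMap(
                        width_oct=g["tw_oct"][()],
                        center_s=np.full_like(g["tw_oct"][()], np.nan),
                        r2=g["tw_r2"][()],
                        valid=g["tw_valid"][()].astype(bool), depth=depth)
    return all_maps, all_tuning


def maps_to_frame(all_maps: dict) -> pd.DataFrame:
    rows = []
    for subject, maps in all_maps.items():
        for depth, amap in maps.items():
            for v in range(amap.z.size):
                rows.append((subject, depth, v, amap.z[v], amap.logf[v],
                             amap.latency[v], bool(amap.valid[v])))
    return pd.DataFrame(rows, columns=["subject", "depth", "vertex", "z",
                                       "logf", "latency", "valid"])


def tuning_to_frame(all_tuning: dict) -> pd.DataFrame:
    rows = []
    for subject, maps in all_tuning.items():
        for depth, tmap in maps.items():
            for v in range(tmap.width_oct.size):
                rows.append((subject, depth, v, tmap.width_oct[v], tmap.r2[v],
                             bool(tmap.valid[v])))
    return pd.DataFrame(rows, columns=["subject", "depth", "vertex",
                                       "tw_oct", "r2", "valid"])


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
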