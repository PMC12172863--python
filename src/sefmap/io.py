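"""Round-trip readers and writers for the pipeline's on-disk formats.

Meshes as ASCII PLY, parcellations and sensor arrays as TSV, epochs /
evoked / lead fields in HDF5, ground truth / regions / dipoles as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh

from .evoked import Evoked
from .forward import LeadField, SensorArray
from .geometry import Parcellation, SourceSpace, TriangleMesh
from .inverse import DipoleFit
from .localize import ActivationRegion
from .simulate import EpochsArray, GroundTruth

__all__ = [
    "write_mesh_ply",
    "read_mesh_ply",
    "write_parcellation_tsv",
    "read_parcellation_tsv",
    "write_sensors_tsv",
    "read_sensors_tsv",
    "write_epochs_h5",
    "read_epochs_h5",
    "write_evoked_h5",
    "read_evoked_h5",
    "write_leadfield_h5",
    "read_leadfield_h5",
    "write_json",
    "read_json",
    "ground_truth_to_dict",
    "ground_truth_from_dict",
    "region_to_dict",
    "region_from_dict",
    "dipole_to_dict",
    "dipole_from_dict",
]


def write_mesh_ply(mesh: TriangleMesh, path: str | Path) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    Path(path).write_bytes(tm.export(file_type="ply", encoding="ascii"))


def read_mesh_ply(
    path: str | Path,
    hemisphere: str = "left",
    center: np.ndarray | None = None,
    nominal_radius: float = 1.0,
) -> TriangleMesh:
    tm = trimesh.load(str(path), file_type="ply", process=False)
    return TriangleMesh(
        np.asarray(tm.vertices, dtype=float),
        np.asarray(tm.faces, dtype=np.int64),
        hemisphere,
        np.zeros(3) if center is None else np.asarray(center, dtype=float),
        nominal_radius,
    )


def write_parcellation_tsv(parc: Parcellation, labels_path: str | Path, table_path: str | Path) -> None:
    pd.DataFrame(
        {"source_id": np.arange(len(parc.labels)), "label_id": parc.labels}
    ).to_csv(labels_path, sep="\t", index=False)
    rows = [
        {"label_id": lid, "label_name": name, "hemisphere": hemi}
        for lid, (name, hemi) in sorted(parc.label_table.items())
    ]
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


def read_parcellation_tsv(labels_path: str | Path, table_path: str | Path) -> Parcellation:
    labels = pd.read_csv(labels_path, sep="\t")["label_id"].to_numpy(dtype=np.int64)
    tab = pd.read_csv(table_path, sep="\t")
    table = {int(r.label_id): (str(r.label_name), str(r.hemisphere)) for r in tab.itertuples()}
    return Parcellation(labels, table)


def write_sensors_tsv(sensors: SensorArray, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "channel_id": np.arange(sensors.n_channels),
            "kind": sensors.kinds,
            "x": sensors.positions[:, 0],
            "y": sensors.positions[:, 1],
            "z": sensors.positions[:, 2],
            "ox": sensors.orientations[:, 0],
            "oy": sensors.orientations[:, 1],
            "oz": sensors.orientations[:, 2],
            "pair_offset": sensors.pair_offsets,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_sensors_tsv(path: str | Path, center: np.ndarray | None = None) -> SensorArray:
    df = pd.read_csv(path, sep="\t")
    return SensorArray(
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        orientations=df[["ox", "oy", "oz"]].to_numpy(dtype=float),
        kinds=df["kind"].to_numpy(dtype=object),
        pair_offsets=df["pair_offset"].to_numpy(dtype=float),
        center=np.zeros(3) if center is None else np.asarray(center, dtype=float),
    )


def write_epochs_h5(epochs: EpochsArray, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=epochs.data)
        d.attrs["sfreq"] = epochs.sfreq
        d.attrs["t0_ms"] = epochs.t0_ms
        d.attrs["stim_sample"] = epochs.stim_sample
        if epochs.ch_kinds is not None:
            f.create_dataset("ch_kinds", data=np.asarray(epochs.ch_kinds, dtype="S"))


def read_epochs_h5(path: str | Path) -> EpochsArray:
    with h5py.File(path, "r") as f:
        d = f["data"]
        kinds = None
        if "ch_kinds" in f:
            kinds = np.array([k.decode() for k in f["ch_kinds"][()]], dtype=object)
        return EpochsArray(
            data=d[()],
            sfreq=float(d.attrs["sfreq"]),
            t0_ms=float(d.attrs["t0_ms"]),
            ch_kinds=kinds,
        )


def write_evoked_h5(evoked: Evoked, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("evoked", data=evoked.data)
        d.attrs["n_ave"] = evoked.n_ave
        f.create_dataset("times", data=evoked.times)
        if evoked.ch_kinds is not None:
            f.create_dataset("ch_kinds", data=np.asarray(evoked.ch_kinds, dtype="S"))


def read_evoked_h5(path: str | Path) -> Evoked:
    with h5py.File(path, "r") as f:
        kinds = None
        if "ch_kinds" in f:
            kinds = np.array([k.decode() for k in f["ch_kinds"][()]], dtype=object)
        return Evoked(
            data=f["evoked"][()],
            times=f["times"][()],
            n_ave=int(f["evoked"].attrs["n_ave"]),
            ch_kinds=kinds,
        )


def write_leadfield_h5(lf: LeadField, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_dataset("gain", data=lf.gain)
        g.attrs["units_mag"] = "T per nA*m"
        g.attrs["units_grad"] = "T/m per nA*m"
        g.attrs["head_radius_mm"] = lf.head_radius
        f.create_dataset("channel_ids", data=np.arange(lf.n_channels))
        f.create_dataset("source_ids", data=np.arange(lf.n_sources))


def read_leadfield_h5(path: str | Path, sensors: SensorArray, source_space: SourceSpace) -> LeadField:
    with h5py.File(path, "r") as f:
        gain = f["gain"][()]
        head_radius = float(f["gain"].attrs["head_radius_mm"])
    return LeadField(gain, sensors, source_space, head_radius)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def ground_truth_to_dict(gt: GroundTruth) -> dict:
    return {
        "patch": gt.patch.tolist(),
        "taper": gt.taper.tolist(),
        "waveform": gt.waveform.tolist(),
        "peak_latencies": list(gt.peak_latencies),
        "side": gt.side,
        "seed_vertex": gt.seed_vertex,
        "moment_total": gt.moment_total,
    }


def ground_truth_from_dict(d: dict) -> GroundTruth:
    return GroundTruth(
        patch=np.asarray(d["patch"], dtype=np.int64),
        taper=np.asarray(d["taper"], dtype=float),
        waveform=np.asarray(d["waveform"], dtype=float),
        peak_latencies=tuple(d["peak_latencies"]),
        side=d["side"],
        seed_vertex=int(d["seed_vertex"]),
        moment_total=float(d["moment_total"]),
    )


def region_to_dict(region: ActivationRegion) -> dict:
    return {
        "members": region.members.tolist(),
        "loadings": region.loadings.tolist(),
        "centroid": region.centroid.tolist(),
        "centroid_vertex": region.centroid_vertex,
        "centroid_label": region.centroid_label,
        "peak_time": region.peak_time,
        "threshold": region.threshold,
    }


def region_from_dict(d: dict) -> ActivationRegion:
    return ActivationRegion(
        members=np.asarray(d["members"], dtype=np.int64),
        loadings=np.asarray(d["loadings"], dtype=float),
        centroid=np.asarray(d["centroid"], dtype=float),
        centroid_vertex=int(d["centroid_vertex"]),
        centroid_label=d["centroid_label"],
        peak_time=float(d["peak_time"]),
        threshold=float(d["threshold"]),
    )


def dipole_to_dict(dip: DipoleFit) -> dict:
    return {
        "time": dip.time,
        "gof": dip.gof,
        "moment": dip.moment.tolist(),
        "moment_nam": dip.moment_magnitude,
        "x": float(dip.position[0]),
        "y": float(dip.position[1]),
        "z": float(dip.position[2]),
        "kind": dip.kind,
        "accepted": dip.accepted,
    }


def dipole_from_dict(d: dict) -> DipoleFit:
    return DipoleFit(
        time=float(d["time"]),
        position=np.array([d["x"], d["y"], d["z"]], dtype=float),
        moment=np.asarray(d["moment"], dtype=float),
        gof=float(d["gof"]),
        kind=d["kind"],
        accepted=d["accepted"],
    )
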