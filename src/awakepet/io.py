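"""Readers and writers for every artifact the pipeline produces.

Formats
-------
* Event streams: HDF5 (``.h5``/``.hdf5``) with integer-microsecond
  timestamps and crystal index columns, or a CSV text dialect for small
  fixtures (a ``#``-prefixed JSON header line, then ``t_us,crystal_a,
  crystal_b`` rows).
* Volumes: NIfTI-1 via nibabel, mm units, world frame = scanner frame;
  atlases carry a JSON sidecar with the label -> region-name map.
* Trajectories: JSON lines, one header record then one record per pose
  (time, quaternion wxyz, translation, accepted flag).
* Marker models: JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import GridSpec
from .markers import MarkerModel
from .pose import RigidPose, Trajectory
from .simulate import EventStream
from .volumes import BrainAtlas, MuMap, VoxelImage

__all__ = ["write_events", "read_events", "write_volume", "read_volume",
           "read_atlas", "write_trajectory", "read_trajectory",
           "write_marker_model", "read_marker_model"]

_EVENTS_MAGIC = "awakepet-events"
_TRAJ_MAGIC = "awakepet-trajectory"


# ---------------------------------------------------------------- events

def _events_header(stream: EventStream) -> dict:
    meta = {k: v for k, v in stream.meta.items()
            if isinstance(v, (int, float, str, bool, type(None)))}
    return {"format": _EVENTS_MAGIC, "version": 1,
            "geometry": stream.geometry_name,
            "duration_ms": stream.duration_ms,
            "n_events": len(stream), "meta": meta}


def write_events(stream: EventStream, path) -> Path:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "w") as f:
            f.attrs["header"] = json.dumps(_events_header(stream))
            f.create_dataset("t_us", data=stream.t_us)
            f.create_dataset("crystal_a", data=stream.crystal_a)
            f.create_dataset("crystal_b", data=stream.crystal_b)
    elif path.suffix == ".csv":
        with open(path, "w") as f:
            f.write("# " + json.dumps(_events_header(stream)) + "\n")
            f.write("t_us,crystal_a,crystal_b\n")
            for t, a, b in zip(stream.t_us, stream.crystal_a, stream.crystal_b):
                f.write(f"{t},{a},{b}\n")
    else:
        raise ValueError(f"unsupported event-stream extension {path.suffix!r}")
    return path


def read_events(path) -> EventStream:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "r") as f:
            hdr = json.loads(f.attrs["header"])
            _check_header(hdr, path)
            t = f["t_us"][:]
            a = f["crystal_a"][:]
            b = f["crystal_b"][:]
    elif path.suffix == ".csv":
        with open(path) as f:
            first = f.readline()
            if not first.startswith("# "):
                raise ValueError(f"{path}: line 1: missing JSON header line")
            try:
                hdr = json.loads(first[2:])
            except json.JSONDecodeError as e:
                raise ValueError(f"{path}: line 1: malformed header: {e}") from e
            _check_header(hdr, path)
            cols = f.readline().strip()
            if cols != "t_us,crystal_a,crystal_b":
                raise ValueError(f"{path}: line 2: unexpected column header {cols!r}")
            body = f.read()
        if body.strip():
            data = np.loadtxt(body.splitlines(), delimiter=",",
                              dtype=np.int64, ndmin=2)
        else:
            data = np.empty((0, 3), dtype=np.int64)
        t, a, b = data[:, 0], data[:, 1], data[:, 2]
    else:
        raise ValueError(f"unsupported event-stream extension {path.suffix!r}")
    if len(t) != hdr["n_events"]:
        raise ValueError(f"{path}: truncated stream: header says "
                         f"{hdr['n_events']} events, found {len(t)}")
    return EventStream(t, a, b, hdr["geometry"], hdr["duration_ms"],
                       meta=dict(hdr.get("meta", {})))


def _check_header(hdr: dict, path) -> None:
    if hdr.get("format") != _EVENTS_MAGIC:
        raise ValueError(f"{path}: not an event-stream file (format field "
                         f"{hdr.get('format')!r})")


# ---------------------------------------------------------------- volumes

def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.voxel_size)
    aff[:3, 3] = np.asarray(grid.origin) + 0.5 * np.asarray(grid.voxel_size)
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> GridSpec:
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError("only axis-aligned NIfTI volumes are supported")
    vox = np.diag(rot)
    if np.any(vox <= 0):
        raise ValueError("negative voxel sizes (flipped axes) not supported")
    origin = aff[:3, 3] - 0.5 * vox
    return GridSpec(tuple(shape), tuple(vox), tuple(origin))


def write_volume(volume, path) -> Path:
    """Write a VoxelImage / MuMap (float32) or BrainAtlas (int16 + JSON
    sidecar of region names) as NIfTI-1."""
    import nibabel as nib

    path = Path(path)
    if isinstance(volume, BrainAtlas):
        img = nib.Nifti1Image(volume.labels.astype(np.int16), _affine(volume.grid))
        nib.save(img, path)
        sidecar = Path(str(path) + ".labels.json")
        sidecar.write_text(json.dumps(
            {str(k): v for k, v in volume.region_names.items()}))
        return path
    values = volume.mu if isinstance(volume, MuMap) else volume.values
    img = nib.Nifti1Image(values.astype(np.float32), _affine(volume.grid))
    nib.save(img, path)
    return path


def read_volume(path, kind: str = "image"):
    """Read a NIfTI volume.  ``kind``: "image", "mu" or "atlas"."""
    import nibabel as nib

    path = Path(path)
    img = nib.load(path)
    grid = _grid_from_affine(img.affine, img.shape)
    data = np.asanyarray(img.dataobj)
    if kind == "image":
        return VoxelImage(grid, np.asarray(data, dtype=np.float64))
    if kind == "mu":
        return MuMap(grid, np.asarray(data, dtype=np.float64))
    if kind == "atlas":
        sidecar = Path(str(path) + ".labels.json")
        names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()} \
            if sidecar.exists() else None
        labels = np.asarray(data).astype(np.int64)
        if names is None:
            return BrainAtlas(grid, labels)
        return BrainAtlas(grid, labels, region_names=names)
    raise ValueError(f"unknown volume kind {kind!r}")


def read_atlas(path) -> BrainAtlas:
    return read_volume(path, kind="atlas")


# ---------------------------------------------------------------- trajectory

def write_trajectory(traj: Trajectory, path) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        f.write(json.dumps({"format": _TRAJ_MAGIC, "version": 1,
                            "frame_duration_ms": traj.frame_duration_ms,
                            "knot_offset_ms": traj.knot_offset_ms,
                            "n_poses": len(traj)}) + "\n")
        for p in traj.poses:
            f.write(json.dumps({"t_ms": p.t_ms,
                                "q_wxyz": [float(x) for x in p.quat_wxyz],
                                "t_xyz_mm": [float(x) for x in p.translation_mm],
                                "accepted": bool(p.accepted)}) + "\n")
    return path


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    with open(path) as f:
        try:
            hdr = json.loads(f.readline())
        except json.JSONDecodeError as e:
            raise ValueError(f"{path}: line 1: malformed header: {e}") from e
        if hdr.get("format") != _TRAJ_MAGIC:
            raise ValueError(f"{path}: not a trajectory file")
        poses = []
        for i, line in enumerate(f, start=2):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"{path}: line {i}: malformed pose record: {e}") from e
            poses.append(RigidPose(rec["t_ms"], np.array(rec["q_wxyz"]),
                                   np.array(rec["t_xyz_mm"]), rec["accepted"]))
    if len(poses) != hdr.get("n_poses", len(poses)):
        raise ValueError(f"{path}: truncated: header says {hdr['n_poses']} "
                         f"poses, found {len(poses)}")
    return Trajectory(poses, frame_duration_ms=hdr["frame_duration_ms"],
                      knot_offset_ms=hdr.get("knot_offset_ms", 0.0))


# ---------------------------------------------------------------- markers

def write_marker_model(model: MarkerModel, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "points_mm": model.points.tolist(),
        "activities_kbq": model.activities_kbq.tolist(),
        "diameter_mm": model.diameter_mm,
        "activity_range_kbq": list(model.activity_range_kbq)}, indent=2))
    return path


def read_marker_model(path) -> MarkerModel:
    rec = json.loads(Path(path).read_text())
    return MarkerModel(np.array(rec["points_mm"]),
                       np.array(rec["activities_kbq"]),
                       diameter_mm=rec.get("diameter_mm", 1.0),
                       activity_range_kbq=tuple(rec.get("activity_range_kbq",
                                                        (296.0, 370.0))))
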