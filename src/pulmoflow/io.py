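"""File interfaces: NIfTI / HDF5 studies, VTK geometry, CSV/JSON sidecars.

Studies round-trip either as NIfTI series (one 4D magnitude image plus
three 4D phase images, frame axis last, with a JSON sidecar for venc,
period and frame times) or as a single HDF5 container.  Geometry is
exported as legacy-ASCII VTK structured points (readable by ParaView);
analysis planes travel in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from pulmoflow.flowquant import FlowWaveform
from pulmoflow.phantom import FlowMRIStudy
from pulmoflow.segmentation import Plane, VesselGeometry
from pulmoflow.windkessel import WindkesselParams

__all__ = [
    "save_study_nifti",
    "load_study_nifti",
    "save_study_hdf5",
    "load_study_hdf5",
    "save_geometry_vtk",
    "save_geometry_npz",
    "load_geometry_npz",
    "save_waveform_csv",
    "load_waveform_csv",
    "save_windkessel_json",
    "load_windkessel_json",
]


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_study_nifti(study: FlowMRIStudy, prefix: str | Path) -> list[Path]:
    """Write magnitude + three phase NIfTI series and a JSON sidecar.

    Volumes are stored (n0, n1, n2, F) with the frame axis fourth, the
    voxel size in the affine.  Returns the written paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.voxel_spacing)
    paths = []
    mag = np.moveaxis(study.magnitude, 0, -1)
    p = prefix.with_name(prefix.name + "_mag.nii")
    nib.save(nib.Nifti1Image(mag.astype(np.float32), aff), p)
    paths.append(p)
    for c, tag in enumerate(("vx", "vy", "vz")):
        vol = np.moveaxis(study.phase_velocity[:, c], 0, -1)
        p = prefix.with_name(f"{prefix.name}_{tag}.nii")
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), p)
        paths.append(p)
    side = prefix.with_name(prefix.name + "_meta.json")
    side.write_text(
        json.dumps(
            {
                "venc": study.venc,
                "period": study.period,
                "frame_times": study.frame_times.tolist(),
                "voxel_spacing": list(study.voxel_spacing),
            }
        )
    )
    paths.append(side)
    return paths


def load_study_nifti(prefix: str | Path) -> FlowMRIStudy:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_name(prefix.name + "_meta.json").read_text())
    mag = np.asarray(nib.load(prefix.with_name(prefix.name + "_mag.nii")).dataobj)
    phases = [
        np.asarray(nib.load(prefix.with_name(f"{prefix.name}_{tag}.nii")).dataobj)
        for tag in ("vx", "vy", "vz")
    ]
    return FlowMRIStudy(
        voxel_spacing=tuple(meta["voxel_spacing"]),
        frame_times=np.asarray(meta["frame_times"]),
        magnitude=np.moveaxis(mag, -1, 0).astype(float),
        phase_velocity=np.stack([np.moveaxis(p, -1, 0) for p in phases], axis=1).astype(float),
        venc=meta["venc"],
        period=meta["period"],
    )


def save_study_hdf5(study: FlowMRIStudy, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("magnitude", data=study.magnitude, compression="gzip")
        f.create_dataset("phase_velocity", data=study.phase_velocity, compression="gzip")
        f.create_dataset("frame_times", data=study.frame_times)
        f.attrs["voxel_spacing"] = study.voxel_spacing
        f.attrs["venc"] = study.venc
        f.attrs["period"] = study.period
    return path


def load_study_hdf5(path: str | Path) -> FlowMRIStudy:
    with h5py.File(path, "r") as f:
        return FlowMRIStudy(
            voxel_spacing=tuple(f.attrs["voxel_spacing"]),
            frame_times=f["frame_times"][()],
            magnitude=f["magnitude"][()],
            phase_velocity=f["phase_velocity"][()],
            venc=float(f.attrs["venc"]),
            period=float(f.attrs["period"]),
        )


def save_geometry_vtk(geometry: VesselGeometry, path: str | Path) -> Path:
    """Legacy-ASCII VTK structured points with the region labels.

    A minimal writer (no VTK dependency); the companion ``.planes.json``
    sidecar stores the analysis planes in world-mm coordinates.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lab = geometry.labels
    n0, n1, n2 = lab.shape
    s0, s1, s2 = geometry.spacing
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("pulmoflow vessel geometry (region labels)\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {n0} {n1} {n2}\n")
        f.write(f"ORIGIN {s0 / 2} {s1 / 2} {s2 / 2}\n")
        f.write(f"SPACING {s0} {s1} {s2}\n")
        f.write(f"POINT_DATA {lab.size}\n")
        f.write("SCALARS region_label int 1\nLOOKUP_TABLE default\n")
        # VTK expects x fastest: transpose to (n2, n1, n0) before ravel
        np.savetxt(f, lab.transpose(2, 1, 0).ravel()[None], fmt="%d")
    planes = {"inlet": _plane_dict(geometry.inlet_plane)}
    planes.update({k: _plane_dict(v) for k, v in geometry.outlet_planes.items()})
    Path(str(path) + ".planes.json").write_text(json.dumps(planes, indent=1))
    return path


def _plane_dict(plane: Plane | None):
    if plane is None:
        return None
    return {"origin": list(plane.origin), "normal": list(plane.normal)}


def save_geometry_npz(geometry: VesselGeometry, path: str | Path) -> Path:
    """Lossless geometry round-trip (mask, labels, spacing, planes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    planes = {"inlet": _plane_dict(geometry.inlet_plane)}
    planes.update({k: _plane_dict(v) for k, v in geometry.outlet_planes.items()})
    np.savez_compressed(
        path,
        mask=geometry.mask,
        labels=geometry.labels,
        spacing=np.asarray(geometry.spacing),
        planes=json.dumps(planes),
    )
    return path


def load_geometry_npz(path: str | Path) -> VesselGeometry:
    d = np.load(path, allow_pickle=False)
    planes = json.loads(str(d["planes"]))

    def mk(p):
        return None if p is None else Plane(tuple(p["origin"]), tuple(p["normal"]))

    outlets = {k: mk(v) for k, v in planes.items() if k != "inlet" and v is not None}
    return VesselGeometry(
        mask=d["mask"],
        labels=d["labels"],
        spacing=tuple(d["spacing"].tolist()),
        inlet_plane=mk(planes.get("inlet")),
        outlet_planes=outlets,
    )


def save_waveform_csv(waveform: FlowWaveform, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": waveform.times, "flow_m3_s": waveform.flow_rate}).to_csv(
        path, index=False
    )
    with open(path, "a") as f:
        f.write(f"# period_s,{waveform.period}\n")
    return path


def load_waveform_csv(path: str | Path) -> FlowWaveform:
    lines = Path(path).read_text().strip().splitlines()
    period = None
    if lines[-1].startswith("# period_s"):
        period = float(lines[-1].split(",")[1])
        lines = lines[:-1]
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines)))
    if period is None:
        dt = np.median(np.diff(df["time_s"]))
        period = float(df["time_s"].iloc[-1] + dt)
    return FlowWaveform(
        times=df["time_s"].to_numpy(), flow_rate=df["flow_m3_s"].to_numpy(), period=period
    )


def save_windkessel_json(params: dict[str, WindkesselParams], path: str | Path) -> Path:
    """Parameters keyed by branch (and optionally patient): SI units."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = {
        k: {"r1": p.r1, "r2": p.r2, "c": p.c, "distal_pressure": p.distal_pressure}
        for k, p in params.items()
    }
    path.write_text(json.dumps(out, indent=1))
    return path


def load_windkessel_json(path: str | Path) -> dict[str, WindkesselParams]:
    raw = json.loads(Path(path).read_text())
    return {k: WindkesselParams(**v) for k, v in raw.items()}
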