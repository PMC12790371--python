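"""HDF5 run container: one file per run, stage groups appended in order.

Layout (all arrays row-major; units attached as attributes):

    /phantom/attenuation            (nx, ny, nz)  [1/um]
    /phantom/fibril_axis            (nx, ny, nz, 3)
    /phantom/anisotropy             (nx, ny, nz)
    /phantom/mean_density           (nx, ny, nz)
    /phantom/mineral_label          (nx, ny, nz)
    /phantom/region_label           (nx, ny, nz)
    /geometry/rotations             (n, 2)  [deg]
    /geometry/q_edges               (n_q + 1,)  [1/nm]
    /projections/<k>/segments       (n_slow, n_fast, n_seg, n_q)  [counts]
    /projections/<k>/transmission   (n_slow, n_fast)
    /recon/..., /minerals/...       stage outputs (optional)
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .geometry import AcquisitionGeometry
from .phantom import MineralSpec, Phantom
from .simulate import ProjectionScan


def write_phantom(h5: h5py.File, phantom: Phantom) -> None:
    g = h5.require_group("phantom")
    for name, arr, units in (
        ("attenuation", phantom.attenuation, "1/um"),
        ("fibril_axis", phantom.fibril_axis, ""),
        ("anisotropy", phantom.anisotropy, ""),
        ("mean_density", phantom.mean_density, "arb"),
        ("mineral_label", phantom.mineral_label, ""),
        ("region_label", phantom.labels, ""),
    ):
        if name in g:
            del g[name]
        d = g.create_dataset(name, data=arr)
        d.attrs["units"] = units
    g.attrs["voxel_size_um"] = phantom.voxel_size
    g.attrs["name"] = phantom.name
    g.attrs["seed"] = -1 if phantom.seed is None else phantom.seed
    g.attrs["mineral_phases"] = json.dumps([s.as_dict() for s in phantom.mineral_phases])


def read_phantom(h5: h5py.File) -> Phantom:
    g = h5["phantom"]
    phases = [MineralSpec(d["kind"], tuple(d["params"]))
              for d in json.loads(g.attrs["mineral_phases"])]
    return Phantom(
        voxel_size=float(g.attrs["voxel_size_um"]),
        attenuation=g["attenuation"][()],
        fibril_axis=g["fibril_axis"][()],
        anisotropy=g["anisotropy"][()],
        mean_density=g["mean_density"][()],
        mineral_label=g["mineral_label"][()],
        mineral_phases=phases,
        labels=g["region_label"][()],
        name=str(g.attrs["name"]),
        seed=int(g.attrs["seed"]),
    )


def write_geometry(h5: h5py.File, geometry: AcquisitionGeometry) -> None:
    g = h5.require_group("geometry")
    for name in ("rotations", "q_edges"):
        if name in g:
            del g[name]
    g.create_dataset("rotations", data=geometry.rotations).attrs["units"] = "deg"
    g.create_dataset("q_edges", data=geometry.q_edges).attrs["units"] = "1/nm"
    g.attrs["n_fast"] = geometry.n_fast
    g.attrs["n_slow"] = geometry.n_slow
    g.attrs["step_um"] = geometry.step
    g.attrs["n_segments"] = geometry.n_segments
    g.attrs["dwell_time_s"] = geometry.dwell_time


def read_geometry(h5: h5py.File) -> AcquisitionGeometry:
    g = h5["geometry"]
    return AcquisitionGeometry(
        rotations=g["rotations"][()],
        n_fast=int(g.attrs["n_fast"]),
        n_slow=int(g.attrs["n_slow"]),
        step=float(g.attrs["step_um"]),
        q_edges=g["q_edges"][()],
        n_segments=int(g.attrs["n_segments"]),
        dwell_time=float(g.attrs["dwell_time_s"]),
    )


def write_scans(h5: h5py.File, scans: list[ProjectionScan]) -> None:
    g = h5.require_group("projections")
    for k, scan in enumerate(scans):
        sg = g.require_group(f"{k:04d}")
        for name in ("segments", "transmission"):
            if name in sg:
                del sg[name]
        d = sg.create_dataset("segments", data=scan.segments.astype(np.float32))
        d.attrs["units"] = "counts"
        sg.create_dataset("transmission", data=scan.transmission)
        sg.attrs["phi_deg"] = scan.phi
        sg.attrs["chi_deg"] = scan.chi
        sg.attrs["dwell_time_s"] = scan.dwell_time
        sg.attrs["flux_ph_per_s"] = scan.flux
        sg.attrs["noiseless"] = bool(scan.noiseless)


def read_scans(h5: h5py.File) -> list[ProjectionScan]:
    g = h5["projections"]
    q_edges = h5["geometry/q_edges"][()]
    scans = []
    for key in sorted(g.keys()):
        sg = g[key]
        scans.append(
            ProjectionScan(
                phi=float(sg.attrs["phi_deg"]),
                chi=float(sg.attrs["chi_deg"]),
                segments=sg["segments"][()].astype(float),
                transmission=sg["transmission"][()],
                dwell_time=float(sg.attrs["dwell_time_s"]),
                flux=float(sg.attrs["flux_ph_per_s"]),
                q_edges=q_edges,
                noiseless=bool(sg.attrs["noiseless"]),
            )
        )
    return scans


def write_raw_volume(path, volume: np.ndarray, lut: dict | None = None) -> None:
    """Export a label/mask volume as 8-bit raw with a JSON sidecar header.

    ``path`` gets the ``.raw`` payload (C-order uint8) and ``path`` with a
    ``.json`` suffix the header (shape, dtype, order, optional colour
    lookup table mapping label -> RGB) — a lowest-common-denominator format
    volume-rendering tools import directly.
    """
    from pathlib import Path

    path = Path(path)
    vol = np.ascontiguousarray(volume)
    if vol.min() < 0 or vol.max() > 255:
        vol = vol - vol.min()  # shift labels (e.g. -1 for unassigned) into range
    vol.astype(np.uint8).tofile(path)
    header = {"shape": list(volume.shape), "dtype": "uint8", "order": "C"}
    if lut is not None:
        header["lut"] = {str(k): list(v) for k, v in lut.items()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))


def validate_container(path) -> dict:
    """Structural and invariant checks of a run container.

    Returns a machine-readable report ``{"ok": bool, "errors": [...],
    "checks": int}``; structural damage yields errors, never a crash.
    """
    errors = []
    checks = 0
    try:
        with h5py.File(path, "r") as h5:
            checks += 1
            for group in ("geometry",):
                if group not in h5:
                    errors.append(f"missing group /{group}")
            if "geometry" in h5:
                checks += 1
                q = h5["geometry/q_edges"][()]
                if np.any(np.diff(q) <= 0) or q[0] <= 0:
                    errors.append("geometry/q_edges not positive increasing")
                if int(h5["geometry"].attrs.get("n_segments", 16)) % 2:
                    errors.append("geometry n_segments must be even")
            if "phantom" in h5:
                checks += 1
                g = h5["phantom"]
                if np.any(g["attenuation"][()] < 0):
                    errors.append("phantom/attenuation has negative values")
                kappa = g["anisotropy"][()]
                if np.any((kappa < 0) | (kappa >= 1)):
                    errors.append("phantom/anisotropy outside [0, 1)")
                if "units" not in g["attenuation"].attrs:
                    errors.append("phantom/attenuation missing units attribute")
            if "projections" in h5:
                for key in sorted(h5["projections"].keys()):
                    checks += 1
                    sg = h5["projections"][key]
                    t = sg["transmission"][()]
                    if np.any(t <= 0) or np.any(t > 1):
                        errors.append(f"projections/{key}: transmission outside (0, 1]")
                    if np.any(sg["segments"][()] < 0):
                        errors.append(f"projections/{key}: negative counts")
                    if "chi_deg" in sg.attrs and not 0 <= sg.attrs["chi_deg"] <= 45:
                        errors.append(f"projections/{key}: chi outside [0, 45] deg")
    except (OSError, KeyError) as exc:
        errors.append(f"structural error: {exc}")
    return {"ok": not errors, "errors": errors, "checks": checks}
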