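"""Glyph export of fibril orientation fields.

Each voxel with a defined main axis becomes one cylinder glyph: a line
segment along the axis whose length scales with the voxel's mean intensity
(percentile-normalised), with the degree of orientation, mean intensity and
an opacity attribute (0 below the DoO threshold, mirroring the strong
transparency mask applied to weakly oriented fibrils) attached as cell
data.  Files are written as ASCII VTK legacy polydata; any VTK-aware viewer
can render the segments as cylinders with a tube filter.
"""

from __future__ import annotations

import numpy as np

from .recon import FibrilOrientationField


def export_glyphs(orient: FibrilOrientationField, path, mask=None,
                  doo_min: float = 0.4, length_percentile: float = 99.0,
                  max_length_voxels: float = 0.9) -> int:
    """Write one glyph per defined voxel; returns the number of glyphs."""
    axis = orient.main_axis
    defined = np.isfinite(axis).all(axis=-1) & np.isfinite(orient.mean_intensity)
    if mask is not None:
        defined &= np.asarray(mask, dtype=bool)
    idx = np.argwhere(defined)
    if len(idx) == 0:
        raise ValueError("no defined voxels to export")

    v = orient.voxel_size
    shape = np.array(axis.shape[:3])
    centers = (idx - (shape - 1) / 2.0) * v
    vecs = axis[defined]
    inten = orient.mean_intensity[defined]
    doo = orient.doo[defined]
    scale = np.percentile(inten, length_percentile)
    length = np.clip(inten / scale if scale > 0 else inten * 0.0, 0.0, 1.0)
    length = length * max_length_voxels * v
    starts = centers - 0.5 * length[:, None] * vecs
    ends = centers + 0.5 * length[:, None] * vecs
    opacity = (doo >= doo_min).astype(float)

    n = len(idx)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("saxstt fibril orientation glyphs\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {2 * n} float\n")
        pts = np.empty((2 * n, 3))
        pts[0::2] = starts
        pts[1::2] = ends
        np.savetxt(fh, pts, fmt="%.6g")
        fh.write(f"LINES {n} {3 * n}\n")
        lines = np.column_stack([np.full(n, 2), np.arange(0, 2 * n, 2),
                                 np.arange(1, 2 * n, 2)])
        np.savetxt(fh, lines, fmt="%d")
        fh.write(f"CELL_DATA {n}\n")
        for name, arr in (("degree_of_orientation", doo),
                          ("mean_intensity", inten),
                          ("opacity", opacity)):
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr[:, None], fmt="%.6g")
    return n


def read_glyphs(path) -> dict:
    """Minimal reader of the files written by `export_glyphs` (round-trip
    checks and downstream scripting)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    out: dict = {"points": None, "lines": None}
    i = 0
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "POINTS":
            n = int(tok[1])
            out["points"] = np.loadtxt(lines[i + 1 : i + 1 + n]).reshape(n, 3)
            i += n + 1
        elif tok[0] == "LINES":
            n = int(tok[1])
            out["lines"] = np.loadtxt(lines[i + 1 : i + 1 + n], dtype=int).reshape(n, 3)
            i += n + 1
        elif tok[0] == "SCALARS":
            name = tok[1]
            n = out["lines"].shape[0]
            out[name] = np.loadtxt(lines[i + 2 : i + 2 + n]).reshape(n)
            i += n + 2
        else:
            i += 1
    return out
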