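"""End-to-end driver: phantom -> simulate -> project-analyze -> reconstruct
-> minerals -> glyphs, with a run manifest for provenance.

Every stage reads from and appends to one HDF5 container; the manifest
records the configuration snapshot, seeds, stage timings, and SHA-256
checksums of every output file, so a rerun with identical config and seed
reproduces identical checksums for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import container as cio
from .geometry import geometry_for_phantom, tomo_rotations
from .glyphs import export_glyphs
from .minerals import analyze_curves
from .phantom import make_phantom
from .recon import (
    ReconConfig,
    extract_orientation,
    prealign_projections,
    reconstruct_absorption,
    reconstruct_field,
    reconstruct_qbins,
)
from .scanning import build_orientation_map
from .simulate import simulate_tomogram

log = logging.getLogger("saxstt")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list = dc_field(default_factory=list)
    checksums: dict = dc_field(default_factory=dict)
    completed: bool = False

    def record(self, stage: str, seconds: float, **info):
        self.stages.append({"stage": stage, "seconds": round(seconds, 3), **info})

    def checksum(self, path):
        path = Path(path)
        h = hashlib.sha256(path.read_bytes()).hexdigest()
        self.checksums[path.name] = h
        return h

    def save(self, path):
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "stages": self.stages,
             "checksums": self.checksums, "completed": self.completed},
            indent=2, default=str))


def demo_config() -> dict:
    """Small end-to-end configuration (16^3 phantom, 12 phi x 3 chi)."""
    return {
        "recipe": "three_paths",
        "shape": [16, 16, 16],
        "voxel_size": 20.0,
        "n_phi": 12,
        "tilts_deg": [0.0, 22.5, 45.0],
        "q_edges": _demo_q_edges(8),
        "flux": 5.0e5,
        "dwell_time": 0.012,
        "noiseless": False,
        "orientation_q_range": [1.61, 1.7],
        "mineral": {
            "invariant_window": [0.025, 2.6],
            "porod_window": [1.6, 2.6],
            "powerlaw_window": [0.025, 0.055],
            "g_boundary": 2.0,
            "t_boundary": 2.2,
        },
        "doo_min": 0.4,
        "recon": {"lambda_rel": 1e-6, "max_iter": 300},
        "mineral_recon": {"lambda_rel": 1e-4, "max_iter": 80},
    }


def _demo_q_edges(n_low: int = 8) -> list:
    """Radial grid covering the low-q power-law window, the mid-q range and
    the Porod regime of few-nm particles, plus the fibril-orientation range."""
    low = np.geomspace(0.02, 0.06, n_low + 1)
    mid = np.geomspace(0.07, 1.5, 7)
    high = np.linspace(1.6, 2.7, 8)
    return list(np.concatenate([low, mid, high]))


_REQUIRED = ["recipe", "n_phi", "tilts_deg", "q_edges", "orientation_q_range"]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        cfg = yaml.safe_load(Path(path_or_dict).read_text())
    missing = [k for k in _REQUIRED if k not in cfg]
    if missing:
        raise ConfigError(f"config missing required field(s): {', '.join(missing)}")
    return cfg


def run_pipeline(config, seed: int = 0, out_path="run.h5",
                 export_dir=None) -> RunManifest:
    """Execute the full chain and return the run manifest.

    Stage errors abort the run; the manifest (returned inside the raised
    exception's ``manifest`` attribute) records partial completion.
    """
    cfg = load_config(config)
    manifest = RunManifest(config=cfg, seed=seed)
    out_path = Path(out_path)
    export_dir = Path(export_dir) if export_dir else out_path.parent
    export_dir.mkdir(parents=True, exist_ok=True)

    try:
        t0 = time.time()
        phantom = make_phantom(cfg, seed=seed)
        rotations = tomo_rotations(int(cfg["n_phi"]), cfg["tilts_deg"])
        geometry = geometry_for_phantom(
            phantom, rotations, q_edges=np.asarray(cfg["q_edges"], dtype=float),
            dwell_time=float(cfg.get("dwell_time", 0.012)))
        manifest.record("phantom", time.time() - t0, shape=list(phantom.shape))

        t0 = time.time()
        scans = simulate_tomogram(
            phantom, geometry, flux=float(cfg.get("flux", 1e6)), seed=seed,
            noiseless=bool(cfg.get("noiseless", False)), dtype=np.float32)
        with h5py.File(out_path, "w") as h5:
            cio.write_phantom(h5, phantom)
            cio.write_geometry(h5, geometry)
            cio.write_scans(h5, scans)
        manifest.record("simulate", time.time() - t0, n_projections=len(scans))
        log.info("simulated %d projections", len(scans))

        t0 = time.time()
        scans, shifts, align_flags = prealign_projections(scans, geometry)
        omap = build_orientation_map(scans[0], cfg["orientation_q_range"])
        manifest.record("project_analyze", time.time() - t0,
                        max_shift_px=float(np.abs(shifts).max()))

        t0 = time.time()
        absorption = reconstruct_absorption(scans, geometry, shape=phantom.shape)
        recon_cfg = ReconConfig(**cfg.get("recon", {}))
        fieldvol = reconstruct_field(scans, geometry, phantom.shape,
                                     q_range=cfg["orientation_q_range"],
                                     config=recon_cfg)
        orient = extract_orientation(fieldvol)
        manifest.record("reconstruct", time.time() - t0,
                        cg_iterations=len(fieldvol.residuals) - 1)

        t0 = time.time()
        mcfg = cfg.get("mineral", {})
        mineral_cfg = ReconConfig(**cfg.get("mineral_recon", {"lambda_rel": 1e-4,
                                                              "max_iter": 80}))
        volumes = reconstruct_qbins(scans, geometry, phantom.shape,
                                    config=mineral_cfg)
        maps = analyze_curves(
            volumes.reshape(-1, geometry.n_q), geometry.q_centers,
            mask=absorption.mask.reshape(-1),
            invariant_window=mcfg.get("invariant_window", (0.025, 0.28)),
            porod_window=mcfg.get("porod_window", (0.16, 0.28)),
            powerlaw_window=mcfg.get("powerlaw_window", (0.025, 0.055)),
            g_boundary=mcfg.get("g_boundary", 2.0),
            t_boundary=mcfg.get("t_boundary", 2.2),
        )
        manifest.record("minerals", time.time() - t0)

        t0 = time.time()
        glyph_path = export_dir / f"{out_path.stem}_glyphs.vtk"
        n_glyphs = export_glyphs(orient, glyph_path, mask=absorption.mask,
                                 doo_min=float(cfg.get("doo_min", 0.4)))
        manifest.record("glyphs", time.time() - t0, n_glyphs=n_glyphs)

        with h5py.File(out_path, "a") as h5:
            g = h5.require_group("recon")
            for name, arr in (
                ("absorption_mu", absorption.mu), ("absorption_mask", absorption.mask),
                ("field_coeffs", fieldvol.coeffs), ("main_axis", orient.main_axis),
                ("doo", orient.doo), ("mean_intensity", orient.mean_intensity),
                ("orientation_a0", omap.a0), ("orientation_theta0", omap.theta0),
            ):
                if name in g:
                    del g[name]
                g.create_dataset(name, data=arr)
            g = h5.require_group("minerals")
            shp = phantom.shape
            for name, arr in (
                ("invariant_q", maps.invariant_q), ("porod_p", maps.porod_p),
                ("t_param", maps.t_param), ("g_exp", maps.g_exp),
                ("phase", maps.phase),
            ):
                if name in g:
                    del g[name]
                g.create_dataset(name, data=np.asarray(arr).reshape(shp))
        manifest.checksum(out_path)
        manifest.checksum(glyph_path)
        manifest.completed = True
        manifest.save(export_dir / f"{out_path.stem}_manifest.json")
        return manifest
    except Exception as exc:
        manifest.completed = False
        try:
            manifest.save(export_dir / f"{out_path.stem}_manifest.json")
        except OSError:
            pass
        exc.manifest = manifest
        raise
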