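# saxstt

Scanning-SAXS orientation analysis and small-angle scattering tensor
tomography (SAS-TT), exercised end-to-end on synthetic phantoms.

SAS-TT combines raster-scanned small-angle X-ray scattering with computed
tomography: a sample is scanned through a micro-focused beam at many
rotations φ ∈ [0°, 360°) and tilts χ ∈ [0°, 45°], and from the azimuthally
segmented scattering patterns one reconstructs, per voxel, a full 3D
reciprocal-space map. For mineralised tissue such as the auditory ossicles
this yields the orientation and degree of alignment of the mineralised
collagen fibrils together with q-resolved measures of the mineral
nanoparticles — information that no single-contrast tomography provides.
Because such beamline datasets are rarely deposited, this package ships a
forward simulator (phantoms with known fibril fields and mineral
populations, Beer–Lambert transmission, Poisson counting noise) so the
entire chain is reproducible and testable from scratch.

The package is aimed at beamline scientists and image-analysis researchers
who want a transparent, tested reference implementation of the SAS-TT
analysis chain.

## What it computes

* **Projection analysis** — per scan point, a cosine fit
  `I(ψ) = a₀ + a₁ cos 2(ψ − θ₀)` to the 8 azimuthal segments (16 detector
  segments reduced by inversion symmetry): symmetric intensity a₀,
  anisotropic amplitude a₁, main orientation θ₀, degree of orientation
  a₁/a₀; HSV colour maps (hue = orientation, saturation = DoO,
  value = intensity).
* **Photon-statistics similarity** — normalised RMSE
  `E = √(Σ(I−R)²/ΣR²)` of a₀ and a₁ maps, and an angular dissimilarity
  `√(1 − s)` on doubled-angle orientation vectors, against the slowest
  acquisition of a 10–500 Hz frame-rate series.
* **Tensor reconstruction** — per-voxel spherical-harmonic coefficients
  (degrees 0 and 2) by preconditioned conjugate-gradient least squares
  with Laplacian smoothing; fibril axis as the eigenvector of the smallest
  eigenvalue of the rank-2 tensor M = ∫f(û) û ûᵀ dΩ; DoO = std/mean =
  `√(Σc₂ₘ²)/c₀₀`; absorption tomogram by filtered back projection of
  −log T; VTK glyph export with a DoO < 0.4 transparency mask.
* **Mineral analysis** — per voxel, from q-resolved mean-intensity
  reconstructions: background subtraction, invariant Q̃ = ∫I q² dq
  (0.025–0.28 nm⁻¹), Porod constant P (0.16–0.28 nm⁻¹), T parameter
  T = 4Q̃/(πP), power-law exponent G (I ∼ q⁻ᴳ, 0.025–0.055 nm⁻¹), and a
  three-phase segmentation of the (G, T) plane at G = 2 and T = 2.2 nm.

See `docs/methods.md` for models, conventions and numerical choices.

## Worked example

Simulate one projection of the `three_paths` phantom (a bone-like cylinder
with a vascular channel and three oriented fibril bundles), analyse it, and
run the frame-rate similarity study:

```python
import numpy as np
from saxstt import (make_phantom, geometry_for_phantom, simulate_framerate_series,
                    framerate_study, build_orientation_map, simulate_scan)

phantom = make_phantom({"recipe": "three_paths", "shape": (16, 16, 16)})
geometry = geometry_for_phantom(
    phantom, [(20.0, 0.0)],
    q_edges=[0.15, 0.17, 0.22, 0.24, 1.6, 1.65, 1.77, 1.8])

scan = simulate_scan(phantom, geometry, 0, flux=5e4, seed=0)
omap = build_orientation_map(scan, (0.17, 0.22))
print(f"mean a0 = {np.nanmean(omap.a0):.3f}, "
      f"max DoO = {np.nanmax(omap.degree_of_orientation):.3f}")

series = simulate_framerate_series(phantom, geometry,
                                   [10.0, 100.0, 500.0], flux=5e4, seed=0)
table = framerate_study(series, [(0.17, 0.22), (1.65, 1.77)])
print(table.round(4).to_string(index=False))
```

prints

```
mean a0 = 209.352, max DoO = 0.176
 rate_hz  q_lo  q_hi  E_mean  E_aniso  E_angle
    10.0  0.17  0.22  0.0000   0.0000   0.0000
   100.0  0.17  0.22  0.0007   0.0141   0.0263
   500.0  0.17  0.22  0.0015   0.0292   0.0484
    10.0  1.65  1.77  0.0000   0.0000   0.0000
   100.0  1.65  1.77  0.0033   0.0281   0.0199
   500.0  1.65  1.77  0.0069   0.0620   0.0466
```

The reference rows (10 Hz against itself) are exactly zero, and all three
errors grow with frame rate — fewer photons per frame — while staying at
the few-percent level, for both a low-q and a high-q window. `mean a0` is
the transmission-normalised symmetric intensity in the low-q window;
`max DoO` is the strongest in-projection anisotropy (projection through a
partly isotropic body, hence well below the voxel-level value).

The full pipeline (phantom → simulate → project-analyze → reconstruct →
minerals → glyphs) runs from the command line:

```bash
saxstt run --seed 1 --out run.h5          # packaged 16³ demo config
saxstt validate run.h5
saxstt project-analyze run.h5 --qrange 0.5:0.6 --out maps/
saxstt reconstruct run.h5 --qrange 1.61:1.7 --out recon.h5
saxstt minerals run.h5 --out minerals.h5
saxstt glyphs recon.h5 --doo-min 0.4 --out glyphs.vtk
```

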