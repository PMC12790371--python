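# Methods

`saxstt` implements the analysis chain of a scanning small-angle X-ray
scattering tensor tomography (SAS-TT) experiment on mineralised tissue, and
a synthetic-measurement generator that makes every stage testable without
beamline data. This note documents the models, the numerical choices, and
what the synthetic conditions do and do not demonstrate.

## Forward model

**Voxel reciprocal-space map.** Each voxel carries an even, nonnegative
function on the unit sphere describing the local SAXS intensity as a
function of probing direction û:

    f(û) = m · [1 + κ(1 − (û·a)²) − 2κ/3],

where `a` is the mineralised-collagen fibril axis, `κ ∈ [0, 1)` the
anisotropy, and `m` the spherical mean (scattering strength). Intensity is
maximal on the equator perpendicular to `a` — the geometry of equatorial
fibril scattering. The kernel is an even quadratic in û and therefore
*exactly* band-limited to real spherical-harmonic degrees {0, 2}; its six
orthonormal-harmonic coefficients are obtained in closed form via the
addition theorem. Band-limiting the phantom to degree 2 is deliberate: the
reconstruction operates at the same band limit, so noiseless recovery can
be exact and reconstruction errors are attributable to the solver, not to
model mismatch. Higher-degree texture is out of scope.

**Radial factor.** A per-voxel 1D model multiplies the angular kernel:
power-law + Porod (`A q^−G + P q^−4 + b`), dilute spheres (orientation-
averaged sphere form factor, optionally polydisperse via an 11-point
Gauss–Hermite average over a Gaussian radius distribution), or dilute thin
plates. Separability (radial × angular) is an idealisation; real bone
curves change shape with direction, which this generator does not emulate.

**Geometry.** Beam along lab +x; tomographic rotation φ about the lab
vertical z, tilt χ ∈ [0°, 45°] about the horizontal y, applied as
R = R_χ·R_φ; the probed direction for detector azimuth ψ is exactly
perpendicular to the beam (small-angle approximation), û_lab = (0, cos ψ,
sin ψ). Sixteen 22.5° azimuthal segments, segment 0 centred on the
+horizontal detector axis, are reduced to 8 by inversion symmetry
(averaging segments i and i+8 weighted by valid-pixel counts).

**Measurement.** Rays are traced through the voxel grid with a vectorised
Siddon algorithm (exact per-voxel chord lengths, µm); scan step equals the
voxel size (20 µm default, matching a 20 µm beam). Expected counts are
`signal × flux × dwell × transmission`, with Beer–Lambert transmission
`exp(−∫µ dl)` as recorded by a semi-transparent beamstop, and Poisson
noise drawn from counter-split substreams of one master seed (one stream
per (rotation, repetition)), so any subset of projections reproduces
bit-identically. The incident flux-to-counts conversion is a free
parameter; it is constrained only by the Poisson scaling property (counts
∝ dwell), which the tests verify by Monte Carlo.

## Projection analysis

Per scan point, intensities in a q window are exposure- and transmission-
normalised and fit with `I(ψ) = a0 + a1 cos 2(ψ − θ0)` by weighted least
squares (weights = valid-pixel counts; for 8 complete equispaced segments
the fit equals the discrete Fourier coefficient at the doubled angle and is
exact on the model span). `a1` is clipped to `a0` so the degree of
orientation a1/a0 stays in [0, 1] even for data where the best-fitting
cosine would dip negative; θ0 is reported modulo π and undefined where
a1 = 0 or fewer than 3 segments are valid. Maps are rendered in HSV: hue
θ0/π, saturation a1/a0, value a0 clipped at a configurable percentile
(99th by default; the display scaling of the original workflow is not
published, so this is a package choice).

**Similarity metrics.** Images at different frame rates are compared with
the normalised RMSE `E = sqrt(Σ(I−R)²/ΣR²)` on the mean intensity a0 and
on the anisotropic amplitude a1 (not a1/a0), with the slowest acquisition
as reference; missing points are excluded pairwise. Orientation maps are
compared via doubled-angle unit vectors v = (cos 2θ, sin 2θ): the
similarity is the per-point mean of (1 + v·v_ref)/2 and the dissimilarity
`E_angle = sqrt(1 − s)`. The affine rescaling is a design choice: θ is a
half-turn quantity, a raw direction dot product is sign-ambiguous, and
this encoding maps identical → 0 and perpendicular → 1, the stated range
of the metric. Whether the original computation averaged per pixel or
flattened weighted images is not published; this contract is fixed here.

## Tomographic reconstruction

**Absorption.** Parallel-beam FBP (Ram-Lak by default) of −log T from the
untilted (χ = 0) subset, slice by slice; negative values clipped; body
mask by Otsu threshold (the thresholding method of the original workflow
is unstated; an absolute override is provided). Fewer than 8 untilted
projections triggers an algebraic (LSQR) fallback over all projections.
Projections are pre-aligned by fitting the centre of mass of −log T of
every projection to the rigid model of a single rotating centroid, with a
second robustly reweighted pass so a grossly misaligned projection cannot
drag the model; iterative sinogram-refinement alignment is out of scope.

**Tensor field.** The per-voxel degree-{0,2} coefficients c minimise
`Σ_k ‖A_k c − d_k‖² + λ‖Dc‖²`, where A_k composes Siddon path integration
with evaluation of the six harmonics at the eight probing directions of
rotation k, and D is the first-difference gradient (Neumann boundaries).
The normal equations are solved by Jacobi-preconditioned conjugate
gradients (preconditioner: exact diagonal of AᵀA plus the regulariser
diagonal); λ defaults to 10⁻² × a power-iteration estimate of ‖AᵀA‖, with
a 200-iteration cap and a relative-residual tolerance. Noiseless recovery
experiments use a much smaller λ (10⁻⁶ relative) because the default
smoothing, appropriate for photon-limited data, biases coefficients near
sharp features by several percent. Nonnegativity is applied to the
spherical mean only, as a final clip — the problem stays linear, a
documented deviation from constrained solvers. The forward and adjoint
operators share one kernel with the simulator, verified by a dot-product
test at 10⁻⁸.

**Readouts.** Per voxel, the second angular moment M = ∫f(û) û ûᵀ dΩ is
evaluated in closed form from the six coefficients; the fibril axis is the
eigenvector of the smallest eigenvalue of M (fibril scattering
concentrates perpendicular to the fibril), undefined when the two smallest
eigenvalues coincide within 10⁻⁶ relative; the degree of orientation is
std/mean over the sphere, `sqrt(Σ c_{2m}²)/c_{00}`. Glyphs are exported as
VTK legacy line segments (one per voxel along the axis, length scaled by
percentile-normalised mean intensity) with DoO, intensity and an opacity
attribute that is 0 below a configurable DoO threshold (default 0.4).

**q-resolved mean intensity.** Two routes exist. Scalar FBP of the
per-bin segment means is fast but imprints Gibbs ringing of bright thin
structures onto faint bins — fatal when the Porod-window signal is orders
of magnitude below the low-q signal, as it is here. The pipeline therefore
uses a regularised algebraic (CG) inversion of the segment means over all
projections, solving all bins jointly. Treating the segment mean as the
line integral of the voxel mean intensity ignores the difference between
the probing-circle mean and the spherical mean of anisotropic voxels (a
per-voxel factor bounded by κ/6 ≈ 13% at κ = 0.8); the factor is
q-independent and cancels exactly in the T parameter and the power-law
exponent, which are the segmented quantities.

## Mineral analysis

Per voxel curve, after fitting `I = P q⁻⁴ + b` on the Porod window and
subtracting the constant b (a non-physical fit, P < 0, falls back to the
curve minimum and is flagged):

* invariant `Q̃ = ∫ I q² dq` over 0.025–0.28 nm⁻¹ (trapezoid, window edges
  interpolated; optional analytic Porod tail P/q_max for full-range use),
* Porod constant P over 0.16–0.28 nm⁻¹ as the bin-width-weighted mean of
  I·q⁴ (the weighting makes oscillations around the asymptote average out
  fairly; exact on pure q⁻⁴ curves),
* `T = 4Q̃/(πP)` in nm — the volume-to-surface thickness measure; for
  dilute spheres T → 4R/3, for dilute plates T → 2×thickness (T equals
  the plate thickness only near 50% packing, not in the dilute limit),
* power-law exponent G as the negative log–log slope over
  0.025–0.055 nm⁻¹, with a validity flag where G > 2 (the T model is
  unreliable there, but T is still reported),
* three phases from the (G, T) plane: **yellow** G > 2; **green** G ≤ 2,
  T > 2.2 nm; **red** G ≤ 2, T ≤ 2.2 nm. Ties are resolved exactly as
  written (G = 2 is not-yellow; T = 2.2 is red), inferred from the phase
  descriptions ("G > 2" compact phase, "G < 2 with larger T", "significantly
  lower T"). Voxels outside the absorption mask or with invalid fits stay
  unassigned. The (T, G) 2D histogram is returned; its binning (64² by
  default) is configurable since the original resolution is unstated.

Background subtraction precedes all three quantities; the source text
attaches "background subtracted" to the whole list, and subtracting first
is the consistent reading.

**Windows and the demo grid.** The window boundaries above are the module
defaults. The end-to-end demo uses a q grid extending to 2.7 nm⁻¹ with
analysis windows (invariant 0.025–2.6, Porod 1.6–2.6 nm⁻¹) because its
synthetic particles are a few nm and their true Porod regime lies beyond
0.3 nm⁻¹: with a window-limited invariant capped at 0.28 nm⁻¹ the ratio
4Q̃/(πP) is bounded below by ≈5 nm for any physically decreasing curve, so
a sub-2.2 nm phase could never be produced. Real bone curves reach small
T in the narrow window only because additional scattering contributions
sit above the q⁻⁴ trend there; the generator does not emulate those.

## Synthetic study conditions

* `three_paths` (the incus-like demo): a cylindrical body with a central
  low-attenuation channel (vascular channel analogue), one oriented bundle
  wrapping the channel and two outer bundles (κ = 0.8, axis ẑ — the three
  high-alignment paths), an outer annular layer, and three mineral
  classes: "compact" `q^−2.5` power law (G > 2) near the channel, "coarse"
  polydisperse spheres R = 4 nm (T ≈ 3.5 nm under the demo windows) in the
  bulk, "fine" polydisperse spheres R = 1.2 nm (T ≈ 0.7 nm) in the outer
  annulus. Attenuation 10⁻³ µm⁻¹ (bone-like transmission ≈ 0.5–0.6 over
  ≈0.5 mm at hard-X-ray energies). Amplitudes keep the inter-phase dynamic
  range within about one decade at matching q, as in real tissue.
* Acquisition: 7 tilt angles equally spaced over 0–45°, 24 φ angles each
  (168 projections), dwell 12 ms; frame-rate series 10–500 Hz. Demo flux
  5×10⁵ photons/s per point — photon-limited at the faint high-q bins
  (hundreds to thousands of counts) while leaving low-q bins
  noise-dominated by reconstruction rather than counting error.
* Problem sizes: 32³ voxels for the noiseless recovery experiment, 24³ for
  the noisy end-to-end demo, 16³ for the packaged quick demo config
  (12 φ × 3 tilts). These sizes fully exercise every code path; accuracy
  at larger grids improves (more rays per feature) rather than degrades.

Passing tests on these phantoms demonstrate correctness of the operators,
fits and rules, and self-consistency of simulation and reconstruction.
They do not demonstrate robustness to real-data effects that the generator
omits: detector flat-field and geometry distortions, alignment drift
beyond rigid shifts, radiation-damage trends within a scan, non-separable
radial/angular structure, and WAXS/crystalline texture.

## Known limitations

* Degree-2 band limit: crossing fibril populations within a voxel reduce
  DoO rather than resolving multiple axes (visible in the demo where
  bundles graze the body edge).
* The absorption FBP uses only untilted projections; tilted scalar FBP is
  not implemented (the algebraic fallback covers degenerate protocols).
* The alignment stage corrects rigid per-projection shifts only.
* T is reported in the generator's arbitrary intensity units times nm;
  absolute electron-density calibration is out of scope.
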