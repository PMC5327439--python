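# Methods

## Imaging model

The specimen is described by its x-ray refractive index n(r) = 1 − δ(r) +
iβ(r). Under the projection approximation, a parallel beam along x at
rotation angle θ leaves the object with phase φ = −k∫δ ds and log-amplitude
ln A = −k∫β ds (k = 2π/λ; λ from the photon energy, default 9.25 keV, the
Ga-Kα line of a liquid-metal-jet anode). Free-space propagation to the
detector is modeled with the paraxial angular-spectrum propagator
H(k⊥) = exp(−i·z_eff·|k⊥|²/(2k)).

A point-source (cone or "inverse") geometry with source–sample distance z₁
and sample–detector distance z₂ is mapped onto this parallel model by the
Fresnel-scaling equivalence: magnification M = (z₁+z₂)/z₁, effective pixel
p = detector_pixel/M, effective propagation distance z_eff = z₁z₂/(z₁+z₂).
Exact divergent-ray tracing through the specimen is deliberately not
modeled — the single-distance retrieval below relies on the same
equivalence, so the simulation and the inversion share assumptions. Finite
source size enters as a Gaussian penumbra blur of FWHM source_fwhm·z₂/z₁ at
the detector, which is why the high-resolution operating point is the
*inverse* geometry (z₁ ≫ z₂). The simulator warns when the first
Fresnel-zone width √(λ·z_eff) exceeds 5 effective pixels, where the
near-field (transport-of-intensity) picture underlying the retrieval erodes.

## Synthetic data

`build_phantom` produces voxelized δ/β maps with a recorded ground-truth
object list. Presets: `cortex_layers` (a tissue cylinder with horizontal
bands of non-touching 5–10 µm spherical cells at differing densities),
`vessel_tree` (air-filled tubes), `fiber_bundle` (aligned cylinders), and
`disk_stack` (explicit ellipsoids, used with the analytic oracles). Optical
constants default to δ = 5·10⁻⁷/β = 10⁻⁸ for background tissue and
δ = 2·10⁻⁶/β = 4·10⁻⁸ for cell bodies: a fixed composition ratio δ/β = 50,
phase-dominated (well above the ≥10 regime that motivates phase contrast)
yet weak enough that the single-distance linearization holds at cell scale.

`simulate_scan` generates equally spaced angles over 180° or 360° (endpoint
excluded), 20 flats and 20 darks (dark level 1% of the flat level), Poisson
counting noise at a configurable flat-field count (default 10⁴), and
per-detector-column multiplicative gains drawn once per scan from N(1, 2%).
The gains are applied to the sample frames but not to the flats — modeling
gain drift between flat acquisition and the scan, which is what lets
stripes survive flat-field correction and become reconstruction rings. All
randomness flows from a single seed through `numpy.random.SeedSequence`;
identical inputs give bit-identical scans.

`analytic_sinogram` evaluates exact chord lengths through ellipses
(Shepp–Logan style) and serves as the reconstruction oracle; it never
samples a grid.

## Retrieval (MBA + BAC)

Normalization is (raw − dark̄)/(flat̄ − dark̄) with frame-averaged flats and
darks; values below 10⁻⁶ are clamped and counted in the QC table, never
silently. The MBA filter is applied to the contrast 1 − I/I_flat on a
mirror-padded grid (25% per side for all Fourier operations — mirror rather
than constant padding avoids step artifacts at frame borders); α is
expressed in squared Nyquist-normalized frequency units so its meaning is
resolution-independent; the κ = 0 mode is zeroed rather than inverted. All
physical prefactors (k, z_eff, 2π conventions) are absorbed into the scale
of the retrieved phase: only the product with the BAC strength γ matters
downstream, and γ is a free parameter anyway.

BAC divides the normalized frame by (1 + γ∇²φ̃), the Laplacian computed as
a Fourier multiplier on the same padded grid. The sign follows from the
retrieval convention used here: to first order ∇²φ̃ equals the fringe term
(I/I_flat − 1) of a pure phase object, so positive γ cancels the fringes
(under the opposite — Bronnikov's — phase-sign convention the same
correction is conventionally written 1 − γ∇²φ). The denominator is clamped
at 0.05 (QC-logged). γ = 1 removes the fringe term exactly in the weak
limit; `tune_gamma` grid-searches γ on a propagated edge when calibration
data are preferred over theory.

Two α policies exist. The generic default is α = 10⁻³. For objects of
homogeneous composition (δ/β = R), `matched_alpha` returns
α = 2kp²/(z_eff·R·π²), for which the MBA+BAC pair at γ = 1 has an exactly
flat spatial transfer to first order: fringes are removed *without*
erasing genuine high-frequency absorption detail. This is the
single-distance analogue of fixing δ/β in Paganin-style retrieval and is
what the end-to-end benchmarks use.

Factor-2 binning (2×2 mean) is applied after retrieval and before
reconstruction when requested, matching the processing order used for the
published-style figures; a switch allows pre-retrieval binning for
experimentation.

## Reconstruction

Line integrals are −ln of the BAC contrast. Sinograms (rows = angles) are
ring-filtered and back-projected:

- **Wavelet-FFT ring filter** (Münch-style): db4 multi-level decomposition
  (levels default ⌊log₂(channels)⌋ − 4, one level shallower than the usual
  rule — deep decompositions measurably damp object structure that varies
  slowly with angle), FFT along the angle axis inside each vertical-stripe
  detail band, damping by 1 − exp(−f²/2σ²) with σ = 2 frequency bins.
- **Simple ring filter**: subtract the detrended angle-mean per channel
  (moving-average window 21); fast, removes isolated column offsets to
  1/window ≈ 5% residual.

Parallel FBP uses the discrete band-limited Ram-Lak kernel (Kak–Slaney: the
frequency response is the FFT of the sampled spatial kernel, which avoids
the DC bias of naive |f| sampling) on rows zero-padded to ≥2× the channel
count, then linear-interpolation back-projection with π/n_angles weighting.
Angles are counter-clockwise, 0° along +x, the rotation center defaults to
the central channel (n−1)/2 with fractional centers supported, and corners
outside the inscribed circle (not determined by complete data) are zeroed.
The implementation agrees with an independent brute-force back-projection
to 10⁻⁶ and with `skimage.transform.iradon` to float precision once the
half-pixel center and axis-transpose conventions are aligned.

FDK cone-beam reconstruction pre-weights each projection by
z₁/√(z₁²+u²+v²) on the virtual detector through the rotation axis, ramp
filters the rows, and back-projects voxel-driven along source–detector rays
with the (z₁/L)² distance weight (bilinear detector sampling, no short-scan
weighting — full 360° assumed for cone mode). In the small-cone limit it
reproduces parallel FBP (0.1% RMS at a 0.4° half-cone in the benchmark).

Region-of-interest (truncated) projections are extended on both sides with
each row's edge value (default pad = half the detector width) before
filtering and cropped back afterwards, which removes ≈99% of the truncation
cupping in the disk benchmark.

## Virtual histology

`n_slices_for_thickness` converts a physical section thickness to a slice
count (largest n with n·voxel ≤ thickness; 30 µm at 0.95 µm voxels → 31
slices). `slab` computes max/min/mean projections over consecutive planes —
MIP for cytoarchitecture, MinIP for vasculature — axis-aligned exactly or
oblique via trilinear resampling. `render_hne` maps intensity monotonically
onto a white→pink→magenta ramp with 1–99 percentile clipping (cosmetic
only). Segmentation replaces the interactive threshold brush with a
scriptable equivalent: an explicit seed-mask volume, a gray range, 26-
connected components, and a minimum size (default 27 voxels ≈ 3³ at ~1 µm
voxels, rejecting single-voxel noise); `cell_statistics` adds centroids in
µm, equivalent-sphere diameters and per-layer counts.

## Benchmarks and their problem sizes

`phasect.validation` (used by both the acceptance tests and
`scripts/acceptance.py`) runs: the MBA single-mode identity on a 128²
periodic grid; BAC edge suppression on a 128² propagated edge with Poisson
noise at 10⁴ counts (overshoot reduced ≈90%, flat-region CV reduced ≈5×);
the FBP oracle at 256 channels × 400 angles (interior error ≈0.04%); FDK vs
FBP on a 64³ two-sphere phantom at 180 angles over 360°; ring filters on a
400×256 smooth-disk sinogram with injected white-noise gains (wavelet) and
isolated column offsets (simple); ROI cupping on a 128-channel truncation
of a 512-channel disk sinogram; and the full pipeline on a 128³
cortex-layers phantom with 60 cells at 200 angles over 180°, noise-free
(Pearson r ≈ 0.97 against 2kβ) and with Poisson noise plus 2% column gains
(r ≈ 0.90, 58–59 of 60 cells recovered at a threshold halfway between the
tissue and cell attenuation levels). These sizes keep the whole benchmark
suite to a few minutes on one CPU while leaving every effect (fringes,
rings, noise, truncation) clearly super-threshold.

## What the simulations do and do not show

The generator reproduces the features the pipeline must undo — near-field
fringes, penumbra blur, photon noise, column-gain rings, dark offsets,
truncation — but not detector scintillator optics beyond a Gaussian PSF,
polychromatic spectra (a single effective energy is assumed), scatter,
specimen motion, or sub-voxel texture. Passing benchmarks therefore
demonstrate the correctness and stability of the algorithms under the
stated acquisition model, not the absolute image quality attainable on any
particular instrument. Cone-beam data are simulated under the same
Fresnel-scaling equivalence the retrieval assumes; FDK is validated in the
small-cone limit against parallel FBP, not against divergent-ray ground
truth.

## Numerical choices and degenerate inputs

Mirror padding 25% per side for every Fourier operation; normalization
floor 10⁻⁶ and BAC denominator floor 0.05, both QC-logged; rotation by
volume resampling with linear interpolation about the central column;
binning trims odd dimensions (logged); empty segmentation results warn
rather than fail; objects that would exceed the phantom grid are rejected,
never clipped silently. Determinism is part of the contract: two runs from
one configuration produce checksum-identical volumes.
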