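# phasect

Laboratory propagation-based phase-contrast CT for virtual histology of soft
tissue — simulation, single-distance phase retrieval, ring-corrected
tomographic reconstruction, and histology-like sectioning with single-cell
segmentation.

## The problem

Unstained soft tissue (e.g. dried, solvent-evaporated brain specimens) barely
absorbs hard x-rays: at ~9 keV the refractive-index decrement δ in
n = 1 − δ + iβ can exceed the extinction β by orders of magnitude, so the
*phase shift* carries the contrast. A microfocus source, a sample at distance
z₁ and a detector at z₂ form a near-field imaging system in which free-space
propagation converts phase gradients into measurable edge-enhancement
fringes. The chain implemented here turns such edge-enhanced projections back
into sharp, quantitative volumes in which individual neurons are countable —
tomography as a non-destructive substitute for histological sectioning.

## The method

Per projection angle θ, with empty-beam-normalized intensity I_θ:

1. **MBA** (Modified Bronnikov Algorithm): approximate phase by a single 2D
   Fourier filter, φ̃ = F⁻¹[ F(1 − I_θ) / (|κ|² + α) ], κ the
   Nyquist-normalized spatial frequency and α > 0 the absorption-dependent
   regularization parameter.
2. **BAC** (Bronnikov Aided Correction): recover the object-plane intensity
   I₀ ≈ I_θ / (1 + γ∇²φ̃), γ > 0 a free strength parameter; in the near
   field ∇²φ̃ reproduces the fringe term, so the division removes the edge
   enhancement while averaging down the photon noise.
3. **Reconstruction**: −ln I₀ → sinograms → wavelet-FFT or column-mean ring
   removal → filtered back-projection (Ram-Lak; parallel FBP or Feldkamp FDK
   for cone geometry). Truncated region-of-interest scans are extended with
   constant edge values before filtering to suppress cupping.
4. **Virtual histology**: arbitrary-orientation slabs (maximum-intensity
   projections emulate thick sections, minimum-intensity projections show
   vasculature), H&E-like rendering, and threshold-based connected-component
   cell segmentation with per-layer statistics.

For a homogeneous-composition object (δ/β = R) the MBA+BAC pair at γ = 1 has
a flat spatial transfer exactly when α = 2kp²/(z_eff·R·π²) (p the pixel,
z_eff = z₁z₂/(z₁+z₂) the effective propagation distance); `matched_alpha`
computes it.

A full synthetic-data module (`phasect.simulate`) emulates the acquisition —
brain-like δ/β phantoms, parallel projection at the effective pixel, Fresnel
propagation over z_eff, penumbra blur, per-column detector gain errors and
Poisson noise — so the whole chain is testable without any scan data, and an
analytic ellipse sinogram provides an exact oracle for the reconstruction.

## Worked example

Simulate a 128³ cortex-like phantom, retrieve contrast, reconstruct and count
cells:

```python
import numpy as np
from phasect import (AcquisitionGeometry, build_phantom, simulate_scan,
                     RegularizationParams, retrieve_stack, reconstruct_scan,
                     threshold_label, n_slices_for_thickness)
from phasect.retrieval import matched_alpha

geo = AcquisitionGeometry(mode="inverse", z1=2000, z2=10, detector_pixel=1.0)
phantom = build_phantom("cortex_layers", 128, seed=7,
                        voxel_size=geo.effective_pixel, n_cells=60)
scan = simulate_scan(phantom, geo, n_angles=200, photon_count=1e4, seed=7)
params = RegularizationParams(alpha=matched_alpha(geo, 50.0), gamma=1.0)
stack, qc = retrieve_stack(scan, params)
vol = reconstruct_scan(stack, scan.angles, geo, ring="wavelet", force_parallel=True)
truth = 2 * geo.wavenumber * phantom.beta_grid
print("voxel correlation:", round(float(np.corrcoef(vol.values.ravel(), truth.ravel())[0, 1]), 3))
cells = threshold_label(vol, None, (0.00234, np.inf), min_voxels=27)
print("cells detected:", cells.n_cells, "of", 60)
print("slices for a 30 um section at 0.95 um voxels:",
      n_slices_for_thickness(30.0, 0.95))
```

Output:

```
voxel correlation: 0.914
cells detected: 58 of 60
slices for a 30 um section at 0.95 um voxels: 31
```

The correlation is against the phantom's effective attenuation 2kβ (the
threshold 0.00234 µm⁻¹ sits halfway between the tissue and cell attenuation
levels); 58 of 60
ground-truth cells are recovered despite Poisson noise at 10⁴ flat counts and
2% per-column gain errors. The same stages are available as a CLI
(`phasect simulate|retrieve|reconstruct|render|segment|run`).

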