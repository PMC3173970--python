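# mraseg

Multiresolution analysis for 2D medical image segmentation: from-scratch
wavelet, finite ridgelet and fast discrete curvelet transforms, composed
into a threshold → transform-denoise → threshold pipeline that extracts
regions of interest (ROIs) and measures their diameters.

The package is aimed at quantitative-imaging work where lesions or
phantom inserts must be isolated from noisy CT/PET-style slices and their
sizes reported with an error statistic. Wavelets capture point
singularities; ridgelets capture line singularities via the finite Radon
transform on prime grids; curvelets capture curved edges — the dominant
structure in medical images — via scale/angle frequency wedges obeying
the parabolic scaling width ≈ length².

## What is implemented

- **Wavelet**: orthonormal 1D/2D DWT (Haar, 4-tap Daubechies), periodic
  boundaries, multilevel Mallat decomposition, exact inverse, detail-band
  hard thresholding.
- **Ridgelet**: finite Radon transform FRAT on Z_p²
  (`r_k[l] = (1/√p) Σ_{(i,j)∈L(k,l)} f(i,j)`, p+1 directions), exact
  back-projection inverse, FRIT = per-direction 1D DWT, blockwise
  processing with symmetric padding.
- **Curvelet**: wrapping-based FDCT — Meyer-window radial/angular
  partition of unity, frequency wedges wrapped into rectangles, tight
  frame (energy-exact, adjoint inverse), band-adaptive hard thresholding.
- **Phantom**: synthetic IEC-style body phantom slice (elliptical cavity,
  six discs of 10–37 mm) with seeded Gaussian noise, plus the
  spheres-to-background ratio SBR = 100·S/(A−S).
- **Segmentation**: intensity thresholds (defaults 35 and 7 on the 8-bit
  scale), connected components, equivalent-diameter measurement
  ED = 2·√(area/π), signed diameter error %, ROI↔sphere matching, and
  MSE/PSNR/SNR evaluation.
- **CLI**: `mraseg phantom | transform | denoise | segment | evaluate`.

## Worked example

```python
import numpy as np
from mraseg import (
    NEMA_SPHERE_DIAMETERS_MM, NoiseModel, PhantomSpec, SegmentationConfig,
    add_gaussian_noise, generate_phantom, match_rois_to_spheres, psnr,
    sbr, segment,
)
from mraseg.curvelet import denoise_curvelet, plan

# spheres-to-background ratio of the standard six inserts on a
# 128x128 grid of 4.6875 mm pixels
print(round(sbr(NEMA_SPHERE_DIAMETERS_MM, 128, 128, 4.6875), 3))  # 0.702

# segment a noise-free fine-grid phantom and report diameters
spec = PhantomSpec(grid=(512, 512), pixel_size_mm=4.6875 / 4)
img = generate_phantom(spec)
_, rois = segment(img, SegmentationConfig(transform="none"))
for roi, actual in match_rois_to_spheres(rois, spec)[0]:
    print(f"{actual:5.1f} mm -> {roi.equivalent_diameter_mm:6.2f} mm "
          f"({roi.error_pct:+.2f} %)")

# curvelet denoising of a 20%-of-max Gaussian-noise phantom
clean = generate_phantom(PhantomSpec())
noisy = add_gaussian_noise(clean, NoiseModel(0.2, seed=0))
den = denoise_curvelet(noisy, plan(128, 128), t=3 * 0.2 * clean.pixels.max())
print(f"PSNR noisy {psnr(clean, noisy):.2f} dB -> denoised "
      f"{psnr(clean, den):.2f} dB")
```

Output:

```
0.702
 10.0 mm ->  10.07 mm (+0.70 %)
 13.0 mm ->  13.09 mm (+0.69 %)
 17.0 mm ->  16.99 mm (-0.09 %)
 22.0 mm ->  21.89 mm (-0.51 %)
 28.0 mm ->  28.05 mm (+0.18 %)
 37.0 mm ->  37.00 mm (+0.00 %)
PSNR noisy 16.12 dB -> denoised 27.45 dB
```

The six inserts are recovered with sub-pixel diameter accuracy, and
curvelet hard thresholding lifts the phantom's PSNR by ~11 dB; on the same
images wavelet denoising reaches ~26 dB and ridgelet ~22 dB, reproducing
the expected quality ordering (curvelet ≥ wavelet ≥ ridgelet) on data
whose structure is curved edges.

The same pipeline from the shell:

```sh
mraseg phantom --size 512 --pixel-size 1.171875 --out phantom.png
mraseg segment --input phantom.png --out seg/
cat seg/rois.txt
```

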