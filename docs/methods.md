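# Methods

`mraseg` implements three multiresolution image representations from first
principles — an orthonormal 2D wavelet transform, the finite ridgelet
transform on prime grids, and a wrapping-based fast discrete curvelet
transform — and composes them into a threshold → transform-denoise →
threshold segmentation pipeline evaluated on a synthetic body phantom.
This note records the models, the conventions and tolerances, and the
design choices made where the construction was genuinely open.

## Wavelet transform

Analysis uses the convention

    a[n] = Σ_i l(i)·x[(2n − i) mod N],    d[n] = Σ_i h(i)·x[(2n − i) mod N],

with the highpass the quadrature mirror of the lowpass,
h(i) = (−1)^i l(L−1−i). Registered filters are Haar and the 4-tap
Daubechies pair (`db2`, two vanishing moments); the registry is extensible
with any pair passing the orthonormality checks (unit norm, sum √2, QMF).

**Boundary policy.** Extension is periodic (circular convolution). One
step is then an orthogonal N×N matrix, so the inverse is the transpose and
both Parseval and perfect reconstruction hold to machine precision; the
tests assert 1e-8 but observe ~1e-15.

**Odd lengths.** A decimated step needs an even length. In multilevel
transforms an odd-length stage carries its last sample through unchanged
on the approximation side and transforms the remaining N−1 samples. The
carry is an isometry, so energy and invertibility are unaffected. This
matters for the ridgelet stage, whose projections have prime length.

**2D.** The nonstandard (Mallat) decomposition: one row pass, one column
pass per level, recursing on LL only. Band order is (LL, LH, HL, HH), the
first letter being the row-direction filter. Detail-band hard thresholding
spares LL — zeroing the DC band would destroy the very foreground the
segmentation stage thresholds on.

## Finite ridgelet transform

The finite Radon transform (FRAT) on a p×p block (p prime) sums along the
modular lines of Z_p²: for slopes k = 0..p−1 the lines
j = k·i + l (mod p), plus the p vertical lines, normalised by 1/√p.
Because any two distinct points share exactly one line, the incidence Gram
matrix is p·I + J, so FRAT is an exact isometry on zero-mean blocks and
inverts in closed form by back-projection:
f(i,j) = (√p·Σ_k r_k[l_k(i,j)] − S)/p.

The finite ridgelet transform (FRIT) applies a multilevel 1D DWT (default
3 levels, capped at ⌊log₂ p⌋) to each projection row. Every row shares the
same mean (each direction's lines partition the grid), so that common DC
level is removed once before the wavelet stage and restored on inversion;
consequently a constant block produces identically zero coefficients and
no threshold can shift a block's intensity level.

Whole images are processed in non-overlapping p×p blocks after padding to
multiples of p by symmetric edge replication — zero padding would plant an
artificial edge on every block border. The default block size is p = 13;
3, 5, 7, 11 and 31 are exercised in tests. The transform is the direct
finite-geometry construction throughout; an FFT-based factorisation over
radial directions would be a performance variant, not a different result,
and is not implemented.

## Curvelet transform (wrapping FDCT)

**Windows.** Both 1D windows are built from the degree-7 Meyer auxiliary
polynomial ν(x) = x⁴(35 − 84x + 70x² − 20x³), which satisfies
ν(x) + ν(1−x) = 1. The radial window W(r) = √(φ(r/2)² − φ(r)²) (with φ a
smooth lowpass profile, 1 on |x| ≤ 1/4, 0 beyond 1/2) telescopes to
Σ_j W²(2^j r) = 1 for every r > 0; the angular window
V(t) = cos(π·ν(|t|)/2) satisfies Σ_l V²(t − l) = 1. Both identities are
tested at 10⁴ samples to 1e-10 (observed: ~1e-15).

**Discrete tiling.** On the centred frequency grid, lowpass products
Φ_s(ξ) = φ(2^{J−s}ξ₁)·φ(2^{J−s}ξ₂) define concentric-square rings
W_s = √(Φ_s² − Φ_{s−1}²), the outermost Φ_J ≡ 1 so the finest ring reaches
the grid corners. Each ring (scales 2..J) is multiplied by a smooth
periodic partition of unity in the polar angle with n_s wedges; the
coarsest band is a single nondirectional square. The squared masks sum to
exactly one at every frequency sample, so the frame is tight: coefficient
energy equals image energy and the adjoint is the exact inverse (tested at
1e-6 relative; observed ~1e-16). Window samples below 1e-12 are treated as
zero when collecting supports — squared-window cancellation otherwise
leaves ~1e-29 residues that would inflate the wedge rectangles.

**Angles and depth.** The second-coarsest scale has n₂ = 16 wedges by
default (at least eight and a multiple of four is enforced), doubling
every other scale toward fine scales — the discrete form of the parabolic
scaling width ≈ length². The default depth is
max(2, ⌈log₂ min(M,N)⌉ − 4) scales, counting the coarse band as a scale:
five for 512×512. Both are overridable in `plan`.

**Wrapping.** Each wedge's supported samples are folded periodically into
a rectangle sized to the wedge's support extents, which makes the fold
collision-free by construction (the index map is checked for uniqueness);
coefficients are the orthonormal inverse FFT of that rectangle. Axis-near
wedge rectangles grow strictly more anisotropic when compared two scales
apart, tracking the angle-doubling cadence. Coefficients are complex; the
inverse projects onto real images by dropping the imaginary part, which is
at rounding level for untouched coefficients and small but genuine after
thresholding (antipodal wedges are thresholded independently). A strict
residue bound can be requested via `max_imag_residue`.

**Denoising.** `denoise_curvelet` hard-thresholds every band except the
coarsest. With `equalize_noise` (default) the threshold for band (j,l) is
scaled by that band's white-noise gain √(Σ|Ũ|²/(R₁R₂)), so a single t
expressed in image-noise standard deviations (3σ is the working default
throughout) acts uniformly across bands.

## Phantom and noise model

The generator renders the equatorial slice of an IEC body phantom: an
elliptical water cavity (default semi-axes 150 × 110 mm) containing six
discs of diameters 10, 13, 17, 22, 28 and 37 mm, centres angularly
equispaced on a 57 mm ring (the physical ring radius is not standardised
in print; it is configurable). The default grid is 128×128 pixels of
4.6875 mm — a 600 mm field of view — with intensities background 0,
cavity 100, sphere 200 on the 8-bit scale. Membership is decided by the
pixel-centre point; optional 4× supersampling renders area-fraction edges.

The spheres-to-background ratio uses the disc-area form
SBR = 100·S/(A − S) with S = π·Σ(d/2)² = 2509.35 mm² and
A = M·N·h² = 360000 mm², giving 0.702% on the default grid.

Noise is additive i.i.d. Gaussian with σ equal to a fraction (default
20%) of the image maximum, seeded, and deliberately not clipped: metrics
and transforms operate on real arrays, and clipping happens only when an
integer image file is written.

**What the phantom does not emulate:** scanner blur/PSF, Poisson counting
statistics, partial-volume averaging across slice thickness, attenuation
or reconstruction artifacts. Passing tests therefore demonstrate the
correctness of the transforms and the pipeline's geometry-recovery logic
under the stated noise law — not clinical performance.

## Segmentation pipeline

hard threshold at t_pre (default 35) → transform denoise at t_coef
(default 0, i.e. pass-through) → hard threshold at t_post (default 7) →
4-connected labelling of nonzero pixels → ROI measurement. Thresholding
zeroes values strictly below t, so t = 0 is an exact identity on
non-negative images. 4-connectivity is deliberate: diagonal noise bridges
must not merge regions. Components touching the border are background;
components smaller than `min_roi_pixels` (default 4) are dropped.

**Container splitting.** On a phantom slice the cavity survives both
intensity thresholds and encloses the spheres, so the labelled foreground
is one nested component and no purely topological rule can separate it.
When the largest component's intensity histogram is bimodal — its Otsu
classes' means separated by more than 1.8 standard deviations of the
component (a unimodal Gaussian separates by ~1.6) — it is treated as a
container: dim pixels are discarded as cavity, bright pixels re-labelled.
A unimodal largest component is kept as an ordinary ROI, so an image whose
only foreground is the spheres loses none of them. `split_container=False`
disables this.

**Measurement.** The equivalent-circle diameter ED = 2·√(area/π) from the
pixel count is the primary diameter estimate (robust to ragged
boundaries); the maximum Feret diameter is reported alongside but not used
for the error statistic. Diameter error is signed,
100·(measured − actual)/actual, negative for underestimation. ROIs are
matched to sphere centres within half the minimal inter-centre distance;
unmatched ROIs are flagged spurious, unmatched spheres missed. Area
accuracy is 100·(1 − |measured − reference|/reference), floored at zero.
The denoising report flags "high data loss" when the denoised-vs-clean
MSE exceeds a configurable bound (default 200 on the 8-bit scale).

## Numerical choices and problem sizes

- Exactness tolerances: DWT/FRIT round trips 1e-8, FDCT round trip and
  energy 1e-6 relative, window identities 1e-10 — all met with orders of
  magnitude to spare since every stage is algebraically exact.
- Transforms are verified on 64²–512² random images; the denoising
  comparison runs on the native 128² phantom grid over five noise seeds
  (median PSNR reported); noise-free recovery runs at 512² (~1.17 mm
  pixels), where all six diameters are recovered within one pixel width.
- Reproducibility: the only randomness is the noise model, driven by a
  single integer seed everywhere (library, CLI, acceptance script).

## Known limitations

- 2D only; no volumetric transforms or 3D lesion segmentation.
- The wrapping rectangles are support-sized rather than the classical
  sheared parallelogram, so redundancy (~4–10× depending on the plan) is
  somewhat higher than canonical wrapping implementations; exactness and
  anisotropy properties are unaffected.
- The intensity thresholds are calibrated to the 8-bit scale; 16-bit
  inputs need rescaled thresholds.
- With strong noise (σ ≈ 20% of max), the pre-threshold rectifies
  background noise into a low haze that the default t_post = 7 cannot
  clear; segmenting such images needs a post threshold above that floor
  (≈ 3σ·0.3; 20 works for the default phantom).
- DICOM support is read-only, single-slice, and exercised only when
  pydicom is installed.
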