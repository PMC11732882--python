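# Methods

This note documents the models, parameter choices and numerical decisions
behind `cordox`, and what its synthetic experiments do and do not show
about real data.

## Phantom and optical model

The cord phantom is a straight cylinder of diameter 2.5 mm (the typical
mouse spinal cord is 2–3 mm) along the scan axis z, on an isotropic voxel
grid (default 0.25 mm for forward simulations). The z extent is divided
into thoracic/lumbar/sacral segments in proportion 13:6:4, matching the
vertebral counts of the 23-segment scheme. Within a segment, every cord
voxel carries total hemoglobin `hbt_level` (arbitrary units) split so that
sO₂ is exactly `baseline_so2 × multiplier(segment)`; optional thin
axis-parallel cylinders emulate vessels with elevated HbT at the local
saturation. Because saturation is a concentration ratio, all acceptance
properties are invariant to the absolute concentration scale, and the
Grüneisen efficiency is fixed at Γ = 1 (only relative amplitudes matter
downstream; it is configurable).

Extinction spectra are a packaged compilation of standard literature
values for HbO₂ and HbR (cm⁻¹ M⁻¹) at 10 nm spacing over 650–1000 nm with
linear interpolation. The five acquisition wavelengths are exact rows. The
table's job is structural — correct HbR peak near 760 nm, isosbestic
crossing near 800 nm, full-rank well-conditioned design matrix — since all
synthesis and inversion use the same table (closed loop).

Fluence is separable: a Gaussian lateral profile (10 mm FWHM, the
instrument's illumination spot) times exponential depth decay
exp(−μ_eff·z). No light-transport model is implied by the source study, so
μ_eff defaults (0.10→0.08 mm⁻¹ from 700→850 nm) are generic soft-tissue
values and configurable. Closed-loop recovery experiments use the same
fluence for generation and normalization (the "ideal fluence" setting);
passing a different model quantifies fluence-mismatch bias.

## Acoustic forward model

Detector elements sit on a spherical cap (radius 40 mm, 110° coverage,
0.85π sr) in a Fibonacci-spiral layout (the real element layout is not
public; the spiral gives quasi-uniform density). Each nonzero voxel is a
point source contributing p₀·dV/(4πr)·g′(t−r/c), where g′ is the time
derivative of the element impulse response — the standard N-shaped
signature of a small absorber. The element response has a **split-Gaussian
amplitude spectrum**: the detection band (2.6–8.6 MHz FWHM) is not
symmetric about the 7 MHz center frequency, so each flank gets its own
Gaussian width, putting the half-maximum crossings exactly at the band
edges. Speed of sound is constant (1.5 mm/µs, configurable); acoustic
heterogeneity of vertebrae is deliberately ignored (the source system's
aberrations are small at these frequencies).

Pulse averaging is modeled by its sufficient statistic — additive white
Gaussian noise with σ/√n_averages — rather than by drawing n_averages
replicates; the empirical variance law is identical and is verified by
test. Elements are point-like by default; an optional aperture mode
averages 16 sample points across the 7 mm² footprint, which is what makes
the reconstruction-side subelement model testable (with point detectors, a
1-subelement reconstruction already matches the data exactly).

## Reconstruction

Per position: zero-phase Butterworth band-pass 0.1–12 MHz (order 4,
forward–backward), Wiener deconvolution H*/(|H|²+reg·max|H|²) with
reg = 10⁻³ of peak spectral power, then plain delay-and-sum with linear
temporal interpolation onto the voxel grid, each element split 4×4 into 16
subelements tiling its footprint tangent to the cap. The pipeline
deconvolves with the point-source signature g′ (not the bare element
kernel): this restores a band-limited impulse at the time of flight so
delay-and-sum peaks at the source; back-projecting signals that still
carry the derivative shape would put a null at the true position. A
derivative-weighted ("universal back-projection") flavor and
nearest-neighbor interpolation sit behind config flags.

Stitching places per-position volumes on the union lattice and blends
overlaps with a triangular distance-to-frame-center weight along z (seams
averaged smoothly); voxels covered by one frame are copied bit-exactly.
Because every step is linear and wavelength-independent, per-voxel
spectral ratios — hence sO₂ — survive reconstruction wherever the
reconstructed amplitude is positive; this is the key invariant the
unmixing stage relies on.

## Unmixing and quantification

Per voxel, least squares on the fluence-normalized five-wavelength spectra
gives (HbO₂, HbR); negative solutions are clipped to zero by default (a
constrained NNLS solve is available). sO₂ = HbO₂/(HbO₂+HbR) on the 0–1
scale — "percent divided by 100", not min–max rescaling — and is defined
only where HbT exceeds a fraction of the volume maximum (default 0.05,
masking background, where band-limited reconstruction makes the ratio
meaningless).

Quantification happens on the sagittal maximum-intensity projection, as in
the source workflow (a 3D mode exists behind a flag): half-open landmark
intervals along z assign defined pixels to thoracic/lumbar/sacral ROIs;
per-subject means plus a pixel-weighted total feed a two-way ANOVA
(genotype × segment) with four Holm–Šidák-adjusted contrasts (three
segments using the pooled ANOVA residual, the total as a pooled two-sample
t) and percent reductions relative to controls.

The end-to-end recovery experiment uses desk-scale settings: 256 elements
(of 512), three scan positions 10 mm apart, 0.25 mm grids, 4 subelements,
and ROI quantification restricted to the reconstructed cord core
(HbT ≥ 0.4·max). The sparse desk-scale array leaves faint streak artifacts
that smear spectra between neighboring segments; analyzing the
high-confidence core — the synthetic analogue of drawing ROIs on the cord
only — keeps segment means within 0.02 of truth. These sizes were chosen
so a full run takes tens of seconds; they are analysis choices of this
package, not instrument parameters.

## Synthetic cohorts

Group-level experiments run at the study's sample sizes: 4 model (M83) vs
3 control (NTL) subjects for oximetry, 9 vs 6 for histology. Injected sO₂
reductions are 15/13/16% (thoracic/lumbar/sacral) on a 0.80 baseline.
Between-subject noise — subject intercept SD 0.02 plus per-segment
residual SD 0.02 — was chosen to be consistent with the reported
significance levels at these sample sizes (adjusted p ≈ 10⁻³ implies a
standardized effect of roughly 4–5 at n = 4 vs 3) and fixed before the
power analysis. The CSA-agreement generator perturbs true elliptical-cord
areas with 7% multiplicative rater noise, calibrated so the expected
Spearman r matches the very strong agreement (~0.96) reported for
automatic-vs-manual segmentation. Histology cohorts set pS129 pixel
densities to the reported magnitudes (≈1.2% nuclear area in models vs
≈0.006% in controls) with 25% lognormal subject variation; vascular
parameters are genotype-independent, mirroring the absence of vascular
differences.

What passing these tests shows: the implementation of each formula and the
statistical machinery are correct at the study's effect and sample sizes.
What it does not show: robustness to real-tissue physics absent from the
generators — spectral coloring (wavelength-dependent fluence error),
acoustic aberration, motion, anatomical clutter (the cervical signal loss
under brown adipose tissue is not modeled), segmentation errors with
spatial structure, or staining variability.

## Morphometry details

CSAs are voxel counts × in-plane voxel area, per axial slice, without cord
angle correction (matching the validation setting of the source workflow).
Segment summaries average 5 consecutive slices **centered** on each anchor
(window placement was unspecified); both GM/WM and WM/GM ratios are
reported because the source text uses both conventions. The synthetic
label volume uses concentric ellipses (GM strictly inside WM) with
sinusoidal modulation of the semi-axes along the cord; a butterfly-shaped
GM was rejected because the per-slice closed-form area that the oracle
tests need does not exist for it. Pixel-center rasterization leaves ≤2%
CSA error for semi-axes ≥ 14 voxels (≈2.3% worst-case at 11 voxels).
Spearman p-values use the t approximation for n ≥ 10 and exact permutation
enumeration below that.

## Histology details

All mask operations use 8-connectivity. Skeletons come from
topology-preserving thinning; length counts unique skeleton edges with
chamfer weights (1 orthogonal, √2 diagonal, skipping diagonal shortcuts
already covered by orthogonal steps) — the convention of the original
ImageJ script is unknown, so this standard choice is documented as an
assumption. Branch points are skeleton pixels with ≥3 skeleton neighbors,
merged within a 1-pixel radius to avoid double-counting thick junctions.
Otsu (or fixed) thresholding is provided for raw fluorescence, but all
formulas — and all tests — operate on binary masks, which is where the
measurement definitions live. Mann–Whitney tests are exact where sample
sizes permit; all-tied data report p = 1 with a warning.

## Degenerate inputs and tie-breaks

Empty segments and fully masked volumes return flagged NaNs with warnings
rather than raising; zero HbT makes sO₂ undefined everywhere; constant
vectors make Spearman r undefined (flagged); an empty DAPI mask leaves the
nuclear fraction undefined. Wiener regularization (10⁻³) bounds noise
amplification out of band; ties in ranks use average ranks; the MIP takes
the maximum over defined voxels only.

## Known limitations

No Monte-Carlo light transport, no full-wave acoustics, no frequency-
dependent attenuation, no motion or registration errors, no GPU path. The
synthetic cord is geometrically idealized; absolute reconstructed
amplitudes are not calibrated (only ratios are meaningful). Statistical
conclusions transfer to real cohorts only insofar as the noise model
(independent subjects, roughly normal segment means for the ANOVA branch)
holds.
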