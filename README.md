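# cordox

Desk-scale, fully synthetic re-creation of a multimodal measurement chain
for spinal-cord oximetry and morphometry in mouse models of
alpha-synucleinopathy: volumetric optoacoustic (photoacoustic) simulation
and reconstruction, spectral unmixing to oxygen-saturation maps with
segment-wise group statistics, MRI gray/white-matter cross-sectional-area
(CSA) morphometry, and formula-defined histology metrics.

It is written for imaging scientists and analysts who want to exercise,
test or extend each stage of such a pipeline against known ground truth —
every input is generated by the package itself, with the generating
parameters recorded.

## The measurement chain

**Oximetry.** A voxelized cord phantom assigns oxy-/deoxyhemoglobin
concentrations so that each spinal segment (thoracic, lumbar, sacral) has a
known saturation sO₂ = HbO₂/(HbO₂+HbR). Optical absorption at wavelength λ
is μₐ(λ) = ε_HbO₂(λ)·C_HbO₂ + ε_HbR(λ)·C_HbR, and initial acoustic pressure
p₀ = Γ·μₐ·Φ with a Gaussian-beam/exponential-depth fluence Φ. A
hemispherical array (512 elements, 40 mm radius, 110° coverage ≈ 0.85π sr,
7 MHz center frequency, 2.6–8.6 MHz FWHM band) records time traces at
40 MSps for five wavelengths (700/730/760/800/850 nm, 20 pulse averages) at
step-and-go scan positions. Reconstruction band-passes (0.1–12 MHz),
Wiener-deconvolves the element response, back-projects by delay-and-sum
with 16 subelements per element, and stitches positions along the spine.
After fluence normalization, per-voxel least squares on the five-wavelength
spectra yields HbO₂/HbR and the sO₂ map on a 0–1 scale. Quantification uses
the sagittal maximum-intensity projection, landmark-based thoracic/lumbar/
sacral ROIs, per-subject segment means, and a two-way ANOVA
(genotype × segment) with Holm–Šidák-adjusted contrasts and percent
reductions 100·(mean_control − mean_model)/mean_control.

**Morphometry.** GM/WM label volumes (0 background / 1 GM / 2 WM, 50 µm
voxels) give per-slice CSAs as voxel count × in-plane area (no angle
correction), averaged over 5 consecutive slices per segment for the
23-segment scheme (T1–T13, L1–L6, S1–S4); agreement between two
segmentations is Spearman rank correlation.

**Histology.** On binary masks: vessel area fraction, skeleton length
(chamfer 1/√2 weighting) and branch count (CD31); area fraction (GLUT1);
and relative nuclear / cytoplasmic pS129 α-synuclein signal areas,
|pS129∩DAPI|/|DAPI| and |pS129∖DAPI|/(|image|−|DAPI|), compared across
groups by Mann–Whitney U with Holm–Šidák adjustment.

## Worked example

Recover the injected genotype effect end-to-end (about half a minute on a
laptop-class CPU):

```python
from cordox.pipeline import run_so2_recovery

res = run_so2_recovery(seed=1)   # 15% thoracic sO2 reduction injected
print(res.segment_table[["segment", "mean_so2", "n_pixels"]])
print("truth:", res.ground_truth)
```

prints

```
    segment  mean_so2  n_pixels
0  thoracic  0.689367       540
1    lumbar  0.802949       236
2    sacral  0.805389       151
3     total  0.737182       927
```

against ground truth `{'thoracic': 0.68, 'lumbar': 0.8, 'sacral': 0.8}`:
the full simulate → reconstruct → unmix → project → quantify chain returns
every segment mean within 0.02 of the phantom's true saturation, including
the 15% thoracic drop. Group-level statistics on a synthetic cohort
(4 model vs 3 control subjects):

```python
from cordox.cohort import simulate_so2_cohort
from cordox.roi_quant import group_compare

res = group_compare(simulate_so2_cohort(seed=3))
print(res.contrasts[["segment", "percent_reduction", "p_adj"]])
```

```
    segment  percent_reduction     p_adj
0  thoracic          15.137874  0.000194
1    lumbar          11.000110  0.001389
2    sacral          16.528506  0.000119
3     total          14.308601  0.001243
```

i.e. the injected 15/13/16% segment reductions are recovered and all four
contrasts are significant after Holm–Šidák adjustment.

A CLI mirrors the stages for file-based use:

```bash
cordox simulate-phantom --config cfg.toml --seed 1 --out phantom.h5
cordox acquire --phantom phantom.h5 --config cfg.toml --out sino.h5
cordox reconstruct --sinograms sino.h5 --config cfg.toml --out-dir recon/
cordox unmix --in-dir recon/ --out-dir unmixed/
cordox quantify --so2 unmixed/so2.nii --mask unmixed/mask.nii \
    --rois rois.toml --out segments.csv
```

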