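# tacsquant

Quantitative image analysis of collagen I organization at the mammary
tumor–host interface, for researchers studying how stromal remodeling (for
example by matrix metalloproteases such as MMP-13) shifts tumor-associated
collagen signatures (TACS) and with them metastatic behavior.

Tumor boundaries are imaged by two-photon microscopy in simultaneous
channels: collagen I immunofluorescence (IF), backward-detected second
harmonic generation (B_SHG), and optionally forward-detected SHG (F_SHG).
`tacsquant` implements the full quantification pipeline over those channels:

1. **Preprocessing** — per-channel maximum intensity projection of each
   z-stack, and subtraction of a scalar background estimated as the mean
   pixel count of a blank-slide acquisition.
2. **Coherency** — the structure-tensor anisotropy statistic

   ```
   C = (λ_max − λ_min) / (λ_max + λ_min)
   ```

   where λ_max, λ_min are the eigenvalues of the Gaussian-window-smoothed
   structure tensor J = W ∗ (∇I ∇Iᵀ). C = 1 marks perfectly oriented local
   structure (taut, parallel TACS-2-like fibers), C = 0 isotropy (diffuse
   TACS-1-like deposition). The per-image statistic is the mean of C over
   all pixels; HSB overlays (hue constant, saturation = C, brightness =
   image) visualize where ordered collagen sits.
3. **Normalized B_SHG** — mean B_SHG over the thresholded collagen-I-positive
   pixel set divided by mean IF over the identical pixels: an
   expression-adjusted readout of SHG conversion efficiency.
4. **F/B ratio** — the pixelwise F_SHG/B_SHG ratio over a fiber mask,
   reporting on sub-resolution fibril diameter and packing (thicker fibrils
   emit more forward-directed SHG).
5. **Cohort statistics** — mean ± SEM summaries, unpaired t-tests,
   Wilcoxon–Mann–Whitney (exact for small samples), ANOVA with protected
   Fisher LSD post-tests, lung-metastasis density (metastases/cm², animals as
   the unit), and ellipsoid tumor volume L·W²/2.

Because no imaging data are publicly deposited for this assay, the package
ships a first-class synthetic scene generator
(`tacsquant.synthetic`) that renders ground-truth-annotated multi-channel
z-stacks of straight fibers with von Mises-distributed axial orientations
plus a diffuse unoriented collagen bed. Two presets encode the phenotypes of
interest — `WT` (long, thick, strongly co-oriented fibers) and `KO` (short,
thin, weakly oriented fibers in a dense diffuse bed with more total collagen)
— so the whole pipeline is testable end to end against known truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts at the study's field-of-view counts (16 WT vs 14 KO):

```sh
python analysis/01_simulate_cohorts.py   # TIFF stacks -> scratch/, manifest -> results/
python analysis/02_image_metrics.py      # mean IF + coherency per FOV
python analysis/03_shg_metrics.py        # normalized B_SHG + F/B per FOV
python analysis/04_group_statistics.py   # group summaries, tests, directions
python analysis/05_metastasis_density.py # simulated metastasis count table
```

Output of `04_group_statistics.py` (seed 1):

```
mean_if:         WT 42.35 ± 0.34  (n=16) vs KO 64.13 ± 0.75  (n=14); expected KO greater; holds=True; t p=8.39e-22
mean_coherency:  WT 0.797 ± 0.0055 (n=16) vs KO 0.6307 ± 0.0029 (n=14); expected KO less;   holds=True; t p=5.92e-21
normalized_bshg: WT 0.9845 ± 0.0013 (n=16) vs KO 1.575 ± 0.0017 (n=14); expected KO greater; holds=True; t p=9.02e-50
mean_fb_ratio:   WT 5.228 ± 0.027  (n=16) vs KO 2.092 ± 0.016  (n=14); expected KO less;   holds=True; t p=1.07e-36
all four contrasts reproduced: True
```

Read: relative to WT, the knockout cohort shows more total collagen I
(higher mean IF), less ordered collagen (lower coherency), more backward SHG
per unit collagen I (higher normalized B_SHG), and thinner/differently packed
fibrils (lower F/B) — the four directional signatures of the TACS-2 → TACS-1
shift, each significant at the cohort scale.

The same pipeline is available as a CLI (`tacsquant simulate | preprocess |
coherency | shg | compare | replicate`); `tacsquant replicate --out DIR` runs
everything in one command and writes a JSON report.

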