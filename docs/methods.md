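# Methods

## Imaging model and preprocessing

Each field of view (FOV) is a z-stack per detection channel: collagen I
immunofluorescence (IF), backward SHG (B_SHG), and optionally forward SHG
(F_SHG). Stacks are collapsed by per-pixel maximum intensity projection,
which acts as an autofocus for an effectively single collagen layer. The
background is estimated as the scalar mean pixel count of a blank-slide
acquisition processed the same way (maximum projection of the blank stack),
and subtracted from every projection with negatives clipped to zero —
downstream means and ratios assume non-negative intensities. One blank
estimate per slide is applied to all FOVs of that slide. A pixelwise
subtraction path (the maximum projection of a closed-shutter stack,
subtracted image-from-image) is available via
`AnalysisConfig(background_mode="image")` for the F/B acquisition geometry.

Stacks are written as multi-page grayscale 16-bit TIFF with values rounded
to integer counts (detector semantics); integer-valued stacks round-trip
exactly. Pixel coordinates are 0-based `(row, column) = (y, x)`.

## Structure-tensor coherency

Gradients are estimated by Gaussian-derivative filtering (default
σ_g = 1 px); the outer-product fields gx², gx·gy, gy² are smoothed by a
Gaussian window (default σ_w = 2 px), or by a uniform box window when an
exact integer-period average is required. Boundaries are reflected. The
coherency per pixel is

C = (λ_max − λ_min)/(λ_max + λ_min) = sqrt((Jxx − Jyy)² + 4 Jxy²)/(Jxx + Jyy),

with the closed form verified against eigen-decomposition in the tests.
Where the tensor trace is ≤ 1e-12 × the image's maximum trace the pixel
carries no orientation and C := 0 (a flat region is maximally isotropic).
The image statistic is the arithmetic mean of C over **all** pixels,
background included; a masked variant exists but is not the default. Tests
that need analytic values exclude a border margin of 3 × (σ_g + window
scale), where filter support interacts with reflection.

Two analytic anchors pin the estimator: a linear intensity ramp has a
rank-one tensor everywhere in the interior, so mean C = 1 exactly; the sum
of two orthogonal equal-amplitude sinusoidal gratings, window-averaged over
an integer number of periods, has Jxx = Jyy and Jxy = 0, so mean C = 0.
Absolute coherency values on real images depend on the gradient/window
scales; group **contrasts** are the reproducible object, which is why the
defaults are fixed package-wide and applied identically to all groups.

HSB maps encode hue = constant, saturation = C, brightness = image rescaled
by its maximum, so bright saturated regions mark ordered, bright collagen.

## Ratiometric SHG measures

*Normalized B_SHG*: the IF projection is thresholded to select
collagen-I-positive features; B_SHG is masked to the identical pixel set and
the metric is mean(B_SHG | mask)/mean(IF | mask). *F/B*: the
background-subtracted F and B projections are divided pixelwise; pixels at
or below the B_SHG threshold are excluded by binary masking (which also
guarantees a nonzero denominator), and the metric is the pixel-weighted mean
of the ratio. The IF-derived mask gates normalized B_SHG and the
B_SHG-derived mask gates F/B; the two are never interchanged. Ratio pixels
outside the mask are NaN, not 0, so they cannot silently enter a mean.

The thresholds of the original assay are not recoverable; the default is a
quantile standard (95th percentile of the background-corrected image)
applied identically to every image of every group, overridable by a fixed
absolute value (`fixed:<v>`). Absolute metric values are
threshold-dependent; directions of group contrasts are robust to it.

## Synthetic scenes

The generator emulates what the analysis assumes, not SHG wave optics.
Fibers are straight anti-aliased segments with Gaussian cross-section
(σ = width/2); axial orientations follow a von Mises law on the doubled
angle (concentration κ; κ = 0 isotropic), folded to [0, π). Widths and
lengths are truncated-normal. An unoriented diffuse speckle field (smoothed
exponential noise) carries a prescribed fraction `diffuse_fraction` of the
total collagen signal; with `diffuse_fraction = 1` fibers are suppressed and
the diffuse field carries the whole budget (a nominal 2% coverage reference
scales a fiber-free scene). Channels are linked by per-scene gains:
IF = if_gain × (fibers + diffuse); B_SHG = bshg_gain × (fibers + 0.2 ×
diffuse), since diffuse, immature collagen converts weakly; F_SHG = B_SHG ×
fb_gain with fb_gain = fb_gain_per_um × local dominant-fiber width
(diffuse-equivalent width 0.5 µm elsewhere), making F/B strictly increasing
in fibril width by construction. z-slices are intensity-jittered copies of
the in-focus plane with one slice always at full signal, so maximum
projection recovers the noiseless scene exactly; Gaussian read noise and a
constant offset are added everywhere, and the blank stack contains offset +
noise only. Defaults: 256 × 256 px at 680/512 ≈ 1.33 µm/px, 8 slices,
offset 10, noise SD 4 counts.

Preset magnitudes are package constants chosen once so that all four
phenotype contrasts hold with wide margins — the source assay reports
directions, not effect sizes, so magnitudes are necessarily invented and
labeled as such:

| parameter | WT | KO |
|---|---|---|
| n_fibers | 45 | 70 |
| orientation κ | 8 | 0.5 |
| width mean ± sd (µm) | 5 ± 0.8 | 2 ± 0.4 |
| length mean ± sd (µm) | 150 ± 30 | 50 ± 15 |
| fiber intensity | 120 | 300 |
| diffuse fraction | 0.10 | 0.55 |
| if_gain / bshg_gain | 1.0 / 1.0 | 1.3 / 2.2 |

The KO preset's higher fiber intensity and IF gain encode the knockout's
collagen I accumulation; its higher bshg_gain encodes greater SHG conversion
per unit collagen I. What passing tests show is that the pipeline recovers
each generator dial (κ → coherency, width → F/B, gains → IF and normalized
B_SHG) and the four contrast directions at the study's FOV counts; they do
not certify absolute values on real tissue, where fiber curvature,
cross-hatching, depth attenuation and detector nonlinearity — none of which
the generator emulates — shift absolute coherency and threshold behavior.

## Statistics

Group summaries are mean ± SEM (sample SD with n−1 denominator over √n; SEM
is reported absent for n = 1). Tests are two-sided: unpaired pooled-variance
Student's t; Wilcoxon–Mann–Whitney with the exact null for combined n ≤ 20
without ties and the tie-corrected normal approximation otherwise; one-way
ANOVA whose Fisher LSD pairwise t-tests (pooled within-group mean square,
df = N − k) run only when the omnibus test is significant ("protected",
which holds the familywise error at α for three groups). Identical constant
samples yield t = 0, p = 1; zero variance in both groups with different
means is an error rather than an infinite statistic. The unit of analysis is
the FOV for image metrics and the animal for metastasis density (per animal:
total counts over total sectioned area across its 10 sections); FOVs within
an animal are treated as independent, as in the source assay — a mixed-model
treatment of FOV-within-animal correlation is a known limitation, noted but
not implemented. Tumor volume uses the ellipsoid estimator V = L·W²/2 with
the formula name recorded; swapped calipers are auto-corrected with a
warning.

## Replication run and problem sizes

`run_replication` simulates WT (16 FOVs) and KO (14 FOVs) cohorts from one
global seed (per-FOV seeds spawned via `numpy.random.SeedSequence` children,
reduced mod 2³¹), measures all four metrics per FOV in memory, and tests
each contrast. Scenes default to 256 × 256 px — a quarter of the 512-px
acquisition raster at the same pixel pitch — which keeps a 20-seed
Monte-Carlo replication under a minute while leaving each FOV large relative
to fiber width and filter support; tests that only exercise structure use
64 × 64 scenes. Reports are JSON with sorted keys, byte-identical for a
given configuration.

## Numerical conventions

Gaussian kernels are sampled and truncated at 4σ with the order-0 kernel
normalized to unit sum; correlation (not convolution) orientation is used
throughout and mirrored by the loop oracles in the tests. Thresholding is
strictly greater-than. Masks record their threshold and source channel.
Empty masks make a metric absent (None/NaN) with a warning rather than zero.
All intensities are float64 internally; 16-bit only at the TIFF boundary.
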