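# Methods

## The generative phantom

### Geometry

`mouse_retina_model()` builds a light-adapted mouse retina as a contiguous
piecewise-constant ("staircase") axial reflectance profile. Depths are
0-based µm from the vitreous edge of the axial window; the retina starts at a
60 µm offset. Calibrated totals: inner retina 79.42 µm (OPL/ONL boundary −
inner surface), ONL 58.08 µm (ELM peak − OPL/ONL boundary), ELM–RPE complex
48.73 µm (basal RPE − ELM peak); the cone- and rod-tip IZ bands sit 13.4 and
20.9 µm outer of the ISe peak. The internal partition of the inner retina
(NFL 12, GCL 10, IPL 28, INL 18, OPL 11.4 µm) and the band reflectances
(ONL 0.45, ELM 1.9, ISe 4.0, cone tip 1.8, rod tip 2.8, RPE 2.6, choroid 1.1
a.u., hypo-reflective separators 0.55–0.9) are plausible-mouse choices, not
calibrated quantities; only ordering (ONL hypo, named bands hyper) and the
resulting peak separability matter to the pipeline.

Thin hypo-reflective separators — the IS myoid between ELM and ISe, the
inter-tip rod outer-segment stretch, and a pre-RPE gap — are modelled
explicitly. Without them a piecewise-constant profile cannot exhibit the
named bands as *distinct local maxima* after PSF blur: adjacent bright
segments merge into shoulders. These separators are visible in real mouse
OCT and carry no kinetics of their own.

Retinal curvature is a quadratic axial bowing, default 111 µm/mm² (≈40 µm
across the 1.2 mm field), applied radially over both lateral axes. It makes
flattening a real task rather than a no-op.

### Optics and noise

A-lines are the staircase convolved with a Gaussian axial PSF whose FWHM is
the source coherence length `(2 ln 2/π)·λ²/Δλ` (2.9 µm at λ = 810 nm,
Δλ = 100 nm). The convolution is evaluated in closed form (sums of Gaussian
CDFs), so the noiseless profile has no kernel-discretization error; lateral
curvature and jitter shifts are applied by linear interpolation on a 0.25 µm
grid (error ≲ 10⁻⁴ of the peak).

Speckle is multiplicative unit-mean gamma noise with shape = number of
independent looks (fully developed speckle with L looks). The default is 4
looks per recorded pixel, representing mild spatial oversampling; averaging
N independent frames multiplies the look count by N, which gives the
pipeline's 1/N variance reduction. `speckle_looks = inf` renders noiseless
data. High-speed frames optionally carry a slow sinusoidal axial drift
(default 1 µm at 0.1 Hz) emulating respiration; it is slow enough that
within-column (1 s) smear stays sub-pixel.

### Kinetics

`KineticsParams` drives all time dependence through one ramp r(t): 0 before
lights-off, then rising to 1 at `t_sat_min` (default 30 min) — linearly by
default, because the measured changes progress approximately linearly over
the 30-min dark period; a saturating-exponential alternative is provided.
At ramp r:

* ISe reflectance × (1 − 0.25·r) — the fractional drop default (0.25) is a
  package choice of realistic magnitude; no calibrated value exists for it;
* the ELM band (and everything outer) shifts inward by 1.76·r µm (ONL
  shortening), and depths outer of the ELM band contract so the basal RPE
  moves by exactly 4.07·r µm (ELM–RPE shortening). The two defaults make the
  displacement bookkeeping self-consistent: total outer-retinal displacement
  at saturation is 4.07 + 1.76 = 5.83 µm, of which the ELM–RPE complex
  carries 69.8% (~70%);
* both IZ tip reflectances relax toward the OS level by a fractional
  contrast loss (default 0.5);
* NFL…OPL are strictly invariant.

`KineticsParams.null()` zeroes every change — the light-stable control
scenario.

## Estimators

**ELM detection** (`detect_elm`): each A-line is normalized-cross-correlated
against an outer-retina template (a canonical noiseless phantom profile from
25 µm inner to 45 µm outer of the ELM). The correlation maximum is refined
with a 3-point parabola — the score pools the whole template, making the
refinement far less speckle-sensitive than refining the raw intensity peak.
Windows with negligible variance (background) are excluded from scoring. A
lateral median filter (15 A-lines) replaces positions jumping > 4 px;
detection fails loudly if fewer than 50% of A-lines reach correlation 0.5.

**Flattening** shifts each A-line by linear interpolation so the ELM sits at
a common reference row (median trace depth by default; a volume-wide median
when reducing a volume). Zero-fill outside the window.

**Representative profile**: average the 4 co-located repeats, flatten each
central B-scan, average 150 central B-scans, then 200 central A-lines,
upsample 4× by linear interpolation (sample pitch 1.25/4 ≈ 0.31 µm). With
default windows one profile aggregates 120,000 raw A-scans. Averaging
happens on linear intensities; log compression is considered display-only.

**Normalization**: divide by the mean intensity over the central 50% of the
ONL span (default span 50→10 µm inner of the ELM anchor). The mean (not the
minimum) is the default reference; the minimum is available behind a flag.

**Band segmentation** (`locate_bands`): smooth with σ = 1 original pixel,
find local maxima with prominence ≥ 0.1 × the ISe-candidate height, anchor
the ELM via the same template correlation applied to the 1-D profile
(robust even when the ISe is not the global maximum), assign NFL, IPL, OPL,
ISe and RPE in ordered windows relative to the ELM, and refine each peak
with a parabola (clamped to half a sample). ELM, ISe and RPE are mandatory;
inner bands may be absent on cropped profiles.

**Double OS-tip peaks**: search the open interval (ISe + 2 µm, RPE − 2 µm)
for up to two maxima with prominence ≥ 0.1 (ONL-normalized units). Two
maxima → cone tip (shallower) + rod tip (deeper), `resolved=True`; one →
rod tip only. Absence is encoded, never an error. Tips separated by less
than the PSF FWHM merge into one maximum by construction.

**Boundaries**: inner surface = first rise through 50% of the NFL peak;
OPL/ONL = half-prominence crossing on the outer OPL flank; ELM = ELM peak;
basal RPE = half-prominence crossing on the outer RPE flank (midpoint of
peak and outer trough — a strict half-*maximum* level can fall below the
choroid baseline and never be crossed, so the prominence-referenced level is
used for both flanks; under a symmetric PSF it lands on the staircase edge).
All criteria are relative → gain-invariant. Thicknesses are boundary
differences, so ONL + ELM–RPE = outer retina holds exactly by construction.

**M-scan** (`build_mscan`): 16-frame blocks → averaged frame → flatten →
average 200 central A-lines → upsample 4× → align every column's ELM peak to
the common median row → normalize each column by its own ONL mean. Trailing
partial blocks are dropped (1 column = 1 s stays exact). Transition kinetics
re-locate the ISe peak (±4 µm window) and basal RPE (±6 µm) per column,
seeded by the pre-lights-off mean profile; per-column smoothing uses
σ = 2.5 µm — wider than the volume-profile default because one column
averages ~40× fewer A-scans. Displacement is referenced to the
pre-lights-off column mean; Pearson correlations and line fits (time in
minutes since lights-off) use post-lights-off columns only.

**Statistics**: one-way repeated-measures ANOVA (univariate sums of squares,
via pingouin) with df = (k−1, (k−1)(n−1)); no sphericity correction on the
primary F (Greenhouse–Geisser ε is reported as a diagnostic only). Post-hoc:
paired two-sided t-tests of each dark timestamp vs the light baseline,
Bonferroni factor = number of comparisons (6 for seven timestamps),
adjusted p clamped at 1. The vs-baseline family (not all 21 pairs) is the
primary design; figures use means with 95% CIs. Degenerate tables: zero
between-timestamp variation returns F = 0, p = 1; zero error variance with a
non-zero timestamp effect raises.

## Numerical choices

* Sub-pixel operations (peaks, crossings) use 3-point parabolas and linear
  interpolation on the 4×-upsampled grid; refinement is clamped to ±0.5
  sample so it can never leave the discrete extremum's cell.
* All randomness derives from one seed (`AcquisitionProtocol.seed` or an
  explicit `numpy.random.Generator`); volumes spawn per-repeat substreams
  deterministically, so re-rendering is bit-identical.
* The noiseless linear-ramp displacement slope is recovered to ~1% of
  −ΔL/T_sat; the residual is a systematic of linear-interpolation resampling
  and of the RPE band narrowing slightly as it compresses, not noise.

## What the phantom does and does not emulate

Emulated: staircase band structure with the double OS-tip peaks, Gaussian
axial PSF, multiplicative speckle with averaging statistics, retinal
curvature, slow axial breathing drift, linear dark-adaptation kinetics of
the four measured changes, and the null (light-stable) control.

Not emulated: vascular shadowing and choroidal flow, lateral eye motion
between volumes, non-Gaussian PSF tails and sensitivity roll-off, raw
spectral-domain reconstruction (simulation starts at linear intensity),
biological between-eye variability (all phantom eyes share one anatomy, so
between-subject variance in the statistics reflects noise only). Passing
recovery tests therefore demonstrates that the *pipeline* is unbiased and
correctly calibrated at realistic noise, not that real-retina values would
be recovered with the same accuracy.

## Problem sizes used in tests and acceptance runs

The protocol defaults are acquisition-scale (4 × 600 × 600 A-scans;
4800-frame recordings). The test suite and acceptance checks keep every
kinetics, optics and noise parameter at those study conditions but shrink
the lateral raster — volumes of 4 × 48 × 64 A-scans with 40 × 50 averaging
windows, recordings of 24–208 A-lines — which the package treats as its
standard desk-scale configuration. The 14-eye recovery check, the
1000-replicate type-I calibration (profile-level null measurements) and the
100-seed null-correlation sweep all use these reduced rasters.

## Known limitations

* Band search windows are mouse-anatomy defaults; other species need a
  different `BandWindows` and template model.
* The ELM template is generated from the canonical phantom; grossly
  atypical anatomies would need a matched template.
* `rm_anova` assumes a complete table (no missing cells), matching the
  experimental design; there is no mixed-model fallback.
* The IZ contrast fade couples weakly into the half-prominence basal-RPE
  estimate (trough level changes over time); at study conditions the induced
  displacement bias is ≪ 0.1 µm but it is the main contributor to the ~1%
  noiseless slope residual above.
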