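# Methods

This note documents the models, numerical conventions and design choices
behind `periocort`, in the spirit of a statistical software appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Texture pipeline

**ROI protocol.** ROIs are resolved on a 0-based, row-major pixel
lattice; rectangles are half-open `[start, end)`, which removes the
off-by-one ambiguity inherent in closed-interval conventions. The
1500-pixel ROI area of the acquisition protocol is enforced as a
*warning*, not an error, so the toolkit remains usable with other
protocols. Pixel spacing (default 0.07 mm) is carried as metadata only:
every feature is a pixel-lattice quantity, so no result depends on it.

**Normalization and quantization.** Each ROI is windowed to
`[μ − 3σ, μ + 3σ]`, with `μ` and the population SD `σ` computed from the
raw ROI pixels, then linearly mapped and floored to levels `1..N_g`
(`N_g = 2^bits`, 6 bits by default):

```
level(x) = clamp(floor((x − μ + 3σ) / 6σ · N_g), 0, N_g − 1) + 1
```

A constant ROI (`σ = 0`) maps to level 1 with a `degenerate` flag rather
than raising, which keeps batch runs alive. Level boundaries are decided
in **exact integer arithmetic** from the ROI pixel sums `(n, Σx, Σx²)`:
the comparison `N_g(nx − Σx) ≥ (6m − 3N_g)·√(nΣx² − (Σx)²)` is evaluated
with integer squaring whenever a floating-point tie is possible. The
practical consequence is that an integer affine rescaling of the raw
data, `x → a·x + b` with `a > 0`, leaves the quantized levels — and thus
every downstream feature and the CI — bit-identical. Detector gain and
offset therefore cannot move the features.

**Mean optical density** is computed on the normalized, quantized
levels, consistent with deriving all three features from one prepared
ROI; because the window is centred on `μ`, it sits near `(N_g + 1)/2`
for roughly symmetric ROIs and carries little contrast on its own. For
workflows that want the raw-histogram mean instead,
`analyze_roi(..., mean_on_raw=True)` switches that one feature to the
raw gray values.

**Co-occurrence difference histogram.** Pairs at offset `d` are counted
symmetrically (`+d` and `−d`, ordered), and only when both members lie
inside the ROI mask — a pair never bridges non-ROI pixels, which matters
for polygonal and masked ROIs. The spacing is 5 *lattice steps* per
axis, i.e. offsets `(0,5), (−5,5), (−5,0), (−5,−5)` (Chebyshev distance
5; the diagonal offsets are ~7.07 px Euclidean). Difference entropy uses
the common logarithm with `0·log 0 := 0`, giving the bounds
`0 ≤ DifEntr ≤ log₁₀ N_g`.

**Run-length matrix.** Maximal equal-level runs are traced along the
primitive (unit-step) version of each direction, breaking wherever the
next lattice point leaves the ROI. Long-run emphasis is
`Σ k²p(i,k) / Σ p(i,k) ≥ 1`, with equality exactly for fully alternating
patterns.

**Directional averaging.** Second-order features are computed per
direction and averaged arithmetically afterwards; matrices are *not*
pooled across directions. The corticalization index is
`CI = mean_od · LngREmph_avg / DifEntr_avg`; a zero average difference
entropy (possible only for essentially periodic two-level patterns or
degenerate ROIs) yields `CI = NaN` with a warning instead of an
exception, so batch feature tables keep one row per ROI.

## Synthetic data

**Texture model.** Patches are Gaussian random fields: white noise
smoothed with a Gaussian kernel, standardized, scaled to a tissue-class
contrast, shifted to a tissue-class mean, plus uncorrelated sensor noise
(SD 3 gray levels), clipped and rounded to 8 bits. The
`correlation_length_px` parameter is the **FWHM of the smoothing
kernel** (σ = length/2.355), i.e. the typical structure size in pixels.
This convention was chosen so that the generator meets its contract:
with the narrower σ = length/2.355 reading, trabecular bone
(length 4 px, contrast 40) is rough at the pixel scale relative to its
normalization window while corticalized bone (length 12 px, contrast 12)
stays smooth despite the shared sensor noise, producing the intended
ordering — longer uniform runs and lower difference entropy in cortical
patches, hence higher CI. Under the wider σ = length reading both
classes quantize to comparably rough level maps and the run-length
contrast degenerates. Class defaults (mean gray level / contrast SD /
correlation length): trabecular 120/40/4, cortical 190/12/12,
soft tissue 60/8/8.

The model reproduces only second-order gray-level statistics. It does
not model radiographic physics (beam hardening, scatter), projection
geometry, implant thread rendering, or anisotropic trabecular
orientation — so passing tests demonstrate that the *pipeline* responds
correctly to controlled texture contrasts, not that the synthetic images
are radiographically realistic.

**Study frames.** A 476 × 620 canvas (the storage-phosphor plate
geometry, 70 μm/pixel) holds a trabecular background, a dark implant
silhouette with a wider neck platform, and a corticalized band flanking
the neck. The peri-implant ROI (30 × 50 = 1500 px) sits inside that
band; the reference ROI sits in distant trabecular bone.

**Cohorts.** Per timepoint (initial / 5 y / 10 y):

- **MBL** is zero-inflated: a point mass at 0 mm (fractions 0.867 /
  0.544 / 0.444) plus a positive component drawn from a normal truncated
  to (0, ∞) whose parent parameters are solved (via the stable
  `erfcx`-based hazard and Brent's method) so the *realized* conditional
  mean/SD equal the configured 1.93±1.85 / 1.91±1.26 / 2.67±2.04 mm.
- **CI** marginals use the same moment-matched truncated normal
  (200±146 / 282±182 / 261±168), so configured mean and SD are the
  moments of the generated non-negative variable — this is what makes
  "recovered within 3 standard errors" a meaningful test.
- **Coupling.** CI = base + slope·(MBL − E[MBL]) + Σⱼ eⱼ·zⱼ, clipped at
  0. The slope defaults to `cc·sd(CI)/sd(MBL)` per timepoint with target
  population correlations 0 / 0.11 / 0.12 (no association at baseline, a
  weak positive one later). Covariate effects eⱼ (CI units per
  population SD) default to TSH +10, serum calcium −10, age +8, weight
  −8 — weak effects (population r ≈ 0.05) whose *sign* is recoverable at
  study scale while per-timepoint significance is not guaranteed. The
  coupling and covariate variance are subtracted from the base draw so
  the marginal CI moments stay at their configured values.

All generators consume a single integer seed through
`numpy.random.default_rng` / `SeedSequence` spawning; identical seeds
give bit-identical outputs, with no global random state.

## Statistics

- **Test selection.** Shapiro–Wilk per group (on differences for paired
  data) at α = 0.05, plus Levene's test across unpaired groups; any
  failure — including groups too small to screen (n < 3) or with zero
  spread — routes to the rank-based branch. Two groups: Student's t vs
  Mann–Whitney U (signed-rank when paired); three or more: one-way ANOVA
  vs Kruskal–Wallis. Degenerate inputs (all values identical, all paired
  differences zero) report statistic 0, p = 1.
- **Group tables** report per-option medians with `H`/`L` flags on the
  highest/lowest-median option, assigned only when the omnibus p-value
  is below the flag alpha (0.05). p-values are per-comparison — no
  multiplicity correction, matching the per-comparison convention of the
  underlying protocol — with an optional Holm adjustment (`holm=True`)
  as an explicitly opt-in alternative; this is a documented caveat.
- **Regression** is ordinary least squares with Pearson CC,
  `R² = 100·CC²` (percent), and the two-sided slope p-value; constant
  inputs yield an `undefined` result. Missing values are dropped
  pairwise everywhere, and every table carries its per-cell n.
- **Longitudinal pairing.** Timepoint-to-timepoint comparisons are
  *paired* over implants observed at both timepoints (a pragmatic choice
  where the underlying protocol is silent; unpaired data simply drop out
  of the pair set).

## Problem sizes and calibration checks

The test suite exercises: exhaustive equivalence of the GLCM difference
histogram and run-length matrix against brute-force enumerators on all
4⁹ 3×3 images at N_g = 4, d = 1, in all four directions; affine
invariance over 50 random ROIs × 20 integer rescalings; CI
discrimination over 100 paired texture seeds; null calibration of the
flag machinery over 200 replicates against exact binomial 99% bounds at
the nominal 5%; and recovery of configured cohort moments and the
CI–MBL slope sign at n = 2000. The acceptance script uses 10 replicates
of n = 2700 cohorts — the scale of the motivating study — which keeps
the full run within a few seconds while holding Monte-Carlo error on
reported means well below the reporting precision.

## Known limitations

- Only the three features entering the CI are implemented; no other
  Haralick/GLRLM, wavelet or autoregressive features, and no feature
  selection.
- The CI is the "version 1" composite; the older bone index BI (and
  1/BI) is out of scope.
- No multiple-testing correction by default (see above); no
  mixed-effects modelling of repeated measures, survival analysis of
  implant loss, or causal interpretation of design-feature contrasts.
- The synthetic generator is calibrated to qualitative orderings
  (cortical > trabecular CI; weak positive CI–MBL coupling), not to the
  absolute CI scale of clinical radiographs.
- DICOM I/O, scanner calibration and inter-timepoint image registration
  are out of scope; images enter as plain 8/16-bit PNG/TIFF rasters.
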