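# Methods

This note documents the models, estimators, numerical choices and
limitations behind `rmekit`. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic scene model

Cells are rendered as circles (radius in µm, converted through
`pixel_size`); the plasma membrane is an annulus of `membrane_thickness`,
the nucleus a concentric disk rendered at 20% of cytoplasmic intensity (dim
enough that profile placement can detect and avoid it, bright enough to be
realistic). Rendering happens on a 4× supersampled grid that is
block-averaged down, so partial-pixel coverage at circle edges is exact and
ring/interior means are stable; the integrated noise-free protein signal
equals the cell's `total_signal` to well under 1% (asserted in tests).

**Signal placement.** `membrane_fraction` (f) interpolates between the two
anchor distributions of the RME statistic: a fraction f of `total_signal`
is placed exclusively in the membrane ring and the remaining 1 − f is
spread uniformly over the *whole* cell footprint (ring included, nucleus
dimmed). This makes f = 0 exactly the "even distribution" anchor (ring and
interior equally bright, RME 0) and f = 1 the "all at the membrane" anchor
(RME 100). An alternative parameterization that gives the ring f·S and the
interior (1 − f)·S makes f = 0 a *membrane-depleted* cell (strongly
negative RME), which is not what "evenly distributed" means, so the mixing
form is used.

**ER puncta.** `er_fraction` of the intracellular signal is moved into 24
Gaussian spots (σ = 2 px) at seeded random cytoplasmic positions, clear of
ring and nucleus; the same spots are rendered into the `er_marker` channel.
With these densities the puncta are comparable in brightness to the
cytoplasm, as ER-retained protein is, rather than outshining the membrane.

**Channels.** The protein channel renders only transfected cells; the
membrane-dye channel renders rings for *all* cells (this is what lets the
morphology module measure non-transfected swelling); noise — optional
Poisson on the intensity, then additive Gaussian `noise_gaussian_sd` — is
applied last. Both noise sources are off by default so the analytic anchors
are exact. All randomness flows from explicit seeds; there is no global
random state.

**Time courses.** `render_timecourse` relaxes the membrane fraction as
f(t) = f_end + (f_start − f_end)·exp(−t/τ), frames at t_k = k/frame_rate up
to `duration` inclusive (0.1 Hz and 120 s by default ⇒ 13 frames).
Optionally the cell area relaxes toward `swelling_area_ratio` with the same
time constant.

**ELISA plates.** Each condition × biological-repeat lysate occupies
`n_replicate_wells` wells (default 3 × 3) on a 96-well layout with
absorbance `blank_level + level·exp(ε)`, ε ~ N(0, cv) — multiplicative
noise, since plate-reader error scales with signal — plus one triplicate of
blank wells.

## RME measurement

**Background.** The image mode outside all cell masks is subtracted from
M, C and I_max before the ratio. Without this the fully-membrane anchor
fails whenever the background is nonzero.

**Profile placement.** Deterministic angle sweep: n lines (default 3) aim
through the cell centroid at 0°, 180°/n, …; a candidate that intersects the
nucleus dilated by 2 px (the perinuclear region) is shifted sideways in
whole-pixel steps until clear, and if no chord at that angle is admissible
the angle advances in 5° steps. Lines extend 20% of the chord beyond the
boundary on both sides. Coordinates are 0-based, pixel-centred, row-major;
distances are reported in µm.

**Sampling.** Bilinear interpolation at steps of ≤ 0.5 px, endpoints
included.

**Membrane detection.** Within the cell span of a profile, the entry (exit)
peak is the highest sample in the outer 25% of that end; the membrane
segment around each peak is the contiguous run of samples at or above half
height over the intracellular baseline (median of the central 50% of the
span). A profile whose boundary peaks do not rise above the baseline (the
evenly-filled cell) is handled by a flat rule: M falls back to the
baseline, driving RME to 0 exactly rather than leaving it undefined.

**M as peak height.** M is the mean of the two crossing *peak heights*
(parabolically refined between samples), not the mean over the half-height
segments. For a ring a few pixels wide, the segment mean is pulled down
10–20% by the ramp samples on either side of the crest, and the
fully-membrane anchor would read ≈ 80–90 instead of 100; the peak height is
the estimator under which "100% at the membrane → RME 100" actually holds.
The half-height segments are still used to exclude membrane samples from C.

**Intracellular mean C.** Mean over the cell span excluding: the membrane
segments plus a 1 px guard (sub-half-height membrane tails), a 2 px guard
at each span edge (samples that blend cell and background through partial
coverage and interpolation), nucleus samples, and — when ER exclusion is
active — samples inside the ER mask (Otsu threshold of the ER channel
restricted to the cell). Exclusion of ER-colocalized samples, rather than
pixel-value subtraction, is the default because it is insensitive to
channel gain differences.

**Normalization.** I_max is the per-profile maximum within the cell span —
the only reading under which a fully membrane-localized cell scores 100
regardless of its brightness. RME is not clamped; negative values
(intracellular excess) are reported and flagged.

**Aggregation.** Unweighted hierarchical means: profiles → cell, cells →
repeat, repeats → condition; SEM across repeats with n = number of repeats
(undefined and flagged when n < 2). This matches a design of three
profiles/cell, at least three cells/image, three repeats.

## Morphology

Segmentation: global Otsu, hole filling, 8-connected components, minimum
particle size 50 px (both exposed as parameters), labels stable in raster
order of centroids. The membrane-dye channel is segmented when present so
non-transfected cells are included; transfection is called per cell when
the mean protein intensity strictly exceeds background mode + 3 SD (ties
break non-transfected). Pre/post matching is greedy nearest-centroid with a
displacement cap of 25% of the mean cell equivalent diameter; unmatched
cells are dropped with a warning. Percent area change is 100·post/pre
per cell (100 = no change), averaged per group, with "increase" = mean − 100.
Per-cell means (not pooled-pixel ratios) are used throughout.

## Kinetics

RME is a bounded ratio statistic: for the circular-cell model,
RME/100 = K·f/(1 + (K − 1)·f) with K the ratio of effective cell area to
membrane-ring area (K ≈ 2–7 for realistic geometries). First-order
trafficking is exponential in f, so RME(t) is a *compressed* exponential,
and fitting rme0 + Δ(1 − exp(−t/τ)) directly to RME underestimates τ by
15–40% across that K range. The primary estimator therefore fits the
4-parameter saturating-link model (f_0, f_∞, τ, K, with the exponential
acting on f); the parameterization is identifiable — two curves coincide
for all t only if all four parameters agree — degenerating gracefully to
the plain exponential as K → 1. Initialization: τ from the half-change time
divided by ln 2, K from a small grid {1.5, 3, 6, 12} keeping the
least-squares best. The plain single-exponential τ and the time to 90% of
the fitted response are reported alongside, since "response timescale" is
often read as either.

A series whose total range is below 3× a robust noise estimate (MAD of
successive differences) is a non-responder: the fit returns a flagged null
result instead of a number. Down-steps (reversal) fit with the same
machinery and a negative amplitude.

Line placements are chosen on frame 0 and reused, rescaled radially from
the cell centroid by the square root of the cell-area ratio when the cell
swells, so lines keep crossing the membrane.

## ELISA quantification

Per-lysate value = mean of its replicate wells − blank mean (dedicated
blank wells preferred, scalar fallback); negative values are floored at 0
with a warning. Condition level = mean over biological repeats, SEM across
repeats. Fold changes pair repeats (repeat i vs control repeat i), average
the per-repeat folds and take their SEM; when repeat counts differ, the
ratio of means with a first-order delta-method SEM is used instead. An
optional `protein_scale` column divides each well first (total-protein
normalization); its absence means lysates were loaded pre-normalized.
Percent-of-reference is 100·level/reference with propagated SEM and a
low-expression flag at level 0.

## Statistics

Paired t tests for same-cells comparisons, Welch t tests (equal-variance
optional) for independent groups, both two-sided; a one-way
repeated-measures ANOVA (classic within-subject decomposition, verified
against `statsmodels.AnovaRM`) gates the pairwise tests when three or more
conditions are compared, falling back to ordinary one-way ANOVA with a
warning for unbalanced input. Bonferroni correction multiplies raw p by the
number of *planned* comparisons m (recorded in the report footer), capped
at 1. Displayed p values are rounded **up** to one significant figure
(0.00102 → 0.002), so a reported value never understates the corrected p.
Zero-variance degenerate cases return p = 1 (no differences at all) or a
flagged p = 0 (perfectly consistent shift).

A condition is called "translocation: Yes" iff the ANOVA gate passed, its
hypotonic-vs-isotonic paired test is significant after correction, *and*
the hypotonic mean exceeds the isotonic mean; a significant decrease is
called No and flagged anomalous.

## Validation studies and problem sizes

`rmekit.studies` fixes the study conditions used by both the acceptance
tests and `scripts/acceptance.py`:

- **Anchors:** one noise-free 128×128 cell (radius 5 µm at 0.2 µm/px, ring
  0.6 µm, nucleus 1.5 µm), 3 profiles.
- **ELISA:** control level 1.0 vs treated 2.7, cv 0.1, 3 repeats ×
  3 wells, 200 seeds.
- **Swelling:** 192×224 fields with 3 transfected (+45% area) and
  3 non-transfected (+5%) cells, per-cell ratio jitter SD 0.02, Gaussian
  noise 1.5 a.u., 20 seeds.
- **Kinetics:** single-cell stacks, f 0.09 → 0.33 (resting → stimulated,
  RME ≈ 30 → 67), τ = 30 s, 0.1 Hz, 120 s, noise 1.5 a.u., 20 seeds.

These sizes keep the full suite and the acceptance script in the
tens-of-seconds range on one CPU while leaving each estimate's Monte-Carlo
error well inside its assertion tolerance.

## What the generator does and does not emulate

It emulates: ring/cytoplasm/nucleus intensity structure, partial-pixel
edges, ER puncta and their marker channel, membrane-dye staining of all
cells, cell-to-cell and repeat-to-repeat biological variability (jittered
membrane fraction and swelling), Poisson–Gaussian sensor noise, triplicate
ELISA wells with multiplicative noise and blanks.

It does not emulate: irregular cell outlines (circles only; passing tests
shows the estimators are correct on idealized geometry, not that placement
heuristics survive highly non-convex cells), point-spread-function optics,
photobleaching, z-structure, cell migration between frames, touching or
overlapping cells (scene validation forbids them), or plate position
effects. Results on real micrographs additionally depend on segmentation
quality, which the synthetic benchmark exercises only under Otsu-friendly
contrast.

## Known limitations

- The membrane-detection rule assumes the profile crosses the membrane
  roughly transversally; grazing chords widen the ring crossing and can
  inflate the membrane segment.
- `fit_timescale`'s saturating-link fit needs visible curvature to pin K;
  for short, noisy series K and the amplitude can trade off, though τ
  remains the most stable of the parameters (median-of-seeds reporting is
  recommended, and is what the validation studies use).
- The repeated-measures ANOVA assumes sphericity; no correction
  (Greenhouse–Geisser or similar) is applied, matching common practice for
  n = 3 designs but inflating type-I error under strong non-sphericity.
- Fold-change SEMs use first-order propagation; for very noisy control
  levels (cv ≳ 0.3) the ratio distribution is skewed and the symmetric CI
  is approximate.
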