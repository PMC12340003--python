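# Methods

## The scoring model

`organoidqc` encodes a hierarchical score-card rubric for 60-day cortical
organoids.  Five criteria (A Morphology, B Size and growth profile, C
Cellular populations, D Cytoarchitectural organization, E Cellular
viability/cytotoxicity) are divided into thirteen indices, each rated on an
integer 0–5 scale by an evaluator or by a quantitative measurement mapped
through score bins.  Three rules govern a card:

1. **Per-index minima with early exit.**  Criteria are visited in rubric
   order and indices in order within each criterion.  The first index whose
   score falls below its minimum classifies the organoid as failed; all later
   indices are recorded as `not_evaluated`.  The failing index's score *is*
   included in the total, so a card that fails at the second morphology index
   with scores 3 and 0 totals 3.  The default exit granularity is the index;
   a criterion-level option completes the current criterion before stopping.
2. **Composite minima.**  A fully passing criterion must additionally meet a
   minimum over the sum of its indices.  Morphology requires 9/15 — one point
   above the sum of its per-index minima — so an organoid cannot pass on bare
   minima alone.  Composites for the other criteria default to the sum of
   index minima and are configuration overrides, since their calibrated
   values belong to the illustrated rubric rather than to this package.
3. **Total thresholds.**  Initial mode (criteria A–B, non-invasive,
   pre-study) passes at ≥ 16 of 25; final mode (all applicable criteria,
   post-study) at ≥ 35 of 50.  `NA` (not-assessed) indices contribute zero to
   the total, are skipped by minimum checks, and reduce the achievable
   maximum by 5; the pass threshold then rescales proportionally, rounded up
   (e.g. a full 13-index final card passes at ceil(35·65/50) = 46/65).
   Composites over partially assessed criteria scale the same way
   (cytoarchitecture with rosettes NA requires ceil(15·4/5) = 12/20).
   Organoids that cannot be measured for a criterion at all (e.g. too fragile
   to section) fail at that criterion's first index with a recorded reason.

Indices marked `NA` in the input keep that state even when they lie after a
failure point: the decision not to assess them was made independently of the
hierarchy, and failed cards therefore still report totals out of the same
achievable maximum (e.g. 3/50).  Cells marked `x` exist only because
evaluation stopped earlier and do not reduce the maximum.

Batch summaries report pass/fail counts, an exclusion percentage
(round-half-up to integer percent), per-condition medians of totals,
per-index score distributions, and a failure-point histogram.

## Image measurements

All operators take 2-D rasters calibrated by an isotropic pixel size (µm/px)
and return physical units.  Binarization is a global threshold — Otsu's
method on the channel histogram, or a fixed value emulating a manually
adjusted threshold; the value used is always recorded in the mask's
provenance.  Constant images reject automatic thresholding with a pointer to
the fixed alternative.

- **Cellular density** is area-based, not object-based: estimated cell count
  = DAPI-positive area / 80 µm² (mean nucleus cross-section), and density
  normalizes the count to the section surface.  The section surface is the
  *filled outline* of an elevated-threshold tissue mask (holes filled), so
  density and hole measurements share one denominator.  The upper bound is
  10⁶/80 = 12,500 cells·mm⁻² at full coverage.
- **Cell-less regions** are pixels inside the filled outline but outside the
  elevated-threshold mask, as a percentage of the outline; hole and tissue
  fractions partition the outline exactly.
- **GFAP coverage** divides GFAP-positive pixels by a selectable reference —
  DAPI-positive surface (default) or section surface — with the choice
  recorded in provenance, because published coverage numbers are quoted
  against both conventions.
- **Foci counting** labels the binarized channel with 8-connectivity and
  filters objects by physical area (default ≥ 15 µm²) and circularity
  4π·area/perimeter², using the Crofton perimeter estimator and clamping to
  1.0 — matching the ImageJ Analyze Particles convention the thresholds were
  designed with.  Degenerate one-pixel perimeters count as circular.
- **The positive-control ratio** summarizes DNA damage as
  (mean(controls) − value) / sd(controls) with the sample (n−1) standard
  deviation; ≥ 2 controls with nonzero spread are required.

All area operators are calibration-covariant (areas scale with the square of
the pixel size; fractions are invariant), which the suite tests directly.

## Score bins

Quantitative measurements map to scores through five ordered cut points per
index; values exactly on an edge take the higher score (ties favor quality).
Replicate slices (2–3 per organoid) are averaged by arithmetic mean before
mapping.  The shipped defaults are *declared, uncalibrated anchors*
consistent with the rubric's documented failure examples (densities of
6,900–7,600 cells·mm⁻² score 0 and fail D1; GFAP at 22% or 31% scores 0 and
fails C2; a positive-control ratio below 1 cannot reach the E1 minimum of
4).  They are not a transcription of the full illustrated rubric and should
be replaced by laboratories holding calibrated thresholds — every edge is
config-overridable.

Size and growth (B1/B2) have no absolute defaults because expected areas
depend on seeding density; they are scored relative to the batch: the
measurement is |value − batch median| in units of the batch median absolute
deviation (MAD), top score within 0.5 MAD and one score lost per additional
0.5 MAD.  A zero-MAD batch scores median-valued organoids 5 and anything
else 0.

## Growth profiles

Growth series are (day, area) observations with strictly increasing days;
the profile is an ordinary least-squares line (area ~ day, µm²/day) plus
reference sizes at days 10/30/60 taken from the nearest observation within
±3 days (the default imaging grid — days 2, 9, 16, 23, 30, 33, 40, 48, 54,
61 — is non-uniform, so exact-day lookup would usually miss).  Growth-curve
comparison treats shared days as blocks and organoids as treatments in a
Friedman test.

## Rank statistics

Kruskal–Wallis, Dunn's post hoc, and Friedman are implemented in-package
with mid-ranks and the standard tie corrections; p-values come from the
chi-square (k−1 df) or normal approximations.  Dunn p-values are two-sided
and adjusted over the requested comparison set by Bonferroni (default) or
Holm.  Fully tied data return statistic 0 and p = 1 rather than an error.
Tests verify the implementations against hand-ranked toy tables and against
scipy's `kruskal`/`friedmanchisquare` as independent oracles, and a
10,000-replicate null simulation checks the type-I error at α = 0.05 to
within ±0.01.

## Synthetic data

The generator exists so every measurement has a ground-truth oracle.  A
section image is a disk-shaped organoid whose radius is perturbed by
low-order Fourier modes (the `raggedness` parameter), on a 512×512 canvas at
2 µm/px with a 400 µm radius by default.  Nuclei are filled disks (radius
5 ± 1 µm) with a mild radial intensity falloff, painted at random positions
until their union coverage reaches the target implied by an area-based
density (coverage fraction = density × 80 µm² / 10⁶; the default
10,000 cells·mm⁻² gives 80% coverage, and densities above 12,500 are
rejected as unachievable).  Ground truth is recorded from the *rendered*
masks, not the requested parameters, so round-trip tests are exact up to the
measurement model.  Cell-less holes are interior disks carved from all
channels, kept a 3-px margin away from the border so they remain enclosed
cavities; GFAP is painted as blobby patches to a requested fraction of the
section; γH2AX foci are well-separated disks of known radius.

The intensity model is deliberately simple: background 10, intra-tissue
baseline 60, stained structures ≥ 140, Gaussian noise sd 3 (8-bit range).
Any threshold in (75, 135) recovers stained structures exactly and (25, 55)
recovers the tissue footprint; the constants 100 and 40 are used throughout
tests.  This emulates what the measurements need — coverage geometry at
known calibration — and *not* real microscopy: no point-spread function,
uneven illumination, chromatic effects, section folds, or staining-intensity
variation.  Passing round trips therefore validate the measurement
arithmetic and geometry, not robustness to acquisition artifacts.

Growth series are linear with additive Gaussian noise, clipped at zero.
Score batches draw per-index scores from quality-level distributions:
"high"/"medium" rows always pass initial QC, "low" rows sit at 13–15/25
(always excluded), and "destroyed" rows fail at the first morphology index
by construction.  Every stream derives from the master seed plus stable
per-object identifiers (CRC32), so outputs are bit-reproducible and
independent of generation order.

## Problem sizes and numerical choices

The validation suite uses desk-scale problems chosen to exercise every code
path: single 512×512 sections per phenotype, 200 replicate growth series for
slope recovery (mean error < 2% of an 8,000 µm²/day slope), and 10,000 null
replicates of 3×10 groups for test calibration.  Exclusion percentages round
half-up; composite and total thresholds round up after proportional scaling
(conservative: a rescaled threshold is never easier to pass).  Labeling
connectivity defaults to 8 (configurable); coordinates are 0-based
row/column pixels; physical units are µm, µm² and mm² throughout.

## Known limitations

- Qualitative indices (A1–A3, C1, D3–D5) are manual rubric entries; the
  package validates and aggregates them but does not score images for them.
- Default score bins are uncalibrated anchors (above); passing the shipped
  tests does not certify agreement with any laboratory's calibrated rubric.
- The synthetic generator's realism limits are listed above; no claim is
  made about segmentation robustness on real micrographs.
- Published between-condition p-values from small-n post-hoc comparisons are
  not reproduction targets: the underlying raw tables and the original
  software's adjustment method are not available to desk-scale validation.
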