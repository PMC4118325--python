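# Methods

This note documents the models and procedures stemsense implements, the
choices made where the published procedures leave details open, and what
the synthetic data generator does and does not emulate.

## Sensing model and coordinates

The platform carries a vertical-plane time-of-flight laser scanner (1°
angular resolution, 10 Hz, ±5 mm statistical ranging error, ~3 cm footprint
at the working distance) and four stacked infrared light-curtain beams at
127/178/229/280 mm above ground.  A wheel encoder supplies the along-track
coordinate; with the default 1 mm per count, encoder counts and millimetres
are interchangeable.  Heights are measured from the top of the raised
nursery bed, which is taken as the ground reference for all thresholds (the
alternative, the furrow bottom, is never used).  Beam angles use a
horizontal-origin, positive-downward convention (`depth = r·cosφ`,
`z = h − r·sinφ`); a configurable angle offset in `RigConfig` absorbs any
other instrument origin.

Speed planning quantises to whole cm/s: the largest integer speed for which
a stem of diameter *d* is crossed by at least *k* scan planes is
`floor(d·f / 10k)` cm/s — 3 cm/s (0.108 km/h) for a 10 mm stem at 10 Hz and
*k* = 3.

A documented unit erratum: the published sweep ranges for the detection
parameters are labelled "cm" but contain the selected operating values only
when read as millimetres / encoder counts; all grids in
`stemsense.calibrate.SWEEP_GRIDS` use that reading.  Three selected values
(jump 1, blanking 110, minimal tree distance 130) do not lie on their
published grids under any unit reading; the selected values are honoured as
defaults and the grids kept as published.  The published spot spacing
(1.8 cm) is likewise inconsistent with 1° resolution at a 50 cm offset
(0.87 cm); the simulator records it as instrument metadata and derives beam
geometry from the angular resolution instead.

## LIDAR stem identification

The pipeline is a composition of seven stages with six tunable parameters
(defaults are the published selected values; all boundary comparisons are
inclusive on the keep side):

1. **ROI filter** — keep `z ≥ 170 mm`, `100 ≤ depth ≤ 650 mm`,
   `z ≤ 660 mm`.
2. **Height cut** (210 mm) — restrict tree-line estimation to stem-level
   points, where the mixed-pixel artifact dominates but foliage does not.
3. **Tree line** — at nodes every 10 counts, a depth histogram over a
   window of `encoder_range` (200) counts centred on the node; the node
   depth is the modal bin's centre.  Open details fixed here: bin width
   10 mm with bins centred on multiples of the width; modal ties resolve
   toward the *smaller* depth (stems occlude background, so the near mode
   is the row); empty windows are linearly interpolated from neighbouring
   nodes; smoothing is a centred 5-node moving average whose window shrinks
   symmetrically at the ends.
4. **Tree path** — the line ± `path_increment` (50 mm), linearly
   interpolated between nodes.  Mixed-pixel returns lie strictly between
   stem and background range, hence mostly outside this band: the band *is*
   the outlier suppressor.
5. **Presence binarisation** — per encoder count, true iff any ROI-filtered
   point (not the height-cut subset; that alternative reading is exposed as
   `binarize_from_height_cut`) has `z ≤ cut_identification` (190 mm) and
   depth inside the band.
6. **Jump filling** (1 count) — interior absence gaps of length ≤ jump
   flanked by presence become presence; leading/trailing gaps never change.
   The operation is idempotent and monotone.
7. **Runs and blanking** — maximal presence runs yield
   (start, end, median) with `median = start + (end − start)//2` (floor for
   even runs); a greedy left-to-right pass keeps a run iff its median is at
   least `blanking_tree_distance` (110) past the last *kept* median.
   Rejected runs do not reset the reference.

The run median is the reported stem position.  Classification re-derives
the presence series *without* jump filling: gap repair is a detection-only
fix and carries no foliage evidence.

## Light-curtain cascade

An LC0 blocked event is the first count of each maximal blocked run (one
candidate per stem rather than one per count).  The chain proceeds upward
through the configured channels (default LC0–LC2; LC3 mostly sees leaves):
each link must lie within ± `tree_encoder_window` (13) counts of the
previous link's event, the nearest-to-midpoint event being used (ties to
the smaller encoder).  A completed chain at e₀ is accepted iff it is the
first or strictly more than `minimal_tree_distance` (130) counts past the
last accepted tree.  The cascade is strictly LC0-rooted: a stem missed by
LC0 is missed outright.

## Classification

`count_in_window` sums the presence series over
`[centre − ⌊w/2⌋, centre + ⌊w/2⌋]` (the published parameter is a width; the
centred-window reading makes the 55-count window symmetric), clipped to
the series extent.  A tree is alive iff its count reaches the threshold.

Threshold calibration returns the 5th percentile of known-alive counts by
linear interpolation between order statistics — fractional operating
values such as 11.75 arise naturally.  Among the interpolation conventions
the Weibull (type-6) plotting positions are the default because they carry
a guarantee the procedure's purpose demands: for q = 5 % the number of
calibration counts strictly below the returned threshold is at most
`⌊(n+1)q⌋ ≤ nq` for every n, so at least 95 % of the calibration live trees
are always labelled alive.  The numpy default (type-7) positions, available
via `method="linear"`, undershoot that guarantee for most sample sizes.
When several calibration plots each yield a threshold, the operating value
is their minimum, which minimises the costly live-as-dead error.

## Evaluation

Matching is greedy one-to-one by increasing absolute error with a strict
80-count radius; ties break toward the smaller detection, then truth,
encoder.  Whenever surveyed trees are more than twice the radius apart each
detection can match at most one truth, so the greedy result coincides with
the exhaustive optimal assignment (verified against a brute-force
enumerator in the tests).  Localisation uses the sample (n−1) standard
deviation — at the n ≥ 543 of the published tables the n vs n−1 choice is
invisible at print precision — and the standard error σ/√n.  Percentages
round half-up at the printed precision; a truncation mode covers tables
whose printed values are floored (543/567 printed as 95.7 %).  An "encoder
event" in the occupancy confusion is one encoder count, classified by
series occupancy vs proximity (< radius) to a surveyed tree; only the
percentage arithmetic of the published event tables is treated as
reproducible, since those tables do not define their event unit.

## Calibration sweeps

One parameter is swept at a time with every other parameter pinned at the
midpoint of its range (height cut and cut identification 220 mm, encoder
range 1025, path increment 50 mm, jump 5, blanking 125).  Each grid value
is scored by total false detections (FP + FN) over the calibration plots;
the selected value minimises that total, exact ties broken by the smaller
localisation σ, remaining ties toward the smaller value.  A pipeline
failure at a grid point is recorded as a failed point, not raised.  A
calibration/validation split helper mirrors the 4 + 2 plot design.

## Synthetic data generator

No field data accompanies the method, so `stemsense.simulate` renders an
idealised row whose *artifacts* — not whose photometry — match what the
pipelines must survive:

* **Scene**: stems are vertical cylinders (10 mm diameter, 20 cm spacing
  with 3 mm jitter, tops near 220 mm with 15 mm jitter) on the bed plane;
  live trees carry opaque canopy spheres around the upper stem and low
  sucker/leaf spheres hugging the stem (the extra silhouette that makes
  live trees out-count dead ones); dead trees (default fraction 0.2,
  matching the ~21 % dead share of the field counts) are leafless, 30 % of
  them with shortened stems, and their weathered stems drop returns with
  probability 0.15; weeds and clods are ground-level spheres at 0.3/m each.
* **LIDAR rendering**: one 0–90° scan every 3 counts (the 3 cm/s, 10 Hz
  operating point); each beam returns the nearest of stem / sphere / bed /
  background-plane (800 mm) intersections with ±5 mm Gaussian noise.
  Beams whose 30 mm footprint straddles a stem edge return, with
  probability `outlier_fraction` (default 0.5), a uniformly drawn range
  strictly between the stem surface and the backdrop — the mixed-pixel
  model, the simplest one honouring the weighted-average mechanism.
* **Curtain rendering**: one record per encoder count (encoder-triggered
  acquisition); a beam is blocked iff any opaque element crosses its
  horizontal line.
* **Determinism**: a dataset is a pure function of its seed; per-scan
  generators derive from (seed, encoder) so rendering order is immaterial.

`noise_free_config()` is the reference correctness scene: all nuisance
rates and noises zero, all trees alive, and stems at 250 mm so every stem
crosses LC2 (at the default 220 mm tops the 229 mm beam is reached only
via height jitter and foliage, as in the field, where detection then
legitimately degrades).  On such rows both pipelines achieve exact
recall/precision 1.0 with localisation error ≤ 5 counts — the stem radius,
since both sensors report positions at or near the approaching stem edge.

What passing synthetic tests does **not** show: real canopy radiometry,
sunlight and reflectivity effects, wheel slip or odometry drift, curved or
multiple rows, and — most importantly — the real distributions of presence
counts for live and dead trees.  The published operating thresholds (11.75
and 21.4 counts) encode those field distributions and cannot be recovered
from simulation; the simulator is tuned only to reproduce the qualitative
live/dead separation, and the calibration machinery is verified by its
coverage guarantee rather than by those two numbers.

## Numerical and degenerate-input conventions

Empty clouds/series are legal inputs wherever an empty output is
meaningful; tree-line estimation on a pointless cloud raises
`NoTreeLineError`; statistics on fewer than two values raise; unsorted
encoder sequences raise `OrderingError` rather than being silently sorted.
CSV logs round-trip bit-exactly (`%.17g` floats, round-trip parsing).
Problem sizes in the test suite and acceptance script — 20-to-40-tree rows,
1,000-instance randomized oracles — are the package's chosen verification
sizes: large enough that every pipeline stage is exercised end to end,
small enough to keep the suite fast.
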