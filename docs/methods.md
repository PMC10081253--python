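# Methods

This note documents the models, conventions and numerical choices behind
schoolkit, and what the synthetic-data generator does and does not emulate.

## Coordinate and unit conventions

Positions are in centimetres, y up, angles in radians counterclockwise from
the +x axis; degrees appear only at reporting boundaries.  Headings come from
the tracker's body-orientation estimate and are never recomputed from
velocity; they are unwrapped to a continuous sequence on read so that finite
differences never cross a ±π seam.  Distances are reported in cohort body
lengths (BL) for proximity metrics and in tank radii for focal-frame maps and
zones; both conversions are exposed and invertible.  Pixel input is converted
with the factor arena_radius_cm / arena_radius_px.

## Smoothing and kinematics

Tracks are smoothed with a Savitzky–Golay filter, window 5.  The polynomial
order is 2: the smallest order that preserves the curvature the central
second difference needs (orders ≤ window−1 reproduce constant, linear and
quadratic signals exactly, which the analytic oracles exploit).  Derivatives
use

- v⃗ᵢ = (r⃗ᵢ₊₁ − r⃗ᵢ)/dt (forward),
- a⃗ᵢ = (r⃗ᵢ₊₁ + r⃗ᵢ₋₁ − 2 r⃗ᵢ)/dt² (central),
- ωᵢ = (φᵢ₊₁ − φᵢ)/dt (forward),
- αᵢ = (φᵢ₊₁ + φᵢ₋₁ − 2 φᵢ)/dt² (central).

The angular acceleration is deliberately the standard central second
difference, mirroring the linear one; source material for this family of
analyses sometimes prints the dimensionally inconsistent form
φᵢ₊₁ − φᵢ₋₁ − 2φᵢ, which we treat as a typo.  First/last frames, where a
difference is undefined, are NaN — never zero-filled — and are excluded from
every downstream binning.  The speeding force f_speed = a⃗·(cos φ, sin φ) and
turning force f_turn = a⃗·(sin φ, −cos φ) satisfy f_speed² + f_turn² = |a⃗|²
at every interior frame; f_turn is positive to the fish's right.  No
low-speed threshold is applied, because the heading comes from body shape,
not velocity; frames with speed < 0.01 BL/s can be flagged for optional
exclusion (default off).

## Pairwise metrics

Pair angle is folded to [0°, 180°]; the sign of the heading difference is
used only by the aligning statistic.  The trial is the statistical unit:
frame-level values are pooled within a trial and summarised by their median
(means are also reported for normal-routed comparisons).

## Mock-group null model

All C(n, 5) combinations of the n source trials are enumerated; one uniformly
random fish per trial forms each mock group, truncated to the shortest common
frame count.  One master seed spawns per-group child seeds, so every
iteration is bit-reproducible; downstream comparisons use iteration 0, and a
Kruskal–Wallis check across k iterations (with Dunn's rank post-hoc
available) verifies the random fish choices do not matter.  Fish are drawn
independently per mock group (with replacement across groups), matching the
combinatorial count.  For pairwise quantities the package uses the cheaper
exact equivalence: the average over every ordered pair of fish from two
different trials equals the average over every pair within every possible
mock group; this is verified numerically to 1e-9 in the tests.  The
equivalence does not hold for nearest-neighbour quantities, which are
computed on materialised mock groups.

## Focal-frame maps

Radial bin edges are 0, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5 tank radii.  The
sector count is configurable with default 12 (30° wedges); the default is
chosen so the ahead/behind and left/right half-plane splits fall exactly on
sector boundaries, which keeps scalar statistics and heatmaps consistent.
Bins do not overlap and no smoothing is applied between them.  Density values
are probability per bin divided by bin area π(r₂² − r₁²)/n_sectors, so
Σ value·area equals the fraction of observations within 0.5 tank radii
exactly.  Force-map bins are plain means of the focal force given a neighbour
in the bin; empty bins are NaN (undefined), not 0.  No correction is applied
for arena-boundary truncation of bins near the wall: the mock subtraction is
the wall control.  Rendered heatmaps are scaled by the map's max |value| to a
[−1, 1] colour range; numeric outputs are never rescaled.

## Attraction statistics

Zones: attraction 0.15–0.4 tank radii (beyond short-range repulsion at
0.05–0.15), alignment and "schooling zone" 0.05–0.4.  Averaging order:
frame-level signed observations → per-bin means → area-weighted zone mean →
one scalar per trial; the mock scalar is computed identically over
cross-trial pairs, and corrected values are real − mock.  Area weighting
treats every possible neighbour location equally; occupancy weighting is
available and gives the same signs, though not the same magnitudes on the
zonal simulator, whose force field varies strongly with distance inside the
zone.  Observations with a heading difference of exactly 0 or ±180° carry no
defined aligning sign and are dropped (a measure-zero set).  Per-trial
statistics are reported in raw physical units (cm/s² for speeding and
turning, rad/s² for aligning) with speed-normalised values alongside; the
turning force is a linear (normal) acceleration, so its normalised variant,
not the raw one, is the dimensionless analogue of angular units sometimes
quoted for such statistics.  The ambiguity is reported, not resolved: both
columns are emitted.

## Hypothesis testing

Real samples are tested for normality with Shapiro–Wilk; mock samples (which
can be far more numerous) with a Kolmogorov–Smirnov test against a normal
with the sample's own mean and SD — a Lilliefors-style shortcut that is
slightly anti-conservative for normality, logged rather than corrected.  Both
normal ⇒ Student's t; otherwise Mann–Whitney U.  Mock-corrected per-trial
values are tested against zero with a one-sample t-test when
Shapiro–Wilk passes and a Wilcoxon signed-rank test otherwise.  All tests are
two-sided at α = 0.05; reported summaries are means on the normal route and
medians otherwise; no multiple-testing correction is applied across cohorts.
Degenerate inputs (constant samples, all-zero corrected values) short-circuit
to p = 1 with a degenerate flag.  One caveat is inherent to the mock
subtraction: the mock mean is itself an estimate whose variance the
one-sample test ignores, so the corrected test is slightly anti-conservative
when trials are short or mixing is slow; the null-preset calibration in the
test suite bounds this effect under the package's default conditions.

## The simulator

Each agent carries position, continuous heading φ and speed s.  Per step
(dt = 1/30 s) a desired-direction vector D (units 1/s) sums:

| term | default gain | zone |
|---|---|---|
| repulsion: away from neighbours | w_rep = 4.0 /s | d < 1.5 cm |
| alignment: mean neighbour heading | w_ali (preset) | 1.5–5 cm |
| attraction: toward neighbour centroid | w_att (preset) | 5–12 cm |
| wall avoidance: inward, linear ramp | wall_gain = 2.0 /s | last 3 cm |
| wall following: tangential (thigmotaxis) | wall_follow_gain | last 3 cm |
| wall attraction: toward preferred wall distance | wall_attract_gain | whole arena |

Heading turns at ω = ĥ × D (the component of D perpendicular to the heading)
plus wrapped-Gaussian noise of intensity heading_noise_sd √dt (default
0.7 rad/√s).  Speed relaxes to the preferred speed (6 cm/s, relaxation
1 /s) and is additionally forced by speed_forcing × (D_pos·ĥ) × s_pref,
where D_pos contains only the positional terms (repulsion + attraction):
speed modulation serves proximity control, so an attraction target ahead
produces speeding and one behind produces slowing — the signature the
attractive speeding force is designed to detect.  Positions integrate at the
updated heading; the arena (radius 16.95 cm, the subadult assay geometry
with fish of ≈1.54 cm, 22 body lengths per arena diameter) is closed by a
specular reflection that is only a safety net: every preset steers away from
(or along) the wall smoothly, keeping trajectories C¹.  Hard reflections
would create kinks that the smoothing + finite-difference chain converts into
spurious speeding signal near the wall.  The first 10 s are discarded as
burn-in (the analogue of an acclimation period), and trials default to 120 s;
analyses in the tests and the acceptance script use 12 trials per cohort —
the package's study-scale defaults.

Presets:

- `schooling` — w_ali = 3, w_att = 1.5: attraction plus alignment, the
  schooling phenotype.
- `asocial_wall` — all social gains 0, wall_follow_gain = 2,
  wall_attract_gain = 1.5 toward a 2 cm preferred wall distance, heading
  noise 1.0 rad/√s: thigmotaxis without sociality, the cave-like phenotype.
  The noise level matters: it lets fish meander and reverse along the wall,
  so a 120-s trial contains many effective samples rather than one long
  one-directional orbit.
- `null_random` — all social gains 0, heading noise 1.2 rad/√s: independent
  walkers, the mock-equivalent null.

What the generator emulates: group size, frame rate, trial duration, arena
geometry, zonal attraction/alignment/repulsion, wall avoidance and
thigmotaxis, and realistic swim speeds.  What it does not: body shape and
occlusions (tracking error), burst-and-glide gait, vision-based asymmetric
sensing, hydrodynamics, development within a trial, and individual
variability in body length.  Passing the recovery tests therefore shows the
*analysis chain* is correct and sensitive at study scale; it does not certify
any biological claim about real fish.

## Design choices on genuinely open points

- Long-format CSV is the canonical trajectory dialect (one row per fish per
  frame), with a wide-format reader as secondary; gaps ≤ 5% of a fish's
  frames are linearly interpolated (headings on the unwrapped sequence) with
  a warning, larger gaps fail the trial.
- Frame alignment keeps the range common to all fish and never fabricates
  frames absent from every fish; mock assembly truncates to the shortest
  member.
- Ahead/behind and left/right are realised as sector membership (boundaries
  at 0°, 90°, 180°, 270°), so the scalar statistics are exactly the
  area-weighted signed heatmaps.
- The per-trial summary for proximity/alignment metrics is the median of the
  pooled frame-level values; violin-style outputs carry one point per trial.
- Zone averages use rings fully contained in the zone (the default grid's
  edges coincide with every zone boundary).

## Known limitations

- The corrected one-sample test inherits the mock-mean-variance caveat above.
- Spearman speed–metric correlations use trial means; with few trials they
  are only a coarse confound check.
- The KS normality route uses estimated parameters (Lilliefors caveat).
- Area- vs occupancy-weighted zone averages agree in sign but can differ
  ~2× in magnitude when the force field varies within the zone.
- The simulator's ground-truth gains are in model units (1/s); recovered
  statistics are monotone in them (verified) but not calibrated to them.
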