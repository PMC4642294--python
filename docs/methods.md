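# Methods

This note documents the models behind `pamdensity`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data
validation does and does not demonstrate.

## Data reduction

A click-detection log (one row per detected click: time, received level in
dB pp re 1 μPa, species, site) is reduced three ways. *Encounters* are
contiguous clicking periods: successive clicks of one species separated by
at most one hour, retained when the first-to-last-click span exceeds 75 s.
Encounter duration is measured first click to last click — we do not
require 75 s of cumulative click-positive time, which keeps the rule
monotone and cheap to verify against a brute-force scan. *5-min bins* are
300-s slots on an absolute UTC grid, emitted only where wholly covered by
recording effort; a bin "detects a group" when it holds at least 5 clicks,
which suppresses isolated false detections. *Weekly counts* run Sunday
00:00–Saturday 24:00 UTC. The click stream is counted over **all** effort
(the ≥ 5-click filter applies only to the group stream): the two streams
are parallel reductions of the same log, not nested ones. Edge weeks of a
deployment with less than 48 h of cumulative effort are merged into the
adjacent week; "two days" is interpreted as cumulative effort rather than
elapsed time, so a gappy edge week is treated by how much data it actually
holds. A continuous Sunday-aligned week yields exactly 2,016 bins.

False-detection proportions `c_k` are estimated from manually labelled
subsamples as a binomial proportion with CV = SE/p̂. In the delta-method
combination the CV of `c_k` itself is propagated (not the CV of `1 − c_k`);
this choice reproduces the shipped tables' ±sd columns exactly from their
printed component CVs, so it is what the original analysis did.

## Behavioural multipliers

**Modal ICI.** Inter-click-interval measurements mix true single-animal
intervals with multi-animal interleavings and missed-click multiples, so
the mode is the robust location estimate. Weekly batches with ≥ 100 values
in (0, 1) s get a Gaussian-kernel density (Silverman's bandwidth) evaluated
on a 1-ms grid; the mode is the grid argmax with ties broken toward the
smaller interval. Weekly modal rates (reciprocals) are pooled as a weighted
mean with the weekly effort as weight; its CV uses Cochran's finite-sample
ratio-estimator variance, `var = n/((n−1)W²) Σ w²(y−R̂)²`.

**Clicking proportions.** From tag-style dive-cycle records (a dive cycle =
one deep foraging dive plus its shallow dives), the per-second proportion
is the cycle-length-weighted ratio of click-positive seconds to cycle
length; the first cycle of each record is excluded by default (tagging
effect). The per-bin proportion makes each cycle cyclical, draws a uniform
integer start second, cuts 300-s bins dropping the final incomplete one,
and counts bins holding any click-positive second. We average 100 random
starts per cycle (seeded) rather than a single draw — same estimand,
smaller randomization noise — and validate against an exhaustive
enumeration of all starts on short cycles. Binning can only inflate
occupancy, so the bin proportion is ≥ the second proportion.

**Vocal synchrony.** For encounters where ≥ 2 animals were tracked, the
overlap `o` is the period with ≥ 2 animals vocalizing (sweep-line over the
bout intervals) divided by the mean per-animal vocalization period;
encounters are the sampling units. The group vocal-activity probability for
a nominal two-animal group is `P_v = min(1, P_r (2 − o))`: with full
asynchrony a second animal doubles the chance a 5-min bin holds clicking,
with full synchrony it adds nothing. The relation is applied only at group
size 2 (the observed mean group sizes are ≈ 2); requesting another size is
an error rather than a silent extrapolation.

**Click rate.** `r = (proportion of cycle clicking) × (1/modal ICI)`,
CV by root-sum-of-squares of the two components. Proxy usage (e.g. a
Blainville's-tag clicking proportion standing in for Gervais', Cuvier's
synchrony standing in for Gervais') is configuration, not code: the
multipliers are named inputs per species and site.

## Detection probability

A click leaves the animal at source level SL ~ N(mean, 3 dB) (225 dB pp for
Cuvier's, 220 for Gervais', peak-to-peak re 1 μPa @ 1 m) and is attenuated
by spherical spreading `20 log10(r)` over the slant range, seawater
absorption α·r, and the off-axis beam loss. Absorption defaults to the
printed site values (10.05 dB/km @ 40.2 kHz, 11.30 @ 43.8 kHz); the
Ainslie–McColm formula reproduces them to 0.25% under the stated water
column (S 35 ppt, 6 °C, pH 8, 0.98 km) and serves for other frequencies.
Detection requires RL ≥ 121 dB pp, the threshold of the click-detection
analysis. The model deliberately replaces full ray-trace propagation with
spherical spreading + absorption; the substitution is anchored by the
1-km received-level checks (155/149 dB).

**Beam.** The transmission beam is a radially symmetric circular piston:
loss `−20 log10 |2 J1(ka sin θ)/(ka sin θ)|`, with `ka` solved numerically
so that the pattern integrated over the sphere equals the supplied
directivity index (drawn U(24, 28) dB per click). Off-axis loss is floored
at 40 dB (configurable): far-off-axis energy is never detectable at the
ranges that matter, and the floor keeps the back hemisphere from
contributing spurious directivity. The DI→ka inversion and the loss curve
are cached as interpolation tables (400-point log-spaced ka grid; 2.5×10⁻³
x-resolution), accurate to ≪ 0.1 dB.

**Click mode.** Each iteration places 10,000 animals uniformly over the
4-km disc (r = w√U), altitude U(175, 225) m above the seafloor with the
receiver at 10 m, heading uniform on the circle, pitch N(0, sd) with sd
drawn U(5, 15)°; one click per animal. Detected fractions are averaged in
100-m horizontal-range bins over 500 iterations; `P_k` is the overall
detected fraction, its CV the between-iteration spread. Because every
parameter is drawn per click, that CV reflects binomial sampling noise
only (≈ 0.04 at the defaults) — it is smaller than CVs that include
parameter uncertainty shared across an iteration.

**Group mode.** A group is a point source at its centre whose orientation
sweeps a cone during the 5-min window: azimuth width U(140, 160)° centred
on a random heading, elevation width U(55, 65)° (foraging; U(10, 15)° when
descending, fraction configurable, default all-foraging) centred on the
body pitch. The group is detected if *any* orientation in the cone puts a
click above threshold. Rather than scanning the cone on an angular grid,
the minimum attainable beam loss is computed in closed form: the nearest
and farthest cone orientations are found by clamping (the heading optimum
is independent of pitch, so sequential clamping is exact), giving the
achievable off-axis interval [θ\*, θmax]; over any such interval the
piston loss is minimised at an endpoint or at the first interior sidelobe
peak (sidelobe peaks sit at zeros of J2 and their losses increase with
order), so a table lookup suffices. This is the exact limit the grid scan
approaches from below. With zero sweep widths group mode reduces exactly
to click mode on the same seed stream, and group detection dominates click
detection bin by bin.

Randomness uses one `SeedSequence` spawned into per-iteration substreams,
so results are exactly reproducible for a given seed and the two modes
share their geometry stream.

At the shipped scenarios the simulation yields `P_k` ≈ 0.065 (Cuvier's
clicks), 0.033 (Gervais' clicks), 0.37 (Cuvier's groups), 0.23 (Gervais'
groups), unity plateaus ending at 400/200 m (clicks) and 600/400 m
(groups), and maximum click detection ranges ≈ 3.9/3.0 km. The first three
disc averages and the plateau ends match the published calibration within
±0.03; the Gervais' group average sits ≈ 0.05 below its published 0.28,
the mid-range (1–2 km) group curve runs ≈ 0.5–0.6 rather than the
published 0.7 plateau, and the Cuvier's maximum click range comes out
~10% long. All three gaps trace to the propagation substitution: spherical
spreading underestimates long-range transmission loss relative to a
ray-trace model, which stretches the far tail of the click detection
function and, for the weaker-source species, shifts weight into ranges
where the swept cone no longer guarantees detection. We report the model
as specified rather than re-tuning the beam floor or sweep widths to
compensate.

## Density estimation

Densities are computed per km² and reported per 1000 km². Weekly count CVs
come from a seeded nonparametric bootstrap over the week's 5-min bins
(500 resamples; click counts for the click method, detection flags for the
group method); when no bin-level data are supplied the count CV is 0 with
a warning. Record-level averages pool total counts over total effort, with
the count CV from the Cochran ratio variance of the weekly rates weighted
by effort — the empirical week-to-week variation, which absorbs the strong
overdispersion produced by occasional close-range encounters. Confidence
intervals are lognormal: `D ×/÷ exp(z √ln(1+cv²))`, two-sided z from the
normal quantile (1.96 at 95%), log-symmetric and strictly positive.
Reported values round half-away-from-zero at 2 decimals.

## Synthetic data

The generator emulates a recorder watching a 4-km disc at known density.
Groups arrive as a stationary Poisson process (rate chosen so the expected
number of animals present equals density × disc area), sit at a uniform
disc position for one dive cycle (length U(6000, 8400) s — about two
hours), and have sizes drawn from a configurable distribution over 1–5
(defaults: means 2.23/1.93 for the Gervais'/Cuvier's presets, mode 2 and
mode 1 respectively). Each animal clicks during vocal fragments totalling
the configured proportion of its cycle (1 fragment for the Gervais'-like
preset, 3 for the Cuvier's-like one, which places the emergent 5-min-bin
activity near the observed species values); group members offset their
fragments by (1−o) of a fragment so pairwise bout overlap equals the
target. Clicks are spaced at the modal ICI with CV-5% multiplicative
jitter. Received levels reuse the simulator's propagation and beam code:
per-click SL, DI and pitch draws match the click-mode simulation exactly,
and all members of a group share one heading arc per dive cycle (the group
travels together), matching the single swept cone of the group-mode
simulation — orientation varies click to click within the arc. Clicks
below threshold or outside effort are dropped; false detections arrive
uniformly in time (default 3×10⁻⁴ s⁻¹, ≈ 6% of detections at the
5-per-1000-km² validation density) with levels resampled from the detected
clicks. A ledger maps every emitted click to its source group (or the
false pool) and records the true arrivals, positions and sizes.

What the round-trip validation shows: with multipliers estimated from the
generator's own tag/bout output and `P_k` from the simulator, both
estimators recover a true density of 5 animals per 1000 km² over 26-week
records within their 95% lognormal CIs in ≥ 90% of 50 replicates (observed
46/50 click, 48/50 group). What it does not show: robustness to real-data
features the generator omits — animal movement within an encounter, depth-
and bathymetry-dependent propagation, diel or seasonal behaviour, level-
dependent misclassification, or group sizes whose vocal activity departs
from the two-animal synchrony relation (sizes ≠ 2 in the generator create
a known few-percent bias that the wide CIs absorb).

## Problem sizes and tolerances

The test suite runs the simulators at 100 iterations × 5,000 placements
(disc averages stable to ±0.002) and the recovery check at 50 replicates
of 26 weeks; the acceptance script runs the group simulation at the full
500 × 10,000. KDE mode grid 1 ms; piston tables as above; bootstrap 500
resamples; all Monte Carlo paths seeded.

## Known limitations

* Transmission loss is range-only; no bathymetry, sound-speed profile,
  multipath or noise-dependent thresholds (see the calibration gaps above).
* The piston form and the uniform altitude band are explicit substitutes
  for unmeasured quantities; different beam shapes with the same DI move
  the far-range detection tail.
* `P_v` is a two-animal relation applied to all groups.
* The simulator's `P_k` CV understates parameter uncertainty (per-click
  draws); supply an external CV if source-level uncertainty should
  propagate.
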