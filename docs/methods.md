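# Methods

This note documents the models, numerical choices and synthetic study
designs behind `troopstep`, in the spirit of a package vignette: what is
computed, under which assumptions, and what the passing test suite does
and does not demonstrate about real data.

## 1. Data model

**Trajectories.** All individuals share one uniform 1 Hz time axis in a
single projected CRS (meters). Missing fixes are explicit (NaN). Runs of
missing samples no longer than `max_gap_s` (default 1 s) are filled by
linear interpolation between the flanking fixes; longer gaps stay
missing. Outliers are removed by a both-neighbor speed rule: a fix whose
implied speed to *both* temporal neighbors exceeds `speed_max_ms`
(default 8 m/s, configurable) is marked missing — the signature of a
one-sample GPS teleportation. Edge fixes with a single neighbor are never
removed. No smoothing is applied. Lon/lat input is projected with an
in-package WGS84 transverse-Mercator (6th-order Krüger series; round-trip
error < 1e-6 m), so no external projection library is required.

**Steps.** Tracks are discretized by spatial first passage: from the
current anchor fix, the step ends at the first subsequent fix at distance
≥ `step_length_m` (default 5 m), and the anchor advances there. This
yields steps of roughly constant length (in [L, L+v·1s)), matching the
"step" abstraction of the choice model; segments that would span a
missing gap are not emitted and heading continuity is broken across gaps.
Turn angles live in (−π, π], headings are measured counterclockwise from
+x.

**Landscape.** Four co-registered raster layers (vegetation density in
[0,1], binary road and path masks, elevation in m) plus a sleep-site
point. Pixels are half-open, row-major, origin at the minimum corner,
centers at (col+0.5, row+0.5)·resolution — so points exactly on pixel
edges are assigned deterministically. I/O is ESRI ASCII grid text with a
JSON sidecar; registration (shape/origin/resolution) is checked on read.

## 2. Candidate features

Nine features are evaluated for every candidate endpoint. Defaults follow
the field-standard scales; all are configurable.

| feature | definition | scale default |
|---|---|---|
| env_density | mean vegetation density over pixels whose centers lie within a radius | 2.5 m |
| social_density | fraction of troop mates within a radius (unknown positions excluded from the denominator) | 4.25 m |
| sleep_dir | cosine between the step vector and the bearing to the sleep site; one model term per time-of-day bin | morning < 10:00 ≤ midday < 16:00 ≤ evening |
| road / path | mask value of the containing pixel; each interacts with whether the previous location was on a road/path | — |
| recently_used | distinct non-focal individuals with ≥ 1 fix within the occupancy radius during the open window (t − W, t) | W = 270 s, radius 1.25 m |
| ever_used | any non-focal fix ever within the occupancy radius | radius 1.25 m |
| visible | fraction of troop mates whose sight line crosses no pixel with vegetation ≥ 0.5 | threshold 0.5 |
| slope | bilinear elevation difference from the step start to the candidate | — |

The occupancy radius (1.25 m) is a package choice — the underlying field
definition leaves the spatial tolerance of "occupied a location" open —
and is exposed in configuration. The analysis-side occupancy index is an
exact spatial hash (cell lists with per-fix distance and time filters,
verified against brute force). Visibility is computed two ways on
purpose: `habitat.line_of_sight` enumerates every pixel the segment
crosses (conservative traversal via boundary-crossing enumeration), while
`social.visible_fraction` and the simulator sample the segment at ≤ 1/3
pixel spacing — the same kernel in generator and analysis, so generated
and re-extracted values agree exactly; the two disagree only on
measure-zero corner-grazing geometries.

## 3. The conditional logit

The likelihood is the within-stratum multinomial logit; intercepts cancel
and only within-stratum feature differences matter (location invariance
is a tested property). Fitting is Newton ascent from β = 0 with step
halving, convergence at gradient max-norm < 1e-8 (≤ 100 iterations).
Standard errors come from the observed information at the optimum.
Degenerate designs (duplicated or zero-variance columns, e.g. the midday
sleep term in a morning-only dataset) are detected by SVD and fitted via
pseudo-inverse with a `collinear` flag; unidentified terms report zero
coefficients and NaN z-values. Complete separation (diverging |β|) is
flagged, with an optional ridge fallback. AIC = 2k − 2 logL; AICc is
available by flag but the default is AIC since stratum counts are large
relative to parameter counts. Features can be standardized (per-SD)
before fitting for coefficient comparability; results are reported back
on the raw scale either way, and recovery tests use raw features.

**Scale inference** rebuilds one scale-dependent feature column per
candidate scale on a fixed choice set and fits a single-feature logit;
the profile of maximized log-likelihoods identifies the best-supported
scale. Because the candidate set is held fixed, likelihoods are
comparable across scales.

**Multi-model inference** fits all 2^F subsets of the nine feature
*blocks* (an interaction travels with its main effect; the three sleep
terms form one block, so per-feature Akaike weights are well defined),
including the empty (null) model. The Akaike weight of a feature is the
summed normalized exp(−ΔAIC/2) over models containing it, computed per
individual with medians across individuals. Non-converged subsets are
excluded with a warning and the weights renormalized. Weights saturate at
1.0 in double precision once ΔAIC exceeds ~60; ties at saturation share
rank (ties are reported, never broken arbitrarily). For speed, the
full-design rank is checked once (subsets of a full-rank design are
full-rank) and subset fits warm-start from the full-model coefficients.

**Cross-validation** uses time-contiguous folds (default 3) to respect
temporal autocorrelation. Model classes: null (uniform; loss exactly
log(K+1)), habitat-only, social-only, full. Ever-used space belongs to
both feature groups, reflecting its dual control role.

**Preference landscapes** evaluate exp(β_block · x_block(q)) per pixel
center q with features computed by the same code path as choice sets; the
combined panel is exactly the product of per-feature panels before
normalization (a tested identity).

## 4. Paired-choice (direct probability) analysis

Choice sets built with exactly one alternative are converted to pairs;
one endpoint is uniformly relabelled *location 1*, making P(y=1) = 0.5 by
construction marginally and conditionally on any label-symmetric event.
Curves bin the recently-used difference at integers (−5…5, tails pooled,
≥ 20 pairs per reported bin) with exact Clopper–Pearson intervals from
Beta quantiles. Road conditioning stratifies by {neither, both, loc1
only} × focal started on/off road; loc2-only pairs are folded into
loc1-only by swapping labels and complementing the outcome. Sleep-
direction conditioning bins the within-pair directedness difference by
quartiles (the field figures' exact bin edges are not fixed by the
analysis). An optional logistic fit reports the P = 0.5 crossing with a
seeded bootstrap CI — a scalar measure of how many recent troop-mate
passages offset a habitat bias.

## 5. Group structure

Per minute, over individuals with fixes at both minute boundaries (≥ 3
required, else the state is missing):

- **speed** — centroid displacement over the minute (m/min);
- **polarization** — |mean unit heading|, headings from per-individual
  displacements over the minute, individuals displacing < 1 m excluded;
- **spread** — mean distance to the centroid at the minute start;
- **directedness** — net centroid displacement over the forward 10-min
  window divided by the summed per-minute centroid path length;
- **elongation** — (λ₁−λ₂)/(λ₁+λ₂) of the positional covariance at the
  minute start;
- **tilt** — angle in [0°, 90°] between the leading eigenvector and the
  centroid heading.

These formulas are reconstructions chosen to match the depicted semantics
of the six standard troop-level measures; each is validated against
brute-force recomputation and analytic fixtures (aligned motion →
polarization 1; single file → elongation 1, tilt 0°; closed loop →
directedness 0) and is invariant under rigid motions as appropriate.

Context labels use the convex hull of the minute's positions buffered by
5 m (so a single-file group still has area): vegetation and path
fractions are means over hull pixels, road presence is any road pixel in
the hull, and vegetation tertiles (open/medium/dense) are assigned by
rank so the classes are balanced within ±1. Context dependence is
quantified by (a) signed differences of normalized 2-D histograms
(30×30 bins spanning the 1st–99th percentiles of all data; the difference
sums to zero by construction) and (b) all-subsets OLS of each metric on
the four context blocks (vegetation fraction, path density, road
presence, time of day as a categorical) with Gaussian-AIC Akaike weights
and effect directions from the full model.

## 6. The synthetic generator and its two study designs

`gen_landscape` builds vegetation as thresholded Gaussian-smoothed white
noise (quantile threshold hits the cover target; roads/paths are cleared
to open ground), roads as few long near-straight dilated polylines, paths
as many short tortuous one-pixel trails, and elevation as large-scale
smoothed noise scaled to the requested relief. `simulate_troop` runs
decision rounds every `dt_decision_s` (default 20 s): agents in reshuffled
order each draw K+1 candidates from the step proposal (gamma step lengths,
mean 5 m; wrapped-normal turns about the previous heading), evaluate all
features against the current state and 1 Hz history, and choose with
probability ∝ exp(β_true·x). Candidates falling outside the arena are
resampled; since the conditional logit conditions on the realized
candidate set, this leaves the likelihood exact. Positions are emitted at
1 Hz by linear interpolation along chosen steps, and every decision is
logged as a stratum with the exact feature vectors used — so fitting can
be validated both on the log (exact model) and on features re-extracted
from the emitted trajectories (full pipeline). Generated and re-extracted
features agree exactly for all features except ever-used space, where the
generator uses a rasterized coverage approximation (fixes dilated by the
occupancy radius onto the landscape grid) and, necessarily, only the
history up to the decision time, whereas the analysis definition spans
the entire dataset.

Two named coefficient presets are the canonical study conditions:

- **`COMMUTE_BETA`** — the full daily-routine design: negative
  sleep-direction coefficient in the morning, positive in the evening,
  road following, local avoidance of dense vegetation, weak path effect,
  moderate social coefficients. Because the sleep-direction feature is
  radial, the morning drift disperses the troop; social features then
  lose variance over the day. Coefficient recovery remains exactly
  calibrated regardless (the log records the features the softmax used),
  so this design drives the all-feature recovery checks and needs a large
  arena (1.5 km square in the tests).
- **`FORAGING_BETA`** — the home-range design: constant mild attraction
  to the sleep site keeps all agents orbiting a shared core (equilibrium
  spread ≈ 40–80 m in a 400 m arena), so troop-mate trails keep crossing
  and recently-used counts stay informative indefinitely. This design
  drives every analysis that hinges on social-feature variation: feature
  ranking, predictive ordering, paired-choice curves.

This split reflects a real property of the model: the feature set
contains no medium-range cohesion force (the social radii are 4.25 m and
1.25 m), so a troop simulated from the inverted model cannot both commute
radially and stay cohesive. Passing tests therefore demonstrate correct
and calibrated inference *given* the model, and qualitative recovery of
the headline structures (dominant recently-used feature, predictive
ordering, sigmoid paired-choice response, road bias); they do not
demonstrate that the feature set suffices to reproduce real troop
cohesion, which in the wild presumably involves longer-range coordination
not in this model.

The feature-ranking study design additionally strengthens all non-null
coefficients (power calibration on probe runs) so that every genuinely
supported feature carries decisive per-individual evidence; otherwise
sparse features (social density is non-zero in only a few percent of
strata at the 4.25 m radius) occasionally rank below a null feature's
spurious Akaike-weight draws, which is a power failure of the design
rather than an inference failure.

Problem sizes used by the test suite and the acceptance script — e.g.
10 agents × 2000 decisions (K = 10) for recovery, 10 × 300 for scale
profiles, 5 × 1000 for ranking, 20 replicates for the rate-based checks —
are the package's chosen desk-scale study sizes; they give comfortable
statistical margins for every criterion while keeping a full run in
minutes on one CPU.

## 7. Known limitations

- The six group metrics and the group-area construction are explicit
  reconstructions; alternative formulations (e.g. time-averaged spread)
  are plausible and the functions are small and replaceable.
- Visibility is 2-D occlusion against a density threshold; no canopy
  height or observer height is modelled.
- The generator's ever-used feature is approximate at patch boundaries
  (≤ one pixel) and causally truncated, as noted above.
- The paired analysis reports only qualitative/structural properties;
  numeric curve values depend on the generative design.
- UTM support covers single-zone data; cross-zone datasets must be
  projected upstream.
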