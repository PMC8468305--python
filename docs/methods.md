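# Methods

## Track model

The horizontal alignment is a stadium curve: two straights of length
`straight_length` (default 40 m) joined tangentially by two semicircular
bends. Published bend radii for such tracks are quoted on the path 1 m out
from the inside (lure) rail; with the default "52 m measured 1 m out" the
rail itself turns at 51 m. A parallel path at perpendicular offset *d* from
the rail is again a stadium with bend radius 51 + *d* and loop length
2·40 + 2π·(51 + *d*). The reference-offset loop is therefore
2·40 + 2π·52 ≈ 406.73 m.

Frame and conventions: origin at the track centroid, x toward the home
straight, races counter-clockwise, counter-clockwise turning positive
(right-hand rule). The finish line is the arc-length datum; start positions
per race distance are stored in the geometry and, for the synthetic races,
derived as `(loop − distance) mod loop` so each race ends at the finish.

Camber percentages (8% bends / 4% straights on the modelled track) are
carried as metadata only. The modelled alignment has **no built-in
easements**: bends meet straights with a curvature step. That sharp
geometry is deliberate — it is the baseline against which the smoothing
effect of actual running paths is measured.

Because the idealized loop (~407 m) is shorter than the real track's
effective lap (which absorbs camber-transition length), a 525 m race on
this model starts on a bend rather than on the home straight. None of the
computed statistics depend on the start-section type; distance axes are
always per-start.

Perpendicular distance to the rail uses the point-to-polyline distance of a
0.05 m-spaced rail polyline (shapely). 0.05 m vertex spacing keeps every
discretization error (chord sag ≈ 6·10⁻⁶ m at R = 51 m) far below the
0.15 m positioning noise. The stadium also admits a closed-form distance —
|d(point, bend-centre segment) − 51| — which the tests use as an
independent oracle.

## Racing lines with easements

A racing line is built from its curvature profile: zero on straight cores,
constant 1/(51 + bend_offset) on bend cores, and ramps linear in arc length
(the first-order clothoid construction) of the easement length *e* at every
transition. Positions come from numerically integrating heading and
position on a 0.01 m grid; each half lap turns exactly π, so the loop
closes by symmetry, and the residual quadrature error (< 10⁻³ m) is
redistributed linearly in arc length. Bend cores are placed concentric with
the rail bends, so bend-core points sit exactly `bend_offset` from the
rail.

A linear ramp of length *e* forces the straights to run a lateral shift
p(e) ≈ e²κ/24 (computed exactly by quadrature) further out than the bend
cores. Only two of {straight offset, bend offset, easement length} are
therefore free. The constructor resolves this as follows:

- `easement_length=None` (default): *e* is solved so p(e) equals
  `straight_offset − bend_offset`; both offsets are then honoured exactly.
  This mirrors what real racing lines do — wider on the straights, tight on
  the bends, joined by transitions whose length the offsets imply.
- explicit `easement_length`: the bend offset and ramp length are honoured;
  the achieved straight clearance `bend_offset + p(e)` is reported in
  `TrackPath.meta["achieved_straight_offset"]`.

Exact Fresnel-integral clothoids are unnecessary: at 0.05 m vertex spacing
the linear-curvature integration is already exact to well below the noise
floor.

## Synthetic tracking stream

The generator's defaults are the study conditions:

| parameter | default | why |
|---|---|---|
| greyhounds per race | 8 | standard field size |
| race distance | 525 m | the medium start |
| peak speed | 19.4 m/s at 120 m | peaks slightly below 19.5 m/s, 80–150 m in |
| finish speed | 16.1 m/s | medium-distance end speed |
| sampling | 30 ± 1 Hz | the tracking system's rate and its uncertainty |
| per-axis noise SD | 0.106 m | reads the ±150 mm accuracy as planar RMS: 0.106·√2 ≈ 0.150 m |
| bend lane offset | U(0.5, 1.5) m | mean 1 m ⇒ mean bend path radius 52 m |
| straight excess | U(0.3, 1.0) m | straights wider than bends, ~0.8–2.5 m total spread |
| easement | fitted per subject | ≈ 19–35 m, implied by the drawn offsets |
| speed scale jitter | ±2 % per subject | field spread in finishing times |
| artifact window | 0.8 s, fraction 0.3, 2 m | start-box radio interference |

The speed profile rises as a quarter-ellipse
s(d) = peak·√(1 − (1 − d/p)²) — zero speed at the boxes with finite
(≈ peak²/p ≈ 3.1 m/s²) launch acceleration, levelling off exactly at the
peak — then decays linearly to the finish speed. The motion law d(t) is
tabulated by integrating 1/s (the integrable √d singularity at the start is
handled analytically) so time sampling is exact. The sampling rate is drawn
once per race within mean ± jitter (the rate is uncertain; the clock is
not), and samples fall on a regular grid at that rate. All randomness flows
from a single seeded generator recorded in the output metadata; identical
seeds give bit-identical recordings.

What the generator deliberately does **not** model: interaction between
greyhounds (checking, congestion, overtaking), lure-speed control, stride
mechanics below the path level, per-sample timing chaos, and non-Gaussian
error tails. Passing tests therefore demonstrate correctness of the
geometry/kinematics pipeline under known ground truth, not behavioural
realism of greyhound fields.

## Cleaning chain

Order: trim → outlier replacement → moving average → resample.

- **Trim**: the first 1.0 s by default — position fixes near the metal
  starting boxes are unreliable, and launch accelerations make the first
  second uninformative anyway. Positional analyses may use 0.2 s.
- **Outlier replacement**: residuals against a 5-sample centred moving
  average; a sample is flagged when its residual deviates from the local
  residual mean by more than 3 rolling SDs (31-sample window, full windows
  only) and is replaced by the moving-average value. Comparing against the
  local residual *mean* stops the smooth filter bias on curved sections
  from masquerading as outliers; requiring full windows keeps truncated-
  window bias at the series ends from flagging clean data; SDs below 1 µm
  are treated as degenerate (no positioning system resolves that scale).
  x and y are screened independently, but a flag in either axis replaces
  both coordinates — a planar fix is either trusted or it is not.
- **Moving average**: 5 samples (~0.17 s at 30 Hz), below the ~0.3 s
  stride period, so stride-scale path structure survives. The window is a
  free choice and configurable; the induced inward bias on a 52 m bend is
  ≈ 7 mm, inside the stated distortion budget (< 0.02 m on section cores
  for noise-free data).
- **Resample**: linear interpolation onto a uniform grid at 3.34 Hz — the
  mean gallop stride frequency — so consecutive samples are about one
  stride apart and the three-point curvature spans ~2 strides.

## Kinematics

Speed is per-interval displacement over the time step, assigned to interval
midpoints and interpolated back to the grid; forward acceleration is its
finite-difference time derivative (central interior, one-sided ends); no
extra smoothing happens inside the kinematics — smoothing belongs to the
cleaning chain. Curvature uses the circumcircle of three consecutive
stride-resampled samples, κ = 4·area/(a·b·c), signed by the turn direction;
it is exact on circles regardless of point spacing, which is why it suits
stride-scale sampling. The first/last samples take their neighbour's value
to stay grid-aligned. Centripetal acceleration uses |κ| (a magnitude, as
plotted); the signed κ is preserved for yaw. Per-stride jerk multiplies the
consecutive a_c difference by the stride frequency.

Two stride constants coexist on purpose: 3.34 Hz for resampling and
3.54 Hz for the jerk's stride period. Both uses are honoured with their own
defaults and config keys; the tension between them is inherited, not
resolved here.

On noisy data the per-sample curvature estimate is roughly symmetric about
the true value, so cohort statistics average the **signed** curvature (the
folded mean of |κ̂| is biased upward); with the default noise the
race-then-cohort mean recovers the bend-core curvature to well under 5 %.

## Track-path jerk and the comparison

`theoretical_track_jerk` marches a point along a path one stride at a time
under a speed law and differences a_c per stride. Curvature at the stride
samples comes either from the path's analytic profile (`"analytic"`; a
junction crossed within one stride then yields the full step jerk s²κ·f) or
from the same three-point circumradius estimator applied to the stride
samples (`"circumradius"`). The `compare-jerk` pipeline and the acceptance
comparison use the circumradius method: measured running-path jerk is
necessarily estimator-smoothed (a curvature step smears over ~2 strides),
so the track path must be pushed through the identical estimator for a
like-for-like comparison — otherwise the comparison measures the estimator,
not the path. For the consistency check that an easement-free racing line
reproduces the track-path jerk, both routes are evaluated on the identical
stride grid (time-marched via the speed profile's motion law) with no
moving average and no noise, isolating the path geometry itself.

## Aggregation

Distance-binned (default 5 m ≈ one stride) race profiles average all of a
race's subjects and samples per bin; cohort statistics are the unweighted
mean of per-race bin values — two-stage averaging, which equals pooled
averaging only when races contribute equal counts per bin — with min/max
envelopes retained. A 3-SD screen per bin across races (the final outlier
pass of the cleaning procedure, applied to computed dynamics) is on by
default in the CLI and configurable off. Bins with no coverage are reported
absent, never interpolated.

The jerk envelope is per-bin extremes of per-race bin means across races;
extremes of per-race whole-profile means would be the natural alternative
and can be had by aggregating differently, but per-bin extremes match the
envelope-versus-distance presentation.

## Numerical choices and degenerate inputs

- Collinear curvature triples give exactly 0; coincident points are errors.
- κ = 0 maps to an infinite turning radius (`inf`), signalling "straight".
- Zero-speed marching in the track-jerk evaluation terminates (no progress
  is possible) and reports no jerk.
- Validation errors name the offending field; unknown config keys are
  errors, so typos cannot be silently ignored.
- Times serialize at 6 decimals, coordinates at 4 (0.1 mm); CSV round
  trips are byte-stable after one write.

## Problem sizes

The default test and acceptance runs use 20-race cohorts of 8 greyhounds at
30 Hz (~8,500 raw samples per race), which puts cohort-mean sampling error
well below the tolerances being checked while the whole suite stays fast.

## Known limitations

- The stadium alignment omits the real track's camber transitions, so
  synthetic race distances wrap the idealized loop differently than the
  real section tables; per-start distance axes are unaffected.
- Lane-offset statistics are a modelling choice (no per-box data exist to
  fit); they are config, not inference.
- The jerk envelope on noisy synthetic data is dominated by propagated
  position noise at the per-bin extremes; envelope magnitudes are therefore
  conservative upper bounds, while the mean profiles and the
  easement-versus-sharp-path ordering are robust.
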