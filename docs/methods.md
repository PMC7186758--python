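# Methods

`socialspike` reimplements, as a tested pipeline, the analysis chain that
relates the spike activity of a single mushroom-body extrinsic neuron (MB
EN) to the self-initiated social behavior of a freely moving honeybee
inside a small observation hive.  The pipeline consumes two inputs: a
multi-animal tracking table (per-frame bee id, centroid position in cm,
long-body-axis angle) at 10 frames/s, and the sorted spike times of the one
recorded unit.  Everything upstream of those files — electrode work, spike
sorting, pixel-level tracking — is out of scope.

## The behavioral clock and conventions

All series live on the 100 ms frame clock.  Bins are half-open `[t, t+0.1)`
with left-edge timestamps; a spike exactly on an edge belongs to the
right-hand bin; a final partial bin is dropped.  Walking speed at frame *i*
is the centroid displacement from frame *i−1* times the frame rate, with no
smoothing.  Distances are centroid-to-centroid; this matters because the
1 cm contact radius is of the same order as a bee body, and the tracker
gives no finer reference point.  The arena (55 × 55 cm) is tilted 17° to
the horizontal; up-slope is the +y axis, and the gravity-relative body
angle is measured from up-slope so that a bee pointing straight down-slope
reads 180°.  Tracker dropouts are permitted: a bee missing from a frame is
simply skipped in that frame's nearest-bee search (the source analyses do
not state how dropouts were handled; this is this package's rule).

## Social states

Five 4 s window types, each synchronized at its 2 s mark:

| state | definition |
|---|---|
| alone | no other bee closer than 10 cm for the whole window (strict >) |
| random | software-selected control windows, count-matched to passive contacts |
| walking onset | < 1 mm of path for 2 s, then continuous walking ≥ 2 s; sync at the onset |
| passive contact | alone at window start, exactly one bee < 1 cm at the sync; focal never moves, or moves throughout |
| active contact | same geometry; focal still initially and starts walking between the 1 s and 2 s marks |

"Continuous walking" needs a frame-level speed criterion the window
definitions leave open: the default is ≥ 0.5 cm/s in ≥ 90 % of the span's
frames (the 10 % tolerance absorbs tracker jitter); both are configurable
(`StateConfig`).  "Alone beforehand" for contacts is evaluated at the
window-start frame.  Maximal alone runs are tiled greedily from the run
start; windows of the same state never overlap; overlaps between states are
counted and reported.  Random windows may overlap real-state windows
(toggleable decision — they are a baseline sample, not a disjoint

partition).

## Neural analyses

**PETH.**  Each event contributes a 160-bin lag vector (±8 s in 100 ms
bins) aligned to its sync; the vector is divided by its own mean over the
span (events with zero spikes in the span are dropped and counted; dividing
by the grand mean instead is available by flag), then averaged across
events.  Events without a full ±8 s context are dropped and logged, never
padded.  The pre-event peak latency is the lag of the maximum of the
0.3 s-boxcar-smoothed mean relative rate within [−4 s, 0]; a PETH whose
maximum is within 5 % of its mean is reported as "no phasic peak".  The
search interval and smoothing are this package's choices — the source
analyses report sub-second leads but no search rule.

**Window variance.**  The variance of the 40 in-window 100 ms rates with
the population denominator *n* ("average of the squared differences from
the mean"), in Hz².  Pairwise rank-sum tests compare the per-state variance
samples; the Bonferroni family is the 6 pairs among {random, walking onset,
passive contact, active contact}, giving the star thresholds 0.05/6 ≈
0.0083, 0.01/6 ≈ 0.0017 and 0.005/6 ≈ 0.00083.  With 5 states there would
be 10 pairs, so treating the family as the four non-alone states is an
interpretive decision: "alone" pairs are reported alongside but not
star-annotated (an `include_alone` flag switches to the 10-pair, α/10
family).

**Distance deciles.**  Frames with a defined nearest-bee distance are
sorted by rate and split into 10 equal-count groups (remainder spread over
the last groups); the rank-sum test contrasts the distance distributions of
the top and bottom group.  Because 100 ms counts are small integers, ties
are massive and the tie-break decides group membership.  Breaking ties by
frame index makes group 1 "early recording" and group 10 "late recording",
which, with an autocorrelated distance series, turns the null test into an
early-vs-late comparison (≈ 98 % false positives in simulation).  The
default therefore breaks ties with a seeded random permutation —
deterministic, but independent of time — which restores the nominal
rejection rate; `tie_break="index"` remains available.

**Statistics.**  The rank-sum test is exact (dynamic-programming
enumeration of the rank-sum null) for untied samples with n ≤ 20, otherwise
a midrank normal approximation with tie-corrected variance and a 0.5
continuity correction; all tests are two-sided (sidedness was not stated at
the source; two-sided is the conservative default).  The Rayleigh test is
weighted: each frame's body-axis angle enters with its spike count as
weight, mean resultant length R̄ = |Σ w e^{iθ}|/Σw, Z = (Σw)·R̄², and
p = e^{−Z}[1 + (2Z − Z²)/(4Σw)] clipped to [0, 1].  The binned-rate
(unweighted) variant is available, since "spike rate distribution across
orientation angle" does not fix the weighting.

## The synthetic colony generator

The generator exists so that every stage can be validated by parameter
recovery without the original recordings.  What it emulates, and how:

* **Locomotion** — a per-bee stop/go Markov chain (defaults: stop→go 0.02,
  go→stop 0.05 per frame, i.e. ~5 s standing and ~2 s walking bouts);
  walking speed is log-normal with mean 1.5 cm/s (a typical in-hive walking
  speed) and heading is wrapped-normal around the previous heading (sd
  20°/frame); arena walls reflect.  A stationary bee keeps its last body
  angle, as a tracker reporting the long axis would.
* **Social episodes** — planted contacts are scripted: a partner stages to
  10.8 cm, approaches radially to cross 1 cm exactly at the scheduled sync,
  holds 1 s, and departs.  For passive contacts the focal bee is held
  still for the whole window; for active contacts it starts walking toward
  the partner 0.6 s before contact (1.2 cm/s for 1.5 s — long enough to be
  walking, short enough never to register as a walking onset).  Scripted
  walking onsets hold the focal still 3 s and then walk it 3 s.  Outside
  episodes a 12 cm mutual exclusion zone around the focal bee blocks any
  unscripted approach, so the planted event list — including the greedy 4 s
  tiling of the alone intervals, computed from the generator's own realized
  positions — is exhaustive ground truth.  Episode times are uniform with a
  16 s minimum separation; with Poisson counts the realized number stays a
  Poisson draw.
* **Firing rate** — λ(t) = [baseline + β·e^{−d(t)/d₀} + α·g(t − t_c)]·m(t),
  clipped at 0.  Defaults: baseline 3 Hz, β = 15 Hz, d₀ = 6 cm (so the
  distance effect spans ~0.5–15 Hz over the observed distance range, inside
  the 0.6–23 Hz span of real units), α = 8 Hz.  g is a raised-cosine bump
  of full width 0.8 s *centered lead_s before* each planted active contact
  (default 1.2 s) and truncated at the contact: the bump peak is the
  quantity the latency analysis recovers, so it sits at −lead_s.  m(t) is a
  log-normal multiplier, median 1, redrawn every 1 s; inside a planted
  event window its sd is the state's `sigma_state` (defaults 0.1 alone,
  0.2 random/background, 0.5 onset and passive, 1.0 active), elsewhere the
  background sd.  Redrawing *within* the window is what plants a
  state-dependent within-window variance: a multiplier held constant over
  the window would only rescale the window mean and leave the rank-sum on
  per-window variances with no effect to find (P(var_a > var_b) = ½ for any
  sigma pair).
* **Spikes** — inhomogeneous-Poisson thinning against λ_max; constant-rate
  inter-spike intervals pass a KS test against the exponential law.

What the generator does *not* emulate: tracker noise and dropouts,
occlusions, body-size/caste differences, odor or trophallaxis cues,
wall-following and clustering behavior, and non-Poisson spike statistics
(refractoriness, bursting).  Passing recovery tests therefore show that the
detectors and estimators are correct under their stated definitions, not
that those definitions are robust to real tracker artifacts.  One visible
consequence: the scripted focal bee is frozen during episodes, so the
synthetic focal-vs-others walking-speed comparison rejects, whereas real
focal bees walked like their hive mates.

## Numerical and design notes

* Exact float round-trip for fixtures (shortest-repr CSV writing,
  `float_precision="round_trip"` reading); byte-identical outputs under a
  fixed (config, seed); trajectory, multiplier and spike streams are
  seeded independently so changing a rate parameter never changes the
  trajectories.
* Nearest-bee ties break to the lexicographically smallest id; the
  distance-split cut assigns d = 5 cm to the near stratum; quarter splits
  give remainder frames to the last quarter.
* Degenerate inputs: all-equal rank-sum samples give p = 1; empty strata
  are flagged, not fatal; a recording with no contacts reports the
  contact-dependent analyses as "not applicable"; PETH states with zero
  usable events raise with the state named.
* When both the distance effect and the phasic bump are active, the
  approach ramp (distance → 0 at contact) superimposes on the bump and the
  PETH peak moves toward the contact; the latency-recovery analyses
  therefore isolate the bump (β = 0), which is also how the recovery is
  specified.
* Problem sizes used by the test suite and the acceptance script (60–100
  events, 50 windows/state, 100–500 replicate runs, 10⁴ frames) were chosen
  as the smallest sizes at which the planted effects are comfortably
  resolvable; they complete in well under a minute per analysis on one
  core.

## Known limitations

Detector thresholds are exactly the stated window definitions; real
recordings with tracking noise near the 1 cm and 10 cm radii will need the
configurable hysteresis the thresholds in `StateConfig` provide, and
performance there is unmeasured.  The variance analysis assumes the 100 ms
binning; other bin widths change the Poisson floor under the variance.  The
Rayleigh test assumes unimodal departure from uniformity and will miss the
bimodal (axial) orientation profiles that occasionally occur; an axis-
doubling transform is the standard workaround and is easy to apply to the
angle column upstream of the test.
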