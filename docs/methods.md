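# Methods

## Scope and model

`beetrack` reconstructs the nesting and foraging behavior of individually
tagged, cavity-nesting solitary bees from per-frame observations of a
frontally filmed nesting unit. The behavioral model is minimal and matches
what the outputs need: a female alternates **stays inside her nest cavity**
(provisioning brood cells) with **flights** away from the unit (foraging or
mud collection); on each return she may briefly **probe** wrong cavities
before entering her own. Every quantity the package reports — nest
assignments, probe counts, flight durations, flight activity — is a function
of the enter/leave event stream at the cavity mouths.

The identity space is fixed by the tag alphabet: 3 colors (white, yellow,
green) × 8 digits (1–8) = 24 bees; the cavity space by the unit geometry:
at most 12 rows × 10 columns = 120 cavities, indexed `R<row>C<col>` with
row 1 topmost and column 1 leftmost in the image.

## Pipeline stages and their assumptions

**Detection.** The `Detection` record (frame, centroid, box, tag read) is an
interface with two backends. The *oracle* backend converts a simulator
stream verbatim and is the reference path for behavioral tests. The
*classical* backend works on rendered frames: cavities are dark,
near-circular blobs (eccentricity-filtered so bee bodies are rejected); tag
discs are saturated colored blobs or very bright white blobs; tag color
comes from the median hue of saturated pixels (yellow < 0.22 < green < 0.50
on the [0,1) hue circle, white by low saturation at high brightness); the
digit is read by normalized correlation of the dark glyph hole inside the
disc against the eight canonical 5×7 glyph bitmaps. The yellow/green hue
boundary is the reproducible color-confusion axis: a green disc whose hue
drifts below the boundary reads as yellow. The classical backend assumes
imagery like the renderer produces; it is not hardened against real-world
illumination, and a learned detector could be slotted in behind the same
interface.

**Grid indexing.** Cavity centers are clustered into rows and columns by
1-D gap splitting on the sorted y (rows) and x (columns) coordinates. The
split threshold is half the estimated band spacing (the median of the gaps
at or above the mean gap), floored at 10 px so sub-pixel jitter never
fragments a band. This assumes a frontal, axis-aligned view; no homography
is fitted. Center sets clustering into more than 12 rows or 10 columns are
rejected.

**Tracking.** A greedy nearest-centroid linker: per frame, candidate
(path, detection) pairs are sorted by distance and accepted in increasing
order while within `tracker_max_match_dist_px` (default 80 px); unmatched
detections open new paths; a path unmatched for more than
`tracker_max_missed_frames` (default 15 frames) closes. Greedy matching is
a design choice, not a shortcut: its characteristic failure — two bees whose
paths cross at a shallow angle exchange identities — is the documented error
class of centroid trackers, and the evaluation machinery is built to exhibit
it rather than repair it (no appearance-based re-identification). Path
identity is resolved at close time by confidence-weighted majority over the
fully readable tag reads, ties broken toward the later-observed read;
paths with no readable read resolve to `unknown`. Paths shorter than
`min_track_length_frames` (default 3) are discarded as noise.

**Events.** A path whose first detection lies within the cavity association
radius (default: half the median cavity spacing) of a cavity center starts
with a *leave* of that cavity; a path ending there closes with an *enter*.
This relies on the disappearance semantics: a bee inside a cavity or off
screen produces no detections, so every stay and every off-screen flight
fragments the trajectory into one path per visible transit.

**Error correction.** Events with unidentified bees are removed. Then, per
bee, two chronologically consecutive events of the same kind imply a missing
complementary event between them, and exactly the two flanking events are
marked unusable (a longer same-kind run flags every member). After this
single pass, kinds strictly alternate within every unbroken run of usable
events; an unusable stretch acts as a *gap*. No derived measurement window
may span a gap: a candidate nest stay, a nest-recognition window, or a
flight window containing an unusable event of that bee is discarded. The
single-pass rule (rather than re-scanning the usable subsequence to a
fixpoint) is deliberate: a fixpoint cascade would let one missing event
invalidate arbitrarily many good neighbours, which both overshoots the
damage one missing event can do and destroys the "exactly the flanking
pair" accounting that makes the corrected file auditable.

**Address book (double time rule).** A usable enter with a matching next
usable leave of the same cavity assigns the bee to that cavity iff
(i) the stay lasted at least `min_inside_duration_s` — the minimum a nesting
female needs to unload pollen — and (ii) the bee's next usable enter of a
*different* cavity came at least `min_outside_duration_s` after the leave,
or never, in which case at least that much video must remain after the
leave (an undecidable tail withholds the assignment; precision is preferred
over recall). Both thresholds default to 40 s and are config fields, since
other species or setups may need different values. Comparisons are
inclusive (`>=`), so an exactly-40 s stay qualifies at the default.
Re-qualification of an existing (bee, cavity) pair is not re-added; a bee
may legitimately accrue assignments to several cavities over time.

**Active nest.** Nest-recognition and flight records are anchored to the
bee's *active nest*: the assignment with the latest establishment time at or
before the moment of interest. Assignments are applied retrospectively —
before her first assignment is established, the earliest one counts. The
alternative (no nest until established) would drop every bee's first
homecoming, although the bee was demonstrably already nesting there while
the qualifying evidence accrued; the whole video is available when these
files are written, so hindsight is legitimate.

**Nest recognition.** For each usable enter of the active nest, the window
opens at the bee's previous usable leave of that nest (or video start) and
`n_probed` is the number of usable enters of other cavities inside the
window. A short re-entry of the bee's own nest is a homecoming, not a
probe: probes are by definition *wrong* cavities.

**Flight list.** Each usable leave of the active nest paired with the next
usable enter of that same nest yields one flight record (duration = enter −
leave, timestamped at the leave). Probing visits in between belong to the
flight. Flights still open at the video end produce no record.

**used_for flags.** The corrected-events file carries one flag per output;
a flag is true iff the event actually participated in an emitted record of
that output (the qualifying pair for the address book, the window boundary
and window events for nest recognition, the leave/enter pair for flights).
Only flagged events are candidates for manual precision review.

**Evaluation.** Produced events are greedily matched in chronological order
to unclaimed ground-truth events requiring identical bee, cavity, and type
and a timestamp difference within `time_tol_s` (default 1.0 s — enter
timestamps depend on the exact disappearance frame). Precision
TP/(TP+FP) is the primary figure. Recall is computed because ground truth
makes it free, but it is secondary by design: missed events shrink sample
sizes without biasing the measurements themselves.

## The synthetic-data generator

The simulator emulates the study geometry: a 1920×1080 scene (16:9), the
cavity grid centered on the board with 80 px spacing, 18 px cavity radius,
12 px tag discs on 44×26 px body ellipses, bees moving at 400 px/s along
piecewise-linear waypoint paths with a 3 px sinusoidal wobble that vanishes
at path endpoints (so endpoints coincide exactly with cavity centers).

Behavioral defaults, chosen once as field-plausible for *Osmia*-type
females and used as the fixed study conditions of every benchmark:

| parameter | default | meaning |
|---|---|---|
| `flight_duration_lognorm` | lognormal(ln 240 s, 0.4) | foraging-trip length |
| `inside_duration_lognorm` | lognormal(ln 300 s, 0.4) | provisioning stay |
| `initial_inside_range_s` | uniform(30, 300) s | stagger of first departures |
| `n_probes_p` | geometric(0.5) on {0,1,…} | wrong cavities per return |
| `probe_duration_range_s` | uniform(2, 8) s | stay inside a probed cavity |

Probe durations are validated to stay strictly below
`min_inside_duration_s`, so a probe can never qualify as nesting under a
correct implementation. Noise (`miss_rate`, `tag_unreadable_rate`,
`green_yellow_confusion_rate`, `centroid_jitter_px`) applies per detection,
never to the truth; the per-slot random draws are consumed in a fixed order
regardless of the rates, so streams from the same seed at different rates
are coupled (raising the miss rate can only remove detections — the noise
monotonicity property is exact, not statistical).

Crossing-free sessions (`avoid_crossings=True`, the default) are produced by
an airspace scheduler: at most one bee is in visible transit at any moment,
with a 1 s cooldown between transits so the tracker's gap tolerance cannot
bridge two different bees. Delayed bees simply stay inside (or off screen)
longer, and the ground truth records the actual times. A separate scripted
two-bee scene (`scripted_crossing_session`) constructs the opposite regime:
two bees fly in simultaneously on straight paths sharing the same x at every
frame and crossing vertically late in the approach — a geometry that
guarantees the greedy matcher swaps them.

What the generator does **not** emulate: occlusion other than path
crossings, illumination and weather, bee-size variation, tag wear, camera
shake, or realistic flight kinematics. Passing the recovery benchmarks
therefore shows the *logic* of tracking, event extraction, correction, and
the derived outputs is exact under clean conditions and degrades only
through the modelled error channels; it does not certify performance on
real video, which depends on the detector quality for the setup in use.

## Numerical choices

- Time is frame-quantized: all scheduled behavior lands on integer frame
  indices; timestamps are `frame / fps` and render as `HH:MM:SS.mmm`.
  At the default 25 fps every frame time is an exact millisecond multiple,
  so CSV round-trips are lossless.
- Greedy matching breaks distance ties by (distance, track order, detection
  order) — deterministic for identical inputs.
- Identity votes break ties toward the later-observed read; grid clustering
  uses stable sorts; every simulator draw comes from a seeded
  `numpy.random.Generator` (behavior and noise streams are split via
  `SeedSequence.spawn`), so identical scenarios reproduce bitwise-identical
  outputs.
- Degenerate inputs: an empty frame yields no detections (not an error); an
  empty detection stream yields no tracks; an empty result bundle writes
  five header-only CSVs; an empty cavity set cannot be indexed and raises.

## Benchmark sizes

The recovery benchmark uses the full roster (24 bees, 12×10 grid) over 30
simulated minutes at 25 fps (45 000 frames), which exercises every pipeline
stage in a few seconds; imaging tests render single frames on demand rather
than whole videos. The acceptance script runs the same 30-minute session
clean and once more with noise (5% misses, 5% green→yellow confusion, 10%
unreadable tags, 1 px jitter).

## Known limitations

- ID swaps at crossing paths are inherent to centroid tracking and are
  reproduced, not repaired.
- The classical detector is tuned to the renderer's imagery; real footage
  requires a trained detector behind the same interface.
- MP4 input/output requires an ffmpeg-capable imageio backend; without one,
  PNG frame sequences are the supported video interchange.
- Assignment condition (ii) is undecidable for stays ending within
  `min_outside_duration_s` of the video end; such assignments are withheld,
  which can depress the assignment rate for short recordings.
- Nest-recognition counts repeated probes of the same wrong cavity once per
  entry (it is a count of enters, not of distinct cavities).
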