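# beetrack

Automated video analysis of nesting and foraging behavior of individually
tagged, cavity-nesting solitary bees (e.g. *Osmia bicornis*), plus a
synthetic nesting-scene simulator that makes the whole pipeline testable
without field video.

## The problem

Solitary bees are increasingly used in risk assessment of environmental
stressors, but unlike honeybees they cannot be monitored with RFID: each
female nests alone in one of up to 120 cavities (12 rows × 10 columns) on a
nesting unit, and behavioral data have traditionally required painstaking
direct observation. Filming the nesting-unit face and analyzing the video
instead yields, per individually tagged female:

- the cavity (or cavities) she is nesting in (**address book**),
- how many wrong cavities she probes before finding her nest on each return
  (**nest recognition**),
- the duration of every foraging/mud-collection trip (**flight list**), and
- **flight activity**, the fraction of alive females that flew at all.

Bees carry a colored disc (white/yellow/green) bearing a digit (1–8) on the
thorax — 24 distinct identities. Cavities are indexed `R<row>C<col>` from
the top-left of the image.

## How it works

1. **Detection** — per frame, every visible tagged bee is localized and its
   tag read (color, digit, confidence). Two interchangeable backends: a
   classical imaging backend for rendered frames (blob labelling, hue
   ranges, glyph template correlation) and an oracle backend that consumes a
   simulator detection stream. Cavities are found as dark circular blobs and
   indexed into rows/columns by 1-D gap clustering.
2. **Tracking** — a greedy nearest-centroid linker chains detections into
   movement paths (configurable match distance, default 80 px, and gap
   tolerance, default 15 frames). One identity per path by
   confidence-weighted majority vote over its tag reads. Greedy matching is
   deliberate: its characteristic failure — two bees with crossing paths
   swapping identities — is the documented error class of this tracker
   family.
3. **Events** — a path starting at a cavity mouth is a *leave*, one ending
   there an *enter*. Error correction removes unidentified bees and flags
   the two events flanking any detected missing event as unusable.
4. **Derived outputs** — a bee is assigned to a cavity iff she stayed inside
   at least `min_inside_duration_s` (long enough to unload pollen) **and**
   did not enter another cavity within `min_outside_duration_s` of leaving
   (long enough for a genuine collection trip); both default to 40 s.
   Nest-recognition counts and flight durations are read off the corrected
   event stream; windows containing unusable events are skipped, trading
   recall for precision.
5. **Evaluation** — produced events are matched against the simulator's
   ground truth (same bee, cavity, and type, within a time tolerance);
   precision = TP / (TP + FP).

The simulator generates the full behavioral ground truth (event log,
trajectories, nest map, drawn probe counts) and a per-frame detection stream
with injectable noise: detection misses, unreadable tags, green-read-as-
yellow confusion, and centroid jitter. It can also render frames (board,
cavity circles, bee bodies with tag discs and digit glyphs) for the
classical backend.

## Worked example

```bash
$ cat scenario.yaml
n_bees: 6
grid_rows: 12
grid_cols: 10
duration_s: 1800.0
rng_seed: 7

$ beetrack simulate --scenario scenario.yaml --out sim
... simulated 6 bees, 45000 frames, 62 events, 1678 detections in 0.0s

$ beetrack analyze --detections sim/detections.csv \
    --cavities sim/cavity_centers.csv --out results --name session1
... 62 raw events, 62 corrected, 6 assignments, 18 flights -> results/session1

$ beetrack evaluate --results results/session1 --truth sim/ground_truth.csv
TP=58 FP=0 FN=4 precision=100.0% recall=93.5% (recall is secondary)
```

The analysis subfolder holds the five CSV outputs
(`all_events_unfiltered.csv`, `error_corrected_events.csv`,
`address_book.csv`, `nest_recognition.csv`, `flight_list.csv`):

```bash
$ head -4 results/session1/address_book.csv
bee_id,cavity_id,established_at
white-3,R3C4,00:03:22.400
white-1,R4C6,00:03:25.400
white-2,R10C3,00:05:33.880
```

All six bees were assigned to exactly the cavities the simulator placed
them in; the 18 flights match the true leave-to-return durations; the four
missed truth events (recall 93.5%) are final departures whose flights had
not returned by the video end, so they contributed to no measurement —
sample size is traded away rather than risking a wrong value.

## Configuration

Analysis thresholds live in a flat YAML config (`--config`); keys are the
`AnalysisConfig` field names (`min_inside_duration_s`,
`min_outside_duration_s`, `fps`, `tracker_max_match_dist_px`,
`tracker_max_missed_frames`, `cavity_assoc_radius_px`,
`min_track_length_frames`, `rng_seed`). Unknown keys warn and are ignored.
See `docs/methods.md` for the model, its assumptions, and known limitations.
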