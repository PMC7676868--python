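# tagtrax

Video tracking of individually color-tagged insects — and other small
animals that aggregate so densely that they cannot always be told apart,
even by eye.

## The problem and the approach

Marking insects with small colored paint tags is a decades-old,
low-impact way to give every individual in a group a durable identity.
Tracking them automatically is hard for exactly the reason the biology is
interesting: the animals pile up. During aggregations, segmentation
cannot separate individuals, and tags are hidden for long stretches.

`tagtrax` embraces this instead of fighting it:

1. **Segmentation** — each frame is background-subtracted and thresholded
   into *blobs*; a blob may contain one animal or a whole pile. No
   attempt is made to split merged animals.
2. **Tracklet graph** — blobs are linked across frames (mask overlap for
   the unambiguous cases, dense optical flow where several linking
   options exist) into *tracklets*: maximal runs of exclusively linked
   blobs with a constant, unknown animal composition. Merge and split
   events close and open tracklets and are recorded as directed edges,
   yielding a directed acyclic graph over the whole video.
3. **Classification** — a pluggable classifier labels blob images with an
   individual ID (a tag-color combination such as `GO`: green thorax,
   orange abdomen), `unknown`, or `multi`; each tracklet takes the
   plurality ID with a confidence score.
4. **ID propagation** — per tracklet, an *assigned* and a *possible* ID
   set are maintained. Classified tracklets seed the graph in confidence
   order, and constraints are propagated to a fixpoint: an assigned ID
   must flow along edges; an ID cannot be possible where no neighbor can
   deliver it; an assigned ID excludes itself from time-overlapping
   tracklets; blob area bounds how many IDs a node must hold; in a
   closed arena every ID must be somewhere in every frame. Only
   unambiguous deductions are made — conflicts roll back the offending
   (lower-confidence) seed.

The per-ID output is a per-frame trajectory table whose rows are flagged
by provenance (`single_classified`, `single_propagated`,
`multi_propagated`, `unassigned`), plus the two standard performance
measures: the **assignment rate** (assigned ID-frames over IDs x frames)
and the **assignment error** (wrong assignments over assignments made)
with an exact Clopper-Pearson 95% CI.

A bundled synthetic arena — tagged capsule-shaped agents doing a
correlated random walk with social aggregation, rendered with occlusions
and pixel noise, with full ground truth — makes the whole pipeline
reproducible and testable without any external video.

## Worked example

Simulate a 16-individual colony (4 tag colors, ordered 2-tag
combinations) for 150 frames in a closed arena, track it with the
ground-truth oracle classifier, and validate against the simulation's
own ground truth:

```python
from tagtrax import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=3), "out/", n_frames=150)
print(summary["n_tracklets"], summary["n_edges"])
print(summary["assignment_rate"], summary["assignment_error"])
```

prints

```
104 121
1.0 0.0
```

i.e. the 150 frames decompose into 104 tracklets connected by 121
merge/split edges; after propagation every one of the 16 x 150 possible
(ID, frame) locations is assigned (rate 1.0 — longer videos with
aggregates persisting to the final frame retain some provably ambiguous,
unassigned stretches), and a census check of all assigned locations
against ground truth finds zero errors. `out/`
contains `nodes.csv`/`edges.csv` (the graph), `assignments.csv` (with
per-assignment provenance), `trajectories.csv`, and `summary.json`.

The same stages are scriptable from a shell:

```bash
tagtrax simulate --out fixture/ --seed 2 --n-frames 300
tagtrax run --input fixture/ --out results/
tagtrax validate --input results/ --gt fixture/gt.csv --n-points 500 --seed 1
```

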