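# Methods

## Overview

`tagtrax` tracks individually color-tagged insects (or other small
animals) in fixed-camera video. The method deliberately avoids trying to
separate touching animals at segmentation time. Instead it:

1. segments each background-subtracted frame into *blobs* (connected
   foreground components, possibly containing several animals),
2. links blobs across consecutive frames into *tracklets* — maximal runs
   of exclusively linked blobs sharing one (unknown) animal composition —
   organized in a directed acyclic *tracklet graph* whose edges record
   animal flow at merge/split events,
3. classifies identifiable single-animal tracklets to individual IDs
   (tag-color combinations), and
4. infers the composition of all remaining tracklets by greedy, strictly
   non-ambiguous constraint propagation on the graph.

The package bundles a synthetic-arena simulator that renders ground-truth
videos, so every stage is testable end to end without external data.

## Synthetic arena

The simulator emulates the canonical laboratory condition: N agents
(default preset `small16`: 16 agents, ordered two-color tag combinations
from four colors) moving in a closed 384x384 px arena at a scale where a
body spans ~22 px — comparable to filming few-mm insects with a webcam at
~10 px/mm.

*Motion* is a correlated random walk with heading persistence (heading
noise sigma 0.30 rad/frame, speed 2 px/frame) plus two behavioral states:
wandering and social. Social agents steer toward their nearest neighbor
and slow down on contact, which produces the transient dense aggregates
that make this tracking problem hard; state switching probabilities
(0.015/frame on, 0.010/frame off) give aggregate bouts of ~100 frames
engaging roughly half the group at equilibrium. Short rest bouts
(0.02/frame on, mean ~4 frames) emulate stop-and-go locomotion without
letting animals melt into the median background. Soft-core repulsion
keeps body centers at least 0.35 body lengths apart: bodies overlap and
touch but never coincide.

*Contact clusters* (the ground-truth notion of an aggregate) are the
connected components of the pairwise capsule-overlap graph, where each
body is a capsule of length L and width L/3 along its heading. The test
suite checks this predicate against an independent polygon-intersection
oracle (shapely buffered segments).

*Rendering*: light uniform background, dark capsule bodies with a darker
head cap (the fore-aft asymmetry lets orientation be resolved beyond the
mask's mod-pi axis), 1-3 colored tag squares along the body axis in
head-to-tail order, additive Gaussian pixel noise (sigma 3 by default).
Agents are drawn in a per-frame random order, so tags of a lower-drawn
agent can be occluded inside aggregates, as in real footage. Frames are
rendered lazily and per-frame deterministically, so long videos never
have to fit in memory.

What the simulator does *not* emulate: lighting drift and shadows, motion
blur, postural variability (bodies are rigid capsules), tag loss or
fading, debris/larvae, and camera noise correlations. Passing tests
therefore demonstrate the algorithmic machinery (linking, graph
inference, propagation soundness) under controlled conditions — not
robustness to real-world image degradation, which is what the classifier
confidence machinery and conservative propagation exist to absorb.

## Segmentation

Background = per-pixel median over 25 frames sampled uniformly in time
(robust to transient animals as long as no pixel is occupied more than
half the sampled time). Foreground = max-over-channels
|frame - background| > threshold (default 40 of 255; bodies are dark and
tags are saturated, so the max-channel difference captures both),
intersected with the ROI mask; 8-connected components with area below
25% of the expected single-animal area are dropped. Merged animals are
left as one blob by design. Blob orientation is the principal axis of
the mask via second-order central moments, reported in [0, pi);
head/tail disambiguation is deferred to export, where motion direction
is available.

## Linking and the tracklet graph

Blobs in consecutive frames are linked in two tiers:

- *Exclusive-overlap fast path*: if a previous blob's mask overlaps
  exactly one current blob and vice versa, they are linked directly
  (optical flow is expensive; the unambiguous case does not need it).
- *Flow + overlap in ambiguous regions*: for each connected group of
  candidate pairs, a dense iterative Lucas-Kanade flow field is computed
  over the group's bounding region; each previous blob's pixels are
  advected and counted against every current blob's mask (dilated 1 px).
  The pixel evidence for a pair is the larger of the advected count and
  the direct mask-overlap count — inside dense, low-texture aggregates
  the flow field is unreliable, and direct overlap is the stronger
  signal. A link is created when the evidence exceeds ``support_min``
  (default 0.25) of the *smaller* of the two blobs' areas. Normalizing
  by the smaller area keeps a single animal splitting off a large
  aggregate linkable (it carries only ~1/k of the aggregate's pixels);
  erring toward surplus links is deliberate, since a false link merely
  defers resolution to the graph while a missing link silently corrupts
  a tracklet's composition.

Tracklet maintenance follows four rules applied per frame: an unlinked
current blob opens a tracklet; an unlinked previous blob closes its
tracklet; an exclusively linked pair extends a tracklet; any branching
closes all involved tracklets, opens new ones, and records directed
edges from the earlier tracklets to the later ones. Tracklet ids are
assigned in opening order, so the graph is bit-stable given fixed input.

## Classification

The classifier is pluggable: anything mapping a blob to a probability
vector over IDs + {unknown, multi}. Two implementations ship:

- `OracleClassifier` reads the simulation ground truth (optionally
  corrupted at a stated rate, deterministically per blob). It is the
  reference for pipeline testing: with zero corruption it isolates the
  tracking machinery from classification noise.
- `FeatureClassifier`, a small trainable image classifier: crops are
  rotated to a canonical body-axis frame, flipped so the darker head end
  points one way (resolving the mod-pi ambiguity, which is essential
  because tag combinations are *ordered* pairs), downsampled, and fed to
  a one-hidden-layer MLP.

A tracklet takes the plurality ID of its blob labels; a tie leaves it
unlabeled. Confidence = (mean score of plurality-ID blobs) x
(n_plurality - n_contradictory) / n_classified, clipped to [0, 1], with
'unknown' blobs excluded from n_classified — this makes confidence grow
with the number of identified blobs, their scores, and the absence of
contradicting votes, and it is monotone in the plurality fraction.

## ID propagation

Each node carries *assigned* (proven) and *possible* (not yet excluded)
ID sets; initially everything is possible and nothing assigned. Seeds
(classified single tracklets) are applied in descending confidence, each
followed by propagation to a fixpoint of these rules:

- **positive vertical** — an assigned ID must continue into some
  successor and arrive from some predecessor; with exactly one candidate
  neighbor, the ID is assigned there. Multiple candidates = ambiguity =
  no action.
- **negative vertical** — an ID is removed from a node's possible set if
  no predecessor (or successor) can carry it.
- **horizontal** — an assigned ID is excluded from every time-overlapping
  node (tracklet compositions are constant, so partial temporal overlap
  already implies exclusion).
- **capacity / coverage** — every blob holds at least one animal, and a
  blob of area U holds at least ceil(U / A) animals, where A is 1.25x
  the largest blob ever observed in a single-animal tracklet (a safe
  per-animal area bound estimated from the classified data). When a
  node's possible set shrinks to its lower bound, all remaining IDs are
  forced. In a closed arena every ID must be in exactly one node at
  every frame, so an ID with a single covering candidate at some frame
  is assigned there. The coverage rule is disabled wholesale if the
  graph contains detection gaps (nodes opening or closing mid-video with
  no edges), because an ID could then be hiding in an undetected blob.
- **boundary** — tracklets starting/ending at an open ROI boundary are
  exempt from the vertical and coverage requirements on that side.

A contradiction (forcing an excluded ID, a vanishing continuation, a
possible set smaller than the node's animal count) rolls back everything
derived from the current seed, via a journal of state mutations, and the
seed is recorded as contradicted — between conflicting classifications
the lower-confidence one loses, since seeds are applied best-first.
Rollback (rather than permanently blocking the node) was chosen because
it restores exactly the pre-seed state, keeping the soundness argument
local to each seed.

The contract for this rule set is *soundness*, checked against an
exhaustive oracle: on randomized small graphs generated from hidden true
compositions, every assignment the greedy solver makes must be common to
*all* complete consistent compositions (each ID tracing one
edge-connected chain covering every frame; single nodes carrying exactly
one ID; known-multi nodes at least two; every node at least one). The
oracle enumerates per-ID routes with pruning and is feasible up to ~15
nodes and ~5 IDs. It covers closed arenas; open-boundary behavior is
exercised by hand-built fixtures instead.

## Export and validation

Per ID and frame the exporter reports the blob centroid and a flag:
`single_classified`, `single_propagated`, `multi_propagated`, or
`unassigned`. Orientation is reported only for single-animal frames; the
mask axis is lifted from [0, pi) to [0, 2pi) using the mean displacement
over a +-5-frame window when it exceeds 1 px/frame, otherwise only the
axis is reported. Ambiguous segments stay unassigned; gap interpolation
is left to the analyst so the flag semantics stay exact.

*Assignment rate* = assigned (ID, frame) pairs / (IDs x frames).
*Assignment error* = wrong assignments / assignments made, judged
automatically against ground truth: a single-animal assignment is
correct within one body length (22 px default) of the true position; a
multi-animal assignment is correct if the true position falls inside the
assigned blob's mask. Both a full census and a fixed-effort uniform
subsample (e.g. 500 judged points) are supported; the error estimate
carries an exact Clopper-Pearson 95% CI (Beta-quantile form, lower bound
0 at k=0, upper bound 1 at k=n).

## Numerical and design choices

- Coordinates are 0-based pixels, x rightward, y downward, headings in
  radians from +x toward +y; centroids are floats.
- Dense flow is scikit-image's iterative Lucas-Kanade (`optical_flow_ilk`,
  radius 7); any dense flow passing the pure-translation test (mean blob
  displacement within 1 px) is interchangeable here.
- Determinism: every stochastic component takes an explicit seed;
  per-frame render streams are derived from (seed, frame), so frame
  access order never matters. Reruns produce byte-identical CSVs.
- Tie-breaks: seed ranking by (confidence desc, start frame, tracklet
  id); rule application in topological (start-frame, id) order; blob
  order within a frame is raster order of the bounding-box origin.
- Degenerate inputs: blobs with fewer than 3 pixels have undefined
  orientation (reported null); empty frames yield empty graphs; a frame
  sequence shorter than the background sample count uses all frames.

## Problem sizes used by the test and acceptance runs

The bundled end-to-end condition is 16 agents / 2,000 frames in a closed
384x384 arena, which a single CPU tracks in a few minutes; propagation
soundness is checked on 200 random graphs of up to 12 nodes and 4 IDs,
where exhaustive enumeration is near-instant. These sizes are the
package's standing reference condition; all reported quantities are
recomputed from scratch at run time by `scripts/acceptance.py`.

## Known limitations

- A blob is assumed to contain at least one animal; debris or reflections
  would violate the capacity/coverage rules (real deployments would gate
  blobs on appearance, which is out of scope here).
- The per-animal area bound assumes the largest single-animal blob has
  been observed; heavily truncated videos with no single-animal sightings
  of the largest individual weaken the capacity rule (it then falls back
  to kind-based bounds only).
- Multi-to-multi splits with no later single-animal identifications
  downstream (e.g. aggregates persisting to the end of the video) are
  genuinely ambiguous and stay partially unresolved — by design, the
  solver never guesses.
- The exhaustive oracle does not enumerate open-boundary compositions;
  open-ROI propagation is therefore validated structurally (exemption
  behavior) rather than against full enumeration.
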