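"""Blob and tracklet classification.

Every blob of a tracklet is classified into one of the individual IDs,
'unknown' (an unidentifiable single animal), or 'multi' (several animals
merged into one blob). The tracklet then takes the most frequent ID among
its blob labels, together with a confidence score that reflects how many
blobs were identified, how confident each identification was, and how
many blobs contradicted the winning ID.

The classifier itself is pluggable: anything exposing ``class_list`` and
``classify_blob(blob) -> probability vector`` works. Two implementations
are provided: :class:`OracleClassifier`, which reads simulation ground
truth (optionally corrupted at a stated rate) and is the reference for
testing the pipeline, and :class:`FeatureClassifier`, a lightweight
trainable image classifier operating on orientation-canonicalized crops.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .segmentation import Blob
from .synthetic_arena import AgentSpec, GroundTruth
from .tracklet_graph import Tracklet, TrackletGraph

UNKNOWN = "unknown"
MULTI = "multi"

__all__ = [
    "UNKNOWN",
    "MULTI",
    "BlobLabel",
    "TrackletClassification",
    "OracleClassifier",
    "FeatureClassifier",
    "blob_members",
    "classify_tracklet",
    "classify_graph",
    "harvest_examples",
]


@dataclass(frozen=True)
class BlobLabel:
    label: str
    score: float


@dataclass
class TrackletClassification:
    """Tracklet-level label with confidence and the per-blob label histogram."""

    tracklet_id: int
    start_frame: int
    kind: str  # single | multi | unknown
    label: str | None
    confidence: float
    histogram: dict[str, int] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Ground-truth oracle classifier
# --------------------------------------------------------------------------


def blob_members(blob: Blob, gt: GroundTruth, frame: int | None = None) -> list[int]:
    """Indices of agents whose true center lies on the blob's mask."""
    t = blob.frame_index if frame is None else frame
    out = []
    for i in range(gt.n_agents):
        if gt.present[t, i] and blob.contains_point(gt.pos[t, i, 0], gt.pos[t, i, 1]):
            out.append(i)
    return out


class OracleClassifier:
    """Classifier that reads the simulation ground truth.

    A blob containing one agent is labeled with that agent's ID; several
    agents give 'multi'; none gives 'unknown'. With probability
    ``corruption`` a single-animal blob is labeled with a wrong, randomly
    chosen ID, and with probability ``unknown_rate`` it is labeled
    'unknown' instead (both deterministic given ``seed`` and the blob's
    frame and position, so classification does not depend on call order).
    """

    def __init__(
        self,
        gt: GroundTruth,
        corruption: float = 0.0,
        unknown_rate: float = 0.0,
        score: float = 0.99,
        seed: int = 0,
    ):
        if not 0 <= corruption <= 1 or not 0 <= unknown_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        self.gt = gt
        self.corruption = corruption
        self.unknown_rate = unknown_rate
        self.score = score
        self.seed = seed
        self.class_list: list[str] = list(gt.labels) + [UNKNOWN, MULTI]
        self._index = {c: k for k, c in enumerate(self.class_list)}

    def _probs(self, label: str) -> np.ndarray:
        p = np.full(len(self.class_list), (1 - self.score) / (len(self.class_list) - 1))
        p[self._index[label]] = self.score
        return p

    def classify_blob(self, blob: Blob) -> np.ndarray:
        members = blob_members(blob, self.gt)
        if len(members) == 0:
            return self._probs(UNKNOWN)
        if len(members) > 1:
            return self._probs(MULTI)
        true_label = self.gt.labels[members[0]]
        if self.corruption > 0 or self.unknown_rate > 0:
            key = [self.seed, blob.frame_index,
                   int(round(blob.centroid[0])), int(round(blob.centroid[1]))]
            rng = np.random.default_rng(key)
            u = rng.random()
            if u < self.unknown_rate:
                return self._probs(UNKNOWN)
            if u < self.unknown_rate + self.corruption:
                others = [l for l in self.gt.labels if l != true_label]
                return self._probs(others[rng.integers(len(others))])
        return self._probs(true_label)


# --------------------------------------------------------------------------
# Trainable image classifier
# --------------------------------------------------------------------------


class FeatureClassifier:
    """Lightweight trainable classifier on orientation-canonicalized crops.

    Crops are rotated so the body axis is horizontal, flipped so the darker
    head end points left (resolving the mod-pi ambiguity of the mask axis),
    background-subtracted, scaled to [0, 1], downsampled, and fed to a
    small multilayer perceptron that outputs a probability vector over
    IDs + {unknown, multi}. Training is deterministic given ``seed`` up to
    floating-point reduction order.
    """

    def __init__(self, class_list: Sequence[str], seed: int = 0, hidden: int = 64):
        from sklearn.neural_network import MLPClassifier

        self.class_list = list(class_list)
        self.seed = seed
        self._model = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            max_iter=400,
            random_state=seed,
            early_stopping=False,
        )
        self._fitted = False

    # feature extraction ---------------------------------------------------

    @staticmethod
    def _features(crop: np.ndarray, orientation: float | None) -> np.ndarray:
        from skimage.transform import resize, rotate

        img = np.asarray(crop, dtype=float) / 255.0
        if orientation is not None:
            img = rotate(img, np.degrees(orientation), resize=False, mode="edge")
        h, w = img.shape[:2]
        band = img[h // 2 - h // 4 : h // 2 + h // 4, :, :]
        gray = band.mean(axis=-1)
        third = w // 3
        if gray[:, :third].mean() > gray[:, -third:].mean():
            band = band[::-1, ::-1, :]  # 180-degree flip: head to the left
        small = resize(band, (8, 24, 3), anti_aliasing=True)
        return small.ravel()

    # sklearn-style API ----------------------------------------------------

    def fit(self, crops, orientations, labels) -> "FeatureClassifier":
        missing = set(self.class_list) - set(labels)
        if missing:
            raise ValueError(f"missing training examples for classes: {sorted(missing)}")
        x = np.stack([self._features(c, o) for c, o in zip(crops, orientations)])
        self._model.fit(x, np.asarray(labels))
        self._order = [list(self._model.classes_).index(c) for c in self.class_list]
        self._fitted = True
        return self

    def classify_blob(self, blob: Blob) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("classifier has not been trained")
        if blob.crop is None:
            raise ValueError("blob has no stored crop; segment with store_crops=True")
        x = self._features(blob.crop, blob.orientation_rad)[None, :]
        return self._model.predict_proba(x)[0][self._order]


def harvest_examples(
    graph: TrackletGraph,
    gt: GroundTruth,
    rng: np.random.Generator,
    max_per_class: int = 200,
):
    """Collect labeled training crops from a tracked fixture.

    Single-animal blobs are labeled with their true ID, multi-animal blobs
    with 'multi'. 'unknown' examples are synthesized by blanking the tag
    region of single-animal crops (emulating crops where no tag is
    readable). Returns (crops, orientations, labels).
    """
    by_class: dict[str, list] = {}
    for tr in graph.tracklets:
        for blob in tr.blobs:
            if blob.crop is None:
                continue
            members = blob_members(blob, gt)
            if len(members) == 1:
                lab = gt.labels[members[0]]
            elif len(members) > 1:
                lab = MULTI
            else:
                continue
            by_class.setdefault(lab, []).append((blob.crop, blob.orientation_rad))
    crops, orients, labels = [], [], []
    for lab, items in sorted(by_class.items()):
        if len(items) > max_per_class:
            idx = rng.choice(len(items), max_per_class, replace=False)
            items = [items[i] for i in sorted(idx)]
        for c, o in items:
            crops.append(c)
            orients.append(o)
            labels.append(lab)
    # synthetic 'unknown': tag regions blanked with the median body tone
    singles = [k for k, (c, o, l) in enumerate(zip(crops, orients, labels))
               if l not in (MULTI, UNKNOWN)]
    take = singles[: max(1, min(max_per_class, len(singles)) // 4)]
    for k in take:
        c = np.array(crops[k], dtype=float)
        med = np.median(c.reshape(-1, 3), axis=0)
        dark = c.mean(axis=-1) < 150
        c[dark] = np.array([60.0, 57.0, 54.0])
        crops.append(np.clip(c, 0, 255).astype(np.uint8))
        orients.append(orients[k])
        labels.append(UNKNOWN)
        _ = med
    return crops, orients, labels


# --------------------------------------------------------------------------
# Tracklet-level aggregation
# --------------------------------------------------------------------------


def classify_tracklet(
    model,
    tracklet: Tracklet,
    min_labeled_blobs: int = 1,
) -> TrackletClassification:
    """Aggregate per-blob classifications into a tracklet label.

    The plurality ID becomes the tracklet label; a tie between two IDs
    leaves the tracklet unlabeled (conservative). Confidence =
    (mean score of plurality-ID blobs) x (n_plurality - n_contradictory) /
    n_classified, clipped to [0, 1], where n_classified excludes 'unknown'
    blobs and n_contradictory counts classified blobs that voted for a
    different ID or for 'multi'.
    """
    if tracklet.n_blobs < 1:
        raise ValueError("tracklet has no blobs")
    classes = model.class_list
    votes: list[BlobLabel] = []
    for blob in tracklet.blobs:
        probs = np.asarray(model.classify_blob(blob), dtype=float)
        k = int(np.argmax(probs))
        votes.append(BlobLabel(classes[k], float(probs[k])))
    hist = Counter(v.label for v in votes)

    id_counts = {l: c for l, c in hist.items() if l not in (UNKNOWN, MULTI)}
    n_multi = hist.get(MULTI, 0)
    n_classified = sum(hist.values()) - hist.get(UNKNOWN, 0)

    kind, label, conf = "unknown", None, 0.0
    if id_counts:
        best = max(id_counts.values())
        winners = sorted(l for l, c in id_counts.items() if c == best)
        if n_multi > best:
            kind = "multi"
        else:
            kind = "single"
            if len(winners) == 1 and best >= min_labeled_blobs:
                label = winners[0]
                n_contra = n_classified - best
                mean_score = float(
                    np.mean([v.score for v in votes if v.label == label])
                )
                conf = float(np.clip(mean_score * (best - n_contra) / n_classified, 0.0, 1.0))
    elif n_multi > 0:
        kind = "multi"

    return TrackletClassification(
        tracklet_id=tracklet.tracklet_id,
        start_frame=tracklet.start_frame,
        kind=kind,
        label=label,
        confidence=conf,
        histogram=dict(hist),
    )


def classify_graph(
    model, graph: TrackletGraph, min_labeled_blobs: int = 1
) -> list[TrackletClassification]:
    """Classify every tracklet and write kind/label/confidence onto the nodes.

    Also records a per-animal blob-area bound on the graph (1.25x the
    largest blob ever seen in a single-animal tracklet): the ID solver uses
    it as a safe lower bound on how many animals a large blob must hold.
    """
    out = []
    for tr in graph.tracklets:
        cl = classify_tracklet(model, tr, min_labeled_blobs=min_labeled_blobs)
        tr.kind = cl.kind
        tr.label = cl.label
        tr.confidence = cl.confidence if cl.label is not None else None
        out.append(cl)
    single_areas = [
        b.area_px for tr in graph.tracklets if tr.kind == "single" for b in tr.blobs
    ]
    if single_areas:
        graph.area_per_animal = 1.25 * max(single_areas)
    return out
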