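"""Trajectory export and validation measures.

For each individual ID a per-frame table is produced with the assigned
location, the orientation (single-animal frames only, head/tail
disambiguated by motion when the animal moves fast enough), and a flag
stating how the location was obtained: ``single_classified`` (direct
classifier assignment), ``single_propagated`` (inferred single-animal),
``multi_propagated`` (the animal is inside a multi-animal blob; the blob
centroid is reported), or ``unassigned``. Ambiguous segments stay
unassigned — no positions are fabricated.

Validation measures mirror the two standard tracking scores: the
*assignment rate* (assigned (ID, frame) pairs over IDs x frames) and the
*assignment error* (wrong assignments over assignments made), the latter
judged automatically against ground truth with an exact Clopper-Pearson
95% binomial confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .propagation import Solution
from .synthetic_arena import GroundTruth
from .tracklet_graph import TrackletGraph

FLAGS = ("single_classified", "single_propagated", "multi_propagated", "unassigned")

__all__ = [
    "FLAGS",
    "ValidationSummary",
    "export_trajectories",
    "assignment_rate",
    "assignment_error",
    "clopper_pearson",
]


@dataclass
class ValidationSummary:
    n_correct: int
    n_incorrect: int
    assignment_error: float
    ci95: tuple[float, float]

    @property
    def n_judged(self) -> int:
        return self.n_correct + self.n_incorrect


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------


def _smoothed_displacement(tr, frame: int, window: int = 5) -> tuple[float, float, float]:
    """Mean per-frame displacement around ``frame`` within the tracklet."""
    lo = max(tr.start_frame, frame - window)
    hi = min(tr.end_frame, frame + window)
    if hi <= lo:
        return 0.0, 0.0, 0.0
    x0, y0 = tr.blob_at(lo).centroid
    x1, y1 = tr.blob_at(hi).centroid
    n = hi - lo
    return (x1 - x0) / n, (y1 - y0) / n, float(np.hypot(x1 - x0, y1 - y0) / n)


def export_trajectories(
    solution: Solution,
    graph: TrackletGraph,
    head_tail_speed_min: float = 1.0,
) -> pd.DataFrame:
    """Build the per-ID per-frame trajectory table from a solved graph.

    Orientation is reported only for single-animal frames: the blob's
    principal axis in [0, pi), lifted to [0, 2pi) using the local movement
    direction when the mean displacement exceeds ``head_tail_speed_min``
    px/frame over a +-5 frame window.
    """
    ids = solution.states.ids
    n_frames = graph.n_frames
    rows: dict[tuple[str, int], tuple] = {}
    for v in sorted(solution.states.assigned):
        tr = graph.tracklet(v)
        if not tr.blobs:
            continue
        is_single = tr.kind == "single"
        for i in sorted(solution.states.assigned[v]):
            prov = solution.states.provenance.get((v, i), "propagated")
            if is_single:
                flag = "single_classified" if prov == "classifier" else "single_propagated"
            else:
                flag = "multi_propagated"
            for t in range(tr.start_frame, tr.end_frame + 1):
                blob = tr.blob_at(t)
                orient = np.nan
                if is_single and blob.orientation_rad is not None:
                    orient = blob.orientation_rad
                    dx, dy, speed = _smoothed_displacement(tr, t)
                    if speed >= head_tail_speed_min:
                        motion_ang = np.arctan2(dy, dx) % (2 * np.pi)
                        cand = np.array([orient, orient + np.pi])
                        diff = np.abs(np.angle(np.exp(1j * (cand - motion_ang))))
                        orient = float(cand[np.argmin(diff)] % (2 * np.pi))
                key = (i, t)
                if key in rows:
                    raise AssertionError(
                        f"ID {i} assigned to two tracklets covering frame {t}"
                    )
                rows[key] = (blob.centroid[0], blob.centroid[1], orient, flag, v)
    records = []
    for i in ids:
        for t in range(n_frames):
            if (i, t) in rows:
                x, y, o, flag, v = rows[(i, t)]
            else:
                x = y = o = np.nan
                flag, v = "unassigned", -1
            records.append((i, t, x, y, o, flag, v))
    return pd.DataFrame(
        records,
        columns=["id_label", "frame", "x", "y", "orientation_rad", "flag", "tracklet_id"],
    )


# --------------------------------------------------------------------------
# Measures
# --------------------------------------------------------------------------


def assignment_rate(table: pd.DataFrame, n_ids: int, n_frames: int) -> float:
    """Assigned (ID, frame) pairs divided by n_ids x n_frames."""
    total = n_ids * n_frames
    if total == 0:
        raise ValueError("n_ids * n_frames must be positive")
    dup = table.duplicated(subset=["id_label", "frame"])
    if dup.any():
        raise ValueError("trajectory table has duplicate (id, frame) rows")
    return float((table["flag"] != "unassigned").sum() / total)


def assignment_error(
    table: pd.DataFrame,
    ground_truth: GroundTruth,
    match_radius_px: float,
    graph: TrackletGraph | None = None,
    n_points: int | None = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> ValidationSummary:
    """Judge assignments against ground truth.

    Single-animal assignments are correct when the reported location is
    within ``match_radius_px`` of the true position; multi-animal
    assignments when the true position falls inside the assigned blob's
    mask (requires ``graph``; otherwise the radius criterion is used with
    the blob's equivalent radius added). Census mode judges every
    assignment; with ``n_points`` a uniform random subsample of that size
    is judged instead, mimicking a fixed-effort spot check.
    """
    assigned = table[table["flag"] != "unassigned"].reset_index(drop=True)
    if len(assigned) == 0:
        raise ValueError("no assignments to judge")
    if ground_truth.n_frames <= assigned["frame"].max():
        raise ValueError("ground truth does not cover the table's frames")
    if n_points is not None:
        rng = np.random.default_rng(seed)
        k = min(n_points, len(assigned))
        assigned = assigned.iloc[sorted(rng.choice(len(assigned), k, replace=False))]

    idx_of = {lab: k for k, lab in enumerate(ground_truth.labels)}
    n_ok = 0
    n_bad = 0
    for row in assigned.itertuples(index=False):
        ai = idx_of.get(row.id_label)
        t = int(row.frame)
        if ai is None or not ground_truth.present[t, ai]:
            n_bad += 1
            continue
        tx, ty = ground_truth.pos[t, ai]
        if row.flag == "multi_propagated":
            if graph is not None and row.tracklet_id >= 0:
                blob = graph.tracklet(int(row.tracklet_id)).blob_at(t)
                ok = blob.contains_point(tx, ty)
                area = blob.area_px
            else:
                ok = None
            if ok is None:
                ok = np.hypot(row.x - tx, row.y - ty) <= match_radius_px + np.sqrt(
                    getattr(row, "area", 0.0) / np.pi
                )
        else:
            ok = np.hypot(row.x - tx, row.y - ty) <= match_radius_px
        if ok:
            n_ok += 1
        else:
            n_bad += 1
    err = n_bad / (n_ok + n_bad)
    ci = clopper_pearson(n_bad, n_ok + n_bad, alpha)
    return ValidationSummary(n_ok, n_bad, float(err), ci)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval via Beta quantiles.

    The lower bound is 0 when k = 0 and the upper bound is 1 when k = n.
    """
    if not 0 <= k <= n or n <= 0:
        raise ValueError("require 0 <= k <= n with n > 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
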