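"""Background estimation and blob segmentation.

A frame is compared against a per-pixel median background; the
max-over-channels absolute difference is thresholded, intersected with the
ROI, and 8-connected components above a minimum area become blobs. Merged
animals are deliberately left as one blob — splitting them is the job of
the tracklet-graph inference, not the segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "BackgroundModel",
    "Blob",
    "estimate_background",
    "segment_frame",
    "blob_orientation",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class BackgroundModel:
    """Per-pixel median background and a summary background color."""

    image: np.ndarray  # (H, W, 3) float
    mean_color: np.ndarray  # (3,) float

    @property
    def shape(self):
        return self.image.shape


@dataclass
class Blob:
    """One connected foreground component in one frame.

    ``mask`` is stored locally over ``bbox`` (half-open ``x0, y0, x1, y1``
    in frame coordinates). ``centroid`` is the float (x, y) mask centroid.
    ``crop`` is an optional fixed-size RGB patch centered on the centroid.
    ``orientation_rad`` is the principal axis of the mask in [0, pi), or
    ``None`` for degenerate masks; head/tail disambiguation happens later,
    at export, using motion.
    """

    frame_index: int
    bbox: tuple[int, int, int, int]
    mask: np.ndarray
    centroid: tuple[float, float]
    area_px: int
    crop: np.ndarray | None = None
    orientation_rad: float | None = None
    touches_boundary: bool = False

    def contains_point(self, x: float, y: float, tol: int = 1) -> bool:
        """Whether frame point (x, y) falls on the mask (within ``tol`` px)."""
        x0, y0, x1, y1 = self.bbox
        xi = int(round(x)) - x0
        yi = int(round(y)) - y0
        h, w = self.mask.shape
        ylo, yhi = max(0, yi - tol), min(h, yi + tol + 1)
        xlo, xhi = max(0, xi - tol), min(w, xi + tol + 1)
        if ylo >= yhi or xlo >= xhi:
            return False
        return bool(self.mask[ylo:yhi, xlo:xhi].any())


def estimate_background(frames, n_samples: int = 25, seed: int = 0) -> BackgroundModel:
    """Per-pixel median over ``n_samples`` frames sampled uniformly in time.

    If the sequence is shorter than ``n_samples``, all frames are used.
    ``seed`` is accepted for interface uniformity; the uniform-in-time
    sampling is deterministic and does not consume randomness.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    n = len(frames)
    if n == 0:
        raise ValueError("empty frame sequence")
    idx = np.unique(np.round(np.linspace(0, n - 1, min(n_samples, n))).astype(int))
    stack = np.stack([np.asarray(frames[i], dtype=float) for i in idx])
    image = np.median(stack, axis=0)
    return BackgroundModel(image=image, mean_color=image.reshape(-1, image.shape[-1]).mean(axis=0))


def _moments_orientation(mask: np.ndarray) -> float | None:
    """Principal-axis angle of a binary mask in [0, pi) via central moments."""
    ys, xs = np.nonzero(mask)
    if xs.size < 3:
        return None
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20 = float(np.mean(x * x))
    mu02 = float(np.mean(y * y))
    mu11 = float(np.mean(x * y))
    if abs(mu20 - mu02) < 1e-12 and abs(mu11) < 1e-12:
        return None  # isotropic mask: axis undefined
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    return float(np.mod(theta, np.pi))


def blob_orientation(blob: Blob) -> float | None:
    """Mask principal axis in [0, pi); ``None`` when the mask is degenerate."""
    if blob.area_px < 3:
        return None
    return _moments_orientation(blob.mask)


def _extract_crop(frame: np.ndarray, cx: float, cy: float, crop_px: int, fill) -> np.ndarray:
    h, w = frame.shape[:2]
    half = crop_px // 2
    xi, yi = int(round(cx)), int(round(cy))
    out = np.empty((crop_px, crop_px, 3), dtype=frame.dtype)
    out[:] = np.asarray(fill, dtype=frame.dtype)
    x0, x1 = xi - half, xi - half + crop_px
    y0, y1 = yi - half, yi - half + crop_px
    sx0, sy0 = max(0, x0), max(0, y0)
    sx1, sy1 = min(w, x1), min(h, y1)
    if sx0 < sx1 and sy0 < sy1:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = frame[sy0:sy1, sx0:sx1]
    return out


def segment_frame(
    frame: np.ndarray,
    bg: BackgroundModel,
    threshold: float,
    min_area: int,
    roi_mask: np.ndarray | None = None,
    crop_px: int = 64,
    store_crops: bool = False,
    frame_index: int = 0,
) -> list[Blob]:
    """Segment one frame into blobs.

    Foreground is ``max_channel |frame - background| > threshold`` inside
    the ROI; 8-connected components smaller than ``min_area`` are dropped.
    No attempt is made to split merged animals.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    frame = np.asarray(frame)
    if frame.shape != bg.shape:
        raise ValueError(f"frame shape {frame.shape} != background shape {bg.shape}")
    diff = np.abs(frame.astype(float) - bg.image).max(axis=-1)
    fg = diff > threshold
    if roi_mask is not None:
        if roi_mask.shape != fg.shape:
            raise ValueError("roi_mask shape does not match frame")
        fg &= roi_mask
    labels, n = ndimage.label(fg, structure=_EIGHT)
    if n == 0:
        return []
    h, w = fg.shape
    blobs: list[Blob] = []
    roi_edge = None
    if roi_mask is not None:
        roi_edge = roi_mask & ~ndimage.binary_erosion(roi_mask, iterations=2)
    for val, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        ysl, xsl = sl
        mask = labels[ysl, xsl] == val
        area = int(mask.sum())
        if area < min_area:
            continue
        ys, xs = np.nonzero(mask)
        cx = float(xs.mean() + xsl.start)
        cy = float(ys.mean() + ysl.start)
        bbox = (xsl.start, ysl.start, xsl.stop, ysl.stop)
        touches = xsl.start == 0 or ysl.start == 0 or xsl.stop == w or ysl.stop == h
        if roi_edge is not None and not touches:
            touches = bool(roi_edge[ysl, xsl][mask].any())
        blob = Blob(
            frame_index=frame_index,
            bbox=bbox,
            mask=mask,
            centroid=(cx, cy),
            area_px=area,
            touches_boundary=touches,
        )
        blob.orientation_rad = blob_orientation(blob)
        if store_crops:
            blob.crop = _extract_crop(frame, cx, cy, crop_px, bg.mean_color)
        blobs.append(blob)
    # deterministic order: raster order of bbox origin
    blobs.sort(key=lambda b: (b.bbox[1], b.bbox[0]))
    return blobs
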