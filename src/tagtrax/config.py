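"""Run configuration: every tunable parameter of the tracking pipeline.

A single flat configuration object covers segmentation, blob linking,
classification, ID propagation and export.  All parameters are validated
against their documented range before any processing starts, so a bad
config fails fast instead of mid-run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration parameter is outside its valid range."""


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    Attributes
    ----------
    threshold:
        Background-subtraction threshold on the max-over-channels absolute
        difference (8-bit intensity units). Must be > 0.
    expected_body_area_px:
        Expected pixel area of a single animal; used to derive ``min_area``
        when the latter is not set explicitly.
    min_area:
        Minimum blob area in pixels. Defaults to 25% of
        ``expected_body_area_px``.
    bg_samples:
        Number of frames sampled (uniformly in time) for the median
        background estimate.
    crop_px:
        Side of the square crop extracted around each blob centroid for
        classification.
    store_crops:
        Whether segmentation keeps per-blob image crops (needed only for
        image-based classifiers; the ground-truth oracle classifier does not
        use them).
    support_min:
        Minimum fraction of advected pixels that must land in a candidate
        blob for an optical-flow link to be created.
    link_search_margin_px:
        Bounding-box margin within which blobs in consecutive frames are
        considered linking candidates.
    flow_radius:
        Window radius of the dense iterative Lucas-Kanade optical flow.
    boundary_margin_px:
        Distance from the ROI edge below which a tracklet endpoint is
        flagged as touching an open boundary.
    classifier:
        ``"oracle"`` (reads simulation ground truth) or ``"model"`` (a
        trained image classifier loaded from ``model_path``).
    min_labeled_blobs:
        Minimum number of ID-labeled blobs required to label a tracklet.
    match_radius_px:
        Spatial tolerance used when judging single-animal assignments
        against ground truth. Defaults to one body length.
    body_length_px:
        Nominal body length; used for ``match_radius_px`` default and by
        the simulator presets.
    head_tail_speed_min:
        Mean displacement (px/frame over a +-5 frame window) above which
        the exporter disambiguates head from tail using motion direction.
    seed:
        Master seed for every stochastic component of a run.
    """

    # segmentation
    threshold: float = 40.0
    expected_body_area_px: float = 150.0
    min_area: int | None = None
    bg_samples: int = 25
    crop_px: int = 64
    store_crops: bool = False
    # linking
    support_min: float = 0.25
    link_search_margin_px: float = 30.0
    flow_radius: int = 7
    boundary_margin_px: float = 12.0
    # classification
    classifier: str = "oracle"
    model_path: str | None = None
    min_labeled_blobs: int = 1
    # export / validation
    body_length_px: float = 22.0
    match_radius_px: float | None = None
    head_tail_speed_min: float = 1.0
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.threshold > 0:
            raise ConfigError(f"threshold must be > 0, got {self.threshold}")
        if self.expected_body_area_px <= 0:
            raise ConfigError("expected_body_area_px must be positive")
        if self.min_area is not None and self.min_area < 1:
            raise ConfigError("min_area must be >= 1")
        if self.bg_samples < 3:
            raise ConfigError("bg_samples must be >= 3")
        if self.crop_px < 8:
            raise ConfigError("crop_px must be >= 8")
        if not 0.0 < self.support_min <= 1.0:
            raise ConfigError("support_min must be in (0, 1]")
        if self.link_search_margin_px < 0:
            raise ConfigError("link_search_margin_px must be >= 0")
        if self.flow_radius < 2:
            raise ConfigError("flow_radius must be >= 2")
        if self.classifier not in ("oracle", "model"):
            raise ConfigError("classifier must be 'oracle' or 'model'")
        if self.min_labeled_blobs < 1:
            raise ConfigError("min_labeled_blobs must be >= 1")
        if self.body_length_px <= 0:
            raise ConfigError("body_length_px must be positive")
        if self.match_radius_px is not None and self.match_radius_px <= 0:
            raise ConfigError("match_radius_px must be positive")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")

    # ---- derived defaults -------------------------------------------------

    @property
    def effective_min_area(self) -> int:
        if self.min_area is not None:
            return self.min_area
        return max(1, int(round(0.25 * self.expected_body_area_px)))

    @property
    def effective_match_radius(self) -> float:
        if self.match_radius_px is not None:
            return self.match_radius_px
        return self.body_length_px

    # ---- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of parameters")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
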