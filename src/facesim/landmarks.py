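"""Configural-form geometry from landmark-annotated face videos.

A face's "configuration" is the vector of Euclidean distances between every
unordered pair of its landmarks, taken from the first (neutral) video frame.
Pairwise Pearson correlation of configurations over a stimulus set yields the
configural-form similarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .similarity import SimilarityMatrix

__all__ = [
    "LandmarkFrame",
    "LandmarkVideo",
    "ConfigurationVector",
    "compute_configuration",
    "configural_form_similarity",
    "build_form_similarity_matrix",
]


@dataclass(frozen=True)
class LandmarkFrame:
    """A single video frame: ordered 2-D landmark coordinates in pixels."""

    coords: np.ndarray
    landmark_ids: tuple

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"coords must be (L, 2), got {coords.shape}")
        ids = tuple(self.landmark_ids)
        if len(ids) != coords.shape[0]:
            raise ValueError(
                f"{len(ids)} landmark ids for {coords.shape[0]} coordinates"
            )
        if coords.shape[0] < 3:
            raise ValueError("a landmark frame needs at least 3 landmarks")
        if len(set(ids)) != len(ids):
            counts = {i: ids.count(i) for i in set(ids)}
            dupes = sorted(i for i, c in counts.items() if c > 1)
            raise ValueError(f"duplicate landmark ids: {dupes}")
        bad = ~np.isfinite(coords).all(axis=1)
        if bad.any():
            names = [ids[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"non-finite coordinates at landmarks {names}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "landmark_ids", ids)

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class LandmarkVideo:
    """Ordered landmark frames plus stimulus metadata.

    ``coords`` has shape (F, L, 2); landmark identity/order is constant
    across frames.
    """

    coords: np.ndarray
    landmark_ids: tuple
    frame_rate: float
    stimulus_id: str
    identity: str = ""
    expression: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 2:
            raise ValueError(f"coords must be (F, L, 2), got {coords.shape}")
        if coords.shape[0] < 2:
            raise ValueError("a landmark video needs at least 2 frames")
        ids = tuple(self.landmark_ids)
        if len(ids) != coords.shape[1]:
            raise ValueError("landmark id count does not match coordinates")
        if not np.isfinite(coords).all():
            raise ValueError(
                f"non-finite coordinates in video {self.stimulus_id!r}"
            )
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "landmark_ids", ids)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def frame(self, index: int) -> LandmarkFrame:
        """Return frame ``index`` (0-based) as a :class:`LandmarkFrame`."""
        return LandmarkFrame(self.coords[index], self.landmark_ids)


@dataclass(frozen=True)
class ConfigurationVector:
    """Pairwise landmark distances in canonical (lexicographic i<j) order."""

    values: np.ndarray
    pair_index: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("configuration values must be 1-D")
        if (values < 0).any():
            raise ValueError("distances cannot be negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pair_index", tuple(self.pair_index))

    def __len__(self) -> int:
        return self.values.size


def compute_configuration(frame: LandmarkFrame) -> ConfigurationVector:
    """Distances between all unordered landmark pairs of one frame.

    For L landmarks the result has length L(L-1)/2; pairs are ordered
    lexicographically over landmark index (i < j), matching
    :func:`scipy.spatial.distance.pdist`.
    """
    values = pdist(frame.coords)
    pairs = tuple(
        (frame.landmark_ids[i], frame.landmark_ids[j])
        for i, j in combinations(range(frame.n_landmarks), 2)
    )
    return ConfigurationVector(values, pairs)


def _pearson(x: np.ndarray, y: np.ndarray, what: str) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ValueError(f"zero-variance vector: correlation undefined for {what}")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def configural_form_similarity(
    video_a: LandmarkVideo, video_b: LandmarkVideo
) -> float:
    """Pearson correlation of the two first-frame configuration vectors."""
    if video_a.landmark_ids != video_b.landmark_ids:
        raise ValueError(
            f"landmark schemes differ between {video_a.stimulus_id!r} "
            f"and {video_b.stimulus_id!r}"
        )
    ca = compute_configuration(video_a.frame(0))
    cb = compute_configuration(video_b.frame(0))
    return _pearson(
        ca.values,
        cb.values,
        f"stimuli {video_a.stimulus_id!r}/{video_b.stimulus_id!r}",
    )


def build_form_similarity_matrix(
    videos: Sequence[LandmarkVideo],
) -> SimilarityMatrix:
    """Configural-form similarity matrix over a stimulus set.

    Symmetric with unit diagonal; entry (i, j) is the Pearson correlation of
    the first-frame configuration vectors of videos i and j.
    """
    if len(videos) < 2:
        raise ValueError("need at least 2 videos")
    configs = np.stack(
        [compute_configuration(v.frame(0)).values for v in videos]
    )
    sd = configs.std(axis=1)
    if (sd == 0).any():
        bad = [videos[i].stimulus_id for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance configuration for stimuli {bad}")
    values = np.corrcoef(configs)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        values=values,
        stimulus_ids=tuple(v.stimulus_id for v in videos),
        identities=tuple(v.identity for v in videos),
        expressions=tuple(v.expression for v in videos),
        kind="physical",
    )
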