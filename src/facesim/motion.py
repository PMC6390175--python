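"""Motion-pattern measure: rigid correction, landmark flow, feature averaging.

Whole-head (rigid) movement is removed by mapping each frame's fiducial nose
triangle back onto its first-frame position with an exact affine transform.
Flow is then the per-landmark displacement magnitude between consecutive
frames, averaged within anatomical feature groups. The motion pattern is the
vector of absolute differences between every unordered pair of the
(features x transitions) flow values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .landmarks import LandmarkVideo
from .similarity import SimilarityMatrix

__all__ = [
    "FeatureMap",
    "FiducialTriangle",
    "FlowField",
    "MotionPattern",
    "AffineTransform",
    "fit_affine_from_triangle",
    "rigid_correct",
    "landmark_flow",
    "average_flow_by_feature",
    "motion_pattern",
    "video_motion_pattern",
    "build_motion_similarity_matrix",
]

_COLLINEAR_RTOL = 1e-9


@dataclass(frozen=True)
class FeatureMap:
    """Mapping feature name -> tuple of member landmark ids (disjoint sets)."""

    features: dict

    def __post_init__(self):
        feats = {str(k): tuple(v) for k, v in self.features.items()}
        seen: dict = {}
        for name, members in feats.items():
            if not members:
                raise ValueError(f"feature {name!r} has no landmarks")
            for m in members:
                if m in seen:
                    raise ValueError(
                        f"landmark {m!r} in both {seen[m]!r} and {name!r}: "
                        "features must be disjoint"
                    )
                seen[m] = name
        object.__setattr__(self, "features", feats)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> tuple:
        return tuple(self.features)

    def all_landmarks(self) -> tuple:
        return tuple(m for members in self.features.values() for m in members)

    def validate_against(self, landmark_ids: Sequence) -> None:
        missing = set(self.all_landmarks()) - set(landmark_ids)
        if missing:
            raise ValueError(f"feature landmarks absent from scheme: {sorted(missing)}")


@dataclass(frozen=True)
class FiducialTriangle:
    """Three nose landmarks used as the rigid-motion reference."""

    landmark_ids: tuple

    def __post_init__(self):
        ids = tuple(self.landmark_ids)
        if len(ids) != 3 or len(set(ids)) != 3:
            raise ValueError("fiducial triangle needs exactly 3 distinct landmarks")
        object.__setattr__(self, "landmark_ids", ids)


@dataclass(frozen=True)
class FlowField:
    """Flow magnitudes (pixels displaced), rows x (F-1) frame transitions.

    ``row_ids`` are landmark ids for the raw field or feature names after
    averaging.
    """

    values: np.ndarray
    row_ids: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("flow field must be 2-D (rows x transitions)")
        if not np.isfinite(values).all():
            raise ValueError("flow field contains non-finite values")
        if (values < 0).any():
            raise ValueError("flow magnitudes cannot be negative")
        if values.shape[0] != len(tuple(self.row_ids)):
            raise ValueError("row_ids length does not match flow rows")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", tuple(self.row_ids))

    @property
    def n_transitions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MotionPattern:
    """Distances between all unordered pairs of flow values, canonical order."""

    values: np.ndarray
    n_features: int
    n_transitions: int

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        n = self.n_features * self.n_transitions
        expected = n * (n - 1) // 2
        if values.size != expected:
            raise ValueError(
                f"motion pattern should have {expected} values for "
                f"{self.n_features} features x {self.n_transitions} transitions, "
                f"got {values.size}"
            )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class AffineTransform:
    """2-D affine map x -> A @ x + b."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.matrix.T + self.offset


def _triangle_area2(pts: np.ndarray) -> float:
    """Twice the signed triangle area (zero iff collinear)."""
    (x1, y1), (x2, y2), (x3, y3) = pts
    return (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)


def fit_affine_from_triangle(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Exact affine transform mapping three source points onto three targets.

    Solves the six linear equations directly; raises on (near-)collinear
    source triangles with a conditioning diagnostic.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != (3, 2) or dst.shape != (3, 2):
        raise ValueError("src and dst must each be three 2-D points")
    area2 = _triangle_area2(src)
    scale2 = max(float(np.ptp(src, axis=0).max()) ** 2, np.finfo(float).tiny)
    if abs(area2) <= _COLLINEAR_RTOL * scale2:
        raise ValueError(
            "degenerate (collinear) fiducial triangle: |2*area| = "
            f"{abs(area2):.3e} vs extent^2 = {scale2:.3e}"
        )
    design = np.zeros((6, 6))
    rhs = np.zeros(6)
    for k, ((x, y), (u, v)) in enumerate(zip(src, dst)):
        design[2 * k] = [x, y, 1.0, 0.0, 0.0, 0.0]
        design[2 * k + 1] = [0.0, 0.0, 0.0, x, y, 1.0]
        rhs[2 * k] = u
        rhs[2 * k + 1] = v
    params = np.linalg.solve(design, rhs)
    matrix = np.array([[params[0], params[1]], [params[3], params[4]]])
    offset = np.array([params[2], params[5]])
    return AffineTransform(matrix=matrix, offset=offset)


def rigid_correct(video: LandmarkVideo, triangle: FiducialTriangle) -> LandmarkVideo:
    """Remove whole-head motion by registering each frame's fiducial triangle
    onto its first-frame position and applying the same transform to every
    landmark. Frame 1 is returned untouched; the operation is idempotent.
    """
    try:
        tri_idx = [video.landmark_ids.index(i) for i in triangle.landmark_ids]
    except ValueError as exc:
        raise ValueError(
            f"fiducial landmark missing from video {video.stimulus_id!r}: {exc}"
        ) from None
    ref = video.coords[0, tri_idx]
    corrected = np.empty_like(video.coords)
    corrected[0] = video.coords[0]
    for f in range(1, video.n_frames):
        try:
            transform = fit_affine_from_triangle(video.coords[f, tri_idx], ref)
        except ValueError as exc:
            raise ValueError(
                f"frame {f + 1} of video {video.stimulus_id!r}: {exc}"
            ) from None
        corrected[f] = transform.apply(video.coords[f])
    return LandmarkVideo(
        coords=corrected,
        landmark_ids=video.landmark_ids,
        frame_rate=video.frame_rate,
        stimulus_id=video.stimulus_id,
        identity=video.identity,
        expression=video.expression,
    )


def landmark_flow(video: LandmarkVideo, landmark_ids: Sequence | None = None) -> FlowField:
    """Per-landmark displacement magnitude between consecutive frames.

    ``landmark_ids`` restricts the output rows (e.g. to the interior face
    landmarks); expects a rigid-corrected video. Result is (L_sel, F-1).
    """
    if landmark_ids is None:
        sel = np.arange(video.n_landmarks)
        ids = video.landmark_ids
    else:
        ids = tuple(landmark_ids)
        lut = {m: k for k, m in enumerate(video.landmark_ids)}
        missing = [m for m in ids if m not in lut]
        if missing:
            raise ValueError(f"landmarks absent from video: {missing}")
        sel = np.array([lut[m] for m in ids])
    disp = np.diff(video.coords[:, sel, :], axis=0)  # (F-1, L, 2)
    mags = np.linalg.norm(disp, axis=2).T  # (L, F-1)
    return FlowField(values=mags, row_ids=ids)


def average_flow_by_feature(raw: FlowField, fmap: FeatureMap) -> FlowField:
    """Arithmetic mean of member-landmark flow per feature and transition."""
    lut = {m: k for k, m in enumerate(raw.row_ids)}
    rows = []
    for name, members in fmap.features.items():
        missing = [m for m in members if m not in lut]
        if missing:
            raise ValueError(f"feature {name!r}: landmarks {missing} not in flow field")
        idx = [lut[m] for m in members]
        rows.append(raw.values[idx].mean(axis=0))
    return FlowField(values=np.stack(rows), row_ids=fmap.feature_names)


def motion_pattern(flow: FlowField) -> MotionPattern:
    """Distance vector over every unordered pair of flow values.

    Flow values are scalars, so the Euclidean distance between a pair is the
    absolute difference. With n features and T transitions the length is
    C(n*T, 2) — e.g. 12 features x 55 transitions gives 217,470.
    """
    flat = flow.values.reshape(-1, 1)  # row-major: feature-major ordering
    if flat.shape[0] < 2:
        raise ValueError("need at least two flow values")
    values = pdist(flat)
    return MotionPattern(
        values=values,
        n_features=flow.values.shape[0],
        n_transitions=flow.values.shape[1],
    )


def video_motion_pattern(
    video: LandmarkVideo,
    fmap: FeatureMap,
    triangle: FiducialTriangle,
    interior_ids: Sequence | None = None,
) -> MotionPattern:
    """Full per-video motion chain: rigid-correct, flow, feature-average, pattern."""
    corrected = rigid_correct(video, triangle)
    raw = landmark_flow(corrected, interior_ids)
    averaged = average_flow_by_feature(raw, fmap)
    return motion_pattern(averaged)


def build_motion_similarity_matrix(
    videos: Sequence[LandmarkVideo],
    fmap: FeatureMap,
    triangle: FiducialTriangle,
    interior_ids: Sequence | None = None,
) -> SimilarityMatrix:
    """Pearson correlations between per-video motion patterns."""
    if len(videos) < 2:
        raise ValueError("need at least 2 videos")
    patterns = np.stack(
        [video_motion_pattern(v, fmap, triangle, interior_ids).values for v in videos]
    )
    sd = patterns.std(axis=1)
    if (sd == 0).any():
        bad = [videos[i].stimulus_id for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance motion pattern for stimuli {bad}")
    values = np.corrcoef(patterns)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        values=values,
        stimulus_ids=tuple(v.stimulus_id for v in videos),
        identities=tuple(v.identity for v in videos),
        expressions=tuple(v.expression for v in videos),
        kind="physical",
    )
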