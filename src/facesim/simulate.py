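"""Synthetic inputs with planted representational structure.

Three generators cover everything the pipeline consumes:

* :func:`generate_face_set` — landmark videos with identity-specific neutral
  configurations, feature-localized expression trajectories and global rigid
  head motion;
* :func:`generate_judgments` — per-participant pairwise similarity ratings
  that are noisy monotone functions of the physical measures;
* :func:`generate_epochs` — multichannel sensor epochs whose spatial-pattern
  geometry inside a planted time/frequency window follows a target
  similarity matrix.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .landmarks import LandmarkVideo, build_form_similarity_matrix
from .meg import EpochSet
from .motion import FeatureMap, FiducialTriangle, build_motion_similarity_matrix
from .similarity import SimilarityMatrix

__all__ = [
    "FaceSetSpec",
    "JudgmentSimSpec",
    "MegSimSpec",
    "FaceSet",
    "generate_face_set",
    "generate_judgments",
    "session_schedule",
    "generate_epochs",
    "generate_all_epochs",
    "planted_patterns",
]

FEATURE_NAMES = (
    "left_brow",
    "right_brow",
    "left_eye",
    "right_eye",
    "nose_ridge",
    "nose_base",
    "left_cheek",
    "right_cheek",
    "upper_lip",
    "lower_lip",
    "left_jaw",
    "right_jaw",
)

EXPRESSION_NAMES = ("anger", "disgust", "fear", "happy", "sadness", "surprise")


@dataclass(frozen=True)
class FaceSetSpec:
    """Parameters of the synthetic dynamic-face stimulus set."""

    n_identities: int = 6
    n_expressions: int = 6
    n_landmarks: int = 179
    n_interior: int = 141
    n_features: int = 12
    n_frames: int = 56
    frame_rate: float = 28.0  # 56 frames in a 2 s clip
    identity_form_scale: float = 3.0
    expression_motion_scale: float = 4.0
    rigid_motion_amplitude: float = 2.0
    landmark_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_identities, self.n_expressions, self.n_features) < 1:
            raise ValueError("counts must be positive")
        if self.n_frames < 2 or self.n_landmarks < 6:
            raise ValueError("need at least 2 frames and 6 landmarks")
        if self.n_interior > self.n_landmarks:
            raise ValueError("interior subset cannot exceed total landmarks")
        if self.n_interior - 3 < self.n_features:
            raise ValueError(
                "cannot partition interior landmarks (minus 3 fiducials) into "
                f"{self.n_features} nonempty features"
            )


@dataclass(frozen=True)
class JudgmentSimSpec:
    """Weights linking physical similarity to rated similarity, plus noise."""

    form_task_weights: tuple = (1.0, 0.0)  # (form, motion)
    motion_task_weights: tuple = (0.0, 1.0)
    noise_sd: float = 0.05
    n_participants: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        if self.n_participants < 1:
            raise ValueError("need at least 1 participant")


@dataclass(frozen=True)
class MegSimSpec:
    """Parameters of the simulated multichannel recording session."""

    n_participants: int = 16
    n_channels: int = 64
    presentations_per_run: int = 8
    n_runs: int = 4
    sfreq: float = 100.0
    tmin_ms: float = -500.0
    tmax_ms: float = 2500.0
    planted_model: SimilarityMatrix | None = None
    planted_window_ms: tuple = (600.0, 1500.0)
    planted_freqs_hz: tuple = (4.0, 20.0)
    n_planted_freqs: int = 3
    effect_size: float = 1.0
    signal_amplitude: float = 2.0
    noise_sd: float = 1.0
    component: str = "induced"  # or "evoked"
    seed: int = 0

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.component not in ("induced", "evoked"):
            raise ValueError("component must be 'induced' or 'evoked'")
        if self.planted_model is not None:
            lo, hi = self.planted_window_ms
            if not (self.tmin_ms <= lo < hi <= self.tmax_ms):
                raise ValueError(
                    f"planted window {self.planted_window_ms} outside epoch "
                    f"({self.tmin_ms}, {self.tmax_ms}) ms"
                )
            flo, fhi = self.planted_freqs_hz
            if not (0 < flo < fhi < self.sfreq / 2):
                raise ValueError("planted frequency band must sit below Nyquist")

    @property
    def n_trials_per_video(self) -> int:
        return self.presentations_per_run * self.n_runs


@dataclass(frozen=True)
class FaceSet:
    """Generated stimulus set plus the ground truth that was planted."""

    videos: tuple
    feature_map: FeatureMap
    triangle: FiducialTriangle
    interior_ids: tuple
    ground_truth: dict


def _template_landmarks(spec: FaceSetSpec, rng: np.random.Generator):
    """Neutral face template: fiducial nose triangle, interior cloud,
    exterior outline ring."""
    n = spec.n_landmarks
    ids = tuple(f"lm{k:03d}" for k in range(n))
    coords = np.empty((n, 2))
    # fixed non-collinear nose triangle near the face center
    coords[0] = (0.0, -6.0)
    coords[1] = (-7.0, 9.0)
    coords[2] = (7.0, 9.0)
    n_int = spec.n_interior
    angles = rng.uniform(0, 2 * np.pi, n_int - 3)
    radii = np.sqrt(rng.uniform(0.05, 1.0, n_int - 3))
    coords[3:n_int, 0] = 55.0 * radii * np.cos(angles)
    coords[3:n_int, 1] = 75.0 * radii * np.sin(angles)
    n_ext = n - n_int
    if n_ext:
        theta = np.linspace(0, 2 * np.pi, n_ext, endpoint=False)
        coords[n_int:, 0] = 85.0 * np.cos(theta) + rng.normal(0, 2.0, n_ext)
        coords[n_int:, 1] = 110.0 * np.sin(theta) + rng.normal(0, 2.0, n_ext)
    return ids, coords


def _feature_partition(spec: FaceSetSpec, ids: tuple) -> FeatureMap:
    """Partition the non-fiducial interior landmarks into feature groups."""
    members = list(ids[3 : spec.n_interior])
    groups = np.array_split(np.array(members, dtype=object), spec.n_features)
    names = (
        FEATURE_NAMES
        if spec.n_features == len(FEATURE_NAMES)
        else tuple(f"feature{k:02d}" for k in range(spec.n_features))
    )
    return FeatureMap({name: tuple(g) for name, g in zip(names, groups)})


def generate_face_set(spec: FaceSetSpec) -> FaceSet:
    """Simulate n_identities x n_expressions landmark videos.

    Frame 1 is a shared template plus an identity-specific offset (scaled by
    ``identity_form_scale``) plus landmark noise. Later frames add smooth
    feature-localized expression trajectories (scaled by
    ``expression_motion_scale``) composed with global rigid head motion of
    ``rigid_motion_amplitude``. Both the rigid motion and the trajectory
    envelope are zero at frame 1.
    """
    rng = np.random.default_rng(spec.seed)
    ids, template = _template_landmarks(spec, rng)
    fmap = _feature_partition(spec, ids)
    triangle = FiducialTriangle(ids[:3])
    interior_ids = ids[: spec.n_interior]
    lut = {m: k for k, m in enumerate(ids)}

    identity_names = tuple(f"id{k + 1}" for k in range(spec.n_identities))
    expression_names = (
        EXPRESSION_NAMES
        if spec.n_expressions == len(EXPRESSION_NAMES)
        else tuple(f"expr{k + 1}" for k in range(spec.n_expressions))
    )

    identity_offsets = {
        name: rng.normal(0.0, 1.0, (spec.n_landmarks, 2)) * spec.identity_form_scale
        for name in identity_names
    }

    feature_names = fmap.feature_names
    expression_defs = {}
    for name in expression_names:
        # each expression moves a subset of features, each with its own
        # amplitude and onset so flow-magnitude profiles discriminate
        # expressions even where active features overlap
        n_active = max(1, min(spec.n_features, round(0.4 * spec.n_features)))
        active = rng.choice(spec.n_features, size=n_active, replace=False)
        dirs, amps, onsets = {}, {}, {}
        for fi in active:
            fname = feature_names[fi]
            base = rng.normal(0.0, 1.0, 2)
            base /= np.linalg.norm(base)
            jitter = rng.normal(0.0, 0.25, (len(fmap.features[fname]), 2))
            dirs[fname] = base[None, :] + jitter
            amps[fname] = float(rng.uniform(0.4, 1.6))
            onsets[fname] = float(rng.uniform(0.0, 0.35))
        expression_defs[name] = {
            "directions": dirs,
            "amplitudes": amps,
            "onsets": onsets,
            "apex_frac": float(rng.uniform(0.5, 0.85)),
        }

    frames_axis = np.arange(spec.n_frames)
    videos = []
    rigid_truth = {}
    for identity in identity_names:
        for expression in expression_names:
            sid = f"{identity}_{expression}"
            neutral = template + identity_offsets[identity]
            # per-frame landmark tracking jitter: gives flow a noise floor so
            # expression_motion_scale behaves as a signal-to-noise knob.
            # Fiducials stay noise-free: jitter on the reference triangle is
            # amplified by affine extrapolation at distant landmarks and would
            # dominate every other motion source.
            jitter = rng.normal(
                0.0, spec.landmark_noise_sd, (spec.n_frames, spec.n_landmarks, 2)
            )
            jitter[:, :3, :] = 0.0
            edef = expression_defs[expression]
            apex = np.clip(
                edef["apex_frac"] * (1.0 + 0.15 * rng.normal()), 0.3, 0.95
            )
            t_norm = frames_axis / (spec.n_frames - 1)

            nonrigid = np.zeros((spec.n_frames, spec.n_landmarks, 2))
            for fname, dirs in edef["directions"].items():
                onset = edef["onsets"][fname] * apex
                progress = np.clip(
                    (t_norm - onset) / max(apex - onset, 0.05), 0.0, 1.0
                )
                env = 0.5 * (1.0 - np.cos(np.pi * progress))  # 0 at frame 1
                idx = [lut[m] for m in fmap.features[fname]]
                nonrigid[:, idx, :] = (
                    spec.expression_motion_scale
                    * edef["amplitudes"][fname]
                    * env[:, None, None]
                    * dirs[None]
                )

            # global rigid motion, zero at frame 1
            cyc = rng.uniform(0.5, 1.5, 3)
            phase_axis = 2 * np.pi * frames_axis / (spec.n_frames - 1)
            theta = 0.01 * spec.rigid_motion_amplitude * np.sin(cyc[0] * phase_axis)
            trans = spec.rigid_motion_amplitude * np.stack(
                [np.sin(cyc[1] * phase_axis), np.sin(cyc[2] * phase_axis)], axis=1
            )
            cos_t, sin_t = np.cos(theta), np.sin(theta)
            rot = np.stack(
                [np.stack([cos_t, -sin_t], -1), np.stack([sin_t, cos_t], -1)], -2
            )  # (F, 2, 2)
            shaped = neutral[None] + nonrigid + jitter
            coords = np.einsum("fij,flj->fli", rot, shaped) + trans[:, None, :]

            rigid_truth[sid] = {"theta": theta, "translation": trans, "apex_frac": apex}
            videos.append(
                LandmarkVideo(
                    coords=coords,
                    landmark_ids=ids,
                    frame_rate=spec.frame_rate,
                    stimulus_id=sid,
                    identity=identity,
                    expression=expression,
                )
            )

    ground_truth = {
        "template": template,
        "identity_offsets": identity_offsets,
        "expression_defs": expression_defs,
        "rigid": rigid_truth,
    }
    return FaceSet(
        videos=tuple(videos),
        feature_map=fmap,
        triangle=triangle,
        interior_ids=interior_ids,
        ground_truth=ground_truth,
    )


def generate_judgments(faceset: FaceSet, spec: JudgmentSimSpec) -> pd.DataFrame:
    """Per-participant pairwise similarity ratings for form and motion tasks.

    Each rating is a weighted combination of the physical form and motion
    similarities (rescaled from [-1, 1] to [0, 1]) plus Gaussian noise,
    clipped to the rating scale. All S(S-1)/2 pairs appear once per
    participant and task.
    """
    videos = faceset.videos
    form = build_form_similarity_matrix(videos)
    motion = build_motion_similarity_matrix(
        videos, faceset.feature_map, faceset.triangle, faceset.interior_ids
    )
    form01 = (form.cells() + 1.0) / 2.0
    motion01 = (motion.cells() + 1.0) / 2.0
    s = len(videos)
    i_idx, j_idx = np.tril_indices(s, k=-1)
    ids = form.stimulus_ids

    rng = np.random.default_rng(spec.seed)
    rows = []
    tasks = {"form": spec.form_task_weights, "motion": spec.motion_task_weights}
    for p in range(spec.n_participants):
        for task, (w_form, w_motion) in tasks.items():
            base = w_form * form01 + w_motion * motion01
            rating = np.clip(
                base + rng.normal(0.0, spec.noise_sd, base.size), 0.0, 1.0
            )
            for k in range(base.size):
                rows.append(
                    {
                        "participant": f"p{p + 1:02d}",
                        "stim_a": ids[i_idx[k]],
                        "stim_b": ids[j_idx[k]],
                        "rating": rating[k],
                        "task": task,
                    }
                )
    return pd.DataFrame(rows)


def session_schedule(
    stimulus_ids: Sequence,
    presentations_per_run: int = 8,
    n_runs: int = 4,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Trial schedule: every video ``presentations_per_run`` times per run.

    With the defaults and 36 videos this yields 8 x 4 x 36 = 1152 trials and
    32 presentations of each video. Order within a run is shuffled when an
    ``rng`` is supplied.
    """
    ids = list(stimulus_ids)
    rows = []
    for run in range(n_runs):
        run_ids = np.array(ids * presentations_per_run, dtype=object)
        if rng is not None:
            rng.shuffle(run_ids)
        for k, sid in enumerate(run_ids):
            rows.append({"run": run + 1, "trial_in_run": k + 1, "stimulus_id": sid})
    return pd.DataFrame(rows)


def planted_patterns(
    model: SimilarityMatrix, n_channels: int, rng: np.random.Generator
) -> np.ndarray:
    """Channel patterns (S, C) whose Gram structure follows the model matrix.

    Rows of the symmetric square root of the (PSD-projected) model matrix
    mix a random channel basis, so expected pattern correlations reproduce
    the model's off-diagonal cells.
    """
    m = (model.values + model.values.T) / 2.0
    w, v = np.linalg.eigh(m)
    x = v * np.sqrt(np.clip(w, 0.0, None))
    basis = rng.normal(0.0, 1.0, (m.shape[0], n_channels)) / np.sqrt(n_channels)
    patterns = x @ basis
    return patterns / patterns.std()


def _trial_phases(
    schedule: pd.DataFrame,
    stimulus_ids: Sequence,
    n_freqs: int,
    component: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Oscillation phases per (trial, planted frequency).

    Induced responses use random phases assigned in antiphase pairs within
    each stimulus, so phase-locked content cancels exactly in evoked
    averages of an even trial count. Evoked responses are phase-locked (all
    zero phase).
    """
    n_trials = len(schedule)
    if component == "evoked":
        return np.zeros((n_trials, n_freqs))
    phases = np.empty((n_trials, n_freqs))
    labels = schedule["stimulus_id"].to_numpy()
    for sid in stimulus_ids:
        idx = np.flatnonzero(labels == sid)
        base = rng.uniform(0.0, 2 * np.pi, ((len(idx) + 1) // 2, n_freqs))
        paired = np.empty((len(idx), n_freqs))
        paired[0::2] = base[: (len(idx) + 1) // 2]
        paired[1::2] = base[: len(idx) // 2] + np.pi
        phases[idx] = paired
    return phases


def generate_epochs(
    stimulus_ids: Sequence,
    spec: MegSimSpec,
    participant: int,
) -> EpochSet:
    """Simulate one participant's epoched sensor data.

    The planted model's geometry is embedded as band-limited oscillations
    whose per-channel amplitude is sqrt(1 + m * pattern), so oscillatory
    *power* varies linearly with the planted channel patterns; the
    modulation depth m grows with ``effect_size``. Sensor noise is additive
    white Gaussian. Each participant gets an independent random channel
    basis and trial order, all derived from (seed, participant).
    """
    ids = tuple(stimulus_ids)
    if spec.planted_model is not None and spec.planted_model.stimulus_ids != ids:
        raise ValueError("planted model is defined on a different stimulus set")
    rng = np.random.default_rng([spec.seed, 104729, participant])

    n_samples = int(round((spec.tmax_ms - spec.tmin_ms) / 1000.0 * spec.sfreq)) + 1
    times = spec.tmin_ms + np.arange(n_samples) * 1000.0 / spec.sfreq
    schedule = session_schedule(
        ids, spec.presentations_per_run, spec.n_runs, rng=rng
    )
    n_trials = len(schedule)
    data = rng.normal(0.0, spec.noise_sd, (n_trials, spec.n_channels, n_samples))

    if spec.planted_model is not None:
        patterns = planted_patterns(spec.planted_model, spec.n_channels, rng)
        depth = 0.5 * spec.effect_size / (1.0 + spec.effect_size)
        amp = np.sqrt(np.clip(1.0 + depth * patterns, 0.02, None))  # (S, C)

        lo, hi = spec.planted_window_ms
        env = np.zeros(n_samples)
        inside = (times >= lo) & (times <= hi)
        env[inside] = 0.5 * (1.0 - np.cos(2 * np.pi * (times[inside] - lo) / (hi - lo)))

        flo, fhi = spec.planted_freqs_hz
        k = np.arange(spec.n_planted_freqs)
        freqs = flo + (k + 0.5) * (fhi - flo) / spec.n_planted_freqs
        phases = _trial_phases(schedule, ids, freqs.size, spec.component, rng)

        t_sec = times / 1000.0
        stim_index = {sid: s for s, sid in enumerate(ids)}
        trial_stim = schedule["stimulus_id"].map(stim_index).to_numpy()
        # (trials, time): sum of planted oscillations with per-trial phases
        osc = np.sin(
            2 * np.pi * freqs[None, :, None] * t_sec[None, None, :]
            + phases[:, :, None]
        ).sum(axis=1) / np.sqrt(freqs.size)
        waveform = spec.signal_amplitude * env[None, :] * osc  # (trials, time)
        data += amp[trial_stim][:, :, None] * waveform[:, None, :]

    ch_names = tuple(f"MEG{k:03d}" for k in range(spec.n_channels))
    ch_types = tuple("axial" if k % 2 == 0 else "planar" for k in range(spec.n_channels))
    return EpochSet(
        data=data,
        sfreq=spec.sfreq,
        times=times,
        trial_stimulus_ids=tuple(schedule["stimulus_id"]),
        ch_names=ch_names,
        ch_types=ch_types,
    )


def generate_all_epochs(
    stimulus_ids: Sequence, spec: MegSimSpec
) -> Iterator[tuple[int, EpochSet]]:
    """Yield (participant index, EpochSet) for every simulated participant."""
    for p in range(spec.n_participants):
        yield p, generate_epochs(stimulus_ids, spec, p)
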