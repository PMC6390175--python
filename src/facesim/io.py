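"""Plain-text and array-container readers/writers for every artifact.

Landmark videos, feature maps, similarity matrices and judgment tables are
tab-separated text. Epoch sets are a portable ``.npy`` array plus a JSON
metadata sidecar; an import adapter for vendor formats can be plugged in by
constructing :class:`~facesim.meg.EpochSet` directly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .landmarks import LandmarkVideo
from .meg import EpochSet
from .motion import FeatureMap, FiducialTriangle
from .similarity import SimilarityMatrix

__all__ = [
    "write_landmark_video",
    "read_landmark_video",
    "write_video_set",
    "read_video_set",
    "write_feature_map",
    "read_feature_map",
    "write_fiducials",
    "read_fiducials",
    "write_similarity_matrix",
    "read_similarity_matrix",
    "write_judgments",
    "read_judgments",
    "save_epochs",
    "load_epochs",
]


def write_landmark_video(path, video: LandmarkVideo) -> None:
    """One row per (frame, landmark): frame, landmark_id, x, y. Frames are
    1-based in the file."""
    f, l = video.n_frames, video.n_landmarks
    frame_col = np.repeat(np.arange(1, f + 1), l)
    lm_col = np.tile(np.array(video.landmark_ids, dtype=object), f)
    flat = video.coords.reshape(f * l, 2)
    pd.DataFrame(
        {"frame": frame_col, "landmark_id": lm_col, "x": flat[:, 0], "y": flat[:, 1]}
    ).to_csv(path, sep="\t", index=False)


def read_landmark_video(
    path,
    frame_rate: float,
    stimulus_id: str,
    identity: str = "",
    expression: str = "",
) -> LandmarkVideo:
    table = pd.read_csv(path, sep="\t")
    frames = sorted(table["frame"].unique())
    first = table[table["frame"] == frames[0]]
    ids = tuple(first["landmark_id"])
    coords = np.empty((len(frames), len(ids), 2))
    for k, fr in enumerate(frames):
        sub = table[table["frame"] == fr]
        if tuple(sub["landmark_id"]) != ids:
            raise ValueError(f"{path}: landmark order differs at frame {fr}")
        coords[k, :, 0] = sub["x"].to_numpy()
        coords[k, :, 1] = sub["y"].to_numpy()
    return LandmarkVideo(
        coords=coords,
        landmark_ids=ids,
        frame_rate=frame_rate,
        stimulus_id=stimulus_id,
        identity=identity,
        expression=expression,
    )


def write_video_set(directory, videos: Sequence[LandmarkVideo]) -> None:
    """One TSV per stimulus plus a ``stimuli.tsv`` sidecar with labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in videos:
        fname = f"{v.stimulus_id}.tsv"
        write_landmark_video(directory / fname, v)
        rows.append(
            {
                "stimulus_id": v.stimulus_id,
                "identity": v.identity,
                "expression": v.expression,
                "frame_rate": v.frame_rate,
                "file": fname,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "stimuli.tsv", sep="\t", index=False)


def read_video_set(directory) -> tuple[LandmarkVideo, ...]:
    directory = Path(directory)
    table = pd.read_csv(directory / "stimuli.tsv", sep="\t", keep_default_na=False)
    videos = []
    for _, row in table.iterrows():
        videos.append(
            read_landmark_video(
                directory / row["file"],
                frame_rate=float(row["frame_rate"]),
                stimulus_id=str(row["stimulus_id"]),
                identity=str(row["identity"]),
                expression=str(row["expression"]),
            )
        )
    return tuple(videos)


def write_feature_map(path, fmap: FeatureMap) -> None:
    rows = [
        {"feature": name, "landmark_id": m}
        for name, members in fmap.features.items()
        for m in members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_feature_map(path) -> FeatureMap:
    table = pd.read_csv(path, sep="\t")
    features: dict = {}
    for _, row in table.iterrows():
        features.setdefault(str(row["feature"]), []).append(str(row["landmark_id"]))
    return FeatureMap({k: tuple(v) for k, v in features.items()})


def write_fiducials(path, triangle: FiducialTriangle) -> None:
    pd.DataFrame({"landmark_id": list(triangle.landmark_ids)}).to_csv(
        path, sep="\t", index=False
    )


def read_fiducials(path) -> FiducialTriangle:
    table = pd.read_csv(path, sep="\t")
    return FiducialTriangle(tuple(str(x) for x in table["landmark_id"]))


def write_similarity_matrix(path, matrix: SimilarityMatrix) -> None:
    """Square TSV, first row and column hold stimulus ids; labels and kind
    ride along in a JSON sidecar next to the matrix."""
    path = Path(path)
    frame = pd.DataFrame(
        matrix.values, index=matrix.stimulus_ids, columns=matrix.stimulus_ids
    )
    frame.to_csv(path, sep="\t", index_label="stimulus_id")
    meta = {
        "kind": matrix.kind,
        "identities": list(matrix.identities),
        "expressions": list(matrix.expressions),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_similarity_matrix(path) -> SimilarityMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    values = frame.to_numpy(dtype=float)
    # symmetrize away text round-trip noise
    values = (values + values.T) / 2.0
    return SimilarityMatrix(
        values=values,
        stimulus_ids=tuple(str(c) for c in frame.columns),
        identities=tuple(meta.get("identities", ())),
        expressions=tuple(meta.get("expressions", ())),
        kind=meta.get("kind", "physical"),
    )


def write_judgments(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_judgments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_epochs(directory, epochs: EpochSet) -> None:
    """Numeric array container (``data.npy``) + JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "data.npy", epochs.data)
    meta = {
        "sfreq": epochs.sfreq,
        "times_ms": epochs.times.tolist(),
        "trial_stimulus_ids": list(epochs.trial_stimulus_ids),
        "ch_names": list(epochs.ch_names),
        "ch_types": list(epochs.ch_types),
    }
    (directory / "meta.json").write_text(json.dumps(meta))


def load_epochs(directory) -> EpochSet:
    directory = Path(directory)
    data = np.load(directory / "data.npy")
    meta = json.loads((directory / "meta.json").read_text())
    return EpochSet(
        data=data,
        sfreq=float(meta["sfreq"]),
        times=np.asarray(meta["times_ms"], dtype=float),
        trial_stimulus_ids=tuple(meta["trial_stimulus_ids"]),
        ch_names=tuple(meta["ch_names"]),
        ch_types=tuple(meta["ch_types"]),
    )
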