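"""End-to-end orchestration: simulate -> physical measures -> behavioral RSA
-> sensor RSA -> report, with config handling and deterministic outputs."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .landmarks import build_form_similarity_matrix
from .meg import (
    EpochSet,
    evoked_average,
    log_ratio_baseline,
    morlet_power,
    reject_artifacts,
    select_responsive_channels,
)
from .motion import build_motion_similarity_matrix
from .rsa import (
    PermutationScheme,
    RsaStatMap,
    make_evoked_smoother,
    make_tf_smoother,
    pattern_cells_over_tf,
    pattern_cells_over_time,
    rsa_scan,
    spearman_rsa,
)
from .similarity import SimilarityMatrix, category_model_matrix, judgment_matrix
from .simulate import (
    FaceSet,
    FaceSetSpec,
    JudgmentSimSpec,
    MegSimSpec,
    generate_epochs,
    generate_face_set,
    generate_judgments,
)

__all__ = [
    "default_config",
    "load_config",
    "config_manifest",
    "run_simulation",
    "run_physical",
    "build_test_matrices",
    "run_behavioral_rsa",
    "compute_evoked_cells",
    "compute_tf_cells",
    "run_meg_rsa",
    "write_stat_map_table",
    "PLANNED_COMPARISONS",
]

log = logging.getLogger("facesim")

# the planned comparisons among the six test matrices
PLANNED_COMPARISONS = (
    ("form_judgment", "motion_judgment"),
    ("identity", "form_judgment"),
    ("identity", "motion_judgment"),
    ("expression", "form_judgment"),
    ("expression", "motion_judgment"),
    ("identity", "configural_form"),
    ("identity", "motion_pattern"),
    ("expression", "configural_form"),
    ("expression", "motion_pattern"),
    ("configural_form", "form_judgment"),
    ("configural_form", "motion_judgment"),
    ("motion_pattern", "form_judgment"),
    ("motion_pattern", "motion_judgment"),
)


def default_config() -> dict:
    """Every tunable parameter with its default, echoed into run manifests."""
    return {
        "seed": 0,
        "faces": {
            "n_identities": 6,
            "n_expressions": 6,
            "n_landmarks": 179,
            "n_interior": 141,
            "n_features": 12,
            "n_frames": 56,
            "frame_rate": 28.0,
            "identity_form_scale": 3.0,
            "expression_motion_scale": 4.0,
            "rigid_motion_amplitude": 2.0,
            "landmark_noise_sd": 0.1,
        },
        "judgments": {
            "form_task_weights": [1.0, 0.0],
            "motion_task_weights": [0.0, 1.0],
            "noise_sd": 0.05,
            "n_participants": 16,
        },
        "meg": {
            "n_participants": 16,
            "n_channels": 64,
            "presentations_per_run": 8,
            "n_runs": 4,
            "sfreq": 100.0,
            "tmin_ms": -500.0,
            "tmax_ms": 2500.0,
            "planted_model": "identity",
            "planted_window_ms": [600.0, 1500.0],
            "planted_freqs_hz": [4.0, 20.0],
            "effect_size": 1.0,
            "signal_amplitude": 2.0,
            "noise_sd": 1.0,
            "component": "induced",
        },
        "analysis": {
            "freq_lo": 4.0,
            "freq_hi": 50.0,
            "freq_step": 2.0,
            "evoked_baseline_ms": [-500.0, 0.0],
            "tf_baseline_ms": [-350.0, -100.0],
            "tf_time_window_ms": [0.0, 2000.0],
            "wavelet_factor": 7.0,
            "axial_limit": 2000.0,
            "planar_limit": 50.0,
            "select_channels": False,
            "channel_alpha": 1.0e-4,
            "butter_cutoff_hz": 10.0,
            "butter_order": 5,
            "gauss_fwhm_freq_hz": 4.0,
            "gauss_fwhm_time_ms": 20.0,
            "n_permutations": 10000,
            "alpha": 0.05,
            "tfce_extent_power": 0.5,
            "tfce_height_power": 2.0,
        },
    }


def _deep_update(base: dict, override: dict) -> dict:
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and a dict."""
    config = default_config()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        _deep_update(config, loaded)
    if overrides:
        _deep_update(config, overrides)
    return config


def config_manifest(config: dict) -> dict:
    """Run manifest: canonical config hash plus library versions."""
    canonical = json.dumps(config, sort_keys=True)
    import scipy

    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": config,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
    }


def _timed(stage: str, start: float, **shapes) -> None:
    extra = " ".join(f"{k}={v}" for k, v in shapes.items())
    log.info("%s done in %.2fs %s", stage, time.perf_counter() - start, extra)


# ---------------------------------------------------------------------------
# stages


def run_simulation(config: dict, outdir) -> FaceSet:
    """Generate and write the full synthetic input set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    t0 = time.perf_counter()

    fspec = FaceSetSpec(seed=seed, **config["faces"])
    faceset = generate_face_set(fspec)
    fio.write_video_set(outdir / "videos", faceset.videos)
    fio.write_feature_map(outdir / "feature_map.tsv", faceset.feature_map)
    fio.write_fiducials(outdir / "fiducials.tsv", faceset.triangle)

    jcfg = dict(config["judgments"])
    jspec = JudgmentSimSpec(
        form_task_weights=tuple(jcfg.pop("form_task_weights")),
        motion_task_weights=tuple(jcfg.pop("motion_task_weights")),
        seed=seed + 1,
        **jcfg,
    )
    fio.write_judgments(outdir / "judgments.tsv", generate_judgments(faceset, jspec))

    mspec = _meg_spec(config, faceset)
    ids = tuple(v.stimulus_id for v in faceset.videos)
    for p in range(mspec.n_participants):
        fio.save_epochs(outdir / "epochs" / f"participant{p + 1:02d}",
                        generate_epochs(ids, mspec, p))
    (outdir / "run_meta.json").write_text(json.dumps(config_manifest(config), indent=1))
    _timed("simulate", t0, videos=len(faceset.videos), participants=mspec.n_participants)
    return faceset


def _meg_spec(config: dict, faceset: FaceSet) -> MegSimSpec:
    mcfg = dict(config["meg"])
    model_name = mcfg.pop("planted_model")
    model = None
    if model_name:
        ids = tuple(v.stimulus_id for v in faceset.videos)
        labels = {
            "identity": tuple(v.identity for v in faceset.videos),
            "expression": tuple(v.expression for v in faceset.videos),
        }[model_name]
        model = category_model_matrix(ids, labels)
    return MegSimSpec(
        planted_model=model,
        planted_window_ms=tuple(mcfg.pop("planted_window_ms")),
        planted_freqs_hz=tuple(mcfg.pop("planted_freqs_hz")),
        seed=int(config["seed"]) + 2,
        **mcfg,
    )


def run_physical(videos_dir, outdir) -> dict:
    """Configural-form and motion-pattern similarity matrices from disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    videos = fio.read_video_set(videos_dir)
    fmap = fio.read_feature_map(Path(videos_dir).parent / "feature_map.tsv")
    triangle = fio.read_fiducials(Path(videos_dir).parent / "fiducials.tsv")
    form = build_form_similarity_matrix(videos)
    motion = build_motion_similarity_matrix(videos, fmap, triangle)
    fio.write_similarity_matrix(outdir / "configural_form.tsv", form)
    fio.write_similarity_matrix(outdir / "motion_pattern.tsv", motion)
    _timed("physical", t0, stimuli=len(videos))
    return {"configural_form": form, "motion_pattern": motion}


def build_test_matrices(faceset: FaceSet, judgments: pd.DataFrame) -> dict:
    """The six test matrices: two categorical, two physical, two perceptual."""
    videos = faceset.videos
    ids = tuple(v.stimulus_id for v in videos)
    identities = tuple(v.identity for v in videos)
    expressions = tuple(v.expression for v in videos)
    matrices = {
        "identity": category_model_matrix(ids, identities, identities, expressions),
        "expression": category_model_matrix(ids, expressions, identities, expressions),
        "configural_form": build_form_similarity_matrix(videos),
        "motion_pattern": build_motion_similarity_matrix(
            videos, faceset.feature_map, faceset.triangle, faceset.interior_ids
        ),
    }
    for task, name in (("form", "form_judgment"), ("motion", "motion_judgment")):
        matrices[name] = judgment_matrix(
            judgments[judgments["task"] == task], ids
        )
    return matrices


def _label_permutation_p(
    a: SimilarityMatrix, b: SimilarityMatrix, rho_obs: float,
    n_permutations: int, rng: np.random.Generator,
) -> float:
    """Right-sided stimulus-label permutation p for a matrix correlation."""
    cells_a = a.cells()
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(b.n_stimuli)
        permuted = SimilarityMatrix(
            values=b.values[np.ix_(perm, perm)],
            stimulus_ids=b.stimulus_ids,
            kind=b.kind,
        )
        if spearman_rsa(cells_a, permuted.cells()) >= rho_obs:
            count += 1
    return (1.0 + count) / (1.0 + n_permutations)


def run_behavioral_rsa(
    matrices: dict,
    n_permutations: int = 1000,
    seed: int = 0,
    bonferroni_alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlations among the six test matrices.

    One row per planned comparison with rho, a right-sided stimulus-label
    permutation p, and a Bonferroni-adjusted significance flag over the
    planned comparisons.
    """
    missing = {n for pair in PLANNED_COMPARISONS for n in pair} - set(matrices)
    if missing:
        raise ValueError(f"missing test matrices: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    critical = bonferroni_alpha / len(PLANNED_COMPARISONS)
    rows = []
    for name_a, name_b in PLANNED_COMPARISONS:
        a, b = matrices[name_a], matrices[name_b]
        rho = spearman_rsa(a.cells(), b.cells())
        p = _label_permutation_p(a, b, rho, n_permutations, rng)
        rows.append(
            {
                "matrix_a": name_a,
                "matrix_b": name_b,
                "rho": rho,
                "p_permutation": p,
                "significant_bonferroni": p < critical,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensor-level RSA


def compute_evoked_cells(
    epoch_sets: Sequence[EpochSet],
    baseline: tuple = (-500.0, 0.0),
    axial_limit: float = 2000.0,
    planar_limit: float = 50.0,
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Per-participant evoked pattern-similarity cells, stacked (P, T, cells)."""
    all_cells, times, stim_ids = [], None, None
    for epochs in epoch_sets:
        cleaned, _ = reject_artifacts(epochs, axial_limit, planar_limit)
        evoked = evoked_average(cleaned, baseline=baseline)
        all_cells.append(pattern_cells_over_time(evoked))
        times, stim_ids = evoked.times, evoked.stimulus_ids
    return np.stack(all_cells), times, stim_ids


def compute_tf_cells(
    epoch_sets: Sequence[EpochSet],
    freqs: Sequence[float],
    wavelet_factor: float = 7.0,
    tf_baseline: tuple = (-350.0, -100.0),
    time_window: tuple = (0.0, 2000.0),
    axial_limit: float = 2000.0,
    planar_limit: float = 50.0,
    select_channels: bool = False,
    channel_alpha: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple]:
    """Per-participant time-frequency pattern cells, stacked (P, F, T, cells).

    When ``select_channels`` is on, occipitotemporal-style responsive-channel
    selection runs across participants on stimulus-averaged baseline-corrected
    power before the pattern stage.
    """
    powers = []
    for epochs in epoch_sets:
        cleaned, _ = reject_artifacts(epochs, axial_limit, planar_limit)
        power = morlet_power(cleaned, freqs, n_cycles=wavelet_factor)
        powers.append(log_ratio_baseline(power, baseline=tf_baseline))
    mask = None
    if select_channels:
        stacked = np.stack([p.data.mean(axis=0) for p in powers])  # (P, C, F, T)
        mask = select_responsive_channels(stacked, powers[0].times, alpha=channel_alpha)
        if not mask.any():
            raise ValueError("no responsive channels at the selection threshold")
    # crop the requested window to the region free of wavelet edge effects at
    # every frequency scanned
    ref = powers[0]
    valid_cols = ref.edge_valid.all(axis=0)
    usable = ref.times[valid_cols]
    if usable.size == 0:
        raise ValueError("epoch too short: no edge-free samples at the lowest frequency")
    lo = max(time_window[0], usable[0])
    hi = min(time_window[1], usable[-1])
    if lo >= hi:
        raise ValueError(
            f"requested window {time_window} ms has no edge-free samples "
            f"(valid span {usable[0]}..{usable[-1]} ms)"
        )
    time_window = (lo, hi)
    all_cells = []
    out_freqs = out_times = stim_ids = None
    for power in powers:
        cells, out_freqs, out_times = pattern_cells_over_tf(
            power, channel_mask=mask, time_window=time_window
        )
        all_cells.append(cells)
        stim_ids = power.stimulus_ids
    return np.stack(all_cells), out_freqs, out_times, stim_ids


def run_meg_rsa(
    epoch_loader: Callable[[int], EpochSet],
    n_participants: int,
    models: dict,
    analysis: str,
    config: dict,
    controls: dict | None = None,
    outdir=None,
) -> dict:
    """Sensor-level RSA scans for each model matrix.

    ``epoch_loader(p)`` returns participant p's EpochSet (lazy so large sets
    never coexist in memory before reduction). ``controls`` maps a model name
    to the list of model names to partial out. Returns
    ``{name: (RsaStatMap, coords)}`` where coords holds the map axes.
    """
    controls = controls or {}
    acfg = config["analysis"]
    scheme = PermutationScheme(
        n_permutations=int(acfg["n_permutations"]), seed=int(config["seed"])
    )
    epoch_sets = [epoch_loader(p) for p in range(n_participants)]
    t0 = time.perf_counter()

    if analysis == "evoked":
        cells, times, stim_ids = compute_evoked_cells(
            epoch_sets,
            baseline=tuple(acfg["evoked_baseline_ms"]),
            axial_limit=acfg["axial_limit"],
            planar_limit=acfg["planar_limit"],
        )
        sfreq = epoch_sets[0].sfreq
        smoother = make_evoked_smoother(
            sfreq, cutoff=acfg["butter_cutoff_hz"], order=acfg["butter_order"]
        )
        coords = {"time_ms": times}
    elif analysis == "tf":
        freqs = np.arange(
            acfg["freq_lo"], acfg["freq_hi"] + 1e-9, acfg["freq_step"]
        )
        cells, out_freqs, out_times, stim_ids = compute_tf_cells(
            epoch_sets,
            freqs,
            wavelet_factor=acfg["wavelet_factor"],
            tf_baseline=tuple(acfg["tf_baseline_ms"]),
            time_window=tuple(acfg["tf_time_window_ms"]),
            axial_limit=acfg["axial_limit"],
            planar_limit=acfg["planar_limit"],
            select_channels=acfg["select_channels"],
            channel_alpha=acfg["channel_alpha"],
        )
        time_step = 1000.0 / epoch_sets[0].sfreq
        smoother = make_tf_smoother(
            float(acfg["freq_step"]),
            time_step,
            fwhm_freq=acfg["gauss_fwhm_freq_hz"],
            fwhm_time_ms=acfg["gauss_fwhm_time_ms"],
        )
        coords = {"freq_hz": out_freqs, "time_ms": out_times}
    else:
        raise ValueError(f"unknown analysis {analysis!r}; expected 'evoked' or 'tf'")
    _timed(f"{analysis}-cells", t0, shape=cells.shape)

    models = {name: model.reorder(stim_ids) for name, model in models.items()}

    results = {}
    for name, model in models.items():
        t1 = time.perf_counter()
        control_mats = [models[c] for c in controls.get(name, ())]
        stat = rsa_scan(
            cells,
            model,
            controls=control_mats,
            smoother=smoother,
            scheme=scheme,
            alpha=float(acfg["alpha"]),
            extent_power=float(acfg["tfce_extent_power"]),
            height_power=float(acfg["tfce_height_power"]),
        )
        results[name] = (stat, coords)
        _timed(f"scan[{name}]", t1, significant=int(stat.mask.sum()))
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            write_stat_map_table(outdir / f"rsa_{analysis}_{name}.tsv", stat, coords)
            meta = config_manifest(config)
            meta["stat_params"] = stat.params
            (outdir / f"rsa_{analysis}_{name}.json").write_text(
                json.dumps(meta, indent=1)
            )
    return results


def write_stat_map_table(path, stat: RsaStatMap, coords: dict) -> None:
    """Delimited results table: coordinate, mean rho, z, t, TFCE, p, flag."""
    axes = list(coords.items())
    grids = np.meshgrid(*[v for _, v in axes], indexing="ij")
    table = {name: grid.ravel() for (name, _), grid in zip(axes, grids)}
    table["mean_rho"] = stat.rho.mean(axis=0).ravel()
    table["mean_z"] = stat.z_smoothed.mean(axis=0).ravel()
    table["t"] = stat.t.ravel()
    table["tfce"] = stat.tfce_map.ravel()
    table["p_corrected"] = stat.p.ravel()
    table["significant"] = stat.mask.ravel()
    pd.DataFrame(table).to_csv(path, sep="\t", index=False)
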