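"""Epoched multichannel responses: artifact rejection, evoked averages,
Morlet time-frequency power, log-ratio baseline, responsive-channel selection.

Epochs arrive already band-limited and downsampled (acquisition-side
preprocessing is out of scope); the time axis is milliseconds relative to
stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "EpochSet",
    "EvokedSet",
    "TFPower",
    "reject_artifacts",
    "evoked_average",
    "morlet_power",
    "log_ratio_baseline",
    "select_responsive_channels",
]

CHANNEL_TYPES = ("axial", "planar")


@dataclass(frozen=True)
class EpochSet:
    """Trials x channels x time with sampling and labelling metadata."""

    data: np.ndarray
    sfreq: float
    times: np.ndarray  # ms relative to stimulus onset
    trial_stimulus_ids: tuple
    ch_names: tuple
    ch_types: tuple

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"epoch data must be (trials, channels, time), got {data.shape}")
        n_trials, n_ch, n_times = data.shape
        if times.size != n_times:
            raise ValueError("time axis length does not match data")
        if times.size >= 2:
            steps = np.diff(times)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time axis must be uniform")
        trial_ids = tuple(self.trial_stimulus_ids)
        if len(trial_ids) != n_trials:
            raise ValueError("one stimulus id per trial required")
        ch_names = tuple(self.ch_names)
        ch_types = tuple(self.ch_types)
        if len(ch_names) != n_ch or len(ch_types) != n_ch:
            raise ValueError("channel names/types must match channel count")
        bad = set(ch_types) - set(CHANNEL_TYPES)
        if bad:
            raise ValueError(f"unknown channel types {sorted(bad)}; expected {CHANNEL_TYPES}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "trial_stimulus_ids", trial_ids)
        object.__setattr__(self, "ch_names", ch_names)
        object.__setattr__(self, "ch_types", ch_types)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def stimulus_ids(self) -> tuple:
        """Unique stimulus ids in canonical (sorted) order.

        Sorted so per-stimulus reductions line up across participants no
        matter how each session's trial order was shuffled.
        """
        return tuple(sorted(set(self.trial_stimulus_ids)))


@dataclass(frozen=True)
class EvokedSet:
    """Per-stimulus trial-averaged, baseline-corrected responses (S, C, T)."""

    data: np.ndarray
    stimulus_ids: tuple
    ch_names: tuple
    times: np.ndarray
    sfreq: float
    baseline: tuple = (-500.0, 0.0)


@dataclass(frozen=True)
class TFPower:
    """Per-stimulus power, (S, C, F, T).

    ``edge_valid`` is (F, T): False where the wavelet support overlaps an
    epoch edge. ``log_ratio`` records whether the values are log-ratio
    baseline-corrected (raw power is nonnegative; corrected power is not).
    """

    data: np.ndarray
    stimulus_ids: tuple
    ch_names: tuple
    freqs: np.ndarray
    times: np.ndarray
    sfreq: float
    edge_valid: np.ndarray
    log_ratio: bool = False
    baseline: tuple | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"TF power must be (S, C, F, T), got {data.shape}")
        if not self.log_ratio and (data < 0).any():
            raise ValueError("raw power must be nonnegative")
        if not np.isfinite(data).all():
            raise ValueError("TF power contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "edge_valid", np.asarray(self.edge_valid, dtype=bool))
        object.__setattr__(self, "stimulus_ids", tuple(self.stimulus_ids))
        object.__setattr__(self, "ch_names", tuple(self.ch_names))


def reject_artifacts(
    epochs: EpochSet,
    axial_limit: float = 2000.0,
    planar_limit: float = 50.0,
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop trials whose absolute signal exceeds the channel-type limit.

    Default limits follow the 2000 fT (axial magnetometer) / 50 fT/mm
    (planar gradiometer) convention; pass limits in whatever units the data
    are in. Returns the cleaned epochs and a rejection log with one row per
    offending (trial, channel) giving the first offending sample.
    """
    if axial_limit <= 0 or planar_limit <= 0:
        raise ValueError("artifact limits must be positive")
    limits = np.array(
        [axial_limit if t == "axial" else planar_limit for t in epochs.ch_types]
    )
    over = np.abs(epochs.data) > limits[None, :, None]  # (trials, ch, time)
    rows = []
    bad_trials = np.flatnonzero(over.any(axis=(1, 2)))
    for tr in bad_trials:
        for ch in np.flatnonzero(over[tr].any(axis=1)):
            sample = int(np.flatnonzero(over[tr, ch])[0])
            rows.append(
                {
                    "trial": int(tr),
                    "stimulus_id": epochs.trial_stimulus_ids[tr],
                    "channel": epochs.ch_names[ch],
                    "sample": sample,
                    "time_ms": float(epochs.times[sample]),
                    "value": float(epochs.data[tr, ch, sample]),
                }
            )
    log = pd.DataFrame(
        rows, columns=["trial", "stimulus_id", "channel", "sample", "time_ms", "value"]
    )
    if len(bad_trials) == epochs.n_trials:
        raise ValueError("all trials rejected by artifact thresholds")
    keep = np.setdiff1d(np.arange(epochs.n_trials), bad_trials)
    cleaned = replace(
        epochs,
        data=epochs.data[keep],
        trial_stimulus_ids=tuple(epochs.trial_stimulus_ids[k] for k in keep),
    )
    return cleaned, log


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"window {window} ms contains no samples")
    return mask


def evoked_average(
    epochs: EpochSet, baseline: tuple[float, float] = (-500.0, 0.0)
) -> EvokedSet:
    """Baseline-correct each trial (per-channel mean over the baseline
    window) and average trials within stimulus."""
    mask = _window_mask(epochs.times, baseline)
    corrected = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    stim_ids = epochs.stimulus_ids
    out = np.empty((len(stim_ids), epochs.n_channels, epochs.times.size))
    labels = np.asarray(epochs.trial_stimulus_ids, dtype=object)
    for k, sid in enumerate(stim_ids):
        sel = labels == sid
        if not sel.any():
            raise ValueError(f"no surviving trials for stimulus {sid!r}")
        out[k] = corrected[sel].mean(axis=0)
    return EvokedSet(
        data=out,
        stimulus_ids=stim_ids,
        ch_names=epochs.ch_names,
        times=epochs.times.copy(),
        sfreq=epochs.sfreq,
        baseline=baseline,
    )


def _morlet_wavelet(freq: float, sfreq: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized, truncated at +/-2.5 sigma_t."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    n_half = int(np.ceil(2.5 * sigma_t * sfreq))
    t = np.arange(-n_half, n_half + 1) / sfreq
    wav = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return wav / np.linalg.norm(wav)


def morlet_power(
    epochs: EpochSet,
    freqs: Sequence[float],
    n_cycles: float = 7.0,
) -> TFPower:
    """Trial-averaged Morlet wavelet power per stimulus.

    ``n_cycles`` is the wavelet factor (cycles per wavelet; 7 by default).
    Power is the squared magnitude of the complex transform, averaged over
    trials within stimulus. Samples within half a wavelet support of either
    epoch edge are flagged invalid in ``edge_valid``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if n_cycles < 1:
        raise ValueError("wavelet factor must be >= 1")
    if (freqs <= 0).any():
        raise ValueError("frequencies must be positive")
    nyquist = epochs.sfreq / 2.0
    if (freqs >= nyquist).any():
        above = freqs[freqs >= nyquist]
        raise ValueError(f"frequencies {above.tolist()} at/above Nyquist ({nyquist} Hz)")

    n_times = epochs.times.size
    stim_ids = epochs.stimulus_ids
    labels = np.asarray(epochs.trial_stimulus_ids, dtype=object)
    out = np.zeros((len(stim_ids), epochs.n_channels, freqs.size, n_times))
    edge_valid = np.ones((freqs.size, n_times), dtype=bool)

    for fi, f in enumerate(freqs):
        wav = _morlet_wavelet(f, epochs.sfreq, n_cycles)
        n_half = (wav.size - 1) // 2
        if wav.size > n_times:
            raise ValueError(
                f"epoch too short for {f} Hz wavelet "
                f"({wav.size} samples needed, {n_times} available)"
            )
        edge_valid[fi, :n_half] = False
        if n_half > 0:
            edge_valid[fi, -n_half:] = False
        tf = signal.fftconvolve(
            epochs.data.astype(complex), wav[None, None, :], mode="same", axes=-1
        )
        power = np.abs(tf) ** 2  # (trials, ch, time)
        for k, sid in enumerate(stim_ids):
            out[k, :, fi, :] = power[labels == sid].mean(axis=0)

    return TFPower(
        data=out,
        stimulus_ids=stim_ids,
        ch_names=epochs.ch_names,
        freqs=freqs,
        times=epochs.times.copy(),
        sfreq=epochs.sfreq,
        edge_valid=edge_valid,
    )


def log_ratio_baseline(
    power: TFPower, baseline: tuple[float, float] = (-350.0, -100.0)
) -> TFPower:
    """Express power as the natural log of its ratio to mean baseline power.

    The baseline mean is taken per stimulus, channel and frequency over the
    given pre-stimulus window. A global multiplicative gain per channel and
    frequency therefore cancels exactly.
    """
    if power.log_ratio:
        raise ValueError("power is already log-ratio corrected")
    mask = _window_mask(power.times, baseline)
    base = power.data[:, :, :, mask].mean(axis=3, keepdims=True)
    if (base <= 0).any():
        raise ValueError("nonpositive baseline power: log-ratio undefined")
    return replace(
        power,
        data=np.log(power.data / base),
        log_ratio=True,
        baseline=baseline,
    )


def select_responsive_channels(
    power_obs: np.ndarray,
    times: np.ndarray,
    alpha: float = 1e-4,
) -> np.ndarray:
    """Boolean mask of channels responding above zero post-stimulus.

    ``power_obs`` is (n_observations, channels, freqs, times) of
    baseline-corrected power (observations are participants, or trials for a
    single participant). A channel is retained when a right-sided one-sample
    t-test exceeds threshold (p < ``alpha``, uncorrected) at any
    post-stimulus time/frequency bin.
    """
    power_obs = np.asarray(power_obs, dtype=float)
    if power_obs.ndim != 4:
        raise ValueError("power_obs must be (obs, channels, freqs, times)")
    if power_obs.shape[0] < 2:
        raise ValueError("need at least 2 observations per channel")
    times = np.asarray(times, dtype=float)
    post = times > 0
    if not post.any():
        raise ValueError("no post-stimulus samples")
    res = stats.ttest_1samp(
        power_obs[:, :, :, post], popmean=0.0, axis=0, alternative="greater"
    )
    pvals = np.nan_to_num(res.pvalue, nan=1.0)
    return (pvals < alpha).any(axis=(1, 2))
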