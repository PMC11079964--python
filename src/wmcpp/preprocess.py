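"""Preprocessing chain: rereference, downsample, epoch, baseline, smooth,
decision-time exclusion and an automated high-variance trial flag.

The chain mirrors the standard decision-ERP recipe: mastoid-average
rereference, anti-aliased downsampling from 1,000 to 250 Hz, epoching around
cue or response onsets, baseline correction (pre-cue window for cue-locked
data, post-response window for response-locked data), 30 ms Gaussian
smoothing in lieu of a low-pass filter, and removal of trials with decision
times below 200 or above 2,000 ms.  Visual artifact inspection is replaced by
a reproducible, condition-blind robust-variance flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage
import scipy.signal

from .containers import EpochSet, RawSession
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    ref_channels: list = field(default_factory=lambda: ["M1", "M2"])
    target_sfreq_hz: float = 250.0
    cue_window_ms: tuple = (-250.0, 1500.0)
    resp_window_ms: tuple = (-1500.0, 500.0)
    cue_baseline_ms: tuple = (-250.0, 0.0)
    resp_baseline_ms: tuple = (0.0, 250.0)
    smooth_sigma_ms: float = 30.0
    dt_bounds_ms: tuple = (200.0, 2000.0)
    variance_z_threshold: float = 3.5

    def validate(self) -> None:
        for win, base in (
            (self.cue_window_ms, self.cue_baseline_ms),
            (self.resp_window_ms, self.resp_baseline_ms),
        ):
            if not (win[0] <= base[0] <= base[1] <= win[1]):
                raise ConfigError(f"baseline {base} outside epoch window {win}")
        if not self.dt_bounds_ms[0] < self.dt_bounds_ms[1]:
            raise ConfigError("dt_bounds_ms low must be < high")


def rereference(session: RawSession, ref_channels: list[str]) -> RawSession:
    """Subtract the mean of the reference channels from every channel.

    Reference channels are retained (they become +/- half their difference
    for a two-channel reference)."""
    try:
        idx = [session.channel_index(c) for c in ref_channels]
    except DataError as exc:
        raise ConfigError(str(exc)) from exc
    ref = session.data[idx].mean(axis=0)
    return replace(session, data=session.data - ref[None, :], events=session.events.copy())


def downsample(session: RawSession, target_sfreq_hz: float) -> RawSession:
    """Zero-phase anti-alias low-pass (cutoff 0.4 x target rate) followed by
    decimation; event samples are remapped and decision times recomputed on
    the new grid (shift < one target-rate sample period)."""
    ratio = session.sfreq_hz / target_sfreq_hz
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ConfigError(
            f"source rate {session.sfreq_hz} is not an integer multiple of "
            f"target rate {target_sfreq_hz}"
        )
    if factor == 1:
        return replace(session, events=session.events.copy())
    cutoff_hz = 0.4 * target_sfreq_hz
    numtaps = 16 * factor * 2 + 1  # symmetric (zero-phase) FIR, delay 16*factor
    taps = scipy.signal.firwin(numtaps, cutoff_hz, fs=session.sfreq_hz)
    # polyphase evaluation of the centered (zero-phase) filter at the kept
    # samples only; reflect padding reproduces plain 'same' convolution edges
    delay = numtaps // 2
    n = session.n_samples
    padded = np.pad(session.data, ((0, 0), (delay, delay)), mode="symmetric")
    dec = scipy.signal.upfirdn(taps, padded, down=factor, axis=-1)
    start = (2 * delay) // factor
    n_out = -(-n // factor)  # ceil: samples 0, factor, 2*factor, ...
    data = np.ascontiguousarray(dec[:, start : start + n_out])
    events = session.events.copy()
    events["cue_sample"] = events["cue_sample"] // factor
    events["response_sample"] = events["response_sample"] // factor
    events["decision_time_ms"] = (
        (events["response_sample"] - events["cue_sample"]) / target_sfreq_hz * 1000.0
    )
    return replace(session, data=data, sfreq_hz=target_sfreq_hz, events=events)


def epoch(
    session: RawSession, alignment: str, window_ms: tuple[float, float]
) -> EpochSet:
    """Cut one epoch per event around the cue or response onset.

    Trials whose window falls outside the recording are dropped (count kept
    on the returned EpochSet and logged)."""
    if alignment not in ("cue", "response"):
        raise ConfigError(f"alignment must be 'cue' or 'response', got {alignment!r}")
    fs = session.sfreq_hz
    start_off = int(np.floor(window_ms[0] * fs / 1000.0))
    end_off = int(np.ceil(window_ms[1] * fs / 1000.0))
    if end_off - start_off + 1 < 2:
        raise ConfigError("epoch window must cover at least 2 samples")
    times_ms = np.arange(start_off, end_off + 1) / fs * 1000.0
    anchor_col = "cue_sample" if alignment == "cue" else "response_sample"
    anchors = session.events[anchor_col].to_numpy()
    keep = (anchors + start_off >= 0) & (anchors + end_off < session.n_samples)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info(
            "epoch(%s): dropped %d/%d trials at recording edges",
            alignment, n_dropped, len(keep),
        )
    if not keep.any():
        raise DataError("no trials survive epoching (all windows exceed recording)")
    anchors = anchors[keep]
    offsets = np.arange(start_off, end_off + 1)
    idx = anchors[:, None] + offsets[None, :]
    data = session.data[:, idx]            # (ch, trials, time)
    data = np.moveaxis(data, 0, 1).astype(np.float64)  # (trials, ch, time)
    return EpochSet(
        data=np.ascontiguousarray(data),
        sfreq_hz=fs,
        channel_labels=list(session.channel_labels),
        channel_positions=session.channel_positions,
        times_ms=times_ms,
        alignment=alignment,
        metadata=session.events.loc[keep].reset_index(drop=True),
        participant_id=session.participant_id,
        n_dropped=n_dropped,
    )


def baseline_correct(epochs: EpochSet, baseline_ms: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    mask = epochs.time_mask(baseline_ms)
    if not mask.any():
        raise ConfigError(f"baseline window {baseline_ms} outside epoch window")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base, metadata=epochs.metadata.copy())


def smooth_gaussian(data, sigma_ms: float, sfreq_hz: float):
    """Gaussian smoothing along the time (last) axis.

    Discrete Gaussian truncated at +/-4 sigma, renormalized to unit sum,
    reflect-padded boundaries.  A sigma shorter than one sample period is a
    no-op (with a warning).  Accepts an array or an EpochSet."""
    if sigma_ms <= 0:
        raise ConfigError("sigma_ms must be > 0")
    sigma_samples = sigma_ms * sfreq_hz / 1000.0
    if isinstance(data, EpochSet):
        return replace(
            data,
            data=smooth_gaussian(data.data, sigma_ms, sfreq_hz),
            metadata=data.metadata.copy(),
        )
    arr = np.asarray(data, dtype=float)
    if sigma_samples < 1.0:
        warnings.warn(
            f"smoothing sigma {sigma_ms} ms is below one sample period; identity",
            stacklevel=2,
        )
        return arr.copy()
    return scipy.ndimage.gaussian_filter1d(
        arr, sigma=sigma_samples, axis=-1, mode="reflect", truncate=4.0
    )


def exclude_by_decision_time(
    epochs: EpochSet, bounds_ms: tuple[float, float] = (200.0, 2000.0)
) -> tuple[EpochSet, dict]:
    """Remove trials with decision time strictly below/above the bounds
    (boundary values are kept).  Returns the retained epochs and a report."""
    dt = epochs.metadata["decision_time_ms"].to_numpy(dtype=float)
    low, high = bounds_ms
    below = dt < low
    above = dt > high
    keep = ~(below | above)
    report = {
        "n_total": int(len(dt)),
        "n_below": int(below.sum()),
        "n_above": int(above.sum()),
        "n_kept": int(keep.sum()),
        "bounds_ms": [float(low), float(high)],
    }
    return epochs.select(keep), report


def flag_high_variance_trials(
    epochs: EpochSet,
    z_threshold: float = 3.5,
    channels: list[str] | None = None,
) -> tuple[np.ndarray, dict]:
    """Condition-blind robust flag for trials with exceptional variance.

    The log broadband variance per trial (over the given channels, default
    all) is z-scored with median/MAD; trials with z > threshold are flagged.
    Returns (boolean flag mask, report).  Uses no trial metadata."""
    if epochs.n_trials < 8:
        raise DataError("need at least 8 trials to estimate a variance norm")
    if channels is None:
        sub = epochs.data
    else:
        idx = [epochs.channel_index(c) for c in channels]
        sub = epochs.data[:, idx, :]
    trial_var = sub.reshape(epochs.n_trials, -1).var(axis=1)
    logv = np.log(np.maximum(trial_var, np.finfo(float).tiny))
    med = np.median(logv)
    mad = np.median(np.abs(logv - med))
    if mad == 0:
        warnings.warn("MAD of trial variance is zero; no trials flagged", stacklevel=2)
        flags = np.zeros(epochs.n_trials, dtype=bool)
    else:
        z = (logv - med) / (1.4826 * mad)
        flags = z > z_threshold
    report = {
        "n_total": int(epochs.n_trials),
        "n_flagged": int(flags.sum()),
        "z_threshold": float(z_threshold),
    }
    return flags, report
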