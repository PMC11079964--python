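"""In-memory containers for continuous sessions and epoched data.

A :class:`RawSession` is one participant's continuous multichannel recording
(microvolts) plus its event table; an :class:`EpochSet` is the trials x
channels x time array cut around cue or response onsets, with the per-trial
metadata carried along.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

#: Columns every event/metadata table must carry.
EVENT_COLUMNS = [
    "trial_id",
    "cue_sample",
    "response_sample",
    "condition",
    "item_side",
    "response_hand",
    "decision_time_ms",
    "reproduction_error_deg",
]


def _check_events(events: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise DataError(f"event table missing columns: {missing}")


@dataclass
class RawSession:
    """Continuous recording for one participant.

    data : (n_channels, n_samples) float array, microvolts
    events : one row per trial, sorted by cue_sample
    """

    data: np.ndarray
    sfreq_hz: float
    channel_labels: list[str]
    channel_positions: np.ndarray
    events: pd.DataFrame
    participant_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 2:
            raise DataError("RawSession.data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise DataError("channel count does not match label count")
        _check_events(self.events)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise DataError(f"channel {label!r} not in session") from None

    def validate_events(self) -> None:
        """Check the structural invariants of the event table."""
        ev = self.events
        if not (ev["response_sample"] > ev["cue_sample"]).all():
            raise DataError("response_sample must exceed cue_sample for every trial")
        if not ev["cue_sample"].is_monotonic_increasing:
            raise DataError("events must be sorted by cue_sample")
        dt = (ev["response_sample"] - ev["cue_sample"]) / self.sfreq_hz * 1000.0
        if not np.allclose(dt, ev["decision_time_ms"], atol=1e-9):
            raise DataError("decision_time_ms inconsistent with event samples")


@dataclass
class EpochSet:
    """Trials x channels x time array around an alignment event.

    times_ms is the time axis relative to the anchor (cue or response onset);
    metadata has one row per retained trial, in epoch order.
    """

    data: np.ndarray
    sfreq_hz: float
    channel_labels: list[str]
    channel_positions: np.ndarray
    times_ms: np.ndarray
    alignment: str
    metadata: pd.DataFrame
    participant_id: str
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise DataError("EpochSet.data must be 3-D (trials x channels x time)")
        if self.data.shape[1] != len(self.channel_labels):
            raise DataError("channel count does not match label count")
        if self.data.shape[2] != self.times_ms.size:
            raise DataError("time axis length does not match data")
        if self.alignment not in ("cue", "response"):
            raise DataError(f"alignment must be 'cue' or 'response', got {self.alignment!r}")
        _check_events(self.metadata)
        if len(self.metadata) != self.data.shape[0]:
            raise DataError("metadata row count does not match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise DataError(f"channel {label!r} not in epochs") from None

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Pure trial selection by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            metadata=self.metadata.iloc[mask].reset_index(drop=True),
        )

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples with start <= t <= end (closed interval)."""
        lo, hi = window_ms
        return (self.times_ms >= lo - 1e-9) & (self.times_ms <= hi + 1e-9)
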