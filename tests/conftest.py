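"""Shared fixtures: small synthetic sessions and toy containers."""

import numpy as np
import pandas as pd
import pytest

from wmcpp.containers import RawSession, EpochSet
from wmcpp.montage import montage_positions
from wmcpp.synth import SimConfig, simulate_participant


def small_config(**overrides) -> SimConfig:
    """Fast simulation config: short padding, few trials."""
    defaults = dict(
        n_participants=3,
        n_trials=24,
        seed=5,
        start_pad_ms=1800.0,
        pre_cue_ms=400.0,
        post_response_ms=600.0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def noiseless_config(**overrides) -> SimConfig:
    # short decay so one trial's post-response tail cannot reach the next
    # trial's samples under the compact test padding
    overrides.setdefault("decay_tau_ms", 60.0)
    return small_config(
        pink_rms_uV=0.0,
        white_rms_uV=0.0,
        alpha_rms_uV=0.0,
        ref_drift_rms_uV=0.0,
        cue_evoked_amp_uV=0.0,
        **overrides,
    )


@pytest.fixture(scope="session")
def small_session() -> RawSession:
    return simulate_participant(small_config(), "sub-01", 42)


@pytest.fixture(scope="session")
def noiseless_session() -> RawSession:
    return simulate_participant(noiseless_config(), "sub-01", 43)


def toy_events(n: int, cue: np.ndarray, resp: np.ndarray, sfreq: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "cue_sample": cue,
            "response_sample": resp,
            "condition": ["selection"] * n,
            "item_side": ["left"] * n,
            "response_hand": ["right"] * n,
            "decision_time_ms": (resp - cue) / sfreq * 1000.0,
            "reproduction_error_deg": np.zeros(n),
        }
    )


def toy_session(data: np.ndarray, labels: list[str], sfreq: float = 1000.0) -> RawSession:
    """Minimal session around an existing data matrix (one dummy event)."""
    n_samp = data.shape[1]
    return RawSession(
        data=data,
        sfreq_hz=sfreq,
        channel_labels=labels,
        channel_positions=montage_positions(labels),
        events=toy_events(1, np.array([0]), np.array([max(1, n_samp // 2)]), sfreq),
        participant_id="toy",
    )


def toy_epochs(
    data: np.ndarray,
    times_ms: np.ndarray,
    sfreq: float = 250.0,
    alignment: str = "response",
    dt_ms: np.ndarray | None = None,
) -> EpochSet:
    """EpochSet around a (trials, channels, time) array with stub metadata."""
    n = data.shape[0]
    if dt_ms is None:
        dt_ms = np.full(n, 700.0)
    resp = (np.arange(n) + 1) * 10_000
    cue = resp - np.round(np.asarray(dt_ms) * sfreq / 1000.0).astype(int)
    meta = toy_events(n, cue, resp, sfreq)
    meta["decision_time_ms"] = dt_ms
    labels = [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(
        data=data,
        sfreq_hz=sfreq,
        channel_labels=labels,
        channel_positions=np.zeros((data.shape[1], 2)),
        times_ms=times_ms,
        alignment=alignment,
        metadata=meta,
        participant_id="toy",
    )
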