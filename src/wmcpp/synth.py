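"""Synthetic EEG cohorts with a ground-truth accumulation-to-bound CPP.

The generator emulates the structure the analysis assumes: ~1 kHz continuous
multichannel recordings on a 10-10 montage, a centro-parietal component that
ramps linearly from a fixed post-cue onset to a *fixed bound amplitude* at
response (so the pre-decision slope is A / (DT - t0), inversely proportional
to decision time), shifted-lognormal decision times, 1/f + white + alpha-band
noise, a cue-evoked posterior transient, a common reference drift shared by
all channels (so mastoid rereferencing is testable), and an optional
two-condition manipulation ("selection" = item selection required after the
memory cue vs "preselected") that raises both the bound amplitude and the
decision times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.fft

from .containers import RawSession
from .errors import ConfigError, SimulationError
from .montage import DEFAULT_MONTAGE, montage_positions, spatial_weights

#: Condition labels: selection among two memory items required after the cue,
#: or the relevant item preselected before encoding.
SELECTION = "selection"
PRESELECTED = "preselected"


@dataclass
class SimConfig:
    """Generative parameters for one synthetic cohort.

    Decision times are drawn as ``dt_shift_ms + dt_condition_offset_ms[cond]
    + LogNormal(mu, sigma)``; defaults give a cohort mean near 756 ms for the
    selection condition.  ``bound_uV`` maps condition to the CPP amplitude at
    response; noise RMS values are per channel, in microvolts.
    """

    n_participants: int = 25
    n_trials: int = 620
    sfreq_hz: float = 1000.0
    # shifted-lognormal decision-time law (ms)
    dt_shift_ms: float = 250.0
    dt_lognorm_mu: float = 6.102
    dt_lognorm_sigma: float = 0.5
    dt_condition_offset_ms: dict = field(
        default_factory=lambda: {SELECTION: 0.0, PRESELECTED: -250.0}
    )
    # accumulation-to-bound CPP
    onset_ms: float = 100.0
    bound_uV: dict = field(default_factory=lambda: {SELECTION: 10.0, PRESELECTED: 8.0})
    decay_tau_ms: float = 300.0
    onset_jitter_ms: float = 0.0
    # spatial profile (schematic head coordinates)
    topo_center: tuple = (0.0, -0.375)  # between Pz and CPz
    topo_width: float = 0.4
    # cue-evoked visual transient: occipital, spatially narrower than the CPP
    transient_center: tuple = (0.0, -0.85)  # Oz
    transient_width: float = 0.25
    transient_peak_ms: float = 150.0
    transient_sigma_ms: float = 40.0
    # noise (per-channel RMS, uV)
    pink_rms_uV: float = 12.0
    white_rms_uV: float = 6.0
    alpha_rms_uV: float = 4.0
    ref_drift_rms_uV: float = 5.0
    # cue-evoked transient
    cue_evoked_amp_uV: float = 5.0
    # behavior: von Mises concentration of the reproduction-error law
    # (kappa 3.164 / 4.728 give mean absolute errors of 14.14 / 11.1 deg)
    p_condition: float = 1.0  # probability of the selection-required condition
    error_kappa: dict = field(
        default_factory=lambda: {SELECTION: 3.164, PRESELECTED: 4.728}
    )
    # layout
    channel_labels: list = field(default_factory=lambda: list(DEFAULT_MONTAGE))
    pre_cue_ms: float = 600.0
    post_response_ms: float = 900.0
    start_pad_ms: float = 1800.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("pink_rms_uV", "white_rms_uV", "alpha_rms_uV",
                     "ref_drift_rms_uV", "cue_evoked_amp_uV", "decay_tau_ms",
                     "onset_jitter_ms", "topo_width"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if any(a < 0 for a in self.bound_uV.values()):
            raise ConfigError("bound amplitudes must be >= 0")
        if self.dt_shift_ms < 0:
            raise ConfigError("dt_shift_ms must be >= 0")
        if not 0.0 <= self.p_condition <= 1.0:
            raise ConfigError("p_condition must lie in [0, 1]")
        if self.n_trials < 0 or self.n_participants < 0:
            raise ConfigError("counts must be >= 0")
        if self.sfreq_hz <= 0:
            raise ConfigError("sfreq_hz must be positive")
        typical_dt = self.dt_shift_ms + float(np.exp(self.dt_lognorm_mu))
        if self.onset_ms >= typical_dt:
            raise ConfigError("onset_ms must fall before the typical decision time")

    def expected_mean_dt_ms(self, condition: str = SELECTION) -> float:
        """Analytic mean of the shifted-lognormal decision-time law."""
        return (
            self.dt_shift_ms
            + self.dt_condition_offset_ms.get(condition, 0.0)
            + float(np.exp(self.dt_lognorm_mu + self.dt_lognorm_sigma**2 / 2.0))
        )

    @classmethod
    def two_condition(cls, **overrides) -> "SimConfig":
        """Cohort emulating the load manipulation: 20% selection-required
        trials with a higher bound (12 vs 8 uV) and +250 ms slower decisions."""
        cfg = cls(
            p_condition=0.2,
            bound_uV={SELECTION: 12.0, PRESELECTED: 8.0},
            error_kappa={SELECTION: 3.619, PRESELECTED: 4.728},  # 13.0 / 11.1 deg
            **overrides,
        )
        return cfg


def expected_slope(config: SimConfig, condition: str, dt_ms: float) -> float:
    """Noiseless ground-truth ramp slope (uV/s) for a given decision time.

    With a fixed bound A reached at the response, the pre-decision ramp has
    slope A / (DT - t0); steeper for faster decisions.
    """
    if dt_ms <= config.onset_ms:
        raise ConfigError("dt_ms must exceed the accumulation onset")
    amp = config.bound_uV[condition]
    return amp / ((dt_ms - config.onset_ms) / 1000.0)


def draw_decision_times(
    config: SimConfig,
    conditions: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """Per-trial decision times (ms), redrawing any draw that would end before
    accumulation onset.  Not clipped to the analysis bounds [200, 2000] ms —
    the exclusion filter is meant to see out-of-range trials."""
    conditions = np.asarray(conditions)
    offsets = np.array(
        [config.dt_condition_offset_ms.get(c, 0.0) for c in conditions], dtype=float
    )
    n = len(conditions)
    dt = np.full(n, np.nan)
    min_dt = config.onset_ms + 2.0 * 1000.0 / config.sfreq_hz
    todo = np.ones(n, dtype=bool)
    for _ in range(max_tries):
        k = int(todo.sum())
        if k == 0:
            return dt
        draws = config.dt_shift_ms + offsets[todo] + rng.lognormal(
            config.dt_lognorm_mu, config.dt_lognorm_sigma, size=k
        )
        dt[todo] = draws
        todo = dt <= min_dt
    raise SimulationError(
        f"{int(todo.sum())} decision times still <= onset after {max_tries} redraws; "
        "check dt_shift_ms / dt_condition_offset_ms against onset_ms"
    )


def _spectral_norm(gain: np.ndarray, nfft: int) -> float:
    """Output std of circularly filtering unit white noise with rFFT gain."""
    w = np.full(gain.shape, 2.0)
    w[0] = 1.0
    if nfft % 2 == 0:
        w[-1] = 1.0
    return float(np.sqrt(np.sum(w * gain * gain) / nfft))


def _combined_gain(
    f: np.ndarray,
    nfft: int,
    pink_rms: float,
    white_rms: float,
    alpha_rms: float,
    alpha_freq_hz: float,
    alpha_bw_hz: float,
    pink_floor_hz: float,
) -> np.ndarray:
    """rFFT gain whose filtered-white-noise output has the summed PSD of the
    pink, white and alpha components, each normalized to its target RMS."""
    gain_sq = np.zeros_like(f)
    if pink_rms > 0:
        g = 1.0 / np.sqrt(np.maximum(f, pink_floor_hz))
        g[0] = 0.0
        gain_sq += (pink_rms / _spectral_norm(g, nfft)) ** 2 * g * g
    if white_rms > 0:
        g = np.ones_like(f)
        gain_sq += (white_rms / _spectral_norm(g, nfft)) ** 2 * g * g
    if alpha_rms > 0:
        g = np.exp(-((f - alpha_freq_hz) ** 2) / (2.0 * alpha_bw_hz**2))
        gain_sq += (alpha_rms / _spectral_norm(g, nfft)) ** 2 * g * g
    return np.sqrt(gain_sq)


def shaped_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sfreq_hz: float,
    pink_rms: float,
    white_rms: float,
    alpha_rms: float,
    alpha_freq_hz: float = 10.0,
    alpha_bw_hz: float = 1.0,
    pink_floor_hz: float = 0.5,
    block: int = 65536,
) -> np.ndarray:
    """Gaussian noise with summed pink (1/f power above the floor), white and
    alpha-band PSDs; each component's RMS is exact in expectation.

    Long recordings are synthesized as windowed overlap-added independent
    blocks (sqrt-Hann, 50% overlap), which preserves the variance exactly and
    the PSD up to the ~0.03 Hz window kernel; block length comfortably
    resolves the 0.5 Hz pink floor."""
    if pink_rms == 0 and white_rms == 0 and alpha_rms == 0:
        return np.zeros((n_channels, n_samples))
    args = (pink_rms, white_rms, alpha_rms, alpha_freq_hz, alpha_bw_hz, pink_floor_hz)

    if n_samples <= block:  # single shot
        nfft = scipy.fft.next_fast_len(n_samples)
        f = np.fft.rfftfreq(nfft, 1.0 / sfreq_hz)
        gain = _combined_gain(f, nfft, *args)
        spec = scipy.fft.rfft(rng.standard_normal((n_channels, nfft)), axis=-1)
        out = scipy.fft.irfft(spec * gain, n=nfft, axis=-1)
        return np.ascontiguousarray(out[:, :n_samples])

    L = int(block)
    H = L // 2
    f = np.fft.rfftfreq(L, 1.0 / sfreq_hz)
    gain = _combined_gain(f, L, *args).astype(np.float32)
    k = np.arange(L)
    win = np.sqrt(0.5 * (1.0 - np.cos(2.0 * np.pi * k / L))).astype(np.float32)
    n_blocks = (H + n_samples) // H + 1
    out = np.zeros((n_channels, H + n_samples + L), dtype=np.float32)
    for b in range(n_blocks):
        white = rng.standard_normal((n_channels, L), dtype=np.float32)
        spec = scipy.fft.rfft(white, axis=-1)
        blockdata = scipy.fft.irfft(spec * gain, n=L, axis=-1) * win
        out[:, b * H : b * H + L] += blockdata
    return np.ascontiguousarray(out[:, H : H + n_samples])


def _reference_drift(
    rng: np.random.Generator, n_samples: int, sfreq_hz: float, rms: float
) -> np.ndarray:
    """Slow common-mode drift (1/f amplitude below 5 Hz) shared by all
    channels, emulating reference instability removed by rereferencing."""
    if rms == 0:
        return np.zeros(n_samples)
    nfft = scipy.fft.next_fast_len(n_samples)
    f = np.fft.rfftfreq(nfft, 1.0 / sfreq_hz)
    g = np.where(f <= 5.0, 1.0 / np.maximum(f, 0.1), 0.0)
    g[0] = 0.0
    g *= rms / _spectral_norm(g, nfft)
    spec = scipy.fft.rfft(rng.standard_normal(nfft))
    return scipy.fft.irfft(spec * g, n=nfft)[:n_samples]


def simulate_participant(
    config: SimConfig, participant_id: str, seed: int
) -> RawSession:
    """One participant's continuous session with ground-truth CPP trials."""
    config.validate()
    rng = np.random.default_rng(seed)
    fs = config.sfreq_hz
    n_tr = config.n_trials

    labels = list(config.channel_labels)
    positions = montage_positions(labels)
    w_cpp = spatial_weights(positions, config.topo_center, config.topo_width)
    w_cue = spatial_weights(positions, config.transient_center, config.transient_width)
    # mastoids carry reference drift and noise but no neural components
    for i, lb in enumerate(labels):
        if lb in ("M1", "M2"):
            w_cpp[i] = 0.0
            w_cue[i] = 0.0

    conditions = np.where(
        rng.random(n_tr) < config.p_condition, SELECTION, PRESELECTED
    )
    dt_drawn = draw_decision_times(config, conditions, rng)
    resp_offset = np.round(dt_drawn * fs / 1000.0).astype(int)
    resp_offset = np.maximum(resp_offset, int(np.ceil(config.onset_ms * fs / 1000.0)) + 2)
    dt_ms = resp_offset / fs * 1000.0  # exact on the sample grid

    pre = int(round(config.pre_cue_ms * fs / 1000.0))
    post = int(round(config.post_response_ms * fs / 1000.0))
    cue_samples = np.empty(n_tr, dtype=int)
    cursor = int(round(config.start_pad_ms * fs / 1000.0))
    for i in range(n_tr):
        cue_samples[i] = cursor + pre
        cursor = cue_samples[i] + resp_offset[i] + post
    n_samples = cursor + pre

    data = shaped_noise(
        rng, len(labels), n_samples, fs,
        config.pink_rms_uV, config.white_rms_uV, config.alpha_rms_uV,
    )
    data += _reference_drift(rng, n_samples, fs, config.ref_drift_rms_uV)[None, :]

    if config.onset_jitter_ms > 0:
        jitter = rng.normal(0.0, config.onset_jitter_ms, size=n_tr)
    else:
        jitter = np.zeros(n_tr)

    tau = config.decay_tau_ms
    decay_len = int(round(5.0 * tau * fs / 1000.0))
    for i in range(n_tr):
        cue = cue_samples[i]
        rsamp = cue + resp_offset[i]
        amp = config.bound_uV[conditions[i]]
        t0 = config.onset_ms + jitter[i]
        t0 = min(max(t0, 10.0), dt_ms[i] - 2.0 * 1000.0 / fs)
        if amp > 0:
            k0 = cue + int(np.ceil(t0 * fs / 1000.0))
            k = np.arange(k0, rsamp + 1)
            t_rel = (k - cue) * 1000.0 / fs
            ramp = amp * np.maximum(0.0, (t_rel - t0) / (dt_ms[i] - t0))
            data[:, k0 : rsamp + 1] += np.outer(w_cpp, ramp)
            kd = np.arange(rsamp + 1, min(rsamp + 1 + decay_len, n_samples))
            if kd.size:
                dec = amp * np.exp(-((kd - rsamp) * 1000.0 / fs) / tau)
                data[:, kd[0] : kd[-1] + 1] += np.outer(w_cpp, dec)
        if config.cue_evoked_amp_uV > 0:
            t_pk, t_sd = config.transient_peak_ms, config.transient_sigma_ms
            span = int((t_pk + 4.0 * t_sd) * fs / 1000.0)
            kt = np.arange(cue, min(cue + span, n_samples))
            t_rel = (kt - cue) * 1000.0 / fs
            bump = config.cue_evoked_amp_uV * np.exp(
                -((t_rel - t_pk) ** 2) / (2.0 * t_sd**2)
            )
            data[:, kt[0] : kt[-1] + 1] += np.outer(w_cue, bump)

    kappa = np.array([config.error_kappa.get(c, 3.0) for c in conditions])
    theta = rng.vonmises(0.0, kappa)
    err_deg = np.degrees(theta) / 2.0  # orientation space has a 180 deg period

    events = pd.DataFrame(
        {
            "trial_id": np.arange(n_tr),
            "cue_sample": cue_samples,
            "response_sample": cue_samples + resp_offset,
            "condition": conditions,
            "item_side": rng.choice(["left", "right"], size=n_tr),
            "response_hand": rng.choice(["left", "right"], size=n_tr),
            "decision_time_ms": dt_ms,
            "reproduction_error_deg": err_deg,
        }
    )
    return RawSession(
        data=data,
        sfreq_hz=fs,
        channel_labels=labels,
        channel_positions=positions,
        events=events,
        participant_id=str(participant_id),
    )


def iter_cohort(config: SimConfig):
    """Lazily yield the cohort's sessions (sub-seeds derived deterministically
    from ``config.seed``); lets long pipelines hold one recording at a time."""
    config.validate()
    if config.n_participants == 0:
        return
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_participants)
    for i in range(config.n_participants):
        yield simulate_participant(config, f"sub-{i + 1:02d}", int(seeds[i]))


def simulate_cohort(config: SimConfig) -> list[RawSession]:
    """n_participants independent sessions (see :func:`iter_cohort`)."""
    return list(iter_cohort(config))


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["topo_center"] = list(d["topo_center"])
    d["transient_center"] = list(d["transient_center"])
    return d
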