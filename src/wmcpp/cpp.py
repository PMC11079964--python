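"""CPP quantities: electrode-cluster ERPs, decision-time-binned ERP images,
pre-decision slopes, the slope-vs-bin correlation, and the slope-window sweep.

All slope estimates are ordinary least-squares regressions of potential (uV)
on time (s) over a closed window, so they are invariant to any constant
baseline shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet
from .errors import ConfigError, DataError
from . import inference

#: A priori centro-parietal electrode cluster centered on Pz.
CLUSTER_CHANNELS = ["Pz", "CPz", "POz", "P1", "P2"]


@dataclass
class AnalysisConfig:
    cluster_channels: list = field(default_factory=lambda: list(CLUSTER_CHANNELS))
    n_bins_fine: int = 100
    n_bins_coarse: int = 4
    slope_window_ms: tuple = (-500.0, -50.0)
    sweep_starts_ms: tuple = tuple(np.arange(-1000.0, -199.0, 50.0))
    sweep_ends_ms: tuple = tuple(np.arange(-400.0, 1.0, 50.0))
    min_window_ms: float = 100.0
    topo_window_cue_ms: tuple = (300.0, 600.0)
    topo_window_resp_ms: tuple = (-300.0, 0.0)
    topo_window_contrast_ms: tuple = (-600.0, -300.0)
    smooth_binned: bool = True  # smooth per-bin ERPs after binning

    def validate(self) -> None:
        if self.slope_window_ms[1] > 0:
            raise ConfigError("slope window must end at or before the response")
        if self.n_bins_fine < 1 or self.n_bins_coarse < 1:
            raise ConfigError("bin counts must be >= 1")
        if self.min_window_ms <= 0:
            raise ConfigError("min_window_ms must be > 0")


@dataclass
class BinnedErp:
    """Per-participant decision-time-binned ERP matrix."""

    participant_id: str
    bin_means: np.ndarray       # (n_bins, n_time), uV
    bin_mean_dt_ms: np.ndarray  # per-bin mean decision time
    bin_counts: np.ndarray
    alignment: str
    times_ms: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.bin_means.shape[0]


@dataclass
class SlopeResult:
    participant_id: str
    window_ms: tuple
    slopes_per_bin: np.ndarray  # uV/s
    r_slope_vs_bin: float


@dataclass
class SweepResult:
    """Group-level t map over slope-window (start, end) pairs."""

    starts_ms: np.ndarray
    ends_ms: np.ndarray
    t_map: np.ndarray           # (n_starts, n_ends), NaN where invalid
    mean_r_map: np.ndarray
    apriori_window_ms: tuple


def cluster_average(epochs: EpochSet, channels: list[str] | None = None) -> np.ndarray:
    """Unweighted mean over the electrode cluster: (n_trials, n_time)."""
    channels = CLUSTER_CHANNELS if channels is None else channels
    try:
        idx = [epochs.channel_index(c) for c in channels]
    except DataError as exc:
        raise ConfigError(str(exc)) from exc
    return epochs.data[:, idx, :].mean(axis=1)


def grand_erp(
    per_participant_means: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Across-participant mean and SEM of per-participant mean time courses.

    Input is (n_participants, n_time): the first-level (within-participant
    trial) average.  SEM is computed across participants; NaN for n = 1."""
    M = np.atleast_2d(np.asarray(per_participant_means, dtype=float))
    mean = M.mean(axis=0)
    if M.shape[0] < 2:
        return mean, np.full(mean.shape, np.nan)
    sem = M.std(axis=0, ddof=1) / np.sqrt(M.shape[0])
    return mean, sem


def bin_by_decision_time(
    trial_series: np.ndarray,
    dt_ms: np.ndarray,
    n_bins: int,
    times_ms: np.ndarray,
    alignment: str,
    participant_id: str = "",
    trial_ids: np.ndarray | None = None,
) -> BinnedErp:
    """Partition trials into ``n_bins`` contiguous decision-time groups.

    Trials are stably sorted by decision time (ties broken by trial id) and
    split as equally as possible, remainders going to the earliest bins."""
    trial_series = np.asarray(trial_series, dtype=float)
    dt_ms = np.asarray(dt_ms, dtype=float)
    n = trial_series.shape[0]
    if n_bins > n:
        raise DataError(f"n_bins = {n_bins} exceeds trial count {n}")
    if trial_ids is None:
        trial_ids = np.arange(n)
    order = np.lexsort((np.asarray(trial_ids), dt_ms))
    sizes = np.full(n_bins, n // n_bins, dtype=int)
    sizes[: n % n_bins] += 1
    edges = np.concatenate(([0], np.cumsum(sizes)))
    bin_means = np.empty((n_bins, trial_series.shape[1]))
    bin_dt = np.empty(n_bins)
    for b in range(n_bins):
        sel = order[edges[b] : edges[b + 1]]
        bin_means[b] = trial_series[sel].mean(axis=0)
        bin_dt[b] = dt_ms[sel].mean()
    return BinnedErp(
        participant_id=participant_id,
        bin_means=bin_means,
        bin_mean_dt_ms=bin_dt,
        bin_counts=sizes,
        alignment=alignment,
        times_ms=np.asarray(times_ms, dtype=float),
    )


def erp_image(binned: list[BinnedErp]) -> tuple[np.ndarray, np.ndarray]:
    """Across-participant average of binned ERPs: (bins x time image,
    per-bin mean decision-time trace)."""
    if not binned:
        raise DataError("erp_image needs at least one participant")
    ref = binned[0]
    for b in binned[1:]:
        if b.n_bins != ref.n_bins or not np.array_equal(b.times_ms, ref.times_ms):
            raise DataError("binned ERPs have mismatching bins or time axes")
    image = np.mean([b.bin_means for b in binned], axis=0)
    dt_trace = np.mean([b.bin_mean_dt_ms for b in binned], axis=0)
    return image, dt_trace


def slope(series: np.ndarray, times_ms: np.ndarray, window_ms: tuple) -> float:
    """OLS slope (uV/s) of the series over the closed time window; NaN if
    fewer than 3 samples fall inside."""
    series = np.asarray(series, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    lo, hi = window_ms
    mask = (times_ms >= lo - 1e-9) & (times_ms <= hi + 1e-9)
    if mask.sum() < 3:
        return float("nan")
    t_s = times_ms[mask] / 1000.0
    y = series[mask]
    t_c = t_s - t_s.mean()
    return float(np.dot(t_c, y - y.mean()) / np.dot(t_c, t_c))


def slope_bin_profile(binned: BinnedErp, window_ms: tuple) -> SlopeResult:
    """Per-bin pre-decision slope and its Pearson correlation with bin number
    (1..n); degenerate (zero-variance) slopes yield a NaN correlation."""
    if binned.alignment != "response":
        raise ConfigError("slope_bin_profile requires response-aligned binning")
    slopes = np.array(
        [slope(binned.bin_means[b], binned.times_ms, window_ms) for b in range(binned.n_bins)]
    )
    if np.isnan(slopes).any():
        warnings.warn("missing slope in at least one bin; correlation undefined",
                      stacklevel=2)
        r = float("nan")
    elif np.ptp(slopes) == 0:
        warnings.warn("identical slopes across bins; correlation undefined",
                      stacklevel=2)
        r = float("nan")
    else:
        r = inference.pearson_r(np.arange(1, binned.n_bins + 1), slopes)
    return SlopeResult(
        participant_id=binned.participant_id,
        window_ms=tuple(window_ms),
        slopes_per_bin=slopes,
        r_slope_vs_bin=r,
    )


def window_sweep(
    binned_per_participant: list[BinnedErp],
    starts_ms=None,
    ends_ms=None,
    min_window_ms: float = 100.0,
    apriori_window_ms: tuple = (-500.0, -50.0),
) -> SweepResult:
    """Group-level t of the slope-vs-bin correlation for every valid
    (start, end) slope window on a grid.

    Cells with end - start < min_window are NaN; the a priori window is
    recorded so reports can mark it."""
    cfg = AnalysisConfig()
    starts = np.asarray(cfg.sweep_starts_ms if starts_ms is None else starts_ms, float)
    ends = np.asarray(cfg.sweep_ends_ms if ends_ms is None else ends_ms, float)
    if not binned_per_participant:
        raise DataError("window_sweep needs at least one participant")
    t_map = np.full((starts.size, ends.size), np.nan)
    r_map = np.full((starts.size, ends.size), np.nan)
    any_valid = False
    for i, s in enumerate(starts):
        for j, e in enumerate(ends):
            if e - s < min_window_ms or e > 0:
                continue
            rs = np.array(
                [
                    slope_bin_profile(b, (s, e)).r_slope_vs_bin
                    for b in binned_per_participant
                ]
            )
            if np.isnan(rs).any():
                continue
            any_valid = True
            res = inference.one_sample_t(rs)
            t_map[i, j] = res.t
            r_map[i, j] = res.mean
    if not any_valid:
        raise DataError("window sweep produced no valid cells")
    return SweepResult(
        starts_ms=starts,
        ends_ms=ends,
        t_map=t_map,
        mean_r_map=r_map,
        apriori_window_ms=tuple(apriori_window_ms),
    )


def topography_values(
    epochs_per_participant: list[EpochSet], window_ms: tuple
) -> tuple[list[str], np.ndarray]:
    """Time-window mean per channel, averaged over trials then participants.

    Returns (channel labels, per-channel mean in uV); export with
    :func:`wmcpp.session_io.export_matrix` — no scalp interpolation here."""
    if not epochs_per_participant:
        raise DataError("topography_values needs at least one participant")
    ref = epochs_per_participant[0]
    mask = ref.time_mask(window_ms)
    if not mask.any():
        raise ConfigError(f"window {window_ms} outside epoch window")
    per_p = []
    for ep in epochs_per_participant:
        if ep.channel_labels != ref.channel_labels:
            raise DataError("channel sets differ across participants")
        per_p.append(ep.data[:, :, mask].mean(axis=(0, 2)))
    return list(ref.channel_labels), np.mean(per_p, axis=0)
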