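"""Pipeline orchestration: simulate -> preprocess -> analyze -> report.

``analyze_cohort`` runs the full analysis chain on a list of raw sessions and
returns a results bundle (plain dict of arrays / stat bundles);
``write_bundle`` serializes it as TSV + JSON under an output directory, and
``render_report`` produces the human-readable summary.  Every stage is
deterministic given the config and seed; a manifest records config, seeds and
content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cpp, inference, preprocess, session_io, synth
from .containers import EpochSet, RawSession
from .cpp import AnalysisConfig, BinnedErp
from .errors import ConfigError, DataError
from .preprocess import PreprocessConfig
from .synth import SimConfig

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-participant chain


def preprocess_session(
    raw: RawSession, pre: PreprocessConfig, cluster_channels: list[str] | None = None
) -> dict:
    """Rereference, downsample, epoch (both alignments), exclude and flag.

    Returns dict with baseline-corrected 'cue' and 'resp' EpochSets over the
    same retained trials, plus a retention report."""
    pre.validate()
    n_events = len(raw.events)
    ses = preprocess.rereference(raw, pre.ref_channels)
    ses = preprocess.downsample(ses, pre.target_sfreq_hz)
    ep_cue = preprocess.epoch(ses, "cue", pre.cue_window_ms)
    ep_resp = preprocess.epoch(ses, "response", pre.resp_window_ms)

    common = np.intersect1d(
        ep_cue.metadata["trial_id"].to_numpy(), ep_resp.metadata["trial_id"].to_numpy()
    )
    ep_cue = ep_cue.select(ep_cue.metadata["trial_id"].isin(common).to_numpy())
    ep_resp = ep_resp.select(ep_resp.metadata["trial_id"].isin(common).to_numpy())
    n_edge = n_events - len(common)

    ep_resp, dt_report = preprocess.exclude_by_decision_time(ep_resp, pre.dt_bounds_ms)
    flags, var_report = preprocess.flag_high_variance_trials(
        ep_resp, pre.variance_z_threshold, channels=cluster_channels
    )
    ep_resp = ep_resp.select(~flags)
    kept = ep_resp.metadata["trial_id"].to_numpy()
    ep_cue = ep_cue.select(ep_cue.metadata["trial_id"].isin(kept).to_numpy())

    ep_cue = preprocess.baseline_correct(ep_cue, pre.cue_baseline_ms)
    ep_resp = preprocess.baseline_correct(ep_resp, pre.resp_baseline_ms)
    retention = {
        "participant_id": raw.participant_id,
        "n_events": int(n_events),
        "n_edge_dropped": int(n_edge),
        "n_dt_below": dt_report["n_below"],
        "n_dt_above": dt_report["n_above"],
        "n_variance_flagged": var_report["n_flagged"],
        "n_retained": int(len(kept)),
    }
    return {"cue": ep_cue, "resp": ep_resp, "retention": retention}


def analyze_participant(raw: RawSession, pre: PreprocessConfig, ana: AnalysisConfig) -> dict:
    """First-level analysis of one session."""
    ana.validate()
    pp = preprocess_session(raw, pre, ana.cluster_channels)
    ep_cue: EpochSet = pp["cue"]
    ep_resp: EpochSet = pp["resp"]
    fs = ep_resp.sfreq_hz
    sigma = pre.smooth_sigma_ms

    ca_cue = cpp.cluster_average(ep_cue, ana.cluster_channels)
    ca_resp = cpp.cluster_average(ep_resp, ana.cluster_channels)
    dt = ep_resp.metadata["decision_time_ms"].to_numpy(dtype=float)
    tid = ep_resp.metadata["trial_id"].to_numpy()

    out = {
        "participant_id": raw.participant_id,
        "retention": pp["retention"],
        "times_cue_ms": ep_cue.times_ms,
        "times_resp_ms": ep_resp.times_ms,
        "trace_cue": preprocess.smooth_gaussian(ca_cue.mean(axis=0), sigma, fs),
        "trace_resp": preprocess.smooth_gaussian(ca_resp.mean(axis=0), sigma, fs),
        "n_trials_retained": ep_resp.n_trials,
        "ca_cue": ca_cue,
        "ca_resp": ca_resp,
        "dt_ms": dt,
        "trial_ids": tid,
        "smooth": (ana.smooth_binned, sigma, fs),
    }

    def _binned(series, times, alignment, n_bins) -> BinnedErp:
        b = cpp.bin_by_decision_time(
            series, dt, n_bins, times, alignment, raw.participant_id, trial_ids=tid
        )
        if ana.smooth_binned:
            b.bin_means = preprocess.smooth_gaussian(b.bin_means, sigma, fs)
        return b

    out["binned_quartile_resp"] = _binned(
        ca_resp, ep_resp.times_ms, "response", ana.n_bins_coarse
    )
    out["slope_result"] = cpp.slope_bin_profile(
        out["binned_quartile_resp"], ana.slope_window_ms
    )

    # per-channel window means (topography values), reduced here so the
    # (large) epoch arrays need not outlive this participant
    labels, topo_cue = cpp.topography_values([ep_cue], ana.topo_window_cue_ms)
    _, topo_resp = cpp.topography_values([ep_resp], ana.topo_window_resp_ms)
    out["topo"] = {"labels": labels, "cue": topo_cue, "resp": topo_resp}

    meta = ep_resp.metadata
    contrast_mask = ep_resp.time_mask(ana.topo_window_contrast_ms)
    conditions = sorted(meta["condition"].unique())
    per_condition = {}
    for cond in conditions:
        m = (meta["condition"] == cond).to_numpy()
        per_condition[cond] = {
            "n": int(m.sum()),
            "trace_cue": preprocess.smooth_gaussian(ca_cue[m].mean(axis=0), sigma, fs),
            "trace_resp": preprocess.smooth_gaussian(ca_resp[m].mean(axis=0), sigma, fs),
            "mean_dt_ms": float(meta.loc[m, "decision_time_ms"].mean()),
            "mean_abs_error_deg": float(
                meta.loc[m, "reproduction_error_deg"].abs().mean()
            ),
            "topo_contrast_window": ep_resp.data[m][:, :, contrast_mask].mean(
                axis=(0, 2)
            ),
        }
    out["per_condition"] = per_condition
    out["behavior"] = {
        "mean_dt_ms": float(meta["decision_time_ms"].mean()),
        "mean_abs_error_deg": float(meta["reproduction_error_deg"].abs().mean()),
    }
    return out


# ---------------------------------------------------------------------------
# group level


def format_retention(n_retained: np.ndarray, n_events: np.ndarray) -> str:
    """Retention in the conventional 'M ± SEM trials (M ± SEM%)' style."""
    mean_n, sem_n = inference.describe(n_retained)
    pct = 100.0 * np.asarray(n_retained, float) / np.asarray(n_events, float)
    mean_p, sem_p = inference.describe(pct)
    sem_n = 0.0 if np.isnan(sem_n) else sem_n
    sem_p = 0.0 if np.isnan(sem_p) else sem_p
    return f"{mean_n:,.0f} ± {sem_n:.0f} trials ({mean_p:.0f} ± {sem_p:.0f}%)"


def analyze_cohort(
    sessions: list[RawSession],
    pre: PreprocessConfig | None = None,
    ana: AnalysisConfig | None = None,
    n_permutations: int = 10_000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> dict:
    """Full two-level analysis of a cohort of raw sessions."""
    pre = pre or PreprocessConfig()
    ana = ana or AnalysisConfig()
    # sessions may be a lazy iterable: each raw recording is released once
    # its first-level summary has been computed
    firsts = [analyze_participant(s, pre, ana) for s in sessions]
    if not firsts:
        raise DataError("analyze_cohort needs at least one session")
    n_p = len(firsts)

    results: dict = {
        "n_participants": n_p,
        "participant_ids": [f["participant_id"] for f in firsts],
        "times_cue_ms": firsts[0]["times_cue_ms"],
        "times_resp_ms": firsts[0]["times_resp_ms"],
        "config": {
            "n_permutations": n_permutations,
            "cluster_alpha": cluster_alpha,
            "seed": seed,
        },
    }

    # grand ERPs and cluster tests against zero
    for key, align in (("cue", "times_cue_ms"), ("resp", "times_resp_ms")):
        traces = np.vstack([f[f"trace_{key}"] for f in firsts])
        mean, sem = cpp.grand_erp(traces)
        results[f"grand_{key}"] = {"mean": mean, "sem": sem}
        if n_p >= 2:
            results[f"cluster_{key}"] = inference.cluster_test(
                traces,
                cluster_alpha=cluster_alpha,
                n_permutations=n_permutations,
                seed=seed + 1 if key == "cue" else seed + 2,
                times_ms=results[align],
                exhaustive=exhaustive,
            )

    # ERP images: fine bin count shared across the cohort so the
    # across-participant average is well defined
    n_fine = min(ana.n_bins_fine, min(f["n_trials_retained"] for f in firsts))
    results["n_bins_fine"] = n_fine
    for key, align in (("cue", "times_cue_ms"), ("resp", "times_resp_ms")):
        binned = []
        for f in firsts:
            b = cpp.bin_by_decision_time(
                f[f"ca_{key}"],
                f["dt_ms"],
                n_fine,
                results[align],
                "cue" if key == "cue" else "response",
                f["participant_id"],
                trial_ids=f["trial_ids"],
            )
            do_smooth, sigma, fs = f["smooth"]
            if do_smooth:
                b.bin_means = preprocess.smooth_gaussian(b.bin_means, sigma, fs)
            binned.append(b)
        image, dt_trace = cpp.erp_image(binned)
        results[f"erp_image_{key}"] = {"image": image, "mean_dt_ms": dt_trace}

    # quartile slopes, slope-vs-bin correlation, group test
    slope_rows = []
    rs = []
    for f in firsts:
        sr = f["slope_result"]
        bq = f["binned_quartile_resp"]
        slope_rows.append(
            {
                "participant_id": f["participant_id"],
                **{f"slope_bin{i + 1}_uV_s": sr.slopes_per_bin[i] for i in range(bq.n_bins)},
                **{f"mean_dt_bin{i + 1}_ms": bq.bin_mean_dt_ms[i] for i in range(bq.n_bins)},
                "r_slope_vs_bin": sr.r_slope_vs_bin,
            }
        )
        rs.append(sr.r_slope_vs_bin)
    results["slope_table"] = pd.DataFrame(slope_rows)
    rs = np.asarray(rs, dtype=float)
    results["r_per_participant"] = rs
    if n_p >= 2 and np.isfinite(rs).all():
        results["group_slope_corr"] = inference.one_sample_t(rs)

    # window sweep
    results["sweep"] = cpp.window_sweep(
        [f["binned_quartile_resp"] for f in firsts],
        starts_ms=ana.sweep_starts_ms,
        ends_ms=ana.sweep_ends_ms,
        min_window_ms=ana.min_window_ms,
        apriori_window_ms=ana.slope_window_ms,
    )

    # topographies (channel values; no interpolation)
    results["topography"] = {
        "channel_labels": firsts[0]["topo"]["labels"],
        "cue": np.mean([f["topo"]["cue"] for f in firsts], axis=0),
        "resp": np.mean([f["topo"]["resp"] for f in firsts], axis=0),
        "window_cue_ms": ana.topo_window_cue_ms,
        "window_resp_ms": ana.topo_window_resp_ms,
    }

    # condition contrast (only when every participant has both conditions)
    conds = set.intersection(*(set(f["per_condition"]) for f in firsts))
    if len(conds) >= 2:
        c_hi, c_lo = synth.SELECTION, synth.PRESELECTED
        if not {c_hi, c_lo} <= conds:
            c_hi, c_lo = sorted(conds)[:2]
        contrast: dict = {"conditions": [c_hi, c_lo]}
        for key, align in (("cue", "times_cue_ms"), ("resp", "times_resp_ms")):
            a = np.vstack([f["per_condition"][c_hi][f"trace_{key}"] for f in firsts])
            b = np.vstack([f["per_condition"][c_lo][f"trace_{key}"] for f in firsts])
            contrast[f"cluster_{key}"] = inference.cluster_test(
                a,
                design="paired",
                data_b=b,
                cluster_alpha=cluster_alpha,
                n_permutations=n_permutations,
                seed=seed + 3 if key == "cue" else seed + 4,
                times_ms=results[align],
                exhaustive=exhaustive,
            )
            contrast[f"grand_{key}"] = {c_hi: a.mean(axis=0), c_lo: b.mean(axis=0)}
        for metric in ("mean_dt_ms", "mean_abs_error_deg"):
            hi = np.array([f["per_condition"][c_hi][metric] for f in firsts])
            lo = np.array([f["per_condition"][c_lo][metric] for f in firsts])
            contrast[f"behavior_{metric}"] = {
                c_hi: inference.describe(hi),
                c_lo: inference.describe(lo),
                "difference": float(hi.mean() - lo.mean()),
                "paired": inference.paired_t(lo, hi),  # preselected - selection
            }
        # condition-contrast topography in the pre-decision window
        contrast["topography_resp"] = np.mean(
            [
                f["per_condition"][c_hi]["topo_contrast_window"]
                - f["per_condition"][c_lo]["topo_contrast_window"]
                for f in firsts
            ],
            axis=0,
        )
        results["condition_contrast"] = contrast
    else:
        log.info("single-condition cohort: condition-contrast outputs skipped")
        results["condition_contrast"] = None

    # retention + behavior
    ret = pd.DataFrame([f["retention"] for f in firsts])
    results["retention_table"] = ret
    results["retention_summary"] = format_retention(
        ret["n_retained"].to_numpy(), ret["n_events"].to_numpy()
    )
    results["behavior"] = {
        "mean_dt_ms": inference.describe([f["behavior"]["mean_dt_ms"] for f in firsts]),
        "mean_abs_error_deg": inference.describe(
            [f["behavior"]["mean_abs_error_deg"] for f in firsts]
        ),
    }
    return results


# ---------------------------------------------------------------------------
# serialization


def _cluster_dict(res: inference.ClusterTestResult) -> dict:
    return {
        "threshold": res.threshold,
        "n_permutations": res.n_permutations,
        "seed": res.seed,
        "tail": res.tail,
        "exhaustive": res.exhaustive,
        "clusters": [c.to_dict() for c in res.clusters],
    }


def bundle_stats(results: dict) -> dict:
    """JSON-serializable statistics bundle extracted from a results dict."""
    out: dict = {
        "n_participants": results["n_participants"],
        "retention_summary": results["retention_summary"],
        "behavior": {
            k: {"mean": v[0], "sem": v[1]} for k, v in results["behavior"].items()
        },
    }
    if "group_slope_corr" in results:
        out["group_slope_corr"] = results["group_slope_corr"].to_dict()
        out["r_mean_sem"] = list(inference.describe(results["r_per_participant"]))
    for key in ("cluster_cue", "cluster_resp"):
        if key in results:
            out[key] = _cluster_dict(results[key])
    cc = results.get("condition_contrast")
    if cc is not None:
        out["condition_contrast"] = {
            "conditions": cc["conditions"],
            "cluster_cue": _cluster_dict(cc["cluster_cue"]),
            "cluster_resp": _cluster_dict(cc["cluster_resp"]),
        }
        for metric in ("mean_dt_ms", "mean_abs_error_deg"):
            beh = cc[f"behavior_{metric}"]
            out["condition_contrast"][metric] = {
                "difference": beh["difference"],
                "paired": beh["paired"].to_dict(),
            }
    return out


def write_bundle(results: dict, out_dir: str | Path) -> dict:
    """Write the results bundle as TSV/JSON files; returns path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}

    for key, tkey in (("cue", "times_cue_ms"), ("resp", "times_resp_ms")):
        t = results[tkey]
        g = results[f"grand_{key}"]
        df = pd.DataFrame(
            {"time_ms": t, "mean_uV": g["mean"], "sem_uV": g["sem"]}
        ).set_index("time_ms")
        paths[f"grand_{key}"] = session_io.export_matrix(df, out_dir / f"grand_erp_{key}.tsv")

        im = results[f"erp_image_{key}"]
        cols = [f"t{v:+.0f}ms" for v in t]
        df = pd.DataFrame(im["image"], columns=cols)
        df.insert(0, "mean_dt_ms", im["mean_dt_ms"])
        df.index = pd.RangeIndex(1, len(df) + 1, name="bin")
        paths[f"erp_image_{key}"] = session_io.export_matrix(
            df, out_dir / f"erp_image_{key}.tsv"
        )
        if f"cluster_{key}" in results:
            paths[f"cluster_{key}"] = session_io.export_matrix(
                results[f"cluster_{key}"].to_table(), out_dir / f"clusters_{key}.tsv"
            )

    paths["slopes"] = session_io.export_matrix(
        results["slope_table"].set_index("participant_id"), out_dir / "slopes_quartile.tsv"
    )
    sweep = results["sweep"]
    paths["sweep"] = session_io.export_matrix(
        sweep.t_map,
        out_dir / "sweep_t_resp.tsv",
        row_labels=[f"{s:+.0f}" for s in sweep.starts_ms],
        col_labels=[f"{e:+.0f}" for e in sweep.ends_ms],
        index_name="start_ms\\end_ms",
    )
    topo = results["topography"]
    df = pd.DataFrame(
        {"cue_uV": topo["cue"], "resp_uV": topo["resp"]},
        index=pd.Index(topo["channel_labels"], name="channel"),
    )
    paths["topography"] = session_io.export_matrix(df, out_dir / "topography.tsv")
    paths["retention"] = session_io.export_matrix(
        results["retention_table"].set_index("participant_id"), out_dir / "retention.tsv"
    )
    cc = results.get("condition_contrast")
    if cc is not None:
        for key in ("cue", "resp"):
            paths[f"contrast_cluster_{key}"] = session_io.export_matrix(
                cc[f"cluster_{key}"].to_table(),
                out_dir / f"contrast_clusters_{key}.tsv",
            )
    stats = bundle_stats(results)
    stats_path = out_dir / "group_stats.json"
    stats_path.write_text(json.dumps(stats, indent=1))
    paths["group_stats"] = stats_path
    report_path = out_dir / "summary.txt"
    report_path.write_text(render_report(stats))
    paths["summary"] = report_path
    return paths


def render_report(stats: dict) -> str:
    """Human-readable summary in the conventional reporting style."""
    if not stats:
        return "nothing to report (empty bundle)\n"
    lines = [f"Cohort: n = {stats['n_participants']} participants"]
    lines.append(f"Retained {stats['retention_summary']} per participant")
    beh = stats.get("behavior", {})
    if "mean_dt_ms" in beh:
        m = beh["mean_dt_ms"]
        lines.append(f"Decision time: {m['mean']:.2f} ± {m['sem']:.2f} ms (M ± SEM)")
    if "mean_abs_error_deg" in beh:
        m = beh["mean_abs_error_deg"]
        lines.append(f"Reproduction error: {m['mean']:.2f} ± {m['sem']:.2f} deg (M ± SEM)")
    if "group_slope_corr" in stats:
        g = stats["group_slope_corr"]
        r = stats.get("r_mean_sem")
        if r:
            lines.append(f"Slope vs decision-time bin: r = {r[0]:.3f} ± {r[1]:.3f} (M ± SEM)")
        lines.append(
            "  group level: "
            + GroupFormatter(g).format()
        )
    for key, name in (
        ("cluster_cue", "Cue-locked ERP vs 0"),
        ("cluster_resp", "Response-locked ERP vs 0"),
    ):
        if key in stats:
            lines.append(f"{name}: " + _format_clusters(stats[key]))
    cc = stats.get("condition_contrast")
    if cc is not None:
        hi, lo = cc["conditions"]
        lines.append(f"Condition contrast ({hi} vs {lo}):")
        for key, name in (("cluster_cue", "cue-locked"), ("cluster_resp", "response-locked")):
            lines.append(f"  {name}: " + _format_clusters(cc[key]))
        for metric, unit in (("mean_dt_ms", "ms"), ("mean_abs_error_deg", "deg")):
            if metric in cc:
                d = cc[metric]
                lines.append(
                    f"  {metric}: difference {d['difference']:.1f} {unit}; "
                    + GroupFormatter(d["paired"]).format()
                )
    return "\n".join(lines) + "\n"


class GroupFormatter:
    """Format a serialized GroupStatResult dict as t(df), p, d."""

    def __init__(self, d: dict):
        self.d = d

    def format(self) -> str:
        d = self.d
        return f"t({d['df']}) = {d['t']:.3f}, p = {d['p']:.4g}, d = {d['cohen_d']:.3f}"


def _format_clusters(cdict: dict) -> str:
    cl = cdict["clusters"]
    if not cl:
        return "no suprathreshold clusters"
    return "; ".join(
        f"cluster {c['start_ms']:+.0f}..{c['end_ms']:+.0f} ms, "
        f"mass {c['mass']:.1f}, p = {c['p_perm']:.4g}"
        for c in cl
    )


# ---------------------------------------------------------------------------
# commands (library surface of the CLI)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def cmd_simulate(sim: SimConfig, out_dir: str | Path) -> dict:
    """Simulate a cohort and write one raw-session container per participant."""
    sim.validate()
    if sim.n_trials == 0:
        raise ConfigError("n_trials must be > 0 to simulate a cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stems = []
    hashes = {}
    for session in synth.simulate_cohort(sim):
        stem = out_dir / session.participant_id
        for p in session_io.write_raw(session, stem):
            hashes[p.name] = _sha256(p)
        stems.append(str(stem))
    manifest = {
        "stage": "simulate",
        "config": synth.config_to_dict(sim),
        "seed": sim.seed,
        "n_sessions": len(stems),
        "stems": stems,
        "hashes": hashes,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def cmd_analyze(
    session_stems: list[str | Path],
    out_dir: str | Path,
    pre: PreprocessConfig | None = None,
    ana: AnalysisConfig | None = None,
    n_permutations: int = 10_000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> dict:
    """Read sessions, run the cohort analysis, and write the results bundle."""
    sessions = (session_io.read_raw(stem) for stem in session_stems)
    results = analyze_cohort(
        sessions,
        pre=pre,
        ana=ana,
        n_permutations=n_permutations,
        cluster_alpha=cluster_alpha,
        seed=seed,
        exhaustive=exhaustive,
    )
    paths = write_bundle(results, out_dir)
    manifest = {
        "stage": "analyze",
        "seed": seed,
        "n_permutations": n_permutations,
        "cluster_alpha": cluster_alpha,
        "n_participants": results["n_participants"],
        "trial_counts": results["retention_table"][
            ["participant_id", "n_events", "n_retained"]
        ].to_dict(orient="records"),
        "inputs": [str(s) for s in session_stems],
        "outputs": {k: str(p) for k, p in paths.items()},
        "hashes": {Path(p).name: _sha256(Path(p)) for p in paths.values()},
    }
    (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results


def cmd_report(bundle_dir: str | Path) -> str:
    """Render the summary for a written bundle directory."""
    stats_path = Path(bundle_dir) / "group_stats.json"
    if not stats_path.exists():
        raise DataError(f"bundle incomplete: missing {stats_path}")
    stats = json.loads(stats_path.read_text())
    return render_report(stats)
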