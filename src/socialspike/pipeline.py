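"""Pipeline stages: simulate -> detect -> analyze -> report.

Each stage is a plain function over files plus a config; the CLI wraps
them thinly.  Every run writes a manifest (config snapshot, seeds, input
digests, per-stage counts) from which it can be reproduced exactly.
The pipeline never reads the ground-truth JSON: planted truth is for the
test harness only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    angular_rate_profile,
    behavior_table,
    compare_focal_vs_others_speed,
    quarter_split,
    walking_speed,
)
from .config import AnalysisConfig
from .io import FOCAL_ID, bin_spikes, read_spikes, read_tracks
from .neural import (
    decile_distance_analysis,
    distance_split_profiles,
    peak_pre_event_latency,
    peth,
    window_variances,
)
from .social_states import classify_all, count_within_contact
from .stats import pairwise_variance_comparisons, rayleigh_test
from .synthetic import SimConfig, make_fixture

log = logging.getLogger("socialspike")

PETH_STATES = ("walking_onset", "passive_contact", "active_contact")
VARIANCE_STATES = ("alone", "random", "walking_onset", "passive_contact", "active_contact")


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_manifest(out_dir, stage: str, config: dict, seed, inputs: dict, counts: dict) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": {}}
    manifest["version"] = __version__
    manifest["stages"][stage] = {
        "config": config,
        "seed": seed,
        "inputs": {k: _digest(v) for k, v in inputs.items()},
        "counts": counts,
    }
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path


def cmd_simulate(sim_cfg: SimConfig, out_dir) -> dict:
    """Generate a synthetic fixture (tracks, spikes, planted truth)."""
    paths = make_fixture(sim_cfg, out_dir)
    write_manifest(
        out_dir,
        "simulate",
        dataclasses.asdict(sim_cfg),
        sim_cfg.seed,
        {k: p for k, p in paths.items()},
        {"n_frames": sim_cfg.n_frames, "n_bees": 1 + sim_cfg.n_other_bees},
    )
    return {k: str(p) for k, p in paths.items()}


def cmd_detect(tracks_path, cfg: AnalysisConfig, seed, out_dir) -> Path:
    """Detect social-state windows and write the event catalog CSV."""
    tracks = read_tracks(tracks_path, cfg.frame_rate_hz)
    behav = behavior_table(tracks)
    behav["n_within_contact"] = count_within_contact(tracks, FOCAL_ID, cfg.state)
    catalog = classify_all(behav, cfg.frame_rate_hz, cfg.state, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cat_path = out / "events.csv"
    catalog.to_frame().to_csv(cat_path, index=False)
    behav_path = out / "behavior.csv"
    behav.reset_index(names="frame").to_csv(behav_path, index=False, float_format="%.6f")
    counts = {s: len(catalog.by_state(s)) for s in VARIANCE_STATES}
    counts["unclassified_contacts"] = catalog.n_unclassified_contacts
    counts["cross_state_overlaps"] = catalog.cross_state_overlaps
    log.info("detected events: %s", counts)
    write_manifest(
        out_dir, "detect", cfg.to_dict(), seed, {"tracks": tracks_path}, counts
    )
    return cat_path


def cmd_analyze(tracks_path, spikes_path, catalog_path, cfg: AnalysisConfig, out_dir) -> dict:
    """All spike-rate analyses; writes tables and a summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks = read_tracks(tracks_path, cfg.frame_rate_hz)
    spikes = read_spikes(spikes_path)
    catalog = pd.read_csv(catalog_path, dtype={"partner_id": str}, keep_default_na=False)
    behav = behavior_table(tracks)
    rate = bin_spikes(spikes, 0.0, tracks.duration_s, cfg.bin_w_s)
    rates = rate.rates
    n = min(len(rates), len(behav))
    summary: dict = {"n_frames": n, "n_spikes": len(spikes)}

    # walking-speed sanity check: focal vs. the closest co-tracked bees
    other_speeds = []
    for bee in tracks.bee_ids:
        if bee != FOCAL_ID:
            other_speeds.append(walking_speed(tracks.bee(bee), cfg.frame_rate_hz).to_numpy())
    if other_speeds:
        res = compare_focal_vs_others_speed(
            behav["speed_cm_s"].to_numpy(), np.concatenate(other_speeds)
        )
        summary["speed_comparison"] = {"statistic": float(res.statistic), "p": float(res.p)}

    # angular profiles (gravity-relative and relative body axis), whole + quarters
    profiles = []
    for label, col in (("gravity", "gravity_angle_deg"), ("relative_axis", "relative_angle_deg")):
        angles = behav[col].to_numpy(dtype=float)[:n]
        prof = angular_rate_profile(angles, rates[:n], cfg.angle_bin_deg)
        prof.insert(0, "angle_kind", label)
        prof.insert(1, "quarter", 0)  # 0 = whole recording
        profiles.append(prof)
        ok = np.isfinite(angles)
        if ok.any() and rate.counts[:n][ok].sum() > 0:
            ray = rayleigh_test(angles[ok], rate.counts[:n][ok])
            summary[f"rayleigh_{label}"] = {"rbar": ray.statistic, "p": ray.p}
        for q, (aq, rq) in enumerate(
            zip(quarter_split(angles), quarter_split(rates[:n])), start=1
        ):
            prof_q = angular_rate_profile(aq, rq, cfg.angle_bin_deg)
            prof_q.insert(0, "angle_kind", label)
            prof_q.insert(1, "quarter", q)
            profiles.append(prof_q)
    pd.concat(profiles, ignore_index=True).to_csv(out / "angular_profiles.csv", index=False)

    # distance analyses
    dist = behav["distance_cm"].to_numpy(dtype=float)[:n]
    if np.isfinite(dist).sum() >= 10:
        dec = decile_distance_analysis(rates[:n], dist)
        dec.summary.to_csv(out / "decile_distance.csv", index=False)
        summary["decile_top_vs_bottom"] = {
            "statistic": float(dec.test_top_vs_bottom.statistic),
            "p": float(dec.test_top_vs_bottom.p),
        }
        distance_split_profiles(rates[:n], dist, cfg.distance_cut_cm).to_csv(
            out / "distance_split.csv", index=False
        )
    else:
        summary["decile_top_vs_bottom"] = "not_applicable"

    # PETHs and phasic-lead latencies per state
    peth_rows = []
    summary["peth"] = {}
    for state in PETH_STATES:
        syncs = catalog.loc[catalog["state"] == state, "t_sync_s"].to_numpy(dtype=float)
        if len(syncs) == 0:
            summary["peth"][state] = "not_applicable"
            continue
        try:
            p = peth(rate, syncs, cfg.peth_half_span_s, state=state)
        except ValueError:
            summary["peth"][state] = "not_applicable"
            continue
        lat = peak_pre_event_latency(p, cfg.peak_search_s, cfg.peak_smooth_s)
        summary["peth"][state] = {
            "n_events": p.n_events,
            "n_dropped_context": p.n_dropped_context,
            "peak_latency_s": lat,
        }
        peth_rows.append(
            pd.DataFrame(
                {"state": state, "lag_s": p.lags_s, "mean_relative_rate": p.mean_relative_rate}
            )
        )
    if peth_rows:
        pd.concat(peth_rows, ignore_index=True).to_csv(out / "peth.csv", index=False)

    # per-window spike-rate variance and the pairwise state comparisons
    var_samples = {}
    var_rows = []
    for state in VARIANCE_STATES:
        starts = catalog.loc[catalog["state"] == state, "t_start_s"].to_numpy(dtype=float)
        starts = starts[
            (starts >= rate.edges[0]) & (starts + cfg.state.window_s <= rate.edges[-1] + rate.bin_w)
        ]
        if len(starts) == 0:
            continue
        v = window_variances(rate, starts, cfg.state.window_s)
        var_samples[state] = v
        var_rows.append(pd.DataFrame({"state": state, "t_start_s": starts, "variance_hz2": v}))
    if var_rows:
        pd.concat(var_rows, ignore_index=True).to_csv(out / "variance_samples.csv", index=False)
    if sum(len(v) >= 2 for v in var_samples.values()) >= 2:
        comp = pairwise_variance_comparisons(var_samples, cfg.alpha)
        comp.to_csv(out / "variance_comparisons.csv", index=False)
        summary["variance_comparisons"] = int(len(comp))
    else:
        summary["variance_comparisons"] = "not_applicable"

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    write_manifest(
        out_dir,
        "analyze",
        cfg.to_dict(),
        None,
        {"tracks": tracks_path, "spikes": spikes_path, "catalog": catalog_path},
        {"n_variance_states": len(var_samples)},
    )
    return summary


def cmd_report(analysis_dir, figures: bool = False) -> Path:
    """Collect stage outputs into a run report (and optional figures)."""
    adir = Path(analysis_dir)
    summary = json.loads((adir / "summary.json").read_text())
    report = {"summary": summary, "tables": sorted(p.name for p in adir.glob("*.csv"))}
    path = adir / "report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    if figures:
        _make_figures(adir)
    return path


def _make_figures(adir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = adir / "figures"
    figdir.mkdir(exist_ok=True)
    peth_path = adir / "peth.csv"
    if peth_path.exists():
        df = pd.read_csv(peth_path)
        fig, ax = plt.subplots()
        for state, grp in df.groupby("state"):
            ax.plot(grp["lag_s"], grp["mean_relative_rate"], label=state)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("relative spike rate")
        ax.legend()
        fig.savefig(figdir / "peth.png", dpi=120)
        plt.close(fig)
    var_path = adir / "variance_samples.csv"
    if var_path.exists():
        df = pd.read_csv(var_path)
        fig, ax = plt.subplots()
        states = df["state"].unique().tolist()
        ax.boxplot([df.loc[df["state"] == s, "variance_hz2"] for s in states], tick_labels=states)
        ax.set_ylabel("spike-rate variance (Hz$^2$)")
        fig.autofmt_xdate(rotation=30)
        fig.savefig(figdir / "variance_by_state.png", dpi=120)
        plt.close(fig)


def run_all(sim_cfg: SimConfig, cfg: AnalysisConfig, seed, out_dir, figures: bool = False) -> dict:
    """simulate -> detect -> analyze -> report in one call."""
    out = Path(out_dir)
    paths = cmd_simulate(sim_cfg, out / "fixture")
    cat = cmd_detect(paths["tracks"], cfg, seed, out / "detect")
    summary = cmd_analyze(paths["tracks"], paths["spikes"], cat, cfg, out / "analysis")
    cmd_report(out / "analysis", figures=figures)
    return summary
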