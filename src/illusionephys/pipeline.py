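"""Session-level orchestration: simulate -> analyze -> report tables.

``analyze_session`` turns a :class:`~illusionephys.synthetic.RecordingBundle`
into tidy per-unit metric tables (evoked flags, latencies, tuning, indices,
phases, E/I labels, laminar labels), a population phase summary, a
responsive-unit partition, an optional light-on/off comparison and a
behavioral summary.  ``run_pipeline`` drives the whole chain from a config
dict and writes CSV/JSON outputs; ``report`` renders them as markdown and
figures without recomputing any number.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior as beh
from . import circstats as cs
from . import stimgen
from . import synthetic
from . import tuning as tn
from . import unitclass as uc
from .evoked import build_psth, detect_evoked_and_latency

log = logging.getLogger("illusionephys")

__all__ = ["default_config", "validate_config", "run_pipeline", "analyze_session", "report"]


def default_config() -> dict:
    return {
        "seed": 0,
        "n_units": 50,
        "trials_per_condition": 30,
        "stimulus_types": ["NCS", "DBC", "LDG"],
        "directions": list(stimgen.DIRECTIONS_8),
        "temporal_frequency": 2.0,
        "duration_s": 1.0,
        "iti_s": 0.5,
        "run_fraction": 0.3,
        "run_gain": 1.3,
        "light": False,
        "light_gain_ncs": 1.0,
        "light_gain_ldg": 1.0,
        "n_channels": 32,
        "sink_channel": 15,
        "equi_tolerance": 0.1,
        "cohort": {},
    }


_REQUIRED_TYPES = {
    "seed": int,
    "n_units": int,
    "trials_per_condition": int,
    "temporal_frequency": (int, float),
    "run_fraction": (int, float),
    "light": bool,
}


def validate_config(config: dict) -> dict:
    """Merge onto defaults and fail descriptively on schema violations."""
    cfg = default_config()
    unknown = set(config) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(config)
    for key, typ in _REQUIRED_TYPES.items():
        if not isinstance(cfg[key], typ):
            raise ValueError(f"config key {key!r} must be {typ}, got {type(cfg[key]).__name__}")
    if cfg["n_units"] < 1:
        raise ValueError("n_units must be >= 1")
    if not 0.0 <= cfg["run_fraction"] <= 1.0:
        raise ValueError("run_fraction must lie in [0, 1]")
    return cfg


def simulate_from_config(cfg: dict) -> synthetic.RecordingBundle:
    trials = stimgen.condition_table(
        stimulus_types=cfg["stimulus_types"],
        directions=cfg["directions"],
        trials_per_condition=cfg["trials_per_condition"],
        order_seed=cfg["seed"],
        duration_s=cfg["duration_s"],
        iti_s=cfg["iti_s"],
        light=(False, True) if cfg["light"] else (False,),
    )
    units = synthetic.make_cohort(
        cfg["n_units"],
        seed=cfg["seed"],
        n_channels=cfg["n_channels"],
        light_gain_ncs=cfg["light_gain_ncs"],
        light_gain_ldg=cfg["light_gain_ldg"],
        **cfg["cohort"],
    )
    return synthetic.simulate_session(
        units,
        trials,
        seed=cfg["seed"],
        temporal_frequency=cfg["temporal_frequency"],
        run_fraction=cfg["run_fraction"],
        run_gain=cfg["run_gain"],
        n_channels=cfg["n_channels"],
        sink_channel=cfg["sink_channel"],
    )


def _direction_rates(spikes: pd.DataFrame, trials: pd.DataFrame, stim_s: float = 1.0):
    """Mean per-trial stimulus-window rate for every (unit, type, direction, light)."""
    merged = spikes.merge(
        trials[["trial_id", "stimulus_type", "direction", "light", "onset_s"]],
        on="trial_id",
        how="inner",
    )
    rel = merged["t_s"] - merged["onset_s"]
    in_stim = (rel >= 0) & (rel < stim_s)
    counts = (
        merged[in_stim]
        .groupby(["unit_id", "stimulus_type", "direction", "light"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    n_trials = (
        trials.groupby(["stimulus_type", "direction", "light"], observed=True)
        .size()
        .rename("n_trials")
        .reset_index()
    )
    out = counts.merge(n_trials, on=["stimulus_type", "direction", "light"])
    out["rate"] = out["count"] / (out["n_trials"] * stim_s)
    return out


def analyze_session(
    bundle: synthetic.RecordingBundle,
    tf: float | None = None,
    equi_tolerance: float = 0.1,
    directions: tuple[float, ...] = stimgen.DIRECTIONS_8,
) -> dict:
    """Full per-unit and population analysis of one session.

    Returns a dict with keys ``unit_metrics`` (DataFrame), ``partition``,
    ``phase_summary``, ``ei_summary``, ``light_table``, ``behavior`` and
    ``equi_responsive``.
    """
    tf = tf if tf is not None else bundle.meta.get("temporal_frequency", 2.0)
    trials = bundle.trials
    trials_off = trials[~trials["light"].astype(bool)] if "light" in trials else trials
    has_light = "light" in trials and bool(trials["light"].astype(bool).any())
    spikes = bundle.spikes
    unit_ids = sorted(spikes["unit_id"].unique())

    rates = _direction_rates(spikes, trials)
    rates_off = rates[~rates["light"].astype(bool)]

    # E/I classification from waveforms
    tpl_by_unit = {
        uid: uc.tpl(wf, bundle.waveform_fs) for uid, wf in bundle.waveforms.items()
    }
    valid_tpl = {u: v for u, v in tpl_by_unit.items() if v is not None}
    ei = None
    if len(valid_tpl) >= 50:
        ei = uc.ei_threshold(list(valid_tpl.values()))
        ei_labels = dict(zip(valid_tpl.keys(), ei["labels"]))
    else:
        ei_labels = {}

    # laminar labels from the session CSD
    csd_map = uc.csd(bundle.lfp)
    gt_channel = {u.unit_id: u.channel for u in bundle.ground_truth}

    records = []
    phases = []
    for uid in unit_ids:
        rec: dict = {"unit_id": uid}
        sub = rates_off[rates_off["unit_id"] == uid]

        def curve(stype):
            resp = np.zeros(len(directions))
            s = sub[sub["stimulus_type"] == stype].set_index("direction")["rate"]
            for i, d in enumerate(directions):
                resp[i] = s.get(d, 0.0)
            return resp

        ldg_curve = curve("LDG")
        ncs_curve = curve("NCS")
        # baseline from a pooled pre-onset PSTH (cheap: use LDG psth baseline)
        pref_dir = float(directions[int(np.argmax(ldg_curve))]) if ldg_curve.any() else directions[0]

        psths = {}
        for stype in ("LDG", "NCS", "DBC"):
            cond = {"stimulus_type": stype}
            if stype in ("LDG", "NCS"):
                cond["direction"] = pref_dir
            if "light" in trials:
                cond["light"] = False
            try:
                psths[stype] = build_psth(spikes, trials, cond, unit_id=uid)
            except ValueError:
                psths[stype] = None

        for stype, ps in psths.items():
            key = stype.lower()
            if ps is None:
                rec[f"evoked_{key}"] = False
                rec[f"latency_{key}"] = np.nan
                continue
            det = detect_evoked_and_latency(ps)
            rec[f"evoked_{key}"] = det["evoked"]
            rec[f"latency_{key}"] = det["latency_ms"] if det["latency_ms"] is not None else np.nan
            rec[f"baseline_{key}"] = ps.baseline_rate

        base = psths["LDG"].baseline_rate if psths["LDG"] is not None else 0.0
        rate_ldg = max(float(ldg_curve.max()) - base, 0.0)
        rate_ncs_at_pref = max(float(ncs_curve[int(np.argmax(ldg_curve))]) - base, 0.0)
        rec["rate_ldg"] = rate_ldg
        rec["rate_ncs"] = rate_ncs_at_pref
        if rate_ldg + rate_ncs_at_pref > 0:
            rec["igr"] = tn.igr(rate_ncs_at_pref, rate_ldg)
        else:
            rec["igr"] = np.nan

        pa_ldg = tn.preferred_angle(tn.TuningCurve(np.asarray(directions), ldg_curve))
        pa_ncs = tn.preferred_angle(tn.TuningCurve(np.asarray(directions), ncs_curve))
        rec["pref_angle_ldg"] = pa_ldg["angle_deg"]
        rec["pref_angle_ncs"] = pa_ncs["angle_deg"]
        rec["untuned_ldg"] = pa_ldg["untuned"]
        rec["delta_pref"] = tn.delta_preferred(pa_ncs["angle_deg"], pa_ldg["angle_deg"])

        if psths["LDG"] is not None and psths["NCS"] is not None:
            comp_ldg = tn.f0_f1(psths["LDG"], tf)
            comp_ncs = tn.f0_f1(psths["NCS"], tf)
            rec["f0_ldg"] = comp_ldg["f0"]
            rec["f1_ldg"] = comp_ldg["f1"]
            rec["f0_ncs"] = comp_ncs["f0"]
            rec["f1_ncs"] = comp_ncs["f1"]
            rec["f1_dominant"] = bool(comp_ldg["f1_dominant"] and comp_ncs["f1_dominant"])
            rec["csm"] = tn.csm(comp_ldg["f1"], comp_ldg["f0"]) if (
                comp_ldg["f1"] + comp_ldg["f0"]
            ) > 0 else np.nan
            if comp_ldg["f1"] + comp_ncs["f1"] > 0:
                rec["igr_f1"] = tn.igr_f1(comp_ncs["f1"], comp_ldg["f1"])
            else:
                rec["igr_f1"] = np.nan
            if rec["f1_dominant"] and comp_ldg["f1"] > 0 and comp_ncs["f1"] > 0:
                shift = cs.f1_phase_shift(psths["NCS"], psths["LDG"], tf)
                rec["phase_shift_deg"] = shift
                phases.append({"unit_id": uid, "phase_shift_deg": shift})
            else:
                rec["phase_shift_deg"] = np.nan

        rec["tpl_ms"] = tpl_by_unit.get(uid, np.nan)
        rec["cell_class"] = ei_labels.get(uid, None)
        ch = gt_channel.get(uid)
        rec["depth_label"] = (
            uc.assign_relative_depth(csd_map, ch) if ch is not None else None
        )
        records.append(rec)

    metrics = pd.DataFrame.from_records(records)

    both = metrics["evoked_ldg"] & metrics["evoked_ncs"]
    partition = pd.DataFrame(
        {
            "category": ["both", "LDG_only", "NCS_only", "none"],
            "count": [
                int(both.sum()),
                int((metrics["evoked_ldg"] & ~metrics["evoked_ncs"]).sum()),
                int((~metrics["evoked_ldg"] & metrics["evoked_ncs"]).sum()),
                int((~metrics["evoked_ldg"] & ~metrics["evoked_ncs"]).sum()),
            ],
        }
    )

    phase_summary = {"n": 0}
    if len(phases) >= 2:
        ph = [p["phase_shift_deg"] for p in phases]
        ci = cs.circular_mean_ci(ph)
        z, p = cs.rayleigh_test(ph)
        phase_summary = {
            "n": len(ph),
            "mean_deg": ci["mean_deg"],
            "ci_deg": list(ci["ci_deg"]),
            "rayleigh_z": z,
            "rayleigh_p": p,
        }

    ei_summary = None
    if ei is not None:
        grp = metrics.dropna(subset=["igr"]).groupby("cell_class")
        ei_summary = {
            "threshold_ms": ei["threshold_ms"],
            "mean_igr": {k: float(v) for k, v in grp["igr"].mean().items()},
            "n": {k: int(v) for k, v in metrics["cell_class"].value_counts().items()},
        }

    light_table = None
    if has_light:
        light_table = _light_comparison(spikes, trials, metrics, directions)

    behavior_summary = _behavior_summary(bundle)

    equi = None
    if "csm" in metrics:
        equi = metrics.pipe(
            lambda m: m[np.isfinite(m["rate_ncs"] + m["rate_ldg"])]
        )
        from .evoked import select_equiresponsive

        equi = select_equiresponsive(equi, tolerance=equi_tolerance)

    return {
        "unit_metrics": metrics,
        "partition": partition,
        "phase_summary": phase_summary,
        "ei_summary": ei_summary,
        "light_table": light_table,
        "behavior": behavior_summary,
        "equi_responsive": equi,
    }


def _light_comparison(spikes, trials, metrics, directions) -> pd.DataFrame:
    """Per-unit light-on vs light-off evoked rates for NCS and LDG, with a
    two-sided sign test on the per-unit deltas."""
    rates = _direction_rates(spikes, trials)
    rows = []
    for stype in ("NCS", "LDG"):
        deltas = []
        for _, m in metrics.iterrows():
            uid = m["unit_id"]
            pref = m["pref_angle_ldg"]
            # snap to nearest sampled direction
            d8 = np.asarray(directions)
            pref_dir = float(d8[np.argmin(np.abs((d8 - pref + 180) % 360 - 180))])
            sub = rates[
                (rates["unit_id"] == uid)
                & (rates["stimulus_type"] == stype)
                & (rates["direction"] == pref_dir)
            ]
            off = sub[~sub["light"].astype(bool)]["rate"]
            on = sub[sub["light"].astype(bool)]["rate"]
            if len(off) and len(on):
                deltas.append(float(on.iloc[0] - off.iloc[0]))
        deltas = np.asarray(deltas)
        n_neg = int((deltas < 0).sum())
        n_nonzero = int((deltas != 0).sum())
        p = stats.binomtest(n_neg, n_nonzero, 0.5).pvalue if n_nonzero else np.nan
        rows.append(
            {
                "stimulus_type": stype,
                "n_units": len(deltas),
                "mean_delta": float(np.mean(deltas)) if len(deltas) else np.nan,
                "n_negative": n_neg,
                "sign_test_p": float(p),
            }
        )
    return pd.DataFrame.from_records(rows)


def _behavior_summary(bundle: synthetic.RecordingBundle) -> pd.DataFrame:
    trials = bundle.trials
    t_speed, speed = beh.disk_speed(
        bundle.encoder["t_s"].to_numpy(), bundle.encoder["voltage"].to_numpy()
    )
    run_still = beh.classify_run_still(t_speed, speed, trials)
    di = beh.dilation_index(
        bundle.pupil["t_s"].to_numpy(), bundle.pupil["diameter"].to_numpy(), trials
    )
    per_trial = trials[["trial_id", "stimulus_type"]].copy()
    per_trial["run_still"] = run_still.reindex(per_trial["trial_id"]).to_numpy()
    per_trial["dilation_index"] = di.reindex(per_trial["trial_id"]).to_numpy()
    summary = (
        per_trial.groupby("stimulus_type")
        .agg(
            n_trials=("trial_id", "size"),
            frac_run=("run_still", lambda s: float((s == "run").mean())),
            mean_dilation=("dilation_index", "mean"),
        )
        .reset_index()
    )
    summary.attrs["per_trial"] = per_trial
    return summary


def run_pipeline(config: dict, outdir) -> Path:
    """Simulate a session from ``config``, analyze it and write all outputs."""
    cfg = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("simulating session (%d units, seed %d)", cfg["n_units"], cfg["seed"])
    bundle = simulate_from_config(cfg)
    log.info("analyzing session")
    res = analyze_session(bundle, tf=cfg["temporal_frequency"], equi_tolerance=cfg["equi_tolerance"])

    res["unit_metrics"].to_csv(out / "unit_metrics.csv", index=False)
    res["partition"].to_csv(out / "partition.csv", index=False)
    (out / "phase_summary.json").write_text(json.dumps(res["phase_summary"], indent=2))
    if res["ei_summary"] is not None:
        (out / "ei_summary.json").write_text(json.dumps(res["ei_summary"], indent=2))
    if res["light_table"] is not None:
        res["light_table"].to_csv(out / "light_table.csv", index=False)
    res["behavior"].to_csv(out / "behavior_summary.csv", index=False)
    res["behavior"].attrs["per_trial"].to_csv(out / "behavior_per_trial.csv", index=False)
    if res["equi_responsive"] is not None:
        res["equi_responsive"].to_csv(out / "equi_responsive.csv", index=False)

    import illusionephys

    (out / "run_log.json").write_text(
        json.dumps({"config": cfg, "version": illusionephys.__version__}, indent=2)
    )
    return out


def report(results_dir, outdir=None) -> Path:
    """Render markdown + figures from pipeline outputs (no recomputation)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = Path(results_dir)
    out = Path(outdir) if outdir else res
    required = ["unit_metrics.csv", "partition.csv", "phase_summary.json", "behavior_summary.csv"]
    missing = [f for f in required if not (res / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing pipeline outputs: {missing}")
    out.mkdir(parents=True, exist_ok=True)

    metrics = pd.read_csv(res / "unit_metrics.csv")
    partition = pd.read_csv(res / "partition.csv")
    phase = json.loads((res / "phase_summary.json").read_text())
    behavior = pd.read_csv(res / "behavior_summary.csv")

    # polar phase histogram
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    ph = metrics["phase_shift_deg"].dropna().to_numpy()
    if len(ph):
        ax.hist(np.deg2rad(ph), bins=24)
    ax.set_title("F1 phase shift (NCS - LDG)")
    fig.savefig(out / "phase_polar.png", dpi=120)
    plt.close(fig)

    # tuning panel: delta preferred angle histogram
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(metrics["delta_pref"].dropna(), bins=24)
    ax.set_xlabel("preferred angle NCS - LDG (deg)")
    ax.set_ylabel("units")
    fig.savefig(out / "delta_pref.png", dpi=120)
    plt.close(fig)

    # dilation index bars
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(behavior["stimulus_type"], behavior["mean_dilation"])
    ax.set_ylabel("mean dilation index")
    fig.savefig(out / "dilation_bars.png", dpi=120)
    plt.close(fig)

    # CSD heatmap if available
    csd_png = ""
    if (res / "csd.npy").exists():
        csd_map = np.load(res / "csd.npy")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.imshow(csd_map, aspect="auto", cmap="RdBu_r")
        ax.set_xlabel("time (samples)")
        ax.set_ylabel("channel")
        fig.savefig(out / "csd_heatmap.png", dpi=120)
        plt.close(fig)
        csd_png = "\n![CSD](csd_heatmap.png)\n"

    lines = [
        "# Session report",
        "",
        "## Responsive-unit partition",
        partition.to_markdown(index=False),
        "",
        "## Phase summary",
        "```json",
        json.dumps(phase, indent=2),
        "```",
        "",
        "## Behavior",
        behavior.to_markdown(index=False),
        "",
        "![phase](phase_polar.png)",
        "![delta pref](delta_pref.png)",
        "![dilation](dilation_bars.png)",
        csd_png,
    ]
    (out / "report.md").write_text("\n".join(lines))
    return out / "report.md"
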