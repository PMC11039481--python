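"""Synthetic session generator with serialized ground truth.

Produces a full :class:`RecordingBundle` -- spike tables, mean waveforms,
laminar LFP, rotary-encoder voltage and a pupil trace -- from a cohort of
:class:`GroundTruthUnit` parameter sets, so that every downstream analysis
stage can be validated against known ground truth without any recorded data.

Spiking model
-------------
Spikes are drawn from an inhomogeneous Poisson process discretized at 1 ms:

``rate(t) = baseline + gain * evoked * tuning(direction) * env(t - latency)
            * (1 + f1_ratio * cos(2*pi*TF*t - phase))``

where ``tuning`` is a peak-normalized von-Mises direction tuning curve,
``env`` is a step-onset envelope with an exponential onset transient, and
the sinusoidal modulation is locked to stimulus time (not latency-shifted)
so the injected response phase is recovered directly by Fourier analysis.
Diffusion-blocked (DBC) trials draw baseline spikes only.  Light-on trials
scale the NCS (and optionally LDG) evoked component multiplicatively.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruthUnit",
    "RecordingBundle",
    "make_cohort",
    "simulate_unit_spikes",
    "simulate_waveforms",
    "simulate_lfp_csd",
    "simulate_behavior",
    "simulate_session",
    "von_mises_tuning",
]

WAVEFORM_FS = 30_000.0  # Hz
LFP_FS = 1_000.0        # Hz


@dataclass
class GroundTruthUnit:
    """Ground-truth parameters of one simulated unit."""

    unit_id: int
    preferred_direction: float      # deg
    tuning_width: float             # deg, FWHM of the von-Mises tuning curve
    baseline_rate: float            # sp/s
    evoked_rate_ldg: float          # sp/s at preferred direction
    evoked_rate_ncs: float
    latency_ldg: float              # ms
    latency_ncs: float
    latency_rect: float
    f1_ratio: float                 # 0..1 modulation depth
    response_phase_ldg: float       # deg
    phase_offset_ncs: float         # deg, NCS phase minus LDG phase
    cell_class: str                 # {"E", "I"}
    tpl_ms: float                   # trough-to-peak latency of the waveform
    rf_center: tuple[float, float]  # deg
    rf_sigma: tuple[float, float]   # deg
    surround_index_true: float
    depth_um: float
    channel: int
    light_gain_ncs: float = 1.0
    light_gain_ldg: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.evoked_rate_ldg < 0 or self.evoked_rate_ncs < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.f1_ratio <= 1.0:
            raise ValueError("f1_ratio must lie in [0, 1]")
        self.response_phase_ldg = float(np.mod(self.response_phase_ldg, 360.0))
        self.phase_offset_ncs = float(np.mod(self.phase_offset_ncs, 360.0))

    @property
    def igr_true(self) -> float:
        num = self.evoked_rate_ncs - self.evoked_rate_ldg
        return num / (self.evoked_rate_ncs + self.evoked_rate_ldg)


@dataclass
class RecordingBundle:
    """One synthetic (or imported) session."""

    spikes: pd.DataFrame                 # unit_id, trial_id, t_s
    trials: pd.DataFrame                 # trial_id, stimulus_type, direction, light, onset_s, offset_s, running
    waveforms: dict[int, np.ndarray]     # unit_id -> mean waveform (samples)
    waveform_fs: float
    lfp: np.ndarray                      # channels x time
    lfp_fs: float
    encoder: pd.DataFrame                # t_s, voltage
    pupil: pd.DataFrame                  # t_s, diameter
    ground_truth: list[GroundTruthUnit] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.spikes.to_csv(out / "spikes.csv", index=False)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.encoder.to_csv(out / "encoder.csv", index=False)
        self.pupil.to_csv(out / "pupil.csv", index=False)
        np.save(out / "lfp.npy", self.lfp)
        ids = sorted(self.waveforms)
        np.save(out / "waveforms.npy", np.stack([self.waveforms[i] for i in ids]))
        payload = {
            "waveform_unit_ids": ids,
            "waveform_fs": self.waveform_fs,
            "lfp_fs": self.lfp_fs,
            "meta": self.meta,
            "units": [asdict(u) for u in self.ground_truth],
        }
        (out / "ground_truth.json").write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, indir) -> "RecordingBundle":
        ind = Path(indir)
        payload = json.loads((ind / "ground_truth.json").read_text())
        wf = np.load(ind / "waveforms.npy")
        units = []
        for u in payload["units"]:
            u["rf_center"] = tuple(u["rf_center"])
            u["rf_sigma"] = tuple(u["rf_sigma"])
            units.append(GroundTruthUnit(**u))
        return cls(
            spikes=pd.read_csv(ind / "spikes.csv"),
            trials=pd.read_csv(ind / "trials.csv"),
            waveforms={i: wf[k] for k, i in enumerate(payload["waveform_unit_ids"])},
            waveform_fs=payload["waveform_fs"],
            lfp=np.load(ind / "lfp.npy"),
            lfp_fs=payload["lfp_fs"],
            encoder=pd.read_csv(ind / "encoder.csv"),
            pupil=pd.read_csv(ind / "pupil.csv"),
            ground_truth=units,
            meta=payload.get("meta", {}),
        )


def von_mises_tuning(direction_deg, preferred_deg: float, width_deg: float) -> np.ndarray:
    """Peak-normalized von-Mises direction tuning, exp(kappa*(cos(d)-1)).

    ``width_deg`` is the kappa-equivalent circular dispersion,
    ``kappa = 1 / width_rad**2`` (the curve's approximate Gaussian sigma).
    """
    w = np.deg2rad(width_deg)
    kappa = 1.0 / (w * w)
    d = np.deg2rad(np.asarray(direction_deg, dtype=float) - preferred_deg)
    return np.exp(kappa * (np.cos(d) - 1.0))


def make_cohort(
    n_units: int,
    seed: int = 0,
    *,
    frac_inhibitory: float = 0.3,
    frac_simple: float = 0.4,
    igr_range: tuple[float, float] = (-0.5, 0.5),
    total_evoked_range: tuple[float, float] = (50.0, 90.0),
    baseline_range: tuple[float, float] = (2.0, 8.0),
    tuning_width_range: tuple[float, float] = (30.0, 45.0),
    latency_ldg_range: tuple[float, float] = (55.0, 75.0),
    latency_gap_ms: float = 35.0,
    latency_rect_range: tuple[float, float] = (35.0, 50.0),
    phase_offset_mean: float = 180.0,
    phase_offset_sd: float = 20.0,
    tpl_i: tuple[float, float] = (0.25, 0.04),
    tpl_e: tuple[float, float] = (0.65, 0.08),
    canvas_deg: float = 35.0,
    n_channels: int = 32,
    channel_spacing_um: float = 25.0,
    light_gain_ncs: float = 1.0,
    light_gain_ldg: float = 1.0,
) -> list[GroundTruthUnit]:
    """Draw a cohort of ground-truth units with randomized parameters.

    Ground-truth IGR is uniform over ``igr_range``; NCS and LDG evoked
    rates are derived from it and a random total.  The injected
    NCS-vs-LDG latency gap is exactly ``latency_gap_ms`` for every unit.
    """
    rng = np.random.default_rng(seed)
    units: list[GroundTruthUnit] = []
    for uid in range(n_units):
        is_i = rng.random() < frac_inhibitory
        is_simple = rng.random() < frac_simple
        g = rng.uniform(*igr_range)
        total = rng.uniform(*total_evoked_range)
        lat_ldg = rng.uniform(*latency_ldg_range)
        mu, sd = tpl_i if is_i else tpl_e
        channel = int(rng.integers(0, n_channels))
        units.append(
            GroundTruthUnit(
                unit_id=uid,
                preferred_direction=float(rng.uniform(0.0, 360.0)),
                tuning_width=float(rng.uniform(*tuning_width_range)),
                baseline_rate=float(rng.uniform(*baseline_range)),
                evoked_rate_ldg=float(total * (1.0 - g) / 2.0),
                evoked_rate_ncs=float(total * (1.0 + g) / 2.0),
                latency_ldg=float(lat_ldg),
                latency_ncs=float(lat_ldg + latency_gap_ms),
                latency_rect=float(rng.uniform(*latency_rect_range)),
                f1_ratio=float(rng.uniform(0.7, 0.95) if is_simple else rng.uniform(0.0, 0.2)),
                response_phase_ldg=float(rng.uniform(0.0, 360.0)),
                phase_offset_ncs=float(rng.normal(phase_offset_mean, phase_offset_sd)),
                cell_class="I" if is_i else "E",
                tpl_ms=float(np.clip(rng.normal(mu, sd), 0.08, 1.5)),
                rf_center=(
                    float(rng.uniform(-canvas_deg / 2.5, canvas_deg / 2.5)),
                    float(rng.uniform(-canvas_deg / 2.5, canvas_deg / 2.5)),
                ),
                rf_sigma=(float(rng.uniform(2.0, 4.0)), float(rng.uniform(2.0, 4.0))),
                surround_index_true=float(rng.uniform(-0.2, 0.7)),
                depth_um=float(channel * channel_spacing_um),
                channel=channel,
                light_gain_ncs=light_gain_ncs,
                light_gain_ldg=light_gain_ldg,
            )
        )
    return units


def _onset_envelope(t_rel: np.ndarray, latency_s: float, onset_boost: float, tau_s: float) -> np.ndarray:
    """Step at ``latency_s`` with an exponential onset transient."""
    u = t_rel - latency_s
    env = np.zeros_like(t_rel)
    on = u >= 0
    env[on] = 1.0 + onset_boost * np.exp(-u[on] / tau_s)
    return env


def simulate_unit_spikes(
    unit: GroundTruthUnit,
    trials: pd.DataFrame,
    seed: int = 0,
    *,
    temporal_frequency: float = 2.0,
    run_gain: float = 1.0,
    window_rel: tuple[float, float] = (-0.4, 1.1),
    bin_s: float = 0.001,
    onset_boost: float = 1.0,
    onset_tau_s: float = 0.05,
) -> pd.DataFrame:
    """Inhomogeneous-Poisson spike table for one unit across all trials.

    ``trials`` must have columns stimulus_type, direction, light, onset_s;
    an optional boolean ``running`` column applies the multiplicative
    ``run_gain`` to the evoked component of that trial.  Returns a table
    with columns unit_id, trial_id, t_s (absolute session time).
    """
    rng = np.random.default_rng(seed)
    trials = trials.reset_index(drop=True)
    if "light" not in trials:
        trials = trials.assign(light=False)
    if "direction" not in trials:
        trials = trials.assign(direction=0.0)
    n_bins = int(round((window_rel[1] - window_rel[0]) / bin_s))
    t_rel = window_rel[0] + (np.arange(n_bins) + 0.5) * bin_s
    stim = (t_rel >= 0.0) & (t_rel < 1.0)

    running = trials["running"].to_numpy(bool) if "running" in trials else np.zeros(len(trials), bool)
    gains = np.where(running, run_gain, 1.0)

    out_times: list[np.ndarray] = []
    out_trials: list[np.ndarray] = []
    clipped = False
    for (stype, direction, light), sub in trials.groupby(
        ["stimulus_type", "direction", "light"], sort=False
    ):
        rate = np.full(n_bins, unit.baseline_rate)
        if stype in ("NCS", "LDG"):
            if stype == "NCS":
                evoked = unit.evoked_rate_ncs
                lat = unit.latency_ncs / 1000.0
                phase = unit.response_phase_ldg + unit.phase_offset_ncs
                if light:
                    evoked *= unit.light_gain_ncs
            else:
                evoked = unit.evoked_rate_ldg
                lat = unit.latency_ldg / 1000.0
                phase = unit.response_phase_ldg
                if light:
                    evoked *= unit.light_gain_ldg
            tun = float(von_mises_tuning(direction, unit.preferred_direction, unit.tuning_width))
            env = _onset_envelope(t_rel, lat, onset_boost, onset_tau_s)
            mod = 1.0 + unit.f1_ratio * np.cos(
                2.0 * np.pi * temporal_frequency * t_rel - np.deg2rad(phase)
            )
            drive = evoked * tun * env * mod
            drive[~stim] = 0.0
            rate = rate + drive
        elif stype == "RECT":
            lat = unit.latency_rect / 1000.0
            env = _onset_envelope(t_rel, lat, onset_boost, onset_tau_s)
            drive = unit.evoked_rate_ldg * env
            drive[~stim] = 0.0
            rate = rate + drive
        # DBC (and anything unrecognized): baseline only
        if np.any(rate < 0):
            clipped = True
            rate = np.clip(rate, 0.0, None)
        idx = sub.index.to_numpy()
        lam = rate[None, :] * bin_s * gains[idx][:, None]
        counts = rng.poisson(lam)
        tr_idx, bin_idx = np.nonzero(counts)
        reps = counts[tr_idx, bin_idx]
        tr_idx = np.repeat(tr_idx, reps)
        bin_idx = np.repeat(bin_idx, reps)
        jitter = rng.uniform(-0.5, 0.5, size=len(bin_idx)) * bin_s
        onsets = sub["onset_s"].to_numpy()[tr_idx]
        t_abs = onsets + t_rel[bin_idx] + jitter
        out_times.append(t_abs)
        out_trials.append(sub["trial_id"].to_numpy()[tr_idx])
    if clipped:
        warnings.warn("negative instantaneous rate clipped at 0", stacklevel=2)
    t_all = np.concatenate(out_times) if out_times else np.array([])
    tr_all = np.concatenate(out_trials) if out_trials else np.array([], dtype=int)
    order = np.argsort(t_all, kind="stable")
    return pd.DataFrame(
        {
            "unit_id": np.full(len(t_all), unit.unit_id, dtype=int),
            "trial_id": tr_all[order].astype(int),
            "t_s": t_all[order],
        }
    )


def simulate_waveforms(
    units: list[GroundTruthUnit],
    seed: int = 0,
    *,
    fs: float = WAVEFORM_FS,
    duration_ms: float = 4.0,
    noise_sd: float = 0.005,
) -> dict[int, np.ndarray]:
    """Difference-of-Gaussians mean waveforms realizing each unit's TPL.

    The trough and the following peak are separated by exactly
    ``unit.tpl_ms``; component widths are kept narrow relative to the
    separation so the extrema are not shifted by overlap.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms / 1000.0 * fs))
    t = np.arange(n) / fs * 1000.0  # ms
    out = {}
    for u in units:
        t0 = duration_ms * 0.3
        sigma = max(u.tpl_ms / 5.0, 0.02)
        w = -np.exp(-((t - t0) ** 2) / (2 * sigma**2)) + 0.5 * np.exp(
            -((t - t0 - u.tpl_ms) ** 2) / (2 * (sigma * 1.4) ** 2)
        )
        w = w + rng.normal(0.0, noise_sd, size=n)
        out[u.unit_id] = w
    return out


def simulate_lfp_csd(
    n_channels: int,
    sink_channel: int,
    seed: int = 0,
    *,
    duration_s: float = 2.0,
    fs: float = LFP_FS,
    onset_s: float = 0.5,
    sink_sigma_ch: float = 1.5,
    amplitude: float = 50.0,
    noise_sd: float = 0.0,
    linear_gradient: float = 0.0,
) -> np.ndarray:
    """Laminar LFP whose second spatial derivative has a localized sink.

    The voltage profile is a negative depth-Gaussian centered on
    ``sink_channel`` times a stimulus-locked alpha-function transient,
    plus an optional linear-in-depth component (which contributes nothing
    to the CSD) and white noise.
    """
    if not 0 <= sink_channel < n_channels:
        raise ValueError("sink_channel out of range")
    rng = np.random.default_rng(seed)
    n_t = int(round(duration_s * fs))
    t = np.arange(n_t) / fs
    u = np.clip(t - onset_s, 0.0, None)
    tau = 0.030
    s = (u / tau) * np.exp(1.0 - u / tau)  # alpha function, peak 1 at u=tau
    z = np.arange(n_channels)
    g = np.exp(-((z - sink_channel) ** 2) / (2 * sink_sigma_ch**2))
    lfp = -amplitude * g[:, None] * s[None, :]
    lfp = lfp + linear_gradient * z[:, None]
    if noise_sd > 0:
        lfp = lfp + rng.normal(0.0, noise_sd, size=lfp.shape)
    return lfp


def simulate_behavior(
    trials: pd.DataFrame,
    run_fraction: float = 0.3,
    pupil_effects: dict[str, float] | None = None,
    seed: int = 0,
    *,
    encoder_fs: float = 1000.0,
    pupil_fs: float = 50.0,
    disk_diameter_cm: float = 20.0,
    run_speed_cms: float = 3.0,
    pupil_baseline: float = 2.0,
    pupil_noise_sd: float = 0.005,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Rotary-encoder voltage and pupil trace aligned to the trial table.

    A ``run_fraction`` of trials carry sustained running (speed
    ``run_speed_cms``) covering the classification window; the encoder
    voltage wraps at 5 V.  The pupil shows a per-condition transient with
    amplitude ``pupil_effects[stimulus_type]`` (fractional change) during
    the 1 s stimulus.  Returns (encoder, pupil, run_flags).
    """
    if pupil_effects is None:
        pupil_effects = {"NCS": 0.06, "LDG": -0.08, "DBC": 0.0}
    rng = np.random.default_rng(seed)
    session_end = trials["offset_s"].max() + 1.0
    n_enc = int(round(session_end * encoder_fs))
    t_enc = np.arange(n_enc) / encoder_fs

    n_trials = len(trials)
    run_flags = np.zeros(n_trials, dtype=bool)
    n_run = int(round(run_fraction * n_trials))
    if n_run > 0:
        run_flags[rng.choice(n_trials, size=n_run, replace=False)] = True

    speed = np.zeros(n_enc)
    circumference_per_deg = np.pi * disk_diameter_cm / 360.0  # cm per degree
    for onset, flag in zip(trials["onset_s"].to_numpy(), run_flags):
        if not flag:
            continue
        i0 = int((onset - 0.5) * encoder_fs)
        i1 = int((onset + 1.0) * encoder_fs)
        speed[max(i0, 0) : min(i1, n_enc)] = run_speed_cms
    omega = speed / circumference_per_deg  # deg/s
    angle = np.cumsum(omega) / encoder_fs
    voltage = np.mod(angle, 360.0) / 360.0 * 5.0
    encoder = pd.DataFrame({"t_s": t_enc, "voltage": voltage})

    n_pup = int(round(session_end * pupil_fs))
    t_pup = np.arange(n_pup) / pupil_fs
    pupil = np.full(n_pup, pupil_baseline)
    for onset, stype in zip(trials["onset_s"].to_numpy(), trials["stimulus_type"]):
        amp = pupil_effects.get(str(stype), 0.0)
        if amp == 0.0:
            continue
        sel = (t_pup >= onset) & (t_pup < onset + 1.2)
        u = (t_pup[sel] - onset) / 1.2
        pupil[sel] += pupil_baseline * amp * np.sin(np.pi * u) ** 2
    pupil = pupil + rng.normal(0.0, pupil_noise_sd, size=n_pup)
    pupil_df = pd.DataFrame({"t_s": t_pup, "diameter": pupil})
    return encoder, pupil_df, run_flags


def simulate_session(
    units: list[GroundTruthUnit],
    trials: pd.DataFrame,
    seed: int = 0,
    *,
    temporal_frequency: float = 2.0,
    run_fraction: float = 0.0,
    run_gain: float = 1.3,
    pupil_effects: dict[str, float] | None = None,
    n_channels: int = 32,
    sink_channel: int = 15,
    lfp_noise_sd: float = 1.0,
) -> RecordingBundle:
    """Assemble a complete synthetic session for a cohort of units."""
    root = np.random.SeedSequence(seed)
    s_beh, s_wave, s_lfp, *s_units = root.spawn(3 + len(units))
    encoder, pupil, run_flags = simulate_behavior(
        trials,
        run_fraction=run_fraction,
        pupil_effects=pupil_effects,
        seed=np.random.default_rng(s_beh).integers(2**31),
    )
    trials = trials.copy()
    trials["running"] = run_flags
    spike_tables = [
        simulate_unit_spikes(
            u,
            trials,
            seed=np.random.default_rng(su).integers(2**31),
            temporal_frequency=temporal_frequency,
            run_gain=run_gain,
        )
        for u, su in zip(units, s_units)
    ]
    spikes = pd.concat(spike_tables, ignore_index=True)
    waveforms = simulate_waveforms(units, seed=np.random.default_rng(s_wave).integers(2**31))
    lfp = simulate_lfp_csd(
        n_channels,
        sink_channel,
        seed=np.random.default_rng(s_lfp).integers(2**31),
        noise_sd=lfp_noise_sd,
    )
    return RecordingBundle(
        spikes=spikes,
        trials=trials,
        waveforms=waveforms,
        waveform_fs=WAVEFORM_FS,
        lfp=lfp,
        lfp_fs=LFP_FS,
        encoder=encoder,
        pupil=pupil,
        ground_truth=list(units),
        meta={
            "seed": seed,
            "temporal_frequency": temporal_frequency,
            "run_gain": run_gain,
            "sink_channel": sink_channel,
        },
    )
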