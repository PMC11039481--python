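"""Running-speed extraction and pupillometry.

The rotary-encoder voltage (0-5 V mapped to 0-360 degrees of disk angle,
wrapping at 5 V) is converted to linear rim speed ``|d(angle)/dt| * pi *
diameter / 360``.  Trials are classified "run" when the mean speed over
the 500 ms window starting 300 ms before stimulus onset exceeds 1 cm/s
(strict inequality).

Two distinct pupil baselines coexist deliberately: trace normalization uses
the 300 ms pre-onset mean, while the dilation index uses a 0.2 s pre-onset
baseline against the 1 s stimulus window on the raw (unnormalized) trace.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "disk_speed",
    "classify_run_still",
    "normalize_pupil",
    "dilation_index",
]


def disk_speed(
    t_s: np.ndarray,
    voltage: np.ndarray,
    disk_diameter_cm: float = 20.0,
    out_fs: float = 300.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear rim speed (cm/s) from the encoder voltage trace.

    The trace is resampled to ``out_fs``, mapped to disk angle, unwrapped
    across the 5 V -> 0 V discontinuity and differentiated.  Out-of-range
    voltages are clipped with a warning.
    """
    t = np.asarray(t_s, dtype=float)
    v = np.asarray(voltage, dtype=float)
    if np.any(v < 0.0) or np.any(v > 5.0):
        warnings.warn("encoder voltage outside [0, 5] V clipped", stacklevel=2)
        v = np.clip(v, 0.0, 5.0)
    t_out = np.arange(t[0], t[-1], 1.0 / out_fs)
    v_rs = np.interp(t_out, t, v)
    angle = v_rs / 5.0 * 360.0
    angle = np.unwrap(angle, period=360.0)
    dtheta = np.gradient(angle, t_out)
    speed = np.abs(dtheta) * (np.pi * disk_diameter_cm / 360.0)
    return t_out, speed


def classify_run_still(
    speed_t: np.ndarray,
    speed: np.ndarray,
    trials: pd.DataFrame,
    window_s: tuple[float, float] = (-0.3, 0.2),
    threshold_cms: float = 1.0,
) -> pd.Series:
    """Per-trial run/still labels from the mean pre/peri-onset speed."""
    labels = []
    for onset in trials["onset_s"]:
        sel = (speed_t >= onset + window_s[0]) & (speed_t < onset + window_s[1])
        mean_speed = float(np.mean(speed[sel])) if sel.any() else 0.0
        labels.append("run" if mean_speed > threshold_cms else "still")
    return pd.Series(labels, index=trials["trial_id"].to_numpy(), name="run_still")


def normalize_pupil(
    pupil_t: np.ndarray,
    pupil: np.ndarray,
    trials: pd.DataFrame,
    baseline_s: float = 0.3,
    window_s: tuple[float, float] = (-0.3, 1.5),
) -> pd.DataFrame:
    """Baseline-normalized per-trial pupil traces, ``(p - b) / b``.

    ``b`` is the mean pupil size over ``baseline_s`` before onset.  Trials
    whose baseline contains missing samples are dropped (and reported).
    """
    t = np.asarray(pupil_t, dtype=float)
    p = np.asarray(pupil, dtype=float)
    rows = []
    dropped = []
    for tid, onset in zip(trials["trial_id"], trials["onset_s"]):
        base_sel = (t >= onset - baseline_s) & (t < onset)
        if not base_sel.any() or np.any(~np.isfinite(p[base_sel])):
            dropped.append(int(tid))
            continue
        b = float(np.mean(p[base_sel]))
        if b == 0.0:
            dropped.append(int(tid))
            continue
        sel = (t >= onset + window_s[0]) & (t < onset + window_s[1])
        rows.append(
            pd.DataFrame(
                {
                    "trial_id": int(tid),
                    "t_rel_s": t[sel] - onset,
                    "norm": (p[sel] - b) / b,
                }
            )
        )
    if dropped:
        warnings.warn(f"dropped {len(dropped)} trials with invalid pupil baseline", stacklevel=2)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["trial_id", "t_rel_s", "norm"]
    )
    out.attrs["dropped_trials"] = dropped
    return out


def dilation_index(
    pupil_t: np.ndarray,
    pupil: np.ndarray,
    trials: pd.DataFrame,
    baseline_s: float = 0.2,
    stim_s: float = 1.0,
) -> pd.Series:
    """Per-trial pupil dilation index ``(S - B) / (S + B)``.

    ``B`` is the mean raw pupil size over ``baseline_s`` before onset and
    ``S`` the mean over the ``stim_s`` stimulus window; positive values are
    dilation, negative constriction.
    """
    t = np.asarray(pupil_t, dtype=float)
    p = np.asarray(pupil, dtype=float)
    vals = {}
    for tid, onset in zip(trials["trial_id"], trials["onset_s"]):
        bsel = (t >= onset - baseline_s) & (t < onset)
        ssel = (t >= onset) & (t < onset + stim_s)
        if not bsel.any() or not ssel.any():
            vals[int(tid)] = np.nan
            continue
        b = float(np.mean(p[bsel]))
        s = float(np.mean(p[ssel]))
        vals[int(tid)] = (s - b) / (s + b) if (s + b) != 0 else np.nan
    return pd.Series(vals, name="dilation_index")
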