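"""PSTH construction and Poisson-deviation detection of evoked responses.

The latency detector assumes the pre-onset spiking is Poisson: the
spontaneous rate ``lambda`` is estimated from the 300 ms before stimulus
onset, and the post-onset across-trial summed counts are scanned for the
first run of three consecutive 1 ms bins exceeding the one-sided Poisson
upper tail at p < 0.01, p < 0.01 and p < 0.05 respectively.  The time of
the first bin of that run is the response latency.  Detection runs on
unsmoothed counts; smoothing is applied only to the displayed/Fourier rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Psth",
    "build_psth",
    "poisson_threshold_count",
    "detect_evoked_and_latency",
    "rectangle_latency",
    "select_equiresponsive",
]


@dataclass
class Psth:
    """Across-trial spike histogram at 1 ms resolution."""

    bin_edges_ms: np.ndarray   # length n_bins + 1
    counts: np.ndarray         # unsmoothed summed counts per bin
    rate: np.ndarray           # smoothed sp/s (per trial)
    n_trials: int
    baseline_rate: float       # lambda-hat, sp/s

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])

    @property
    def bin_ms(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0])

    def window_rate(self, t0_ms: float, t1_ms: float, subtract_baseline: bool = False) -> float:
        """Mean smoothed rate over [t0, t1) ms."""
        c = self.bin_centers_ms
        sel = (c >= t0_ms) & (c < t1_ms)
        r = float(np.mean(self.rate[sel]))
        return r - self.baseline_rate if subtract_baseline else r


def _smooth_rate(counts: np.ndarray, n_trials: int, bin_s: float) -> np.ndarray:
    # 2 ms triangular moving average with reflective edges; conserves total count
    padded = np.concatenate([counts[:1], counts, counts[-1:]])
    sm = np.convolve(padded, [0.25, 0.5, 0.25], mode="valid")
    return sm / (n_trials * bin_s)


def build_psth(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    condition: dict | None = None,
    window_ms: tuple[float, float] = (-300.0, 1000.0),
    bin_ms: float = 1.0,
    baseline_ms: float = 300.0,
    unit_id: int | None = None,
) -> Psth:
    """Build an onset-aligned PSTH for the trials matching ``condition``.

    ``condition`` maps trial-table column names to required values, e.g.
    ``{"stimulus_type": "NCS", "direction": 90.0}``.  The baseline rate is
    estimated from the ``baseline_ms`` window before onset (independently
    of ``window_ms``).
    """
    sel = trials
    if condition:
        for col, val in condition.items():
            sel = sel[sel[col] == val]
    if len(sel) == 0:
        raise ValueError("no trials match the requested condition")
    sp = spikes
    if unit_id is not None:
        sp = sp[sp["unit_id"] == unit_id]
    sp = sp[sp["trial_id"].isin(sel["trial_id"])]
    onsets = sel.set_index("trial_id")["onset_s"]
    rel_ms = (sp["t_s"].to_numpy() - onsets.reindex(sp["trial_id"]).to_numpy()) * 1000.0

    n_bins = int(round((window_ms[1] - window_ms[0]) / bin_ms))
    edges = window_ms[0] + np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(rel_ms, bins=edges)

    n_trials = len(sel)
    base_count = int(np.sum((rel_ms >= -baseline_ms) & (rel_ms < 0.0)))
    lam = base_count / (n_trials * baseline_ms / 1000.0)
    rate = _smooth_rate(counts.astype(float), n_trials, bin_ms / 1000.0)
    return Psth(edges, counts, rate, n_trials, lam)


def poisson_threshold_count(mu: float, p: float) -> int:
    """Smallest count c with P(X >= c) < p for X ~ Poisson(mu).

    Strict inequality on the exact inverse CDF.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    c = int(stats.poisson.ppf(1.0 - p, mu)) if mu > 0 else 0
    while stats.poisson.sf(c - 1, mu) >= p:
        c += 1
    while c > 0 and stats.poisson.sf(c - 2, mu) < p:
        c -= 1
    return c


def detect_evoked_and_latency(
    psth: Psth,
    scan_window_ms: tuple[float, float] = (0.0, 500.0),
    p_values: tuple[float, float, float] = (0.01, 0.01, 0.05),
) -> dict:
    """Poisson-deviation detector: evoked flag and response latency.

    Returns ``{"evoked": bool, "latency_ms": float | None}``.
    """
    mu = psth.baseline_rate * psth.n_trials * psth.bin_ms / 1000.0
    if mu == 0.0 and psth.counts.sum() == 0:
        return {"evoked": False, "latency_ms": None}
    thresholds = [poisson_threshold_count(mu, p) for p in p_values]
    centers = psth.bin_centers_ms
    sel = np.nonzero((centers >= scan_window_ms[0]) & (centers < scan_window_ms[1]))[0]
    counts = psth.counts
    k = len(thresholds)
    for i in sel:
        if i + k > len(counts):
            break
        if all(counts[i + j] >= thresholds[j] for j in range(k)):
            return {"evoked": True, "latency_ms": float(psth.bin_edges_ms[i])}
    return {"evoked": False, "latency_ms": None}


def rectangle_latency(
    spikes: pd.DataFrame,
    presentations: pd.DataFrame,
    rf_cells: list[tuple[int, int]],
    unit_id: int | None = None,
    window_ms: tuple[float, float] = (-100.0, 200.0),
    baseline_ms: float = 100.0,
    scan_window_ms: tuple[float, float] = (0.0, 150.0),
) -> float | None:
    """Response latency to RF-mapping rectangles at the RF grid cells.

    ``presentations`` is the table emitted by the rectangle renderer;
    ``rf_cells`` selects the (row, col) cells covering the unit's RF.  The
    same Poisson detector is applied to the rectangle-aligned PSTH.
    """
    mask = presentations.apply(lambda r: (r["row"], r["col"]) in set(rf_cells), axis=1)
    sel = presentations[mask]
    if len(sel) == 0:
        raise ValueError("no presentations at the requested grid cells")
    trials = pd.DataFrame(
        {"trial_id": sel["presentation"].to_numpy(), "onset_s": sel["onset_s"].to_numpy()}
    )
    sp = spikes
    if unit_id is not None:
        sp = sp[sp["unit_id"] == unit_id]
    if "trial_id" not in sp or not sp["trial_id"].isin(trials["trial_id"]).any():
        # align by time instead of trial id (rectangle session uses its own clock)
        sp = sp.copy()
        t = sp["t_s"].to_numpy()
        rel = t[:, None] - trials["onset_s"].to_numpy()[None, :]
        in_win = (rel >= window_ms[0] / 1000.0) & (rel < window_ms[1] / 1000.0)
        pres_idx = np.argmax(in_win, axis=1)
        keep = in_win.any(axis=1)
        sp = pd.DataFrame(
            {
                "unit_id": sp["unit_id"].to_numpy()[keep],
                "trial_id": trials["trial_id"].to_numpy()[pres_idx[keep]],
                "t_s": t[keep],
            }
        )
    psth = build_psth(
        sp, trials, None, window_ms=window_ms, baseline_ms=baseline_ms
    )
    res = detect_evoked_and_latency(psth, scan_window_ms=scan_window_ms)
    return res["latency_ms"]


def select_equiresponsive(
    metrics: pd.DataFrame,
    tolerance: float = 0.1,
    rate_ncs_col: str = "rate_ncs",
    rate_ldg_col: str = "rate_ldg",
    complex_only: bool = True,
    csm_col: str = "csm",
) -> pd.DataFrame:
    """Units with |R(NCS)-R(LDG)| / (R(NCS)+R(LDG)) <= tolerance.

    With ``complex_only`` the selection is restricted to complex cells
    (CSM < 0), matching the latency-control analysis.
    """
    r_ncs = metrics[rate_ncs_col].to_numpy(float)
    r_ldg = metrics[rate_ldg_col].to_numpy(float)
    total = r_ncs + r_ldg
    with np.errstate(divide="ignore", invalid="ignore"):
        igr = np.where(total > 0, (r_ncs - r_ldg) / total, np.nan)
    keep = np.abs(igr) <= tolerance
    if complex_only and csm_col in metrics:
        keep &= metrics[csm_col].to_numpy(float) < 0
    return metrics[keep & np.isfinite(igr)]
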