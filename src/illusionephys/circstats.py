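"""Circular statistics for response-phase analysis.

Phase convention: the F1 phase shift is the NCS response phase minus the
LDG response phase, wrapped to [0, 360) degrees, so a positive shift means
the NCS response lags.  The confidence interval uses Fisher's
dispersion-based method; the Rayleigh test uses the standard approximation
``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` with ``Z = n R-bar^2``.
"""

from __future__ import annotations

import numpy as np

from .evoked import Psth
from .tuning import f0_f1

__all__ = [
    "f1_phase_shift",
    "circular_mean",
    "circular_mean_ci",
    "rayleigh_test",
]


def f1_phase_shift(
    psth_ncs: Psth,
    psth_ldg: Psth,
    tf: float = 2.0,
    window_ms: tuple[float, float] = (500.0, 1000.0),
) -> float:
    """Phase of the NCS F1 component minus the LDG F1 phase, in [0, 360).

    The default window covers the steady-state half of the 1 s stimulus:
    the onset transient has broadband spectral content that leaks into the
    F1 bin and would otherwise bias the phase estimate.
    """
    a = f0_f1(psth_ncs, tf, window_ms)
    b = f0_f1(psth_ldg, tf, window_ms)
    if a["f1"] == 0.0 or b["f1"] == 0.0:
        raise ValueError("F1 amplitude is zero; phase shift undefined")
    return float(np.mod(a["f1_phase_deg"] - b["f1_phase_deg"], 360.0))


def circular_mean(phases_deg) -> float:
    """Direction of the resultant vector, degrees in [0, 360)."""
    th = np.deg2rad(np.asarray(phases_deg, dtype=float))
    return float(np.mod(np.rad2deg(np.angle(np.mean(np.exp(1j * th)))), 360.0))


def circular_mean_ci(phases_deg, confidence: float = 0.95) -> dict:
    """Circular mean with Fisher's dispersion-based confidence interval.

    Returns mean, (lo, hi) in degrees and the resultant length R-bar.  The
    half-width is ``asin(z * sigma)`` with circular standard error
    ``sigma = sqrt((1 - rho2) / (2 n Rbar^2))`` where rho2 is the second
    central trigonometric moment.
    """
    from scipy import stats

    th = np.deg2rad(np.asarray(phases_deg, dtype=float))
    n = th.size
    if n < 2:
        raise ValueError("need at least two phases")
    z_vec = np.mean(np.exp(1j * th))
    mean = np.angle(z_vec)
    rbar = np.abs(z_vec)
    rho2 = float(np.mean(np.cos(2.0 * (th - mean))))
    if rbar == 0:
        raise ValueError("resultant length is zero; mean undefined")
    sigma2 = (1.0 - rho2) / (2.0 * n * rbar**2)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    arg = z * np.sqrt(max(sigma2, 0.0))
    half = np.pi if arg >= 1.0 else float(np.arcsin(arg))
    mean_deg = float(np.mod(np.rad2deg(mean), 360.0))
    half_deg = float(np.rad2deg(half))
    return {
        "mean_deg": mean_deg,
        "ci_deg": (mean_deg - half_deg, mean_deg + half_deg),
        "rbar": float(rbar),
        "n": int(n),
    }


def rayleigh_test(phases_deg) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: returns (Z, p)."""
    th = np.deg2rad(np.asarray(phases_deg, dtype=float))
    n = th.size
    if n < 2:
        raise ValueError("need at least two phases")
    rn = np.abs(np.sum(np.exp(1j * th)))
    z = rn**2 / n
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - rn**2)) - (1.0 + 2.0 * n))
    return float(z), float(min(p, 1.0))
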