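"""Direction/size tuning curves, scalar response indices and F0/F1 analysis.

All contrast-style indices are of the form (a - b) / (a + b) and lie in
[-1, 1] for non-negative inputs:

* ``igr``                 -- evoked-rate contrast of NCS vs LDG responses
* ``igr_f1``              -- same contrast on F1 amplitudes
* ``csm``                 -- complex-simple modulation, (F1 - F0)/(F1 + F0)
* ``ncs_delay_index``     -- latency contrast of NCS vs rectangle responses
* ``surround_modulation`` -- size-tuning suppression index

F1 is reported as a single-sided amplitude (same units as rate) so that the
mixed F1/F0 indices are dimensionally consistent; the F1-dominance flag
compares spectral power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .evoked import Psth

__all__ = [
    "TuningCurve",
    "igr",
    "igr_f1",
    "csm",
    "ncs_delay_index",
    "surround_modulation",
    "f0_f1",
    "preferred_angle",
    "delta_preferred",
]

ANGLES_8 = np.arange(0.0, 360.0, 45.0)


@dataclass
class TuningCurve:
    """Trial-averaged responses at the eight drift directions."""

    angles: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.angles.shape != self.responses.shape:
            raise ValueError("angles and responses must have the same shape")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")


def _contrast(a: float, b: float, what: str) -> float:
    if a < 0 or b < 0:
        raise ValueError(f"{what}: inputs must be non-negative")
    total = a + b
    if total == 0:
        raise ValueError(f"{what}: undefined for (0, 0)")
    return (a - b) / total


def igr(r_ncs: float, r_ldg: float) -> float:
    """Illusory-grating response index; positive = larger NCS response."""
    return _contrast(r_ncs, r_ldg, "igr")


def igr_f1(f1_ncs: float, f1_ldg: float) -> float:
    """IGR computed on F1 amplitudes instead of mean evoked rates."""
    return _contrast(f1_ncs, f1_ldg, "igr_f1")


def csm(f1: float, f0: float) -> float:
    """Complex-simple modulation; positive = simple (phase-locked) cell."""
    return _contrast(f1, f0, "csm")


def ncs_delay_index(lat_ncs_ms: float, lat_rect_ms: float) -> float:
    """Latency contrast of the NCS response vs the rectangle response."""
    if lat_ncs_ms <= 0 or lat_rect_ms <= 0:
        raise ValueError("latencies must be positive")
    return (lat_ncs_ms - lat_rect_ms) / (lat_ncs_ms + lat_rect_ms)


def surround_modulation(sizes_deg, responses) -> float:
    """Size-tuning index: (max R(<30 deg) - R(45 deg)) / max R(<30 deg).

    Positive for suppressive cells, negative for facilitative cells.
    """
    sizes = np.asarray(sizes_deg, dtype=float)
    resp = np.asarray(responses, dtype=float)
    small = resp[sizes < 30.0]
    if small.size == 0 or 45.0 not in sizes:
        raise ValueError("curve must include sizes < 30 deg and 45 deg")
    peak = float(np.max(small))
    if peak <= 0:
        raise ValueError("undefined: no positive response below 30 deg")
    r45 = float(resp[sizes == 45.0][0])
    return (peak - r45) / peak


def f0_f1(
    psth: Psth,
    tf: float = 2.0,
    window_ms: tuple[float, float] = (0.0, 1000.0),
) -> dict:
    """Fourier decomposition of the smoothed PSTH over the stimulus window.

    F0 is the mean rate; F1 is the single-sided amplitude of the discrete
    Fourier component at the stimulus temporal frequency.  Returns a dict
    with f0, f1, f1_phase_deg (phase of a cos(2*pi*tf*t - phi) fit) and
    f1_dominant (F1 power exceeds every other non-DC component).
    """
    dur_s = (window_ms[1] - window_ms[0]) / 1000.0
    if dur_s < 1.0 / tf:
        raise ValueError("analysis window shorter than one stimulus cycle")
    c = psth.bin_centers_ms
    sel = (c >= window_ms[0]) & (c < window_ms[1])
    r = psth.rate[sel]
    n = r.size
    spec = np.fft.rfft(r)
    freqs = np.fft.rfftfreq(n, d=psth.bin_ms / 1000.0)
    k = int(np.argmin(np.abs(freqs - tf)))
    f0 = float(np.mean(r))
    f1 = float(2.0 * np.abs(spec[k]) / n)
    power = np.abs(spec) ** 2
    f1_dominant = bool(k > 0 and power[k] > 0 and np.all(power[k] >= power[1:]) )
    # rate ~ cos(2*pi*f*t - phi)  =>  coefficient = (n/2) exp(-i*phi)
    phase = float(np.mod(-np.angle(spec[k]), 2.0 * np.pi) * 180.0 / np.pi)
    return {"f0": f0, "f1": f1, "f1_phase_deg": phase, "f1_dominant": f1_dominant,
            "freq_hz": float(freqs[k])}


def preferred_angle(curve: TuningCurve, grid_step_deg: float = 1.0) -> dict:
    """Preferred direction from a periodic cubic spline through the curve.

    The spline is evaluated on a dense grid (default 1 degree) and the
    argmax returned.  A perfectly flat curve is flagged untuned and the
    first sampled angle returned.
    """
    ang = curve.angles
    resp = curve.responses
    if np.allclose(resp, resp[0]):
        return {"angle_deg": float(ang[0]), "untuned": True}
    order = np.argsort(ang)
    x = np.concatenate([ang[order], [ang[order][0] + 360.0]])
    y = np.concatenate([resp[order], [resp[order][0]]])
    spline = CubicSpline(x, y, bc_type="periodic")
    grid = np.arange(x[0], x[0] + 360.0, grid_step_deg)
    vals = spline(grid)
    return {"angle_deg": float(np.mod(grid[np.argmax(vals)], 360.0)), "untuned": False}


def delta_preferred(angle_ncs: float, angle_ldg: float) -> float:
    """Wrapped circular difference angle_ncs - angle_ldg in [-180, 180)."""
    d = np.mod(angle_ncs - angle_ldg + 180.0, 360.0) - 180.0
    return float(d)
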