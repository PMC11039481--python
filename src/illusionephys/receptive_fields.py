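"""Receptive-field estimation from rectangle-mapping responses.

The response map is the baseline-subtracted mean evoked rate per grid
cell.  The map is nearest-neighbor upsampled, pixels below a robust
threshold (map median + k standard deviations of the below-median pixels)
are masked, and a rotated 2-D Gaussian is least-squares fitted to the
remaining pixels.  The FWHM ellipse of the fit (semi-axis = sqrt(2 ln 2)
sigma) is intersected with the disk bounded by the outermost inducer
circle of the nearest patch to give the RF-inducer overlap ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .stimgen import InducerLayout

__all__ = [
    "ReceptiveField",
    "rf_response_map",
    "fit_rf",
    "overlap_ratio",
    "rf_inducer_distance",
    "detect_retinotopic_reversals",
    "FWHM_PER_SIGMA",
]

FWHM_PER_SIGMA = float(np.sqrt(2.0 * np.log(2.0)))  # FWHM semi-axis per sigma


@dataclass
class ReceptiveField:
    """2-D Gaussian RF fit in screen coordinates (degrees)."""

    center: tuple[float, float]
    sigma: tuple[float, float]
    rotation_deg: float
    amplitude: float
    fit_residual: float
    no_rf: bool = False

    @property
    def fwhm_semi_axes(self) -> tuple[float, float]:
        return (FWHM_PER_SIGMA * self.sigma[0], FWHM_PER_SIGMA * self.sigma[1])


def rf_response_map(
    spikes: pd.DataFrame,
    presentations: pd.DataFrame,
    window_ms: tuple[float, float] = (0.0, 100.0),
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0),
    unit_id: int | None = None,
    grid_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-grid-cell mean evoked rate, baseline-subtracted (sp/s).

    Raises if any grid cell has zero presentations.
    """
    sp = spikes
    if unit_id is not None:
        sp = sp[sp["unit_id"] == unit_id]
    t = sp["t_s"].to_numpy()
    onsets = presentations["onset_s"].to_numpy()
    rows = presentations["row"].to_numpy()
    cols = presentations["col"].to_numpy()
    if grid_shape is None:
        grid_shape = (int(rows.max()) + 1, int(cols.max()) + 1)
    n_pres = np.zeros(grid_shape, dtype=int)
    np.add.at(n_pres, (rows, cols), 1)
    if np.any(n_pres == 0):
        raise ValueError("grid cell with zero presentations")

    win_s = (window_ms[1] - window_ms[0]) / 1000.0
    base_s = (baseline_window_ms[1] - baseline_window_ms[0]) / 1000.0
    counts = np.zeros(grid_shape)
    base_counts = 0.0
    t_sorted = np.sort(t)
    for onset, r, c in zip(onsets, rows, cols):
        lo = np.searchsorted(t_sorted, onset + window_ms[0] / 1000.0)
        hi = np.searchsorted(t_sorted, onset + window_ms[1] / 1000.0)
        counts[r, c] += hi - lo
        blo = np.searchsorted(t_sorted, onset + baseline_window_ms[0] / 1000.0)
        bhi = np.searchsorted(t_sorted, onset + baseline_window_ms[1] / 1000.0)
        base_counts += bhi - blo
    baseline_rate = base_counts / (len(onsets) * base_s)
    rates = counts / (n_pres * win_s)
    return rates - baseline_rate


def _gauss2d(params, xx, yy):
    amp, x0, y0, sx, sy, th = params
    ct, st = np.cos(th), np.sin(th)
    xr = (xx - x0) * ct + (yy - y0) * st
    yr = -(xx - x0) * st + (yy - y0) * ct
    return amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2))


def fit_rf(
    response_map: np.ndarray,
    upsample_factor: int = 5,
    mask_sd: float = 3.0,
    x_coords: np.ndarray | None = None,
    y_coords: np.ndarray | None = None,
) -> ReceptiveField:
    """Masked rotated-Gaussian fit of a rectangle-response map.

    The map is nearest-neighbor upsampled by ``upsample_factor``; pixels
    below ``median + mask_sd * std(below-median pixels)`` are masked out of
    the fit.  ``x_coords``/``y_coords`` give the degree coordinates of the
    original grid columns/rows (defaults: cell indices).  Returns a fit or
    a no-RF flag when everything is masked or the fit degenerates.
    """
    m = np.asarray(response_map, dtype=float)
    rows, cols = m.shape
    xc = np.asarray(x_coords, float) if x_coords is not None else np.arange(cols, dtype=float)
    yc = np.asarray(y_coords, float) if y_coords is not None else np.arange(rows, dtype=float)

    up = ndimage.zoom(m, upsample_factor, order=0)
    x_up = np.interp(
        (np.arange(cols * upsample_factor) + 0.5) / upsample_factor - 0.5,
        np.arange(cols), xc,
    )
    y_up = np.interp(
        (np.arange(rows * upsample_factor) + 0.5) / upsample_factor - 0.5,
        np.arange(rows), yc,
    )
    xx, yy = np.meshgrid(x_up, y_up)

    med = np.median(up)
    off_peak = up[up <= med]
    sd = float(np.std(off_peak)) if off_peak.size else 0.0
    thr = med + mask_sd * sd
    mask = up >= thr
    if not mask.any() or np.ptp(up) == 0 or up.max() <= 0:
        return ReceptiveField((np.nan, np.nan), (np.nan, np.nan), 0.0, 0.0, np.inf, no_rf=True)

    w = np.where(mask, up, 0.0)
    total = w.sum()
    x0 = float((w * xx).sum() / total)
    y0 = float((w * yy).sum() / total)
    sx0 = float(np.sqrt(max((w * (xx - x0) ** 2).sum() / total, 1e-4)))
    sy0 = float(np.sqrt(max((w * (yy - y0) ** 2).sum() / total, 1e-4)))
    p0 = [float(up.max()), x0, y0, sx0, sy0, 0.0]

    xm, ym, zm = xx[mask], yy[mask], up[mask]

    def resid(p):
        return _gauss2d(p, xm, ym) - zm

    try:
        res = optimize.least_squares(
            resid,
            p0,
            bounds=(
                [0.0, xc.min() - 5, yc.min() - 5, 1e-3, 1e-3, -np.pi],
                [np.inf, xc.max() + 5, yc.max() + 5, np.inf, np.inf, np.pi],
            ),
        )
    except ValueError:
        return ReceptiveField((np.nan, np.nan), (np.nan, np.nan), 0.0, 0.0, np.inf, no_rf=True)
    amp, fx, fy, fsx, fsy, fth = res.x
    if amp <= 0 or not np.isfinite([fx, fy, fsx, fsy]).all():
        return ReceptiveField((np.nan, np.nan), (np.nan, np.nan), 0.0, 0.0, np.inf, no_rf=True)
    return ReceptiveField(
        center=(float(fx), float(fy)),
        sigma=(float(fsx), float(fsy)),
        rotation_deg=float(np.rad2deg(fth)),
        amplitude=float(amp),
        fit_residual=float(np.sqrt(np.mean(res.fun**2))),
    )


def overlap_ratio(
    rf: ReceptiveField,
    layout: InducerLayout,
    resolution_px_per_deg: float = 25.0,
) -> float:
    """Fraction of the RF FWHM ellipse covered by the nearest inducer disk.

    The inducer disk is bounded by the outer edge of the largest circle of
    the patch closest to the RF center; the areas are computed by pixel
    rasterization at ``resolution_px_per_deg``.
    """
    if rf.no_rf:
        raise ValueError("cannot compute overlap for a no-RF unit")
    cx, cy = rf.center
    centers = np.asarray(layout.patch_centers)
    d2 = (centers[:, 0] - cx) ** 2 + (centers[:, 1] - cy) ** 2
    px, py = centers[int(np.argmin(d2))]
    r_disk = layout.outer_radius_deg

    a, b = rf.fwhm_semi_axes
    th = np.deg2rad(rf.rotation_deg)
    half = max(a, b)
    n = max(int(np.ceil(2 * half * resolution_px_per_deg)), 8)
    xs = np.linspace(cx - half, cx + half, n)
    ys = np.linspace(cy - half, cy + half, n)
    xx, yy = np.meshgrid(xs, ys)
    xr = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
    yr = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
    in_ellipse = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    in_disk = (xx - px) ** 2 + (yy - py) ** 2 <= r_disk**2
    n_ell = int(in_ellipse.sum())
    if n_ell == 0:
        return 0.0
    return float((in_ellipse & in_disk).sum() / n_ell)


def rf_inducer_distance(rf: ReceptiveField, layout: InducerLayout) -> float:
    """Euclidean distance from the RF center to the nearest patch center."""
    if rf.no_rf:
        raise ValueError("no valid RF")
    cx, cy = rf.center
    centers = np.asarray(layout.patch_centers)
    d = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)
    return float(d.min())


def detect_retinotopic_reversals(
    channel_rf_x: np.ndarray,
    smooth_window: int = 3,
) -> list[int]:
    """Channels where the along-probe progression of RF azimuth reverses.

    The channel-ordered RF x-positions are smoothed with a centered moving
    average before sign changes of the first difference are located.  A
    monotone progression yields an empty list.
    """
    x = np.asarray(channel_rf_x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 channels with valid RF centers")
    if smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        xp = np.concatenate([x[:1].repeat(pad), x, x[-1:].repeat(pad)])
        x = np.convolve(xp, k, mode="valid")[: len(channel_rf_x)]
    d = np.diff(x)
    signs = np.sign(d)
    # carry the last non-zero sign through flat segments
    last = 0.0
    filled = np.empty_like(signs)
    for i, s in enumerate(signs):
        if s != 0:
            last = s
        filled[i] = last
    reversals = []
    for i in range(1, len(filled)):
        if filled[i] != 0 and filled[i - 1] != 0 and filled[i] != filled[i - 1]:
            reversals.append(i)
    return reversals
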