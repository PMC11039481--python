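"""Waveform-based E/I classification and laminar CSD analysis."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, signal
from sklearn.mixture import GaussianMixture

__all__ = [
    "tpl",
    "ei_threshold",
    "preprocess_lfp",
    "csd",
    "find_sink",
    "assign_relative_depth",
]


def tpl(waveform: np.ndarray, sample_rate: float, interpolate: bool = True) -> float | None:
    """Trough-to-peak latency (ms) of a mean spike waveform.

    The global trough must be followed by a maximum; otherwise the unit is
    unclassifiable and ``None`` is returned.  With ``interpolate`` the
    extrema are refined to sub-sample precision by parabolic fits.
    """
    w = np.asarray(waveform, dtype=float)
    trough = int(np.argmin(w))
    if trough >= len(w) - 1:
        return None
    after = w[trough + 1 :]
    peak = trough + 1 + int(np.argmax(after))
    if w[peak] <= w[trough]:
        return None

    def refine(idx: int) -> float:
        if 0 < idx < len(w) - 1:
            y0, y1, y2 = w[idx - 1], w[idx], w[idx + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                return idx + 0.5 * (y0 - y2) / denom
        return float(idx)

    t0 = refine(trough) if interpolate else float(trough)
    t1 = refine(peak) if interpolate else float(peak)
    return float((t1 - t0) / sample_rate * 1000.0)


def _gaussian_pdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def ei_threshold(tpl_values, random_state: int = 0) -> dict:
    """Two-Gaussian mixture split of the TPL distribution.

    Fits a 2-component Gaussian mixture, finds the density intersection
    between the component means, and labels TPL < threshold as putative
    inhibitory ("I") and the rest as putative excitatory ("E").  Emits a
    warning (and still returns the threshold) when the components are
    closer than their pooled standard deviation.
    """
    x = np.asarray(tpl_values, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 units to fit the TPL mixture")
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=5)
    gm.fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]

    # a two-Gaussian mixture is only bimodal when the means are separated
    # by roughly twice the pooled width
    pooled = np.sqrt((s1**2 + s2**2) / 2.0)
    if (m2 - m1) < 2.0 * pooled:
        warnings.warn("TPL mixture components poorly separated; threshold unreliable",
                      stacklevel=2)

    def diff(v):
        return w1 * _gaussian_pdf(v, m1, s1) - w2 * _gaussian_pdf(v, m2, s2)

    try:
        threshold = float(optimize.brentq(diff, m1, m2))
    except ValueError:
        threshold = float((m1 + m2) / 2.0)  # densities do not cross between means
    labels = np.where(x < threshold, "I", "E")
    return {
        "threshold_ms": threshold,
        "labels": labels,
        "means": (float(m1), float(m2)),
        "sds": (float(s1), float(s2)),
        "weights": (float(w1), float(w2)),
    }


def preprocess_lfp(
    raw: np.ndarray,
    fs: float,
    band_hz: tuple[float, float] = (0.1, 150.0),
    out_fs: float = 1000.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass then downsample to ``out_fs``."""
    nyq = fs / 2.0
    sos = signal.butter(order, [band_hz[0] / nyq, band_hz[1] / nyq], btype="band", output="sos")
    filt = signal.sosfiltfilt(sos, raw, axis=-1)
    step = int(round(fs / out_fs))
    return filt[..., ::step] if step > 1 else filt


def csd(lfp: np.ndarray, spacing_um: float = 25.0) -> np.ndarray:
    """Discrete second spatial derivative CSD of a channels-by-time LFP.

    ``CSD[c] = -(V[c-1] - 2 V[c] + V[c+1]) / spacing^2``; edge channels
    are handled by duplication padding so the output keeps all channels.
    """
    v = np.asarray(lfp, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.shape[0] < 3:
        raise ValueError("CSD needs at least 3 channels")
    padded = np.concatenate([v[:1], v, v[-1:]], axis=0)
    h2 = (spacing_um / 1000.0) ** 2  # mm^2
    out = -(padded[:-2] - 2.0 * padded[1:-1] + padded[2:]) / h2
    return out if lfp.ndim > 1 else out[:, 0]


def interpolate_csd(csd_map: np.ndarray, factor: int = 4) -> np.ndarray:
    """Spatially upsample a CSD map for display (cubic along channels)."""
    from scipy import ndimage

    return ndimage.zoom(csd_map, (factor, 1), order=3)


def find_sink(
    csd_map: np.ndarray,
    fs: float = 1000.0,
    window_s: tuple[float, float] | None = None,
    smooth_ms: float = 10.0,
) -> dict | None:
    """Channel and time of the earliest prominent current sink.

    The CSD is lightly smoothed (boxcar ``smooth_ms`` in time, a [1,2,1]/4
    kernel across channels) before the most negative value within the
    window is located; returns ``None`` when no negative deflection exists.
    """
    c = np.asarray(csd_map, dtype=float)
    if smooth_ms > 0:
        from scipy import ndimage

        n = max(int(round(smooth_ms / 1000.0 * fs)), 1)
        c = ndimage.uniform_filter1d(c, n, axis=1, mode="nearest")
    if c.shape[0] >= 3:
        c = 0.25 * np.vstack([c[:1], c[:-1]]) + 0.5 * c + 0.25 * np.vstack([c[1:], c[-1:]])
    sel = c
    offset = 0
    if window_s is not None:
        i0, i1 = (int(round(w * fs)) for w in window_s)
        sel = c[:, i0:i1]
        offset = i0
    if sel.size == 0 or sel.min() >= 0:
        return None
    ch, ti = np.unravel_index(np.argmin(sel), sel.shape)
    return {"channel": int(ch), "time_s": float((ti + offset) / fs), "value": float(sel.min())}


def assign_relative_depth(
    csd_map: np.ndarray,
    unit_channel: int,
    band_channels: int = 2,
    fs: float = 1000.0,
    window_s: tuple[float, float] | None = None,
) -> str | None:
    """Sink-relative laminar label for a unit's recording channel.

    Channels within ``band_channels`` of the earliest sink are "granular";
    shallower channels (lower index) are "supragranular" and deeper ones
    "infragranular".  Returns ``None`` when no sink is found.
    """
    sink = find_sink(csd_map, fs=fs, window_s=window_s)
    if sink is None:
        return None
    d = unit_channel - sink["channel"]
    if abs(d) <= band_channels:
        return "granular"
    return "supragranular" if d < 0 else "infragranular"
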