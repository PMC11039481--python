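"""Procedural rendering of the illusory-grating stimulus family.

Five stimulus classes are produced as pixel-luminance frame stacks:

* ``NCS``  -- neon-color-spreading inducers: white concentric circles on a
  black background whose intersection with a virtual drifting square-wave
  grating is replaced by gray segments, evoking an illusory drifting grating.
* ``DBC``  -- diffusion-blocked control: the NCS stimulus plus static white
  blocker rings immediately inside and outside every inducer circle.
* ``LDG``  -- luminance-defined grating: a real gray square-wave grating
  drawn in the foreground over the (static) inducers, spatially antiphase to
  the NCS illusory grating.
* ``RECT`` -- sparse-noise receptive-field mapping: black rectangles flashed
  on a gray background over a rows-by-cols grid in pseudo-random order.
* ``SIZE`` -- size-tuning: circular patches of drifting grating of graded
  diameter centered on a receptive field.

All geometry is expressed in degrees of visual angle with the origin at the
canvas center, x rightward and y upward.  Rasterization samples pixel
centers, so every rendered pixel takes exactly one of the three configured
luminance levels (black, gray, white) for the grating stimuli.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DisplayGeometry",
    "GratingSpec",
    "InducerLayout",
    "FrameStack",
    "render_ncs",
    "render_dbc",
    "render_ldg",
    "render_rf_rectangles",
    "render_size_tuning",
    "condition_table",
    "gray_indicator_phase",
    "fundamental_phase_offset",
    "DIRECTIONS_8",
]

#: the eight drift directions used throughout the main session design
DIRECTIONS_8: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)


@dataclass(frozen=True)
class DisplayGeometry:
    """Monitor constants and luminance levels.

    Luminance values are arbitrary units in ``[0, 1]``; defaults are
    black=0, gray=0.5, white=1.
    """

    pixels_per_degree: float = 4.0
    frame_rate: float = 60.0
    screen_width_deg: float = 130.7
    screen_height_deg: float = 73.5
    black: float = 0.0
    gray: float = 0.5
    white: float = 1.0

    def __post_init__(self) -> None:
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not (self.black < self.gray < self.white):
            raise ValueError("luminance levels must satisfy black < gray < white")


@dataclass(frozen=True)
class GratingSpec:
    """Parameters of a drifting square-wave grating (50% duty cycle)."""

    spatial_frequency: float = 0.05  # cycles / degree
    temporal_frequency: float = 2.0  # Hz
    direction: float = 0.0           # degrees; drift direction
    phase0: float = 0.0              # degrees; spatial phase at t=0

    def __post_init__(self) -> None:
        if self.spatial_frequency <= 0:
            raise ValueError("spatial_frequency must be > 0")
        if self.temporal_frequency < 0:
            raise ValueError("temporal_frequency must be >= 0")

    @property
    def period_deg(self) -> float:
        return 1.0 / self.spatial_frequency

    def drift_per_frame_deg(self, frame_rate: float) -> float:
        """Bar displacement per frame: TF / SF / frame_rate degrees."""
        return self.temporal_frequency / self.spatial_frequency / frame_rate


@dataclass(frozen=True)
class InducerLayout:
    """Positions and radii of the concentric-circle inducer patches."""

    patch_centers: tuple[tuple[float, float], ...]
    circle_diameters: tuple[float, ...]
    circle_thickness: float
    blocker_thickness: float
    arrangement: str  # {"grid3x3", "honeycomb"}
    canvas_deg: tuple[float, float]  # rendered width x height in degrees

    def __post_init__(self) -> None:
        if self.circle_thickness <= 0:
            raise ValueError("circle_thickness must be > 0")
        if self.blocker_thickness <= 0:
            raise ValueError("blocker_thickness must be > 0")
        if any(d <= 0 for d in self.circle_diameters):
            raise ValueError("circle diameters must be > 0")

    @classmethod
    def grid3x3(
        cls,
        patch_width_deg: float = 35.0,
        circle_diameters: Sequence[float] = (3.0, 6.0, 9.0),
        circle_thickness: float = 0.1,
        blocker_thickness: float = 0.4,
    ) -> "InducerLayout":
        """Nine patches on a 3-by-3 virtual grid inside a black square."""
        s = patch_width_deg / 3.0
        centers = tuple(
            (c * s, r * s) for r in (-1, 0, 1) for c in (-1, 0, 1)
        )
        return cls(
            patch_centers=centers,
            circle_diameters=tuple(float(d) for d in circle_diameters),
            circle_thickness=circle_thickness,
            blocker_thickness=blocker_thickness,
            arrangement="grid3x3",
            canvas_deg=(patch_width_deg, patch_width_deg),
        )

    @classmethod
    def honeycomb(
        cls,
        spacing_deg: float | None = None,
        gap_diameter_deg: float = 39.0,
        circle_diameters: Sequence[float] = (8.0, 16.0, 24.0),
        circle_thickness: float = 0.4,
        blocker_thickness: float = 0.8,
        canvas_deg: tuple[float, float] = (130.7, 73.5),
    ) -> "InducerLayout":
        """Full-screen hexagonal arrangement (center patch + 6 neighbours).

        By default the patch spacing is chosen so that the largest empty
        circle inscribed between three mutually adjacent patches has
        diameter ``gap_diameter_deg``: for outer patch radius R and spacing
        s, the inscribed radius is s/sqrt(3) - R.
        """
        r_out = max(circle_diameters) / 2.0 + circle_thickness / 2.0
        if spacing_deg is None:
            spacing_deg = np.sqrt(3.0) * (gap_diameter_deg / 2.0 + r_out)
        ang = np.deg2rad(np.arange(6) * 60.0)
        centers = [(0.0, 0.0)] + [
            (spacing_deg * np.cos(a), spacing_deg * np.sin(a)) for a in ang
        ]
        return cls(
            patch_centers=tuple((float(x), float(y)) for x, y in centers),
            circle_diameters=tuple(float(d) for d in circle_diameters),
            circle_thickness=circle_thickness,
            blocker_thickness=blocker_thickness,
            arrangement="honeycomb",
            canvas_deg=canvas_deg,
        )

    @property
    def outer_radius_deg(self) -> float:
        """Outer edge radius of the largest inducer circle."""
        return max(self.circle_diameters) / 2.0 + self.circle_thickness / 2.0


@dataclass
class FrameStack:
    """A rendered stimulus: T x H x W luminance frames plus metadata."""

    frames: np.ndarray          # float32, values in [0, 1]
    frame_times: np.ndarray     # seconds, frame-start times
    condition_label: str        # {"NCS","DBC","LDG","RECT","SIZE"}
    geometry: DisplayGeometry
    grating: GratingSpec | None = None
    layout: InducerLayout | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def pixel_coords_deg(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) degree coordinates of pixel centers for this stack."""
        _, h, w = self.frames.shape
        return _pixel_grid(self.geometry.pixels_per_degree, w, h)

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, (self.frames * 255).astype(np.uint8))

    def config_json(self) -> str:
        cfg = {
            "condition_label": self.condition_label,
            "geometry": asdict(self.geometry),
            "grating": asdict(self.grating) if self.grating else None,
            "layout": asdict(self.layout) if self.layout else None,
            "meta": {k: v for k, v in self.meta.items() if _json_safe(v)},
        }
        return json.dumps(cfg, indent=2)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _pixel_grid(ppd: float, width_px: int, height_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Degree coordinates of pixel centers; origin at canvas center.

    Row 0 is the top of the image (largest y).
    """
    xs = (np.arange(width_px) - (width_px - 1) / 2.0) / ppd
    ys = -(np.arange(height_px) - (height_px - 1) / 2.0) / ppd
    return np.meshgrid(xs, ys)


def _canvas_shape(geometry: DisplayGeometry, canvas_deg: tuple[float, float]) -> tuple[int, int]:
    w = int(round(canvas_deg[0] * geometry.pixels_per_degree))
    h = int(round(canvas_deg[1] * geometry.pixels_per_degree))
    return h, w


def _n_frames(duration: float, frame_rate: float) -> int:
    n = int(round(duration * frame_rate))
    if n < 1:
        raise ValueError("duration must cover at least one frame")
    return n


def grating_dark_mask(
    xx: np.ndarray, yy: np.ndarray, grating: GratingSpec, t: float
) -> np.ndarray:
    """Boolean mask of the dark half-cycle of the square-wave grating.

    The spatial phase is ``SF * proj - TF * t + phase0/360`` cycles, where
    proj is the pixel coordinate projected on the drift axis; fractional
    phases in [0.5, 1) are "dark".  Bars therefore drift toward
    ``grating.direction`` at TF/SF deg/s.
    """
    th = np.deg2rad(grating.direction)
    proj = xx * np.cos(th) + yy * np.sin(th)
    phase = grating.spatial_frequency * proj - grating.temporal_frequency * t
    phase = phase + grating.phase0 / 360.0
    return np.mod(phase, 1.0) >= 0.5


def _inducer_mask(layout: InducerLayout, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    mask = np.zeros(xx.shape, dtype=bool)
    half_t = layout.circle_thickness / 2.0
    for cx, cy in layout.patch_centers:
        r = np.hypot(xx - cx, yy - cy)
        for d in layout.circle_diameters:
            mask |= np.abs(r - d / 2.0) <= half_t
    return mask


def _blocker_mask(layout: InducerLayout, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    """Static blocker rings immediately inside and outside each circle."""
    half_t = layout.circle_thickness / 2.0
    bt = layout.blocker_thickness
    # validate geometry: blocker radial bands must not touch any inducer band
    radii = sorted(d / 2.0 for d in layout.circle_diameters)
    bands = [(r - half_t, r + half_t) for r in radii]
    for r in radii:
        for lo, hi in ((r - half_t - bt, r - half_t), (r + half_t, r + half_t + bt)):
            if lo < 0:
                raise ValueError("blocker ring extends through the patch center")
            for blo, bhi in bands:
                if hi > blo and lo < bhi and not np.isclose(lo, bhi) and not np.isclose(hi, blo):
                    raise ValueError(
                        "blocker ring overlaps an inducer circle; geometry invalid"
                    )
    mask = np.zeros(xx.shape, dtype=bool)
    for cx, cy in layout.patch_centers:
        rr = np.hypot(xx - cx, yy - cy)
        for r in radii:
            inner = (rr >= r - half_t - bt) & (rr < r - half_t)
            outer = (rr > r + half_t) & (rr <= r + half_t + bt)
            mask |= inner | outer
    return mask


def render_ncs(
    geometry: DisplayGeometry,
    layout: InducerLayout,
    grating: GratingSpec,
    duration: float,
) -> FrameStack:
    """Render the neon-color-spreading stimulus.

    Each frame is a black background with white inducer circles; annulus
    pixels covered by the dark half-cycle of the virtual drifting grating
    are replaced with gray segments.  Background pixels are never gray.
    """
    h, w = _canvas_shape(geometry, layout.canvas_deg)
    xx, yy = _pixel_grid(geometry.pixels_per_degree, w, h)
    ind = _inducer_mask(layout, xx, yy)
    n = _n_frames(duration, geometry.frame_rate)
    frames = np.empty((n, h, w), dtype=np.float32)
    times = np.arange(n) / geometry.frame_rate
    any_gray = False
    for k, t in enumerate(times):
        frame = np.full((h, w), geometry.black, dtype=np.float32)
        frame[ind] = geometry.white
        seg = ind & grating_dark_mask(xx, yy, grating, t)
        frame[seg] = geometry.gray
        any_gray = any_gray or bool(seg.any())
        frames[k] = frame
    if not any_gray:
        warnings.warn(
            "grating never intersected the inducers; no gray segments rendered",
            stacklevel=2,
        )
    return FrameStack(frames, times, "NCS", geometry, grating, layout)


def render_dbc(
    geometry: DisplayGeometry,
    layout: InducerLayout,
    grating: GratingSpec,
    duration: float,
) -> FrameStack:
    """Render the diffusion-blocked control: NCS plus static blocker rings.

    The blockers occupy background pixels only, so frame-to-frame pixel
    changes are identical to the matching NCS stimulus.
    """
    stack = render_ncs(geometry, layout, grating, duration)
    xx, yy = stack.pixel_coords_deg()
    blockers = _blocker_mask(layout, xx, yy)
    stack.frames[:, blockers] = geometry.white
    stack.condition_label = "DBC"
    stack.meta["blocker_pixels"] = int(blockers.sum())
    return stack


def render_ldg(
    geometry: DisplayGeometry,
    layout: InducerLayout,
    grating: GratingSpec,
    duration: float,
) -> FrameStack:
    """Render the luminance-defined grating over static inducers.

    Gray bars are drawn in the foreground wherever the grating is in its
    bright half-cycle, i.e. exactly antiphase (180 deg) to the gray
    segments of the matching NCS stimulus.
    """
    h, w = _canvas_shape(geometry, layout.canvas_deg)
    xx, yy = _pixel_grid(geometry.pixels_per_degree, w, h)
    ind = _inducer_mask(layout, xx, yy)
    n = _n_frames(duration, geometry.frame_rate)
    frames = np.empty((n, h, w), dtype=np.float32)
    times = np.arange(n) / geometry.frame_rate
    for k, t in enumerate(times):
        frame = np.full((h, w), geometry.black, dtype=np.float32)
        frame[ind] = geometry.white
        bars = ~grating_dark_mask(xx, yy, grating, t)
        frame[bars] = geometry.gray
        frames[k] = frame
    return FrameStack(frames, times, "LDG", geometry, grating, layout)


def render_rf_rectangles(
    geometry: DisplayGeometry,
    grid_shape: tuple[int, int] = (8, 13),
    rect_width_deg: float = 15.0,
    on_ms: float = 100.0,
    off_ms: float = 100.0,
    order_seed: int = 0,
    n_sweeps: int = 1,
) -> tuple[FrameStack, pd.DataFrame]:
    """Flash black rectangles on gray over a grid in pseudo-random order.

    Returns the frame stack and a presentation table mapping each flash to
    its grid cell (columns: presentation, sweep, row, col, onset_s,
    offset_s, frame_on, frame_off, x_deg, y_deg).
    """
    rows, cols = grid_shape
    if rect_width_deg > min(geometry.screen_width_deg, geometry.screen_height_deg):
        raise ValueError("rectangle larger than the screen")
    h, w = _canvas_shape(geometry, (geometry.screen_width_deg, geometry.screen_height_deg))
    xx, yy = _pixel_grid(geometry.pixels_per_degree, w, h)
    cell_w = geometry.screen_width_deg / cols
    cell_h = geometry.screen_height_deg / rows
    centers = [
        (
            (c + 0.5) * cell_w - geometry.screen_width_deg / 2.0,
            geometry.screen_height_deg / 2.0 - (r + 0.5) * cell_h,
        )
        for r in range(rows)
        for c in range(cols)
    ]
    on_f = int(round(on_ms / 1000.0 * geometry.frame_rate))
    off_f = int(round(off_ms / 1000.0 * geometry.frame_rate))
    rng = np.random.default_rng(order_seed)
    order = np.concatenate([rng.permutation(rows * cols) for _ in range(n_sweeps)])
    n_pres = len(order)
    frames = np.full((n_pres * (on_f + off_f), h, w), geometry.gray, dtype=np.float32)
    records = []
    half = rect_width_deg / 2.0
    for p, cell in enumerate(order):
        r, c = divmod(int(cell), cols)
        cx, cy = centers[int(cell)]
        rect = (np.abs(xx - cx) <= half) & (np.abs(yy - cy) <= half)
        f0 = p * (on_f + off_f)
        frames[f0 : f0 + on_f, rect] = geometry.black
        records.append(
            {
                "presentation": p,
                "sweep": p // (rows * cols),
                "row": r,
                "col": c,
                "onset_s": f0 / geometry.frame_rate,
                "offset_s": (f0 + on_f) / geometry.frame_rate,
                "frame_on": f0,
                "frame_off": f0 + on_f,
                "x_deg": cx,
                "y_deg": cy,
            }
        )
    table = pd.DataFrame.from_records(records)
    times = np.arange(frames.shape[0]) / geometry.frame_rate
    stack = FrameStack(
        frames,
        times,
        "RECT",
        geometry,
        meta={
            "grid_shape": grid_shape,
            "cell_size_deg": (cell_w, cell_h),
            "rect_width_deg": rect_width_deg,
            "order_seed": order_seed,
        },
    )
    return stack, table


def render_size_tuning(
    geometry: DisplayGeometry,
    sizes_deg: Sequence[float] = (2.5, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0),
    grating: GratingSpec | None = None,
    rf_center: tuple[float, float] = (0.0, 0.0),
    duration: float = 0.6667,
    directions: Sequence[float] = (0.0, 90.0),
) -> list[FrameStack]:
    """Circular drifting-grating patches of graded size on gray background.

    One stack per (size, direction); patches are centered on ``rf_center``.
    Default grating: SF 0.05 cyc/deg, TF 3 Hz.
    """
    if any(s <= 0 for s in sizes_deg):
        raise ValueError("sizes must be positive")
    base = grating or GratingSpec(temporal_frequency=3.0)
    h, w = _canvas_shape(geometry, (geometry.screen_width_deg, geometry.screen_height_deg))
    xx, yy = _pixel_grid(geometry.pixels_per_degree, w, h)
    rr = np.hypot(xx - rf_center[0], yy - rf_center[1])
    n = _n_frames(duration, geometry.frame_rate)
    times = np.arange(n) / geometry.frame_rate
    stacks = []
    for size in sizes_deg:
        patch = rr <= size / 2.0
        for direction in directions:
            g = GratingSpec(
                base.spatial_frequency, base.temporal_frequency, direction, base.phase0
            )
            frames = np.full((n, h, w), geometry.gray, dtype=np.float32)
            for k, t in enumerate(times):
                dark = grating_dark_mask(xx, yy, g, t)
                frames[k][patch & dark] = geometry.black
                frames[k][patch & ~dark] = geometry.white
            stacks.append(
                FrameStack(
                    frames,
                    times,
                    "SIZE",
                    geometry,
                    g,
                    meta={"size_deg": size, "rf_center": rf_center},
                )
            )
    return stacks


def gray_indicator_phase(stack: FrameStack) -> float:
    """Phase (radians) of the fundamental drifting component of the
    gray-pixel indicator along the drift axis.

    Each frame's binarized gray indicator is projected onto the complex
    exponential at the grating's spatial frequency and demodulated at the
    drift (temporal) frequency; averaging over a full temporal cycle
    isolates the drifting fundamental and cancels the static inducer-ring
    envelope exactly.
    """
    if stack.grating is None:
        raise ValueError("stack carries no grating specification")
    g = stack.grating
    xx, yy = stack.pixel_coords_deg()
    th = np.deg2rad(g.direction)
    proj = xx * np.cos(th) + yy * np.sin(th)
    carrier = np.exp(-1j * 2.0 * np.pi * g.spatial_frequency * proj)
    zs = []
    for k, t in enumerate(stack.frame_times):
        ind = stack.frames[k] == stack.geometry.gray
        zs.append(np.sum(carrier[ind]) * np.exp(1j * 2.0 * np.pi * g.temporal_frequency * t))
    return float(np.angle(np.mean(zs)))


def fundamental_phase_offset(stack_a: FrameStack, stack_b: FrameStack) -> float:
    """Spatial phase offset (degrees, wrapped to [0, 360)) between the
    fundamental gray-indicator components of two matched stacks."""
    d = gray_indicator_phase(stack_a) - gray_indicator_phase(stack_b)
    return float(np.mod(np.rad2deg(d), 360.0))


def condition_table(
    stimulus_types: Sequence[str] = ("NCS", "DBC", "LDG"),
    directions: Sequence[float] = DIRECTIONS_8,
    trials_per_condition: int = 70,
    order_seed: int = 0,
    duration_s: float = 1.0,
    iti_s: float = 0.5,
    light: Sequence[bool] = (False,),
) -> pd.DataFrame:
    """Pseudo-randomized trial table for the main grating session.

    Conditions are the cross of stimulus types, drift directions and the
    optogenetic-light flag; each condition appears ``trials_per_condition``
    times in a seeded random order.  Columns: trial_id, stimulus_type,
    direction, light, onset_s, offset_s.
    """
    conds = [
        (s, float(d), bool(l))
        for s in stimulus_types
        for d in directions
        for l in light
    ]
    reps = np.repeat(np.arange(len(conds)), trials_per_condition)
    rng = np.random.default_rng(order_seed)
    rng.shuffle(reps)
    onsets = np.arange(len(reps)) * (duration_s + iti_s)
    rows = []
    for i, ci in enumerate(reps):
        s, d, l = conds[ci]
        rows.append(
            {
                "trial_id": i,
                "stimulus_type": s,
                "direction": d,
                "light": l,
                "onset_s": float(onsets[i]),
                "offset_s": float(onsets[i] + duration_s),
            }
        )
    return pd.DataFrame.from_records(rows)
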