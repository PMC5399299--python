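"""Synthetic movies, images and traces with recorded ground truth.

Every generator in this module returns its ground truth alongside the
generated data, so each downstream analysis stage has a parameter-recovery
test: oscillating per-cell traces with known period, jitter, bleaching and
noise; two-channel FRET pairs with a known spatial ratio field and a known
inter-channel shift; punctate cluster images of known area and circularity;
drifting nuclear blobs of known speed; elliptical tissue masks of known
axis ratio.

Conventions: images are (row, col) with y increasing downward; the AP
(anterior–posterior) axis defaults to the +x (column) direction; intensity
values live in a 12-bit range (0–4,095).  The oscillation waveform is a
raised cosine per cycle — smooth, well-defined peaks even under
cycle-length jitter — with cycle lengths drawn from a gamma distribution of
mean ``true_period`` and coefficient of variation ``period_jitter_cv``.
Noise is additive Gaussian clipped at zero, the simplest model consistent
with background-subtracted fluorescence.  Photorealism (PSF convolution,
shot noise, camera gain) is deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .stack import ADU_12BIT_MAX, TimeLapseStack
from .traces import IntensityTrace

__all__ = [
    "TraceGroundTruth",
    "SceneGroundTruth",
    "ClusterSpec",
    "TraceRealization",
    "FretPairTruth",
    "ClusterImageTruth",
    "RotationMovieTruth",
    "EllipseMaskTruth",
    "make_oscillatory_trace",
    "make_fret_pair",
    "make_cluster_image",
    "make_rotation_movie",
    "make_ellipse_mask",
    "grid_cell_layout",
    "rasterize_cells",
    "save_truth_sidecar",
]


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceGroundTruth:
    """Parameters of one synthetic oscillatory intensity trace.

    ``bleach_time_constant`` may be ``math.inf`` (no bleaching);
    ``period_jitter_cv`` is the coefficient of variation of individual
    cycle lengths (0 = perfectly regular).
    """

    true_period: float  # s
    amplitude: float  # AFU
    baseline: float  # AFU
    bleach_time_constant: float = math.inf  # s
    noise_sd: float = 0.0  # AFU
    period_jitter_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_period > 0:
            raise ValueError("true_period must be > 0")
        if self.amplitude < 0 or self.noise_sd < 0 or self.period_jitter_cv < 0:
            raise ValueError("amplitude, noise_sd and period_jitter_cv must be >= 0")
        if not self.bleach_time_constant > 0:
            raise ValueError("bleach_time_constant must be > 0 (inf allowed)")


@dataclass(frozen=True)
class ClusterSpec:
    """One painted punctum: a filled disk (``radius``) or axis-rotated
    ellipse (``axes`` = semi-axes in px) of constant intensity."""

    center: tuple[float, float]  # (row, col) px
    intensity: float  # AFU
    radius: float | None = None  # px
    axes: tuple[float, float] | None = None  # (semi_r, semi_c) px
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if (self.radius is None) == (self.axes is None):
            raise ValueError("give exactly one of radius or axes")

    def analytic_area_um2(self, pixel_size: float) -> float:
        if self.radius is not None:
            return math.pi * self.radius**2 * pixel_size**2
        a, b = self.axes
        return math.pi * a * b * pixel_size**2


@dataclass
class SceneGroundTruth:
    """Geometry and signal layout of one synthetic scene.

    ``cell_layout`` is a list of polygons, each an ``(N, 2)`` array of
    (row, col) vertices.  ``ratio_field`` maps region names to true FRET
    ratios; recognised keys are ``medial``, ``junction`` or the orientation
    split ``junction_dv`` / ``junction_ap``.  ``shift`` is the (dy, dx)
    pixel translation applied to channel II.
    """

    cell_layout: list = field(default_factory=list)
    junction_band_width: float = 1.5  # μm
    medial_signal_fraction: float | None = None
    cluster_specs: list = field(default_factory=list)
    ratio_field: dict = field(default_factory=dict)
    shift: tuple[float, float] = (0.0, 0.0)
    rotation_speed: float = 0.0  # μm/min
    drift_direction_deg: float = 0.0
    nuclei: np.ndarray | None = None  # (N, 2) initial (row, col) px
    ellipse_axes: tuple[float, float] | None = None  # (AP, DV) μm
    pixel_size: float = 0.2  # μm/px
    ap_axis_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.medial_signal_fraction is not None and not (
            0.0 <= self.medial_signal_fraction <= 1.0
        ):
            raise ValueError("medial_signal_fraction must lie in [0, 1]")
        if math.hypot(*self.shift) >= 10:
            raise ValueError("shift magnitude must be < 10 px")


# realization containers -----------------------------------------------------

@dataclass
class TraceRealization:
    """A generated trace plus its full ground truth (cycle boundaries,
    peak times, and the noise-free / bleach-free signals)."""

    trace: IntensityTrace
    truth: TraceGroundTruth
    cycle_boundaries: np.ndarray  # s, cycle start times (first at 0)
    peak_times: np.ndarray  # s, one per complete cycle
    noiseless: np.ndarray  # bleached, noise-free values
    unbleached: np.ndarray  # noise-free, bleach-free values

    @property
    def realized_cycle_lengths(self) -> np.ndarray:
        return np.diff(self.cycle_boundaries)


@dataclass
class FretPairTruth:
    channel_i: TimeLapseStack
    channel_ii: TimeLapseStack
    scene: SceneGroundTruth
    labels: np.ndarray  # cell label image (0 = background)
    junction_mask: np.ndarray
    medial_mask: np.ndarray
    dv_band_mask: np.ndarray
    ap_band_mask: np.ndarray
    ratio_map: np.ndarray  # true per-pixel ratio (1 outside cells)
    ideal_channel_i: np.ndarray  # noise-free, background-free
    ideal_channel_ii_pre_shift: np.ndarray


@dataclass
class ClusterImageTruth:
    image: np.ndarray
    scene: SceneGroundTruth
    pixel_size: float
    cluster_masks: list  # one boolean mask per spec
    pixel_areas_um2: np.ndarray  # painted-pixel areas
    analytic_areas_um2: np.ndarray
    cell_labels: np.ndarray | None
    cell_of_cluster: np.ndarray | None  # cell id per spec (0 = none)


@dataclass
class RotationMovieTruth:
    stack: TimeLapseStack
    scene: SceneGroundTruth
    positions_px: np.ndarray  # (T, N, 2) (row, col)
    true_speed_um_per_min: float
    sigma_px: float


@dataclass
class EllipseMaskTruth:
    mask: np.ndarray
    axes_ap_dv_um: tuple[float, float]
    true_ratio: float
    pixel_size: float


# ---------------------------------------------------------------------------
# oscillatory traces
# ---------------------------------------------------------------------------

def make_oscillatory_trace(
    truth: TraceGroundTruth, duration: float, dt: float
) -> TraceRealization:
    """Generate one oscillating intensity trace.

    The value at time *t* inside cycle *k* (spanning ``[b_k, b_{k+1})``) is

    ``(baseline + amplitude * 0.5 * (1 - cos(2π (t-b_k)/L_k)) + ε_t) * exp(-t/τ)``

    clipped at zero, with ``ε_t ~ N(0, noise_sd)``; cycle lengths ``L_k``
    are gamma distributed with mean ``true_period`` and CV
    ``period_jitter_cv``.  Peaks sit at cycle midpoints and are recorded as
    ground truth.

    The noise term models signal-borne intensity fluctuations, so it is
    scaled by the photobleaching decay together with the signal (as photon
    noise is); this keeps bleach correction well-posed, i.e. a divided-out
    decay restores homoscedastic noise rather than amplifying the tail.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration < 3 * truth.true_period:
        raise ValueError(
            "duration must cover at least three oscillation periods; "
            "parameter recovery is undefined on shorter traces"
        )
    rng = np.random.default_rng(truth.seed)
    cv = truth.period_jitter_cv
    boundaries = [0.0]
    while boundaries[-1] <= duration + truth.true_period:
        if cv == 0:
            L = truth.true_period
        else:
            shape = 1.0 / cv**2
            L = rng.gamma(shape, truth.true_period / shape)
        boundaries.append(boundaries[-1] + L)
    boundaries = np.asarray(boundaries)
    times = np.arange(0.0, duration - dt / 2, dt)
    # map each sample into its cycle
    idx = np.searchsorted(boundaries, times, side="right") - 1
    b = boundaries[idx]
    L = boundaries[idx + 1] - b
    phase = (times - b) / L
    osc = 0.5 * (1.0 - np.cos(2 * np.pi * phase))
    unbleached = truth.baseline + truth.amplitude * osc
    if math.isinf(truth.bleach_time_constant):
        decay = np.ones_like(times)
    else:
        decay = np.exp(-times / truth.bleach_time_constant)
    noiseless = unbleached * decay
    if truth.noise_sd > 0:
        noisy = unbleached + rng.normal(0, truth.noise_sd, times.shape)
        values = np.clip(noisy * decay, 0, None)
    else:
        values = noiseless
    trace = IntensityTrace(times=times, values=values, dt=dt, provenance="raw")
    complete = boundaries[1:] <= duration + 1e-9
    peak_times = (boundaries[:-1] + boundaries[1:])[complete] / 2
    return TraceRealization(
        trace=trace,
        truth=truth,
        cycle_boundaries=boundaries[: int(complete.sum()) + 1],
        peak_times=peak_times,
        noiseless=noiseless,
        unbleached=unbleached,
    )


# ---------------------------------------------------------------------------
# cell geometry helpers
# ---------------------------------------------------------------------------

def grid_cell_layout(
    n_rows: int, n_cols: int, cell_px: int, origin: tuple[int, int] = (2, 2)
) -> list:
    """Rectangular grid of square cell polygons (an idealized epithelium)."""
    cells = []
    r0, c0 = origin
    for i in range(n_rows):
        for j in range(n_cols):
            r, c = r0 + i * cell_px, c0 + j * cell_px
            cells.append(
                np.array(
                    [[r, c], [r, c + cell_px - 1], [r + cell_px - 1, c + cell_px - 1], [r + cell_px - 1, c]],
                    dtype=float,
                )
            )
    return cells


def rasterize_cells(cell_layout, image_shape) -> np.ndarray:
    """Label image (1-based) from cell polygons; 0 is background."""
    labels = np.zeros(image_shape, dtype=np.int64)
    for i, poly in enumerate(cell_layout, start=1):
        poly = np.asarray(poly, dtype=float)
        if (poly < 0).any() or (poly[:, 0] >= image_shape[0]).any() or (
            poly[:, 1] >= image_shape[1]
        ).any():
            raise ValueError(f"cell polygon {i} lies outside the image frame")
        rr, cc = skdraw.polygon(poly[:, 0], poly[:, 1], shape=image_shape)
        labels[rr, cc] = i
    return labels


def _band_and_orientation(
    labels: np.ndarray, scene: SceneGroundTruth
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell junction band from the distance transform, with band pixels
    labeled DV- or AP-oriented by the nearest polygon edge's direction."""
    band_px = scene.junction_band_width / scene.pixel_size
    junction = np.zeros(labels.shape, dtype=bool)
    medial = np.zeros(labels.shape, dtype=bool)
    dv_band = np.zeros(labels.shape, dtype=bool)
    ap_band = np.zeros(labels.shape, dtype=bool)
    dv_axis = math.radians(scene.ap_axis_deg + 90.0)
    for i, poly in enumerate(scene.cell_layout, start=1):
        cell = labels == i
        if not cell.any():
            continue
        dist = ndimage.distance_transform_edt(cell)
        band = cell & (dist <= band_px)
        junction |= band
        medial |= cell & ~band
        # orient band pixels by the nearest polygon edge
        poly = np.asarray(poly, dtype=float)
        segs = list(zip(poly, np.roll(poly, -1, axis=0)))
        pts = np.argwhere(band).astype(float)
        if len(pts) == 0:
            continue
        best_d = np.full(len(pts), np.inf)
        best_dv = np.zeros(len(pts), dtype=bool)
        for a, b in segs:
            ab = b - a
            L2 = float(np.dot(ab, ab))
            if L2 == 0:
                continue
            t = np.clip(((pts - a) @ ab) / L2, 0, 1)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(pts - proj, axis=1)
            theta = math.atan2(ab[0], ab[1])  # angle vs +x, y downward
            dang = abs(((theta - dv_axis) + math.pi / 2) % math.pi - math.pi / 2)
            is_dv = dang <= math.radians(45.0) + 1e-12
            closer = d < best_d
            best_d[closer] = d[closer]
            best_dv[closer] = is_dv
        rows = pts[:, 0].astype(int)
        cols = pts[:, 1].astype(int)
        dv_band[rows[best_dv], cols[best_dv]] = True
        ap_band[rows[~best_dv], cols[~best_dv]] = True
    return junction, medial, dv_band, ap_band


# ---------------------------------------------------------------------------
# FRET pairs
# ---------------------------------------------------------------------------

def make_fret_pair(
    scene: SceneGroundTruth,
    image_shape: tuple[int, int],
    noise_sd: float = 0.0,
    background_level: float = 0.0,
) -> FretPairTruth:
    """Two-channel acquisition with a known per-region ratio field.

    Channel I carries a per-cell base intensity; channel II equals channel I
    times the local true ratio, translated by ``scene.shift``, and both
    channels then receive the background level plus clipped Gaussian noise.
    Pixels outside all cells carry only background and noise.
    """
    labels = rasterize_cells(scene.cell_layout, image_shape)
    if not scene.ratio_field:
        raise ValueError("scene.ratio_field must define ratios for every cell region")
    junction, medial, dv_band, ap_band = _band_and_orientation(labels, scene)
    rng = np.random.default_rng(scene.seed)
    base = rng.uniform(0.18 * ADU_12BIT_MAX, 0.28 * ADU_12BIT_MAX, len(scene.cell_layout))
    ideal_i = np.zeros(image_shape)
    for i in range(1, len(scene.cell_layout) + 1):
        ideal_i[labels == i] = base[i - 1]
    ratio_map = np.ones(image_shape)
    rf = scene.ratio_field
    if "medial" in rf:
        ratio_map[medial] = rf["medial"]
    if "junction" in rf:
        ratio_map[junction] = rf["junction"]
    if "junction_dv" in rf or "junction_ap" in rf:
        ratio_map[dv_band] = rf.get("junction_dv", rf.get("junction", 1.0))
        ratio_map[ap_band] = rf.get("junction_ap", rf.get("junction", 1.0))
    ideal_ii = ideal_i * ratio_map
    shifted_ii = ndimage.shift(ideal_ii, scene.shift, order=1, mode="constant", cval=0.0)
    ch_i = ideal_i + background_level
    ch_ii = shifted_ii + background_level
    if noise_sd > 0:
        ch_i = np.clip(ch_i + rng.normal(0, noise_sd, image_shape), 0, None)
        ch_ii = np.clip(ch_ii + rng.normal(0, noise_sd, image_shape), 0, None)
    return FretPairTruth(
        channel_i=TimeLapseStack(ch_i[None], pixel_size=scene.pixel_size),
        channel_ii=TimeLapseStack(ch_ii[None], pixel_size=scene.pixel_size),
        scene=scene,
        labels=labels,
        junction_mask=junction,
        medial_mask=medial,
        dv_band_mask=dv_band,
        ap_band_mask=ap_band,
        ratio_map=ratio_map,
        ideal_channel_i=ideal_i,
        ideal_channel_ii_pre_shift=ideal_ii,
    )


# ---------------------------------------------------------------------------
# cluster images
# ---------------------------------------------------------------------------

def make_cluster_image(
    scene: SceneGroundTruth,
    image_shape: tuple[int, int],
    pixel_size: float | None = None,
    background_level: float = 0.0,
    noise_sd: float = 0.0,
) -> ClusterImageTruth:
    """Paint hard-edged puncta of known intensity, area and circularity.

    Specs must not overlap or touch (8-connectivity), so each painted
    region is unambiguously one ground-truth cluster.
    """
    pixel_size = pixel_size if pixel_size is not None else scene.pixel_size
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    image = np.zeros(image_shape)
    occupancy = np.zeros(image_shape, dtype=np.int64)
    masks, pixel_areas, analytic = [], [], []
    for k, spec in enumerate(scene.cluster_specs, start=1):
        r, c = spec.center
        yy, xx = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
        dy, dx = yy - r, xx - c
        if spec.radius is not None:
            # inclusive boundary, so the pixel area tracks the analytic area
            m = dy**2 + dx**2 <= spec.radius**2
        else:
            ang = math.radians(spec.angle_deg)
            u = dy * math.cos(ang) + dx * math.sin(ang)
            v = -dy * math.sin(ang) + dx * math.cos(ang)
            m = (u / spec.axes[0]) ** 2 + (v / spec.axes[1]) ** 2 <= 1.0
        if m.sum() == 0:
            raise ValueError(f"cluster spec {k} paints no pixels")
        grown = ndimage.binary_dilation(m, structure=np.ones((3, 3)))
        if (occupancy[grown] > 0).any():
            raise ValueError(
                f"cluster spec {k} overlaps or touches an earlier spec; "
                "ground truth would be ambiguous"
            )
        occupancy[m] = k
        image[m] = spec.intensity
        masks.append(m)
        pixel_areas.append(m.sum() * pixel_size**2)
        analytic.append(spec.analytic_area_um2(pixel_size))
    if scene.cell_layout:
        cell_labels = rasterize_cells(scene.cell_layout, image_shape)
        cell_of = np.array(
            [
                int(cell_labels[int(round(s.center[0])), int(round(s.center[1]))])
                for s in scene.cluster_specs
            ],
            dtype=np.int64,
        )
    else:
        cell_labels, cell_of = None, None
    image = image + background_level
    if noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        image = np.clip(image + rng.normal(0, noise_sd, image_shape), 0, None)
    return ClusterImageTruth(
        image=image,
        scene=scene,
        pixel_size=pixel_size,
        cluster_masks=masks,
        pixel_areas_um2=np.asarray(pixel_areas),
        analytic_areas_um2=np.asarray(analytic),
        cell_labels=cell_labels,
        cell_of_cluster=cell_of,
    )


# ---------------------------------------------------------------------------
# rotation movies
# ---------------------------------------------------------------------------

def make_rotation_movie(
    scene: SceneGroundTruth,
    image_shape: tuple[int, int],
    n_frames: int,
    dt: float,
    n_nuclei: int = 12,
    sigma_px: float = 3.0,
    peak_intensity: float = 1000.0,
    noise_sd: float = 0.0,
) -> RotationMovieTruth:
    """Drifting Gaussian nuclei emulating collective epithelial rotation.

    All nuclei translate at ``scene.rotation_speed`` (μm/min) along
    ``scene.drift_direction_deg``; every per-frame position is recorded as
    ground truth.  Nuclei must stay in frame for all frames.
    """
    rng = np.random.default_rng(scene.seed)
    step_px = scene.rotation_speed * (dt / 60.0) / scene.pixel_size
    ang = math.radians(scene.drift_direction_deg)
    # image convention: y down; direction angle measured from +x toward +y
    vel = np.array([math.sin(ang), math.cos(ang)]) * step_px  # (drow, dcol)
    margin = 4.0 * sigma_px
    total_disp = vel * (n_frames - 1)
    if scene.nuclei is not None:
        pos0 = np.asarray(scene.nuclei, dtype=float)
    else:
        lo = margin + np.maximum(0.0, -total_disp)
        hi = np.asarray(image_shape, dtype=float) - margin - np.maximum(0.0, total_disp)
        if (hi <= lo).any():
            raise ValueError("image too small for the requested drift and margin")
        pos0 = _poisson_disk(rng, lo, hi, n_nuclei, min_dist=6 * sigma_px)
    for t in (0, n_frames - 1):
        p = pos0 + vel * t
        if (p[:, 0] < margin).any() or (p[:, 1] < margin).any() or (
            p[:, 0] > image_shape[0] - margin
        ).any() or (p[:, 1] > image_shape[1] - margin).any():
            raise ValueError("nuclei leave the frame during the movie")
    positions = pos0[None] + vel[None, None] * np.arange(n_frames)[:, None, None]
    yy, xx = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
    frames = np.zeros((n_frames,) + tuple(image_shape))
    for t in range(n_frames):
        f = np.zeros(image_shape)
        for r, c in positions[t]:
            d2 = (yy - r) ** 2 + (xx - c) ** 2
            f += peak_intensity * np.exp(-d2 / (2 * sigma_px**2))
        if noise_sd > 0:
            f = np.clip(f + rng.normal(0, noise_sd, image_shape), 0, None)
        frames[t] = f
    return RotationMovieTruth(
        stack=TimeLapseStack(frames, pixel_size=scene.pixel_size, frame_interval=dt),
        scene=scene,
        positions_px=positions,
        true_speed_um_per_min=scene.rotation_speed,
        sigma_px=sigma_px,
    )


def _poisson_disk(rng, lo, hi, n, min_dist):
    pts = []
    for _ in range(20000):
        cand = np.array([rng.uniform(lo[0], hi[0]), rng.uniform(lo[1], hi[1])])
        if all(np.linalg.norm(cand - p) >= min_dist for p in pts):
            pts.append(cand)
            if len(pts) == n:
                return np.asarray(pts)
    raise ValueError("could not place all nuclei with the requested separation")


# ---------------------------------------------------------------------------
# ellipse masks
# ---------------------------------------------------------------------------

def make_ellipse_mask(
    axes_ap_dv: tuple[float, float], pixel_size: float, pad_px: int = 4
) -> EllipseMaskTruth:
    """Filled elliptical tissue mask; AP along columns, DV along rows.

    ``axes_ap_dv`` are the full axis lengths in μm; the true elongation
    ratio is their quotient.
    """
    ap, dv = axes_ap_dv
    if ap <= 0 or dv <= 0:
        raise ValueError("both axes must be > 0")
    semi_c = ap / 2.0 / pixel_size
    semi_r = dv / 2.0 / pixel_size
    shape = (
        int(math.ceil(2 * semi_r)) + 2 * pad_px + 1,
        int(math.ceil(2 * semi_c)) + 2 * pad_px + 1,
    )
    mask = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.ellipse(shape[0] / 2, shape[1] / 2, semi_r, semi_c, shape=shape)
    mask[rr, cc] = True
    return EllipseMaskTruth(mask, (ap, dv), ap / dv, pixel_size)


# ---------------------------------------------------------------------------
# sidecars
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, TimeLapseStack):
        return {"shape": list(obj.data.shape), "pixel_size": obj.pixel_size,
                "frame_interval": obj.frame_interval}
    return obj


def save_truth_sidecar(path, truth) -> None:
    """Write a JSON ground-truth sidecar next to generated TIFF output."""
    with open(path, "w") as fh:
        json.dump(_jsonable(truth), fh, indent=1, sort_keys=True)
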