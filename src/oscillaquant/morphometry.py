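"""Tissue- and cell-scale morphometry: AP/DV elongation, rotation speed
from nuclear tracking, linescan profiles, planar-polarity ratios and
junctional/medial intensity partitions.

Angle convention: images are (row, col) with y increasing downward; axis
directions are degrees from +x (columns) toward +y (rows).  The AP
(anterior–posterior) axis direction is a required input — chambers are
oriented by the experimenter, not inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters as skfilters
from skimage import measure as skmeasure

from .fret import CellPartition
from .stack import TimeLapseStack

__all__ = [
    "ShapeMeasure",
    "TrackSet",
    "PolarityResult",
    "RegionStats",
    "measure_elongation",
    "detect_nuclei",
    "link_tracks",
    "rotation_speed",
    "linescan_profile",
    "polarity_ratio",
    "region_intensity_stats",
]


@dataclass
class ShapeMeasure:
    """AP and DV extents of a tissue mask and their ratio (elongation)."""

    ap_length: float  # μm
    dv_length: float  # μm

    @property
    def ratio(self) -> float:
        return self.ap_length / self.dv_length


@dataclass
class TrackSet:
    """Linked nuclear trajectories.

    ``tracks`` maps nucleus id → list of ``(t_s, x_um, y_um)`` tuples with
    strictly increasing times (one position per frame at most).
    """

    tracks: dict
    dt: float


@dataclass
class PolarityResult:
    ratio: float
    degenerate: bool = False


@dataclass
class RegionStats:
    """Distribution of a cell's signal between junctional and medial regions."""

    junction_fraction_pct: float
    membrane_medial_ratio: float
    junction_mean: float
    medial_mean: float

    @property
    def medial_fraction_pct(self) -> float:
        return 100.0 - self.junction_fraction_pct


def measure_elongation(
    mask: np.ndarray,
    pixel_size: float,
    ap_axis_deg: float = 0.0,
    method: str = "caliper",
) -> ShapeMeasure:
    """AP-to-DV length ratio of a tissue mask.

    ``caliper`` (default) measures the maximal pixel extent of the mask
    along the AP direction and its perpendicular (each extent includes the
    1-px footprint, so an axis-aligned W×H rectangle measures exactly
    W×pixel_size by H×pixel_size).  ``ellipse`` instead uses the
    moment-fitted ellipse's axis lengths.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if skmeasure.label(mask, connectivity=2).max() != 1:
        raise ValueError("mask must be a single connected region")
    if method == "ellipse":
        prop = skmeasure.regionprops(mask.astype(np.uint8))[0]
        # orientation: angle of the major axis vs the row axis
        major_deg = 90.0 - math.degrees(prop.orientation)
        d = abs(((major_deg - ap_axis_deg) + 90.0) % 180.0 - 90.0)
        major = prop.axis_major_length * pixel_size
        minor = prop.axis_minor_length * pixel_size
        return ShapeMeasure(major, minor) if d <= 45.0 else ShapeMeasure(minor, major)
    if method != "caliper":
        raise ValueError("method must be 'caliper' or 'ellipse'")
    coords = np.argwhere(mask).astype(float)  # (row, col)
    theta = math.radians(ap_axis_deg)
    u_ap = np.array([math.sin(theta), math.cos(theta)])  # (drow, dcol)
    u_dv = np.array([math.cos(theta), -math.sin(theta)])
    proj_ap = coords @ u_ap
    proj_dv = coords @ u_dv
    ap_len = (proj_ap.max() - proj_ap.min() + 1.0) * pixel_size
    dv_len = (proj_dv.max() - proj_dv.min() + 1.0) * pixel_size
    return ShapeMeasure(ap_len, dv_len)


def detect_nuclei(
    frame: np.ndarray,
    expected_radius_um: float,
    pixel_size: float,
    threshold: float | None = None,
) -> np.ndarray:
    """Intensity-weighted centroids of bright nuclear blobs, in (row, col) px.

    The frame is Gaussian-smoothed at half the expected radius, thresholded
    (Otsu by default) and labeled; components smaller than a quarter of the
    expected nuclear disk are discarded as noise.
    """
    frame = np.asarray(frame, dtype=float)
    r_px = expected_radius_um / pixel_size
    smoothed = ndimage.gaussian_filter(frame, r_px / 2.0)
    if threshold is None:
        if smoothed.max() == smoothed.min():
            return np.empty((0, 2))
        threshold = skfilters.threshold_otsu(smoothed)
    binary = smoothed > threshold
    labels = skmeasure.label(binary, connectivity=2)
    min_area = 0.25 * math.pi * r_px**2
    out = []
    for prop in skmeasure.regionprops(labels, intensity_image=frame):
        if prop.area < min_area:
            continue
        out.append(prop.centroid_weighted)
    return np.asarray(out) if out else np.empty((0, 2))


def link_tracks(
    detections_per_frame,
    pixel_size: float,
    dt: float,
    max_displacement_um: float,
) -> TrackSet:
    """Greedy mutual-nearest-neighbour frame-to-frame linking.

    At each frame transition the closest (track end, detection) pairs are
    linked in order of distance; links beyond ``max_displacement_um`` are
    never made (the track simply ends) and unmatched detections start new
    tracks.  No gap closing or merging — epithelial rotation is slow and
    coherent, so this suffices.
    """
    tracks: dict = {}
    active: dict = {}  # track id -> last (row, col) px
    next_id = 0
    for t, dets in enumerate(detections_per_frame):
        dets = np.asarray(dets, dtype=float).reshape(-1, 2)
        assigned = set()
        new_active = {}
        if active and len(dets):
            ids = list(active)
            ends = np.asarray([active[i] for i in ids])
            d = np.linalg.norm(ends[:, None, :] - dets[None, :, :], axis=2) * pixel_size
            pairs = sorted(
                ((d[a, b], a, b) for a in range(len(ids)) for b in range(len(dets))),
            )
            used_tracks = set()
            for dist, a, b in pairs:
                if dist > max_displacement_um:
                    break
                if a in used_tracks or b in assigned:
                    continue
                used_tracks.add(a)
                assigned.add(b)
                tid = ids[a]
                tracks[tid].append((t * dt, dets[b, 1] * pixel_size, dets[b, 0] * pixel_size))
                new_active[tid] = dets[b]
        for b in range(len(dets)):
            if b in assigned:
                continue
            tracks[next_id] = [(t * dt, dets[b, 1] * pixel_size, dets[b, 0] * pixel_size)]
            new_active[next_id] = dets[b]
            next_id += 1
        active = new_active
    return TrackSet(tracks, dt)


def rotation_speed(tracks: TrackSet) -> float:
    """Mean nuclear migration speed of the chamber, in μm/min.

    Each track's speed is its mean frame-to-frame path displacement over
    ``dt`` (path length, not net displacement); the chamber speed is the
    average over all tracks of length ≥ 2.
    """
    speeds = []
    for pts in tracks.tracks.values():
        if len(pts) < 2:
            continue
        arr = np.asarray(pts)
        steps = np.linalg.norm(np.diff(arr[:, 1:3], axis=0), axis=1)
        dts = np.diff(arr[:, 0])
        speeds.append(float(np.mean(steps / dts) * 60.0))
    if not speeds:
        raise ValueError("no track of length >= 2; speed undefined")
    return float(np.mean(speeds))


def per_track_speeds(tracks: TrackSet) -> dict:
    """Per-nucleus path-length speeds in μm/min (tracks of length ≥ 2)."""
    out = {}
    for tid, pts in tracks.tracks.items():
        if len(pts) < 2:
            continue
        arr = np.asarray(pts)
        steps = np.linalg.norm(np.diff(arr[:, 1:3], axis=0), axis=1)
        out[tid] = float(np.mean(steps / np.diff(arr[:, 0])) * 60.0)
    return out


def linescan_profile(
    image: np.ndarray, path: np.ndarray, width_px: int = 10
) -> pd.DataFrame:
    """Mean intensity along a polyline, averaged across a perpendicular stripe.

    The path (``(N, 2)`` array of (row, col) px) is resampled at 1-px
    arclength steps; at each sample the intensity is averaged over
    ``width_px`` bilinear samples spaced 1 px apart along the local normal.
    Returns a table of arclength (px) vs mean intensity.
    """
    image = np.asarray(image, dtype=float)
    path = np.asarray(path, dtype=float).reshape(-1, 2)
    if len(path) < 2:
        raise ValueError("path needs at least two vertices")
    if width_px < 1:
        raise ValueError("width must be >= 1 px")
    if (path < 0).any() or (path[:, 0] > image.shape[0] - 1).any() or (
        path[:, 1] > image.shape[1] - 1
    ).any():
        raise ValueError("path exits the image")
    # resample at 1 px arclength
    seg = np.diff(path, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    s = np.arange(0.0, total + 1e-9, 1.0)
    rows = np.interp(s, arclen, path[:, 0])
    cols = np.interp(s, arclen, path[:, 1])
    # tangent by central differences, normal perpendicular to it
    tr = np.gradient(rows)
    tc = np.gradient(cols)
    norm = np.hypot(tr, tc)
    norm[norm == 0] = 1.0
    nr, nc = -tc / norm, tr / norm
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    rr = rows[None, :] + offsets[:, None] * nr[None, :]
    cc = cols[None, :] + offsets[:, None] * nc[None, :]
    samples = ndimage.map_coordinates(
        image, [rr, cc], order=1, mode="nearest"
    )
    return pd.DataFrame({"arclength_px": s, "mean_intensity": samples.mean(axis=0)})


def polarity_ratio(
    image: np.ndarray, dv_mask: np.ndarray, ap_mask: np.ndarray
) -> PolarityResult:
    """Total intensity on DV-labeled edge pixels ÷ total on AP-labeled ones.

    A class with zero total intensity yields a degenerate-flagged result
    (ratio inf when AP is empty, 0 when DV is empty).
    """
    image = np.asarray(image, dtype=float)
    dv_mask = np.asarray(dv_mask, dtype=bool)
    ap_mask = np.asarray(ap_mask, dtype=bool)
    if not dv_mask.any() or not ap_mask.any():
        raise ValueError("both orientation classes must be non-empty")
    dv_total = float(image[dv_mask].sum())
    ap_total = float(image[ap_mask].sum())
    if ap_total == 0:
        return PolarityResult(math.inf, degenerate=True)
    if dv_total == 0:
        return PolarityResult(0.0, degenerate=True)
    return PolarityResult(dv_total / ap_total)


def region_intensity_stats(image: np.ndarray, partition: CellPartition) -> RegionStats:
    """Junctional vs medial distribution of a cell's signal.

    ``junction_fraction_pct`` is 100 × (signal in the junction band) /
    (signal in the whole cell), so junction and medial fractions sum to
    100% exactly; ``membrane_medial_ratio`` compares the regions' mean
    intensities.
    """
    image = np.asarray(image, dtype=float)
    j_sum = float(image[partition.junction_band].sum())
    m_sum = float(image[partition.medial_region].sum())
    total = j_sum + m_sum
    if total == 0:
        raise ValueError("cell carries zero total intensity")
    j_n = int(partition.junction_band.sum())
    m_n = int(partition.medial_region.sum())
    j_mean = j_sum / j_n if j_n else 0.0
    m_mean = m_sum / m_n if m_n else 0.0
    ratio = j_mean / m_mean if m_mean else math.inf
    if j_mean == 0:
        ratio = 0.0
    return RegionStats(100.0 * j_sum / total, ratio, j_mean, m_mean)
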