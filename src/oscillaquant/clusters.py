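"""Detection and quantification of fluorescent puncta (optogenetic
clusters) by intensity, size and circularity criteria.

A cluster is a connected component of pixels inside an intensity window
that survives three filters: area above a minimum (μm²), circularity
(4π·area/perimeter²) inside a range, and component mean intensity inside
the same window.  Two presets reproduce the published criteria:

* ``hela``     — intensity 2,500–4,095 AU, area > 0.2 μm², circularity 0.5–1.0
* ``follicle`` — intensity 1,200–4,095 AU, area > 0.2 μm², circularity 0.35–1.0

All thresholds assume 12-bit (0–4,095) data.  Perimeter uses the Crofton
multi-direction estimator by default (less biased than the naive boundary
count near circularity thresholds); the naive estimator is available for
sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure as skmeasure

from .stack import TimeLapseStack
from .traces import adjust_to_initial_intensity

__all__ = [
    "ClusterCriteria",
    "ClusterRecord",
    "ClusterSet",
    "PRESETS",
    "circularity",
    "region_perimeter",
    "detect_clusters",
    "cluster_area_per_cell",
    "cluster_time_course",
]


@dataclass(frozen=True)
class ClusterCriteria:
    """Filter thresholds defining a punctum."""

    intensity_range: tuple[float, float]  # (lo, hi) AFU
    min_area: float  # μm², exclusive lower bound
    circularity_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.intensity_range[0] < self.intensity_range[1]:
            raise ValueError("intensity_range must satisfy lo < hi")
        if not self.circularity_range[0] < self.circularity_range[1]:
            raise ValueError("circularity_range must satisfy lo < hi")
        if not self.min_area > 0:
            raise ValueError("min_area must be > 0")


PRESETS: dict[str, ClusterCriteria] = {
    "hela": ClusterCriteria((2500.0, 4095.0), 0.2, (0.5, 1.0)),
    "follicle": ClusterCriteria((1200.0, 4095.0), 0.2, (0.35, 1.0)),
}


@dataclass
class ClusterRecord:
    centroid_um: tuple[float, float]  # (y, x) μm
    area_um2: float
    mean_intensity: float
    circularity: float
    cell_id: int | None = None
    n_pixels: int = 0


@dataclass
class ClusterSet:
    """Detected puncta plus the context needed for per-cell aggregation."""

    records: list
    pixel_size: float
    image_shape: tuple[int, int]
    criteria: ClusterCriteria

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_area_um2(self) -> float:
        return float(sum(r.area_um2 for r in self.records))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "centroid_y_um": r.centroid_um[0],
                    "centroid_x_um": r.centroid_um[1],
                    "area_um2": r.area_um2,
                    "mean_intensity": r.mean_intensity,
                    "circularity": r.circularity,
                    "cell_id": r.cell_id,
                    "n_pixels": r.n_pixels,
                }
                for r in self.records
            ]
        )


def region_perimeter(region_mask: np.ndarray, estimator: str = "crofton") -> float:
    """Perimeter of a binary region in pixel units.

    ``crofton`` uses the 4-direction Crofton formula; ``naive`` counts
    boundary transitions.  The region is padded so the image border never
    truncates the boundary.
    """
    padded = np.pad(np.asarray(region_mask, dtype=bool), 1)
    if estimator == "crofton":
        return float(skmeasure.perimeter_crofton(padded, directions=4))
    if estimator == "naive":
        return float(skmeasure.perimeter(padded))
    raise ValueError("estimator must be 'crofton' or 'naive'")


def circularity(region_mask: np.ndarray, estimator: str = "crofton") -> float:
    """Shape circularity 4π·area/perimeter² of a pixel region.

    1 for a perfect circle, → 0 for elongated shapes; single-pixel regions
    are defined to have circularity 1.  Discretization can push values
    slightly above 1 for tiny regions; raw values are reported (callers
    clamp for filtering).
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    area = int(region_mask.sum())
    if area == 0:
        raise ValueError("region is empty")
    if area == 1:
        return 1.0
    per = region_perimeter(region_mask, estimator)
    return 4.0 * math.pi * area / per**2


def detect_clusters(
    image: np.ndarray,
    criteria: ClusterCriteria,
    pixel_size: float,
    cell_masks: np.ndarray | None = None,
    connectivity: int = 2,
    perimeter_estimator: str = "crofton",
) -> ClusterSet:
    """Find puncta passing the intensity / size / circularity criteria.

    Pixels inside ``intensity_range`` are binarized and grouped into
    8-connected components (``connectivity=1`` for 4-connected).  A
    component is kept iff its physical area exceeds ``min_area``, its
    circularity (clamped at the range's upper bound, so discretization
    overshoot on near-circles never rejects) lies within
    ``circularity_range``, and its mean intensity lies within
    ``intensity_range``.  Kept components are assigned to the cell label
    containing their centroid (``cell_masks`` is an integer label image).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    image = np.asarray(image, dtype=float)
    lo, hi = criteria.intensity_range
    binary = (image >= lo) & (image <= hi)
    labels = skmeasure.label(binary, connectivity=connectivity)
    records = []
    for prop in skmeasure.regionprops(labels, intensity_image=image):
        area_um2 = prop.area * pixel_size**2
        if not area_um2 > criteria.min_area:
            continue
        region = labels[prop.slice] == prop.label
        circ = circularity(region, perimeter_estimator)
        circ_f = min(circ, criteria.circularity_range[1])
        if not (criteria.circularity_range[0] <= circ_f):
            continue
        mean_int = float(prop.intensity_mean)
        if not (lo <= mean_int <= hi):
            continue
        cy, cx = prop.centroid
        cell_id = None
        if cell_masks is not None:
            cell_id = int(cell_masks[int(round(cy)), int(round(cx))])
        records.append(
            ClusterRecord(
                centroid_um=(cy * pixel_size, cx * pixel_size),
                area_um2=float(area_um2),
                mean_intensity=mean_int,
                circularity=float(circ),
                cell_id=cell_id,
                n_pixels=int(prop.area),
            )
        )
    return ClusterSet(records, pixel_size, image.shape, criteria)


def cluster_area_per_cell(
    clusters: ClusterSet, cell_ids=None
) -> dict[int, float]:
    """Total clustered area (μm²) per cell; cells with no clusters report 0."""
    totals: dict[int, float] = {}
    if cell_ids is not None:
        totals = {int(c): 0.0 for c in cell_ids}
    for r in clusters.records:
        if r.cell_id is None or r.cell_id == 0:
            continue
        totals[r.cell_id] = totals.get(r.cell_id, 0.0) + r.area_um2
    return totals


def cluster_time_course(
    stack: TimeLapseStack,
    criteria: ClusterCriteria,
    pixel_size: float | None = None,
    cell_masks: np.ndarray | None = None,
    foreground_mask: np.ndarray | None = None,
    connectivity: int = 2,
) -> pd.DataFrame:
    """Relative clustered area and mean cluster intensity over time.

    The stack is first scaled frame-by-frame to the initial image intensity
    (whole-image bleaching compensation), then clusters are detected per
    frame.  Values are reported relative to frame 0; if frame 0 has no
    clusters the reference is the first frame that does, and the
    ``reference_frame`` column flags this.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames for a time course")
    pixel_size = pixel_size if pixel_size is not None else stack.pixel_size
    adjusted = adjust_to_initial_intensity(stack, foreground_mask)
    rows = []
    for t in range(adjusted.n_frames):
        cs = detect_clusters(
            adjusted.frame(t), criteria, pixel_size, cell_masks, connectivity
        )
        if len(cs):
            pix = np.concatenate(
                [[r.mean_intensity] * r.n_pixels for r in cs.records]
            )
            mean_int = float(np.mean(pix))
        else:
            mean_int = float("nan")
        rows.append(
            {
                "frame": t,
                "time_s": t * stack.frame_interval,
                "n_clusters": len(cs),
                "total_area_um2": cs.total_area_um2,
                "mean_intensity": mean_int,
            }
        )
    df = pd.DataFrame(rows)
    ref_candidates = df.index[df["n_clusters"] > 0]
    ref = int(ref_candidates[0]) if len(ref_candidates) else 0
    ref_area = df.loc[ref, "total_area_um2"]
    ref_int = df.loc[ref, "mean_intensity"]
    df["relative_area"] = df["total_area_um2"] / ref_area if ref_area else np.nan
    df["relative_intensity"] = df["mean_intensity"] / ref_int if ref_int else np.nan
    df["reference_frame"] = ref
    return df
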