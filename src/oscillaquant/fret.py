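"""Ratiometric FRET processing and region-partitioned ratio statistics.

The pipeline mirrors standard two-channel biosensor practice: subtract a
background ROI from each channel, register the acceptor (channel II / YFP)
image onto the donor (channel I / CFP) image by translation, Gaussian-smooth
both, threshold the acceptor into a validity mask, and divide the channels
pixel by pixel on valid pixels only.  Per-cell statistics then compare the
junctional band (a fixed-width rim inside the cell boundary, default
1.5 μm) with the medial interior, and — for planar polarity — the
DV-oriented part of the band with the AP-oriented part.

Ratio convention: channel II over channel I by default, so a higher ratio
means higher biosensor (Rho1) activity; the convention is switchable and
swapping it inverts every reported ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage.registration import phase_cross_correlation

__all__ = [
    "RatioImage",
    "CellPartition",
    "subtract_background",
    "register_translation",
    "smooth",
    "mask_acceptor",
    "ratio_image",
    "partition_cell",
    "junction_medial_ratio",
    "dv_ap_junction_ratio",
]


@dataclass
class RatioImage:
    """Per-pixel FRET ratio with a validity mask.

    ``ratio`` is NaN wherever ``valid_mask`` is False (background or
    sub-threshold pixels carry no ratio value).
    """

    ratio: np.ndarray
    valid_mask: np.ndarray
    channel_convention: str = "II_over_I"

    def __post_init__(self) -> None:
        if self.channel_convention not in ("II_over_I", "I_over_II"):
            raise ValueError("channel_convention must be II_over_I or I_over_II")
        if not np.all(np.isfinite(self.ratio[self.valid_mask])):
            raise ValueError("ratio must be finite on valid pixels")

    def inverted(self) -> "RatioImage":
        """Same map under the opposite channel convention (x → 1/x)."""
        conv = "I_over_II" if self.channel_convention == "II_over_I" else "II_over_I"
        inv = np.full_like(self.ratio, np.nan)
        inv[self.valid_mask] = 1.0 / self.ratio[self.valid_mask]
        return RatioImage(inv, self.valid_mask.copy(), conv)


@dataclass
class CellPartition:
    """Junction band vs medial interior of one cell, with the band further
    labeled by local boundary orientation (DV- or AP-oriented)."""

    cell_id: object
    cell_mask: np.ndarray
    junction_band: np.ndarray
    medial_region: np.ndarray
    dv_band: np.ndarray
    ap_band: np.ndarray


def subtract_background(image: np.ndarray, background_roi: np.ndarray) -> np.ndarray:
    """Subtract the mean of a sample-free ROI, clipping at zero."""
    background_roi = np.asarray(background_roi, dtype=bool)
    if not background_roi.any():
        raise ValueError("background ROI is empty")
    return np.clip(np.asarray(image, dtype=float) - image[background_roi].mean(), 0, None)


def register_translation(
    moving: np.ndarray, reference: np.ndarray, upsample_factor: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the translation of ``moving`` relative to ``reference`` and
    undo it.

    Returns ``(shift, registered)`` where ``shift`` is the (dy, dx)
    displacement by which ``moving`` is offset from ``reference`` (sub-pixel
    via upsampled cross-correlation), and ``registered`` is ``moving``
    shifted by ``-shift``.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("images must share a shape")
    if moving.std() == 0 or reference.std() == 0:
        raise ValueError("cannot register structureless (constant) images")
    # phase_cross_correlation returns the shift that maps moving onto
    # reference, i.e. the negative of moving's displacement
    correction, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample_factor, normalization=None
    )
    shift = -np.asarray(correction, dtype=float)
    registered = ndimage.shift(moving, -shift, order=1, mode="constant", cval=0.0)
    return shift, registered


def smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing; ``sigma=0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma)


def mask_acceptor(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Binary validity mask from the (smoothed, background-subtracted)
    acceptor channel: pixels above the threshold (Otsu by default)."""
    image = np.asarray(image, dtype=float)
    if threshold is None:
        if image.max() == image.min():
            raise ValueError("cannot threshold a constant image")
        threshold = skfilters.threshold_otsu(image)
    mask = image > threshold
    if not mask.any():
        raise ValueError(f"threshold {threshold} exceeds the image maximum; empty mask")
    return mask


def ratio_image(
    channel_i: np.ndarray,
    channel_ii: np.ndarray,
    mask: np.ndarray,
    channel_convention: str = "II_over_I",
    eps: float | None = None,
) -> RatioImage:
    """Per-pixel ratio on valid pixels only.

    Pixels outside ``mask``, or where the denominator-side donor signal is
    at most ``eps`` (default: 1% of channel I's 99th percentile), are
    invalid and carry NaN.
    """
    channel_i = np.asarray(channel_i, dtype=float)
    channel_ii = np.asarray(channel_ii, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("validity mask is empty")
    if eps is None:
        eps = 0.01 * np.percentile(channel_i, 99)
    valid = mask & (channel_i > eps)
    ratio = np.full(channel_i.shape, np.nan)
    if channel_convention == "II_over_I":
        ratio[valid] = channel_ii[valid] / channel_i[valid]
    elif channel_convention == "I_over_II":
        valid = valid & (channel_ii > 0)
        ratio[valid] = channel_i[valid] / channel_ii[valid]
    else:
        raise ValueError("unknown channel_convention")
    return RatioImage(ratio, valid, channel_convention)


def partition_cell(
    cell_mask: np.ndarray,
    band_width: float,
    pixel_size: float = 1.0,
    ap_axis_deg: float = 0.0,
    cell_id=None,
) -> CellPartition:
    """Split one cell into a junctional band and a medial interior.

    The band is every cell pixel within ``band_width`` (μm) of the cell
    boundary, from the Euclidean distance transform.  Each band pixel is
    labeled DV-oriented if the local boundary tangent (PCA over nearby
    boundary pixels) lies within 45° of the DV axis (perpendicular to
    ``ap_axis_deg``), else AP-oriented.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    n_comp = skmeasure.label(cell_mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError("cell mask must be a single connected region")
    band_px = band_width / pixel_size
    dist = ndimage.distance_transform_edt(cell_mask)
    band = cell_mask & (dist <= band_px)
    medial = cell_mask & ~band
    if band.any() and not medial.any():
        raise ValueError("band width consumes the entire cell")
    dv_band = np.zeros_like(cell_mask)
    ap_band = np.zeros_like(cell_mask)
    if band.any():
        boundary = cell_mask & (dist <= 1.0)
        bpts = np.argwhere(boundary).astype(float)
        tree = cKDTree(bpts)
        # local tangent of each boundary pixel by PCA over its neighbourhood
        neigh = tree.query_ball_point(bpts, r=3.5)
        tangents = np.zeros(len(bpts))
        for i, nb in enumerate(neigh):
            pts = bpts[nb]
            centered = pts - pts.mean(axis=0)
            cov = centered.T @ centered
            w, v = np.linalg.eigh(cov)
            t = v[:, int(np.argmax(w))]  # (drow, dcol)
            tangents[i] = math.atan2(t[0], t[1])
        dv_axis = math.radians(ap_axis_deg + 90.0)
        dang = np.abs(((tangents - dv_axis) + math.pi / 2) % math.pi - math.pi / 2)
        is_dv = dang <= math.radians(45.0) + 1e-12
        # band pixels take the orientation of the nearest confidently
        # labeled boundary pixel; corner pixels (tangent ~45° off both
        # axes) and pixels equidistant from a DV and an AP edge are
        # ambiguous and fall back to the centroid-direction rule, which
        # splits corners symmetrically (a pixel AP-ward of the centroid
        # sits on a DV-running edge); exact diagonals alternate by row
        # parity so neither class is inflated
        unambiguous = np.abs(dang - math.pi / 4) > math.radians(5.0)
        band_pts = np.argwhere(band).astype(float)
        dv_set = bpts[unambiguous & is_dv]
        ap_set = bpts[unambiguous & ~is_dv]
        big = 1e9
        d_dv = (cKDTree(dv_set).query(band_pts)[0] if len(dv_set)
                else np.full(len(band_pts), big))
        d_ap = (cKDTree(ap_set).query(band_pts)[0] if len(ap_set)
                else np.full(len(band_pts), big))
        lab = d_dv < d_ap
        ambiguous_px = np.abs(d_dv - d_ap) <= 0.5
        if ambiguous_px.any():
            centroid = np.argwhere(cell_mask).mean(axis=0)
            d = band_pts[ambiguous_px] - centroid
            ap_axis = math.radians(ap_axis_deg)
            ang = np.arctan2(d[:, 0], d[:, 1])
            off_ap = np.abs(((ang - ap_axis) + math.pi / 2) % math.pi - math.pi / 2)
            amb_lab = off_ap < math.pi / 4 - 1e-9
            ties = np.abs(off_ap - math.pi / 4) <= 1e-9
            parity = band_pts[ambiguous_px][:, 0].astype(int) % 2 == 0
            amb_lab[ties] = parity[ties]
            lab[ambiguous_px] = amb_lab
        rows = band_pts[:, 0].astype(int)
        cols = band_pts[:, 1].astype(int)
        dv_band[rows[lab], cols[lab]] = True
        ap_band[rows[~lab], cols[~lab]] = True
    return CellPartition(cell_id, cell_mask, band, medial, dv_band, ap_band)


def _region_mean(img: RatioImage, region: np.ndarray, name: str, min_pixels: int):
    vals = img.ratio[region & img.valid_mask]
    if len(vals) == 0:
        raise ValueError(f"no valid ratio pixels in the {name} region")
    if len(vals) < min_pixels:
        raise ValueError(
            f"only {len(vals)} valid pixels in the {name} region "
            f"(need >= {min_pixels})"
        )
    return vals


def junction_medial_ratio(
    ratio_img: RatioImage, partition: CellPartition, min_pixels: int = 10
) -> float:
    """Mean valid ratio over the junction band ÷ mean over the medial region."""
    j = _region_mean(ratio_img, partition.junction_band, "junction", min_pixels)
    m = _region_mean(ratio_img, partition.medial_region, "medial", min_pixels)
    return float(j.mean() / m.mean())


def dv_ap_junction_ratio(
    ratio_img: RatioImage,
    partition: CellPartition,
    statistic: str = "total",
    min_pixels: int = 10,
) -> float:
    """Ratio of DV-oriented to AP-oriented junctional signal.

    ``statistic="total"`` (the planar-polarity definition: total signal on
    the DV axis relative to the AP axis) sums valid ratio values over each
    orientation class; ``"mean"`` averages them instead.
    """
    dv = _region_mean(ratio_img, partition.dv_band, "DV-oriented band", min_pixels)
    ap = _region_mean(ratio_img, partition.ap_band, "AP-oriented band", min_pixels)
    if statistic == "total":
        num, den = dv.sum(), ap.sum()
    elif statistic == "mean":
        num, den = dv.mean(), ap.mean()
    else:
        raise ValueError("statistic must be 'total' or 'mean'")
    if den == 0:
        raise ValueError("AP-oriented signal is zero; DV/AP ratio is degenerate")
    return float(num / den)
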