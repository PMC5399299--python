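import math

import numpy as np
import pytest

from oscillaquant import synth


@pytest.fixture
def regular_trace():
    """Noiseless, jitter-free 180 s oscillation sampled at 30 s for 1800 s."""
    truth = synth.TraceGroundTruth(
        true_period=180.0, amplitude=4.0, baseline=10.0, seed=0
    )
    return synth.make_oscillatory_trace(truth, 1800.0, 30.0)


@pytest.fixture
def grid_scene():
    """3×3 grid of 40 px square cells with junction ratio 1.5 over medial 1.0."""
    return synth.SceneGroundTruth(
        cell_layout=synth.grid_cell_layout(3, 3, 40, origin=(10, 10)),
        junction_band_width=1.5,
        ratio_field={"junction": 1.5, "medial": 1.0},
        pixel_size=0.2,
        seed=42,
    )


def brute_force_components(binary: np.ndarray, connectivity: int = 2):
    """Exhaustive flood-fill labeling, independent of skimage.

    Returns a list of pixel-index sets, one per connected component.
    """
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    if connectivity == 2:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    comps = []
    h, w = binary.shape
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            comp = set()
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            comps.append(comp)
    return comps


def brute_force_crofton_perimeter(mask: np.ndarray) -> float:
    """Crofton 4-direction perimeter via direct line-intercept counting.

    Boundary crossings are counted along every horizontal, vertical and
    diagonal scan line of the (padded) region; the Crofton formula turns
    intercept counts into a perimeter estimate.  Independent of any image
    library.
    """
    m = np.pad(np.asarray(mask, dtype=bool), 1).astype(int)
    i_h = sum(int(np.sum(np.abs(np.diff(row)))) for row in m)
    i_v = sum(int(np.sum(np.abs(np.diff(col)))) for col in m.T)
    i_d1 = 0
    i_d2 = 0
    h, w = m.shape
    for off in range(-h + 1, w):
        d = np.diagonal(m, off)
        if len(d) > 1:
            i_d1 += int(np.sum(np.abs(np.diff(d))))
        d2 = np.diagonal(np.fliplr(m), off)
        if len(d2) > 1:
            i_d2 += int(np.sum(np.abs(np.diff(d2))))
    return math.pi / 8 * (i_h + i_v + (i_d1 + i_d2) / math.sqrt(2))


def brute_force_clusters(image, criteria, pixel_size, connectivity=2):
    """Independent re-implementation of the punctum filter chain.

    Flood fill on the intensity window, then area / circularity / mean
    intensity verdicts per component, with the same Crofton perimeter
    definition computed by direct intercept counting.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = criteria.intensity_range
    binary = (image >= lo) & (image <= hi)
    out = []
    for comp in brute_force_components(binary, connectivity):
        n_pix = len(comp)
        area_um2 = n_pix * pixel_size**2
        mask = np.zeros(image.shape, dtype=bool)
        for r, c in comp:
            mask[r, c] = True
        if n_pix == 1:
            circ = 1.0
        else:
            per = brute_force_crofton_perimeter(mask)
            circ = 4 * math.pi * n_pix / per**2
        mean_int = float(np.mean([image[r, c] for r, c in comp]))
        keep = (
            area_um2 > criteria.min_area
            and criteria.circularity_range[0] <= min(circ, criteria.circularity_range[1])
            and lo <= mean_int <= hi
        )
        out.append(
            dict(n_pixels=n_pix, area_um2=area_um2, circularity=circ,
                 mean_intensity=mean_int, keep=keep)
        )
    return out
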