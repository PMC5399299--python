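"""Calibrated time-lapse stacks and TIFF I/O.

A :class:`TimeLapseStack` is the package's canonical in-memory movie: a
``(T, Y, X)`` float array with physical calibration (pixel size in μm,
frame interval in s).  Single images are stacks with ``T == 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import tifffile

#: Full-scale value for 12-bit acquisitions ("arbitrary units" ceiling).
ADU_12BIT_MAX = 4095.0


@dataclass
class TimeLapseStack:
    """A T×Y×X intensity movie with physical calibration.

    Parameters
    ----------
    data:
        Array of shape ``(T, Y, X)``.  Stored as float64.
    pixel_size:
        μm per pixel (isotropic).
    frame_interval:
        Seconds between consecutive frames.
    """

    data: np.ndarray
    pixel_size: float = 1.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"stack data must be (T, Y, X), got shape {arr.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        self.data = arr

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]

    def with_data(self, data: np.ndarray) -> "TimeLapseStack":
        """A copy of this stack carrying new pixel data, same calibration."""
        return replace(self, data=np.asarray(data, dtype=float))


def load_stack(
    path,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    expect_12bit: bool = False,
) -> TimeLapseStack:
    """Load a single- or multi-page TIFF as a :class:`TimeLapseStack`.

    Parameters
    ----------
    expect_12bit:
        If True and the file contains values above 4,095 (e.g. a 16-bit
        export), the data are linearly rescaled to the 0–4,095 range with a
        warning, so that 12-bit intensity presets remain meaningful.

    Raises
    ------
    ValueError
        For RGB/multi-sample TIFFs or inconsistent page shapes; the message
        names the file (and page) involved.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            series = tif.series[0]
            if "S" in series.axes:
                raise ValueError(
                    f"{path}: unsupported photometric layout (axes {series.axes!r}); "
                    "RGB/multi-sample TIFFs are not supported, provide grayscale data"
                )
            shapes = {p.shape for p in tif.pages if p is not None}
            if len(shapes) > 1:
                raise ValueError(
                    f"{path}: inconsistent page shapes {sorted(shapes)}"
                )
            data = series.asarray()
    except FileNotFoundError:
        raise FileNotFoundError(f"stack file not found: {path}") from None
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if expect_12bit and data.max() > ADU_12BIT_MAX:
        warnings.warn(
            f"{path}: values exceed the 12-bit range (max {data.max():.0f}); "
            "rescaling to 0-4095 so 12-bit intensity presets apply",
            stacklevel=2,
        )
        data = data * (ADU_12BIT_MAX / data.max())
    return TimeLapseStack(data, pixel_size=pixel_size, frame_interval=frame_interval)


def save_stack(path, stack: TimeLapseStack | np.ndarray, dtype=np.float32) -> None:
    """Write a stack (or bare array) as a multi-page TIFF, one page per frame."""
    data = stack.data if isinstance(stack, TimeLapseStack) else np.asarray(stack)
    if data.ndim == 2:
        data = data[None]
    tifffile.imwrite(str(path), data.astype(dtype))


def save_label_mask(path, labels: np.ndarray) -> None:
    """Write an integer label image (0 = background) as TIFF."""
    tifffile.imwrite(str(path), np.asarray(labels).astype(np.int32))


def load_label_mask(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return np.asarray(arr).astype(np.int64)
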