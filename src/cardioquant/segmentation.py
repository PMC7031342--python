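"""Single-cell segmentation and length readout for contracting-myocyte movies.

The measurement chain mirrors optical edge analysis of an isolated, spontaneously
contracting cardiomyocyte: each frame is binarized with the image mean as the
threshold, the cell outline is smoothed with a Savitzky-Golay filter (second-order
polynomials, 75-sample window), a line is fit along the cell's longest axis, and
the cell length is read off as the chord of the cell under that line, frame by
frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy.ndimage import binary_fill_holes, map_coordinates
from scipy.signal import savgol_filter
from skimage.draw import polygon as draw_polygon
from skimage.measure import find_contours, label


class DegenerateMaskError(ValueError):
    """Raised when thresholding produces no usable single-cell mask."""


@dataclass
class ImageStack:
    """An ordered stack of 2-D grayscale frames with a fixed frame interval.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Frame intensities.  8- or 16-bit integer or float.
    frame_interval : float
        Seconds between consecutive frames (0.04 s for myocyte movies).
    pixel_size : float
        Physical length per pixel; lengths are reported in pixels by default.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need a (T, H, W) stack with at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @classmethod
    def from_tiff(cls, path, frame_interval: float, pixel_size: float = 1.0) -> "ImageStack":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames=frames, frame_interval=frame_interval, pixel_size=pixel_size)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the per-frame segmentation.

    ``sg_window``/``sg_order`` parameterize the outline smoother (defaults: 75
    samples, order 2).  ``min_component_area`` rejects specks that survive
    thresholding.  The threshold itself is always the image mean.
    """

    sg_window: int = 75
    sg_order: int = 2
    min_component_area: int = 9

    def __post_init__(self) -> None:
        if self.sg_order >= self.sg_window:
            raise ValueError("sg_order must be smaller than sg_window")
        if self.sg_window < 3:
            raise ValueError("sg_window must be at least 3")


@dataclass(frozen=True)
class AxisLine:
    """A line through ``anchor`` (x, y) with unit ``direction`` (dx, dy)."""

    anchor: tuple[float, float]
    direction: tuple[float, float]
    isotropic_tie: bool = False

    def __post_init__(self) -> None:
        d = np.hypot(*self.direction)
        if not np.isclose(d, 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")


def binarize_frame(frame: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Threshold a frame at its mean intensity and keep the largest component.

    Foreground is every pixel with intensity >= mean(frame) (inclusive, so the
    boundary pixels of a bright object are kept).  The largest 8-connected
    component is retained and interior holes are filled.

    Raises
    ------
    DegenerateMaskError
        If the frame is uniform (everything is "foreground") or the largest
        component is smaller than ``min_component_area``.
    """
    params = params or SegmentationParams()
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    mask = frame >= frame.mean()
    if mask.all():
        raise DegenerateMaskError("uniform frame: threshold at the mean selects every pixel")
    if not mask.any():
        raise DegenerateMaskError("no pixel at or above the mean threshold")
    labels = label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = counts.argmax()
    if counts[biggest] < params.min_component_area:
        raise DegenerateMaskError(
            f"largest component has {counts[biggest]} px < min_component_area"
        )
    return binary_fill_holes(labels == biggest)


def extract_outline(mask: np.ndarray) -> np.ndarray:
    """Trace the sub-pixel cell boundary at the 0.5 iso-level.

    Returns a closed (first point repeated last), counter-clockwise (N, 2)
    array of (x, y) coordinates.  Masks touching the image border are traced
    along the border with a warning.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    touches = (
        mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    if touches:
        warnings.warn("mask touches the image border; outline clipped at the border")
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0  # undo padding offset
    xy = contour[:, ::-1]  # (row, col) -> (x, y)
    if touches:
        xy[:, 0] = np.clip(xy[:, 0], 0, mask.shape[1] - 1)
        xy[:, 1] = np.clip(xy[:, 1], 0, mask.shape[0] - 1)
    if not np.allclose(xy[0], xy[-1]):
        xy = np.vstack([xy, xy[0]])
    # enforce counter-clockwise orientation in (x, y)
    ring = xy[:-1]
    area2 = np.sum(ring[:, 0] * np.roll(ring[:, 1], -1) - np.roll(ring[:, 0], -1) * ring[:, 1])
    if area2 < 0:
        xy = xy[::-1]
    return xy


def _effective_window(n: int, window: int) -> int:
    w = min(window, n)
    if w % 2 == 0:
        w -= 1
    return max(w, 3)


def smooth_outline(outline: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Savitzky-Golay smooth a closed outline with periodic extension.

    The x- and y-coordinate sequences are filtered independently with an
    order-``sg_order`` window-``sg_window`` filter using wrap-around boundary
    handling, so the result stays closed.  Outlines shorter than the window
    get the largest odd window that fits.
    """
    params = params or SegmentationParams()
    outline = np.asarray(outline, float)
    closed = np.allclose(outline[0], outline[-1])
    ring = outline[:-1] if closed else outline
    n = len(ring)
    window = _effective_window(n, params.sg_window)
    if window < params.sg_window:
        warnings.warn(f"outline of {n} points shorter than window; using window {window}")
    order = min(params.sg_order, window - 1)
    sx = savgol_filter(ring[:, 0], window, order, mode="wrap")
    sy = savgol_filter(ring[:, 1], window, order, mode="wrap")
    smoothed = np.column_stack([sx, sy])
    return np.vstack([smoothed, smoothed[0]])


def rasterize_outline(outline: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill a closed outline back into a binary mask of the given shape."""
    outline = np.asarray(outline, float)
    rr, cc = draw_polygon(outline[:, 1], outline[:, 0], shape=shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def longest_axis(mask_or_outline: np.ndarray, shape: tuple[int, int] | None = None) -> AxisLine:
    """Fit the line along the cell's longest axis.

    The line passes through the foreground centroid in the direction of the
    principal (largest-variance) second-moment axis of the foreground pixel
    coordinates.  For isotropic shapes (equal moment eigenvalues within 1e-9
    relative) the tie is broken toward the image x-axis and flagged.

    Accepts a binary mask, or an (N, 2) outline (which is rasterized first;
    pass ``shape`` to control the raster size).
    """
    arr = np.asarray(mask_or_outline)
    if arr.ndim == 2 and arr.shape[1] == 2 and arr.dtype.kind == "f":
        if shape is None:
            shape = (
                int(np.ceil(arr[:, 1].max())) + 2,
                int(np.ceil(arr[:, 0].max())) + 2,
            )
        mask = rasterize_outline(arr, shape)
    else:
        mask = arr.astype(bool)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask")
    cx, cy = xs.mean(), ys.mean()
    cov = np.cov(np.vstack([xs - cx, ys - cy]))
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    rel_gap = (evals[-1] - evals[0]) / max(evals[-1], 1e-300)
    if rel_gap <= 1e-9:
        return AxisLine(anchor=(cx, cy), direction=(1.0, 0.0), isotropic_tie=True)
    d = evecs[:, -1]
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    return AxisLine(anchor=(cx, cy), direction=(float(d[0]), float(d[1])))


def length_under_line(mask: np.ndarray, line: AxisLine, step: float = 0.25) -> float:
    """Chord length of the cell under the axis line, in pixels.

    The line is sampled at ``step``-pixel intervals across the mask bounding
    box; foreground membership is nearest-neighbour.  The length is the
    distance between the first and last on-mask sample.
    """
    mask = np.asarray(mask, bool)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask")
    dx, dy = line.direction
    ax, ay = line.anchor
    # projections of the bounding-box corners give the sampling range
    corners_x = np.array([xs.min() - 1, xs.max() + 1], float)
    corners_y = np.array([ys.min() - 1, ys.max() + 1], float)
    ts = [
        (cx - ax) * dx + (cy - ay) * dy for cx in corners_x for cy in corners_y
    ]
    t = np.arange(min(ts), max(ts) + step, step)
    px = ax + t * dx
    py = ay + t * dy
    ix = np.rint(px).astype(int)
    iy = np.rint(py).astype(int)
    inb = (ix >= 0) & (ix < mask.shape[1]) & (iy >= 0) & (iy < mask.shape[0])
    on = np.zeros(t.shape, bool)
    on[inb] = mask[iy[inb], ix[inb]]
    hits = np.nonzero(on)[0]
    if hits.size == 0:
        raise ValueError("line does not intersect the mask")
    return float(t[hits[-1]] - t[hits[0]])


def segment_frame(frame: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Binarize a frame and re-rasterize the Savitzky-Golay-smoothed outline."""
    params = params or SegmentationParams()
    mask = binarize_frame(frame, params)
    outline = smooth_outline(extract_outline(mask), params)
    smoothed = rasterize_outline(outline, mask.shape)
    if not smoothed.any():  # degenerate after smoothing; fall back to raw mask
        return mask
    return smoothed


def track_length(stack: ImageStack, params: SegmentationParams | None = None):
    """Measure cell length under the longest-axis line in every frame.

    The axis is estimated once, on the first frame with a valid mask (the cell
    is assumed to open at rest), and held fixed for the whole movie so that
    rigid rotation is not conflated with shortening.  Frames with a degenerate
    mask are marked missing; gaps of up to 3 frames are linearly interpolated,
    longer gaps raise.

    Returns
    -------
    LengthTrace
    """
    from .contractility import LengthTrace

    params = params or SegmentationParams()
    axis: AxisLine | None = None
    lengths = np.full(stack.n_frames, np.nan)
    for i in range(stack.n_frames):
        try:
            mask = segment_frame(stack.frames[i], params)
        except DegenerateMaskError:
            continue
        if axis is None:
            axis = longest_axis(mask)
        try:
            lengths[i] = length_under_line(mask, axis)
        except ValueError:
            continue
    if axis is None:
        raise DegenerateMaskError("no frame produced a valid mask")
    missing = np.isnan(lengths)
    if missing.any():
        runs = _missing_runs(missing)
        if any(r[1] - r[0] > 3 for r in runs):
            raise ValueError("more than 3 consecutive frames with degenerate masks")
        idx = np.arange(stack.n_frames)
        lengths[missing] = np.interp(idx[missing], idx[~missing], lengths[~missing])
    return LengthTrace(
        time=stack.times, length=lengths, frame_interval=stack.frame_interval
    )


def _missing_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, m in enumerate(missing):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(missing)))
    return runs


def make_kymograph(stack: ImageStack, line: AxisLine) -> np.ndarray:
    """Build a time x position kymograph by sampling ``line`` in every frame.

    The line is sampled at 1-px steps across the full image extent; row ``t``
    holds the (bilinearly interpolated) intensities of frame ``t``.
    """
    h, w = stack.frames.shape[1:]
    dx, dy = line.direction
    ax, ay = line.anchor
    ts = [
        (cx - ax) * dx + (cy - ay) * dy
        for cx in (0.0, w - 1.0)
        for cy in (0.0, h - 1.0)
    ]
    t = np.arange(np.floor(min(ts)), np.ceil(max(ts)) + 1.0, 1.0)
    px = np.clip(ax + t * dx, 0, w - 1)
    py = np.clip(ay + t * dy, 0, h - 1)
    rows = [
        map_coordinates(frame.astype(float), [py, px], order=1)
        for frame in stack.frames
    ]
    return np.asarray(rows)
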