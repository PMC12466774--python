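"""Spot detection, chromosome assignment, and intensity measurement.

Spot-like FISH/IF signals are found by local-contrast peak finding: a white
top-hat (disk structuring element sized to the expected spot scale) removes
slowly varying background, and thresholded local maxima of the enhanced
image become detections.  Intensities are always measured on the *raw*
channel so that fold-changes across conditions are not distorted by the
enhancement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.feature import peak_local_max
from skimage.morphology import disk, white_tophat

from .types import LabelMask, Spot, as_label_array

__all__ = [
    "SpotParams",
    "detect_spots",
    "assign_spots",
    "delete_spots",
    "measure_intensity",
]


@dataclass
class SpotParams:
    """Detection parameters for one channel.

    ``tophat_radius`` plays the role of the expected spot scale (px).  The
    threshold applies to the top-hat-enhanced value: an absolute intensity
    when ``threshold_mode="absolute"``, or a fraction of the global maximum
    of the enhanced image when ``"relative"``.
    """

    tophat_radius: int = 5
    min_peak_distance: int = 5
    threshold_mode: str = "relative"  # "absolute" | "relative"
    threshold_value: float = 0.1
    subpixel_refine: bool = True
    aperture_radius: float = 3.0

    def __post_init__(self) -> None:
        if self.tophat_radius < 1:
            raise ValueError("tophat_radius must be >= 1")
        if self.min_peak_distance < 1:
            raise ValueError("min_peak_distance must be >= 1")
        if self.threshold_mode not in ("absolute", "relative"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "relative" and not 0 < self.threshold_value <= 1:
            raise ValueError("relative threshold must be in (0, 1]")


def _round_pos(x: float) -> int:
    """Half-up rounding of a pixel coordinate (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def _refine_subpixel(enhanced: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Intensity-weighted centroid in the 3x3 window around a peak.

    The window minimum is subtracted before weighting; without that, the
    flat pedestal under the peak pulls the centroid toward the window
    center and the refinement loses most of its benefit.  The offset is
    clamped to half a pixel.
    """
    rows, cols = enhanced.shape
    if not (1 <= r < rows - 1 and 1 <= c < cols - 1):
        return float(r), float(c)
    win = enhanced[r - 1 : r + 2, c - 1 : c + 2].astype(float)
    w = win - win.min()
    total = w.sum()
    if total <= 0:
        return float(r), float(c)
    dr, dc = np.mgrid[-1:2, -1:2]
    off_r = float((w * dr).sum() / total)
    off_c = float((w * dc).sum() / total)
    off_r = min(max(off_r, -0.5), 0.5)
    off_c = min(max(off_c, -0.5), 0.5)
    return r + off_r, c + off_c


def detect_spots(
    channel: np.ndarray, params: SpotParams | None = None, channel_name: str = ""
) -> list[Spot]:
    """Detect punctate signals in one channel.

    Returns spots sorted by descending peak intensity (raw value at the
    rounded position; ties broken by position).  An empty list is a valid
    result.
    """
    params = params or SpotParams()
    img = np.asarray(channel, dtype=float)
    if img.size == 0:
        raise ValueError("empty input raster")
    enhanced = white_tophat(img, footprint=disk(params.tophat_radius))
    if params.threshold_mode == "absolute":
        thr = float(params.threshold_value)
    else:
        thr = float(params.threshold_value) * float(enhanced.max())
    peaks = peak_local_max(
        enhanced,
        min_distance=params.min_peak_distance,
        threshold_abs=thr,
        exclude_border=False,
    )
    spots: list[Spot] = []
    for r, c in peaks:
        if not enhanced[r, c] > thr:  # strict threshold
            continue
        if params.subpixel_refine:
            pos = _refine_subpixel(enhanced, int(r), int(c))
        else:
            pos = (float(r), float(c))
        peak, aperture = measure_intensity(img, pos, params.aperture_radius)
        spots.append(
            Spot(
                channel=channel_name,
                position=pos,
                peak_intensity=peak,
                aperture_intensity=aperture,
            )
        )
    spots.sort(key=lambda s: (-s.peak_intensity, s.position))
    return spots


def assign_spots(
    spots: Sequence[Spot], mask: LabelMask | np.ndarray, snap_radius: float = 3.0
) -> list[Spot]:
    """Assign each spot the instance label under its rounded position.

    When that pixel is background, the nearest instance pixel within
    ``snap_radius`` (Euclidean, measured from the sub-pixel position) is
    used instead; ties go to the closer pixel, then the smaller label.
    A spot in deep background keeps label 0.
    """
    arr = as_label_array(mask)
    rows, cols = arr.shape
    out: list[Spot] = []
    reach = int(math.ceil(snap_radius))
    for spot in spots:
        r0 = min(max(_round_pos(spot.row), 0), rows - 1)
        c0 = min(max(_round_pos(spot.col), 0), cols - 1)
        label = int(arr[r0, c0])
        if label == 0 and snap_radius > 0:
            rlo, rhi = max(0, r0 - reach), min(rows, r0 + reach + 1)
            clo, chi = max(0, c0 - reach), min(cols, c0 + reach + 1)
            window = arr[rlo:rhi, clo:chi]
            cand = np.argwhere(window > 0)
            best: tuple[float, int] | None = None
            for pr, pc in cand:
                d = math.hypot(rlo + pr - spot.row, clo + pc - spot.col)
                if d <= snap_radius:
                    key = (d, int(window[pr, pc]))
                    if best is None or key < best:
                        best = key
            if best is not None:
                label = best[1]
        out.append(spot.with_label(label))
    return out


def delete_spots(
    spots: Sequence[Spot],
    indices: Sequence[int] | None = None,
    region: tuple[float, float, float, float] | None = None,
) -> list[Spot]:
    """Remove spots by index or by rectangular region, preserving order.

    ``region`` is ``(row_min, col_min, row_max, col_max)`` with inclusive
    bounds; a spot is removed when its position lies inside.  Exactly one
    of ``indices`` / ``region`` must be given.
    """
    if (indices is None) == (region is None):
        raise ValueError("give exactly one of indices or region")
    if indices is not None:
        idx = set()
        for i in indices:
            i = int(i)
            if not 0 <= i < len(spots):
                raise IndexError(f"spot index {i} out of range (n={len(spots)})")
            idx.add(i)
        return [s for i, s in enumerate(spots) if i not in idx]
    rmin, cmin, rmax, cmax = region
    return [
        s
        for s in spots
        if not (rmin <= s.row <= rmax and cmin <= s.col <= cmax)
    ]


def measure_intensity(
    channel: np.ndarray, position: tuple[float, float] | Spot, aperture_radius: float = 3.0
) -> tuple[float, float]:
    """Raw peak and aperture-mean intensity at a position.

    ``peak`` is the raw value at the rounded position; ``aperture`` is the
    mean raw value over pixels within ``aperture_radius`` of the (possibly
    sub-pixel) position, clipped to the image bounds.
    """
    if isinstance(position, Spot):
        position = position.position
    img = np.asarray(channel, dtype=float)
    rows, cols = img.shape
    pr, pc = float(position[0]), float(position[1])
    r0 = min(max(_round_pos(pr), 0), rows - 1)
    c0 = min(max(_round_pos(pc), 0), cols - 1)
    peak = float(img[r0, c0])
    reach = int(math.ceil(aperture_radius))
    rlo, rhi = max(0, r0 - reach), min(rows, r0 + reach + 1)
    clo, chi = max(0, c0 - reach), min(cols, c0 + reach + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    inside = (rr - pr) ** 2 + (cc - pc) ** 2 <= aperture_radius**2
    if not inside.any():
        return peak, peak
    aperture = float(img[rlo:rhi, clo:chi][inside].mean())
    return peak, aperture
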