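"""Core domain containers shared across the pipeline.

The pixel convention throughout the package is 0-based ``(row, col)`` with
pixel centers at integer coordinates; all distances are Euclidean in pixel
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import FormatError, ShapeMismatchError

__all__ = ["ImageStack", "LabelMask", "Spot", "ChromosomeRecord", "round_half_away"]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used wherever a fractional count of objects (e.g. ``fraction * n``)
    must become an exact integer, so that tests can predict counts.
    """
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class ImageStack:
    """One field of view: named 2D intensity channels on a shared pixel grid.

    Parameters
    ----------
    field_id:
        Identifier derived from the source filenames (or assigned by a
        generator).
    channels:
        Mapping from channel name (e.g. ``"DAPI"``, ``"FISH"``, ``"IF"``)
        to a 2D non-negative intensity array.
    """

    field_id: str
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("an ImageStack needs at least one channel")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise FormatError(f"channels must be 2D rasters, got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ShapeMismatchError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            a = np.asarray(arr)
            if not np.all(np.isfinite(a)):
                raise FormatError(f"channel {name!r} contains non-finite values")
            if a.min() < 0:
                raise FormatError(f"channel {name!r} contains negative intensities")

    @property
    def pixel_shape(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return tuple(np.asarray(arr).shape)  # type: ignore[return-value]

    def channel(self, name: str) -> np.ndarray:
        return np.asarray(self.channels[name])


@dataclass
class LabelMask:
    """2D integer instance map; 0 is background, positive values are instances."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise FormatError(f"label mask must be 2D, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
                arr = arr.astype(np.int64)
            else:
                raise FormatError("label mask must hold integer values")
        if arr.size and arr.min() < 0:
            raise FormatError("label mask contains negative values")
        self.labels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def instance_labels(self) -> np.ndarray:
        """Sorted array of distinct positive labels present."""
        vals = np.unique(self.labels)
        return vals[vals > 0]

    @property
    def instance_count(self) -> int:
        return int(self.instance_labels.size)

    def areas(self) -> dict[int, int]:
        """Pixel count per instance label."""
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts) if v > 0}

    def copy(self) -> "LabelMask":
        return LabelMask(self.labels.copy())

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        arr = self.labels
        if dtype is not None:
            arr = arr.astype(dtype)
        return np.array(arr, copy=True) if copy else arr


def as_label_array(mask) -> np.ndarray:
    """Coerce a LabelMask or array-like to a validated 2D integer array."""
    if isinstance(mask, LabelMask):
        return mask.labels
    return LabelMask(np.asarray(mask)).labels


@dataclass
class Spot:
    """A punctate signal detected in one channel.

    ``position`` is (row, col) in pixel coordinates; sub-pixel values are
    allowed when refinement is enabled.  ``chromosome_label`` is 0 until the
    spot has been assigned to an instance (0 also means "unassigned /
    background").
    """

    channel: str
    position: tuple[float, float]
    peak_intensity: float = 0.0
    aperture_intensity: float = 0.0
    chromosome_label: int = 0

    @property
    def row(self) -> float:
        return self.position[0]

    @property
    def col(self) -> float:
        return self.position[1]

    def with_label(self, label: int) -> "Spot":
        return replace(self, chromosome_label=int(label))


@dataclass
class ChromosomeRecord:
    """Per-instance measurements exported to the chromosome table."""

    field_id: str
    label: int
    area_px: int
    centroid: tuple[float, float]
    spot_counts: Mapping[str, int] = field(default_factory=dict)
    colocalized: bool = False

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise FormatError(f"instance {self.label}: area_px must be >= 1")
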