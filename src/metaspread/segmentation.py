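"""Chromosome instance segmentation from the DNA-stain channel.

Two backends sit behind the same interface: a classical marker-controlled
watershed baseline (fully self-contained, deterministic), and an adapter
contract for learned instance-segmentation models (e.g. a Cellpose-style
network), which this package validates and post-processes but does not
train or ship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .errors import BackendContractError, ModelUnavailableError
from .types import LabelMask, as_label_array

__all__ = [
    "SegmentationParams",
    "segment_watershed",
    "segment_with_model",
    "count_chromosomes",
    "relabel_sequential",
]

logger = logging.getLogger(__name__)

#: An adapter is any callable mapping a 2D raster to an equal-shape integer
#: instance map (0 = background).
ModelAdapter = Callable[[np.ndarray], np.ndarray]


@dataclass
class SegmentationParams:
    """Knobs of the segmentation stage.

    ``foreground_threshold`` is either the string ``"otsu"`` or an absolute
    intensity value applied to the smoothed image.  ``seed_min_distance``
    controls watershed over-segmentation: within one foreground component,
    distance-transform peaks closer than this (Euclidean, px) are
    suppressed, keeping the strongest.
    """

    method: str = "watershed"  # "watershed" | "model"
    smoothing_sigma: float = 1.0
    foreground_threshold: str | float = "otsu"
    seed_min_distance: float = 35.0
    min_object_area: int = 50
    model_path: str | None = None
    model_diameter_hint: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("watershed", "model"):
            raise ValueError(f"unknown segmentation method {self.method!r}")
        if self.seed_min_distance < 1:
            raise ValueError("seed_min_distance must be >= 1")
        if self.min_object_area < 1:
            raise ValueError("min_object_area must be >= 1")


def relabel_sequential(arr: np.ndarray) -> np.ndarray:
    """Relabel positive values to 1..K preserving ascending label order."""
    out = np.zeros_like(arr, dtype=np.int32)
    for new, old in enumerate(np.unique(arr[arr > 0]), start=1):
        out[arr == old] = new
    return out


def _filter_small(arr: np.ndarray, min_area: int) -> np.ndarray:
    vals, counts = np.unique(arr[arr > 0], return_counts=True)
    small = vals[counts < min_area]
    if small.size:
        arr = arr.copy()
        arr[np.isin(arr, small)] = 0
    return arr


def _component_seeds(
    edt: np.ndarray, components: np.ndarray, min_distance: float
) -> np.ndarray:
    """Deterministic marker image: per foreground component, local maxima of
    the distance transform thinned to pairwise Euclidean separation
    >= ``min_distance`` (strongest first; ties broken by raster order).

    Every component keeps at least one seed (its distance-transform argmax),
    so no foreground region is left unlabeled by the watershed flood.
    """
    markers = np.zeros(edt.shape, dtype=np.int32)
    next_marker = 0
    is_max = (edt == ndi.maximum_filter(edt, size=3)) & (edt > 0)
    for comp, sl in enumerate(ndi.find_objects(components), start=1):
        if sl is None:
            continue
        offset = np.array([sl[0].start, sl[1].start])
        in_comp = components[sl] == comp
        cand = np.argwhere(is_max[sl] & in_comp)
        if cand.size == 0:
            sub = np.where(in_comp, edt[sl], -1.0)
            cand = np.array([np.unravel_index(np.argmax(sub), sub.shape)])
        cand = cand + offset
        values = edt[cand[:, 0], cand[:, 1]]
        order = np.lexsort((cand[:, 1], cand[:, 0], -values))
        kept: list[np.ndarray] = []
        for idx in order:
            p = cand[idx]
            if all(np.hypot(*(p - q)) >= min_distance for q in kept):
                kept.append(p)
        for p in kept:
            next_marker += 1
            markers[p[0], p[1]] = next_marker
    return markers


def segment_watershed(dapi: np.ndarray, params: SegmentationParams | None = None) -> LabelMask:
    """Marker-controlled watershed on the DNA-stain channel.

    Pipeline: Gaussian smooth -> foreground threshold (Otsu or absolute) ->
    fill holes -> Euclidean distance transform -> distance-peak seeds
    (separated by >= ``seed_min_distance``) -> watershed on the negated
    distance map restricted to foreground -> drop objects smaller than
    ``min_object_area`` -> sequential relabel from 1.

    An empty foreground yields an all-zero mask with a logged warning, not
    an error.
    """
    params = params or SegmentationParams()
    img = np.asarray(dapi, dtype=float)
    if img.size == 0:
        raise ValueError("empty input raster")
    smoothed = (
        gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)
        if params.smoothing_sigma > 0
        else img
    )
    if params.foreground_threshold == "otsu":
        if np.allclose(smoothed.min(), smoothed.max()):
            logger.warning("constant image: empty foreground")
            return LabelMask(np.zeros(img.shape, dtype=np.int32))
        thr = threshold_otsu(smoothed)
    else:
        thr = float(params.foreground_threshold)
    fg = smoothed > thr
    if not fg.any():
        logger.warning("empty foreground after thresholding")
        return LabelMask(np.zeros(img.shape, dtype=np.int32))
    fg = ndi.binary_fill_holes(fg)
    edt = ndi.distance_transform_edt(fg)
    components = cc_label(fg, connectivity=2)
    markers = _component_seeds(edt, components, params.seed_min_distance)
    labels = watershed(-edt, markers=markers, mask=fg)
    labels = _filter_small(labels, params.min_object_area)
    return LabelMask(relabel_sequential(labels))


def segment_with_model(
    dapi: np.ndarray,
    adapter: ModelAdapter | None,
    params: SegmentationParams | None = None,
) -> LabelMask:
    """Run a learned-model backend through the adapter contract.

    The adapter must return an integer instance map of the input's shape
    with non-negative labels; the output is validated, filtered by
    ``min_object_area``, and relabelled sequentially.
    """
    params = params or SegmentationParams(method="model")
    if adapter is None:
        raise ModelUnavailableError(
            "no learned segmentation backend configured; "
            "use method='watershed' or supply an adapter callable"
        )
    img = np.asarray(dapi)
    out = np.asarray(adapter(img))
    if out.shape != img.shape:
        raise BackendContractError(
            f"adapter returned shape {out.shape}, expected {img.shape}"
        )
    if not np.issubdtype(out.dtype, np.integer):
        raise BackendContractError(
            f"adapter returned dtype {out.dtype}; an integer instance map is required"
        )
    if out.size and out.min() < 0:
        raise BackendContractError("adapter returned negative labels")
    out = _filter_small(out.astype(np.int64), params.min_object_area)
    return LabelMask(relabel_sequential(out))


def count_chromosomes(mask) -> int:
    """Number of distinct positive labels (labels need not be contiguous)."""
    arr = as_label_array(mask)
    return int(np.unique(arr[arr > 0]).size)
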