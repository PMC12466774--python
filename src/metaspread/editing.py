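"""Headless chromosome-mask curation: merge, split, and delete instances.

All edits are pure — the input mask is never modified — and every edit can
be recorded as an :class:`EditAction` and replayed from a JSON-lines log to
reproduce a curated mask bit-exactly.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk

from .errors import MissingLabelError
from .types import LabelMask, as_label_array

__all__ = [
    "EditAction",
    "merge_labels",
    "split_label",
    "delete_label",
    "apply_edits",
    "save_edit_log",
    "load_edit_log",
]

logger = logging.getLogger(__name__)


@dataclass
class EditAction:
    """One recorded curation action.

    ``kind`` is ``"merge"`` (>= 2 target labels), ``"split"`` or
    ``"delete"`` (exactly one target).  For splits, ``split_path`` is a
    polyline of (row, col) vertices and ``split_width`` the cut thickness
    in pixels.
    """

    kind: str
    target_labels: list[int]
    split_path: list[tuple[float, float]] | None = None
    split_width: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("merge", "split", "delete"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        n = len(self.target_labels)
        if self.kind == "merge" and n < 2:
            raise ValueError("merge requires at least 2 target labels")
        if self.kind in ("split", "delete") and n != 1:
            raise ValueError(f"{self.kind} requires exactly 1 target label")
        if self.kind == "split":
            if self.split_path is None or len(self.split_path) < 2:
                raise ValueError("split requires a polyline with >= 2 vertices")

    def to_json(self) -> str:
        d = asdict(self)
        if d["split_path"] is not None:
            d["split_path"] = [list(p) for p in d["split_path"]]
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EditAction":
        d = json.loads(text)
        path = d.get("split_path")
        if path is not None:
            path = [tuple(p) for p in path]
        return cls(
            kind=d["kind"],
            target_labels=[int(v) for v in d["target_labels"]],
            split_path=path,
            split_width=float(d.get("split_width", 1.0)),
        )


def _require_labels(arr: np.ndarray, labels: Iterable[int]) -> None:
    present = set(np.unique(arr[arr > 0]).tolist())
    missing = [lab for lab in labels if lab not in present]
    if missing:
        raise MissingLabelError(f"labels {missing} not present in mask")


def merge_labels(mask, labels: Sequence[int]) -> LabelMask:
    """Merge the listed instances into one, keeping the smallest label.

    Foreground pixel count is conserved; the instance count decreases by
    ``len(labels) - 1``.
    """
    labels = [int(v) for v in labels]
    if len(labels) < 2:
        raise ValueError("merge requires at least 2 labels")
    arr = as_label_array(mask)
    _require_labels(arr, labels)
    out = arr.copy()
    out[np.isin(out, labels)] = min(labels)
    return LabelMask(out)


def delete_label(mask, label: int) -> LabelMask:
    """Set one instance to background."""
    arr = as_label_array(mask)
    _require_labels(arr, [int(label)])
    out = arr.copy()
    out[out == int(label)] = 0
    return LabelMask(out)


def _rasterize_polyline(
    path: Sequence[tuple[float, float]], width: float, shape: tuple[int, int]
) -> np.ndarray:
    """Boolean raster of a polyline with the given thickness, clipped to shape."""
    rows, cols = shape
    strip = np.zeros(shape, dtype=bool)
    verts = [(int(round(r)), int(round(c))) for r, c in path]
    for (r0, c0), (r1, c1) in zip(verts, verts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        strip[rr[keep], cc[keep]] = True
    radius = int(math.floor((width - 1) / 2 + 0.5))
    if radius >= 1:
        strip = dilation(strip, disk(radius))
    return strip


def split_label(
    mask, label: int, split_path: Sequence[tuple[float, float]], split_width: float = 1.0
) -> LabelMask:
    """Cut one instance along a polyline.

    The polyline is rasterized with thickness ``split_width``; instance
    pixels under the cut become background, and the remaining connected
    components (8-connectivity) receive fresh labels above the current
    maximum.  If the cut misses the instance, or fails to bisect it, the
    mask is returned unchanged (with a warning).
    """
    label = int(label)
    arr = as_label_array(mask)
    _require_labels(arr, [label])
    strip = _rasterize_polyline(split_path, split_width, arr.shape)
    body = arr == label
    cut = strip & body
    if not cut.any():
        logger.warning("split: polyline does not touch instance %d; no-op", label)
        return LabelMask(arr.copy())
    remaining = body & ~cut
    comps, n = cc_label(remaining, connectivity=2, return_num=True)
    if n <= 1:
        logger.warning("split: cut did not bisect instance %d; no-op", label)
        return LabelMask(arr.copy())
    out = arr.copy()
    out[body] = 0
    next_label = int(arr.max())
    for comp in range(1, n + 1):
        next_label += 1
        out[comps == comp] = next_label
    return LabelMask(out)


def apply_edits(mask, actions: Sequence[EditAction]) -> LabelMask:
    """Replay a sequence of recorded edits against a mask."""
    out = LabelMask(as_label_array(mask).copy())
    for action in actions:
        if action.kind == "merge":
            out = merge_labels(out, action.target_labels)
        elif action.kind == "delete":
            out = delete_label(out, action.target_labels[0])
        else:
            out = split_label(
                out, action.target_labels[0], action.split_path, action.split_width
            )
    return out


def save_edit_log(actions: Sequence[EditAction], path: str | os.PathLike) -> None:
    """Serialize an edit log as JSON lines (one action per line)."""
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        for action in actions:
            fh.write(action.to_json() + "\n")


def load_edit_log(path: str | os.PathLike) -> list[EditAction]:
    with open(os.fspath(path), encoding="utf-8") as fh:
        return [EditAction.from_json(line) for line in fh if line.strip()]
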