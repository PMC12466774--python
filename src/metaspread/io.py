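"""Multi-channel image loading, label-mask I/O, and CSV export.

Channels are identified by substring tokens in filenames (typically the
excitation wavelength, e.g. ``"435"`` for the DNA stain), one single-plane
TIFF per channel per field of view.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import AmbiguousChannelError, FormatError, ShapeMismatchError
from .types import ChromosomeRecord, ImageStack, LabelMask, Spot

__all__ = [
    "load_field",
    "read_label_mask",
    "write_label_mask",
    "write_results",
    "SPOT_COLUMNS",
    "SUMMARY_COLUMNS",
]

#: Fixed header of spots.csv.
SPOT_COLUMNS = [
    "field_id",
    "channel",
    "row",
    "col",
    "peak_intensity",
    "aperture_intensity",
    "chromosome_label",
]

#: Fixed header of summary.csv (one row per field of view).
SUMMARY_COLUMNS = [
    "field_id",
    "condition",
    "n_chromosomes",
    "n_with_a",
    "n_coloc",
    "coloc_ratio",
]


def _read_plane(path: str | os.PathLike) -> np.ndarray:
    arr = tifffile.imread(os.fspath(path))
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-plane 2D image, got shape {arr.shape}"
        )
    return arr


def _stem(path: str | os.PathLike) -> str:
    base = os.path.basename(os.fspath(path))
    stem, _ = os.path.splitext(base)
    return stem


def match_channel_files(
    paths: Sequence[str | os.PathLike], channel_tokens: Mapping[str, str]
) -> dict[str, str]:
    """Resolve each channel token to exactly one path (case-sensitive
    substring match on the basename).

    Raises
    ------
    AmbiguousChannelError
        If a token matches zero files or more than one file.
    """
    resolved: dict[str, str] = {}
    for name, token in channel_tokens.items():
        hits = [os.fspath(p) for p in paths if token in os.path.basename(os.fspath(p))]
        if len(hits) != 1:
            raise AmbiguousChannelError(
                f"channel {name!r}: token {token!r} matched {len(hits)} files "
                f"({sorted(os.path.basename(h) for h in hits)}), expected exactly 1"
            )
        resolved[name] = hits[0]
    return resolved


def field_id_from_files(
    resolved: Mapping[str, str], channel_tokens: Mapping[str, str]
) -> str:
    """Longest common filename stem once each channel token is removed."""
    cleaned = []
    for name, path in resolved.items():
        stem = _stem(path)
        token = channel_tokens[name]
        cleaned.append(stem.replace(token, "", 1))
    common = os.path.commonprefix(cleaned)
    return common.strip("_-. ") or cleaned[0].strip("_-. ") or "field"


def load_field(
    paths: Sequence[str | os.PathLike], channel_tokens: Mapping[str, str]
) -> ImageStack:
    """Load one field of view from per-channel files.

    Parameters
    ----------
    paths:
        Candidate files (only those matching a token are read).
    channel_tokens:
        Mapping channel name -> filename substring identifying that channel.

    Returns
    -------
    ImageStack
        One channel per token; ``field_id`` is the longest common filename
        stem with the tokens removed.
    """
    resolved = match_channel_files(paths, channel_tokens)
    channels: dict[str, np.ndarray] = {}
    shape = None
    for name, path in resolved.items():
        arr = _read_plane(path)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ShapeMismatchError(
                f"channel {name!r} ({path}) has shape {arr.shape}, expected {shape}"
            )
        channels[name] = arr
    return ImageStack(field_id=field_id_from_files(resolved, channel_tokens), channels=channels)


def read_label_mask(path: str | os.PathLike) -> LabelMask:
    """Read an instance label mask from a single-plane TIFF.

    Float-valued files are accepted only when every value is integral;
    negative values are a format error.
    """
    arr = _read_plane(path)
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
            arr = arr.astype(np.int64)
        else:
            raise FormatError(f"{path}: label mask must contain integer values")
    if arr.size and arr.min() < 0:
        raise FormatError(f"{path}: label mask contains negative values")
    return LabelMask(arr.astype(np.int64))


def write_label_mask(mask: LabelMask | np.ndarray, path: str | os.PathLike) -> None:
    """Write a label mask using the smallest unsigned width holding max label."""
    arr = mask.labels if isinstance(mask, LabelMask) else LabelMask(np.asarray(mask)).labels
    max_label = int(arr.max()) if arr.size else 0
    if max_label <= np.iinfo(np.uint8).max:
        dtype = np.uint8
    elif max_label <= np.iinfo(np.uint16).max:
        dtype = np.uint16
    else:
        dtype = np.uint32
    tifffile.imwrite(os.fspath(path), arr.astype(dtype))


def spots_frame(spots: Iterable[Spot], field_id: str) -> pd.DataFrame:
    rows = [
        {
            "field_id": field_id,
            "channel": s.channel,
            "row": float(s.row),
            "col": float(s.col),
            "peak_intensity": float(s.peak_intensity),
            "aperture_intensity": float(s.aperture_intensity),
            "chromosome_label": int(s.chromosome_label),
        }
        for s in spots
    ]
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def chromosomes_frame(records: Iterable[ChromosomeRecord]) -> pd.DataFrame:
    records = list(records)
    channels: list[str] = []
    for r in records:
        for c in r.spot_counts:
            if c not in channels:
                channels.append(c)
    cols = [
        "field_id",
        "label",
        "area_px",
        "centroid_row",
        "centroid_col",
        *[f"n_spots_{c}" for c in channels],
        "colocalized",
    ]
    rows = [
        {
            "field_id": r.field_id,
            "label": int(r.label),
            "area_px": int(r.area_px),
            "centroid_row": float(r.centroid[0]),
            "centroid_col": float(r.centroid[1]),
            **{f"n_spots_{c}": int(r.spot_counts.get(c, 0)) for c in channels},
            "colocalized": bool(r.colocalized),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)


def write_results(
    out_dir: str | os.PathLike,
    *,
    spots: pd.DataFrame | None = None,
    chromosomes: pd.DataFrame | None = None,
    summary: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write the result tables as CSV (UTF-8, comma-separated, header always
    present, no index column, period decimal separator).

    Returns a mapping table-name -> written path. Tables passed as ``None``
    are skipped.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, str] = {}
    for name, frame in (
        ("spots", spots),
        ("chromosomes", chromosomes),
        ("summary", summary),
    ):
        if frame is None:
            continue
        path = os.path.join(out_dir, f"{name}.csv")
        frame.to_csv(path, index=False, lineterminator="\n")
        written[name] = path
    return written
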