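"""Cross-channel spot pairing, colocalization scoring, and aggregation.

A FISH spot and an IF spot are *colocalized* when their Euclidean distance
is strictly below a threshold (12 px by default, matching typical 60x /
1024x1024 sampling).  Pairing is greedy one-to-one in ascending distance,
so a single bright blob in one channel cannot colocalize many spots in the
other.  Downstream aggregation covers the usual experiment bookkeeping:
fold-change normalization to a control condition, two-sample t-tests
between timepoints, and master-table consolidation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsolidationError, NormalizationError, StatisticsError
from .types import ChromosomeRecord, Spot

__all__ = [
    "ColocParams",
    "ColocSummary",
    "pair_spots",
    "flag_colocalized_chromosomes",
    "coloc_ratio",
    "normalize_intensities",
    "compare_timepoints",
    "consolidate",
]


@dataclass
class ColocParams:
    """Pairing parameters: the two channels and the distance threshold (px)."""

    channel_a: str = "FISH"
    channel_b: str = "IF"
    max_distance: float = 12.0
    denominator_mode: str = "spots_bearing"  # or "all_chromosomes"

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if self.denominator_mode not in ("spots_bearing", "all_chromosomes"):
            raise ValueError(f"unknown denominator_mode {self.denominator_mode!r}")


@dataclass
class ColocSummary:
    """Per-field colocalization bookkeeping.

    ``coloc_ratio`` is a percentage; it is NaN when the chosen denominator
    is zero.
    """

    field_id: str
    condition: str
    n_chromosomes: int
    n_with_a: int
    n_coloc: int
    coloc_ratio: float


def _position(s) -> tuple[float, float]:
    if isinstance(s, Spot):
        return (float(s.row), float(s.col))
    return (float(s[0]), float(s[1]))


def pair_spots(
    spots_a: Sequence, spots_b: Sequence, max_distance: float = 12.0
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of spots across two channels.

    Candidate pairs with Euclidean distance strictly below ``max_distance``
    are accepted in ascending distance order (ties broken by a-index then
    b-index); each spot is used at most once.  Spots may be :class:`Spot`
    objects or bare ``(row, col)`` positions.

    Returns a list of ``(index_a, index_b, distance)``.
    """
    pos_a = [_position(s) for s in spots_a]
    pos_b = [_position(s) for s in spots_b]
    candidates: list[tuple[float, int, int]] = []
    for i, pa in enumerate(pos_a):
        for j, pb in enumerate(pos_b):
            d = math.hypot(pa[0] - pb[0], pa[1] - pb[1])
            if d < max_distance:
                candidates.append((d, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, d))
    return pairs


def flag_colocalized_chromosomes(
    records: Sequence[ChromosomeRecord],
    spots_a: Sequence[Spot],
    pairs: Sequence[tuple[int, int, float]],
) -> list[ChromosomeRecord]:
    """Mark a chromosome colocalized iff an accepted pair's channel-a spot
    is assigned to it.  Returns new records; inputs are not modified."""
    coloc_labels = {
        spots_a[i].chromosome_label for i, _, _ in pairs if spots_a[i].chromosome_label > 0
    }
    return [
        ChromosomeRecord(
            field_id=r.field_id,
            label=r.label,
            area_px=r.area_px,
            centroid=r.centroid,
            spot_counts=dict(r.spot_counts),
            colocalized=r.label in coloc_labels,
        )
        for r in records
    ]


def coloc_ratio(
    n_coloc: int,
    n_with_a: int,
    n_chromosomes: int,
    denominator_mode: str = "spots_bearing",
) -> float:
    """Percentage of chromosomes meeting the proximity criterion.

    The denominator is the count of channel-a-bearing chromosomes by
    default (a locus-specific probe marks only a few chromosomes per
    spread), or all segmented chromosomes.  A zero denominator yields NaN.
    """
    denom = n_with_a if denominator_mode == "spots_bearing" else n_chromosomes
    if denom == 0:
        return float("nan")
    return 100.0 * n_coloc / denom


def normalize_intensities(
    values_by_condition: Mapping[str, Sequence[float]], control_condition: str
) -> dict[str, np.ndarray]:
    """Express intensities as fold-change over the mean of the control
    condition (so normalized control values average to 1.0)."""
    if control_condition not in values_by_condition:
        raise NormalizationError(f"control condition {control_condition!r} missing")
    control = np.asarray(values_by_condition[control_condition], dtype=float)
    if control.size == 0:
        raise NormalizationError("control condition has no values")
    mean = control.mean()
    if mean == 0:
        raise NormalizationError("control mean intensity is zero")
    return {
        cond: np.asarray(vals, dtype=float) / mean
        for cond, vals in values_by_condition.items()
    }


def compare_timepoints(
    values_t1: Sequence[float],
    values_t2: Sequence[float],
    *,
    log2: bool = False,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided independent-samples t-test between two timepoints.

    Pooled-variance by default (``equal_var=False`` switches to Welch).
    ``log2=True`` log2-transforms both groups first, as is standard for
    intensity comparisons.
    """
    a = np.asarray(values_t1, dtype=float)
    b = np.asarray(values_t2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatisticsError("each group needs at least 2 values")
    if log2:
        if (a <= 0).any() or (b <= 0).any():
            raise StatisticsError("log2 transform requires positive intensities")
        a, b = np.log2(a), np.log2(b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise StatisticsError("both groups are constant with different means")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def consolidate(
    tables: Sequence[pd.DataFrame],
    metadata: Sequence[Mapping[str, object]] | None = None,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Row-wise concatenation of per-image tables into one master table.

    ``metadata`` supplies per-table constant columns (condition, timepoint,
    replicate ...).  All tables must share one schema after metadata
    attachment; an empty input yields an empty table with ``columns``.
    """
    tables = list(tables)
    if metadata is not None and len(metadata) != len(tables):
        raise ConsolidationError("metadata list length must match table count")
    if not tables:
        return pd.DataFrame(columns=list(columns) if columns else [])
    augmented = []
    for k, tab in enumerate(tables):
        tab = tab.copy()
        if metadata is not None:
            for key, value in metadata[k].items():
                tab[key] = value
        augmented.append(tab)
    schema = list(augmented[0].columns)
    for tab in augmented[1:]:
        if list(tab.columns) != schema:
            raise ConsolidationError(
                f"schema mismatch: {list(tab.columns)} vs {schema}"
            )
    return pd.concat(augmented, ignore_index=True)
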