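"""Batch orchestration: apply one parameter set across an image folder.

For every complete field of view (all channel tokens matched), the full
pipeline runs — segment, detect spots per channel, assign, pair, flag,
measure — and the per-field rows are consolidated into master tables.  A
JSON manifest records the config hash, software version, and per-field
status; a failing field is logged and skipped without aborting the batch.
"""

from __future__ import annotations

import fnmatch
import json
import logging
import os
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from . import __version__
from .coloc import ColocSummary, coloc_ratio, flag_colocalized_chromosomes, pair_spots
from .config import RunConfig
from .errors import EmptyInputError, MetaspreadError, ModelUnavailableError
from .io import (
    SUMMARY_COLUMNS,
    chromosomes_frame,
    load_field,
    spots_frame,
    write_results,
)
from .segmentation import segment_watershed, segment_with_model
from .spots import assign_spots, detect_spots
from .types import ChromosomeRecord, ImageStack, LabelMask

__all__ = ["run_batch", "run_spots_only", "discover_fields", "analyze_field", "FieldResult"]

logger = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "field_id",
    "row_a",
    "col_a",
    "row_b",
    "col_b",
    "distance",
    "chromosome_label",
]


@dataclass
class FieldResult:
    """Per-field pipeline output (tables are pandas DataFrames)."""

    field_id: str
    condition: dict[str, str]
    spots: pd.DataFrame
    pairs: pd.DataFrame
    chromosomes: pd.DataFrame | None
    summary: ColocSummary | None
    mask: LabelMask | None = field(default=None, repr=False)


def discover_fields(input_dir: str, channel_tokens: dict[str, str]) -> dict[str, dict[str, str]]:
    """Group the files of a folder into complete fields of view.

    A file belongs to channel ``c`` when token ``c`` appears in its name;
    its field id is the stem with the token removed.  Only fields where
    every channel is present exactly once are returned, keyed by field id.
    """
    by_field: dict[str, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    for name in sorted(os.listdir(input_dir)):
        path = os.path.join(input_dir, name)
        if not os.path.isfile(path) or not name.lower().endswith((".tif", ".tiff")):
            continue
        stem = os.path.splitext(name)[0]
        for channel, token in channel_tokens.items():
            if token in name:
                fid = stem.replace(token, "", 1).strip("_-. ")
                by_field[fid][channel].append(path)
    complete: dict[str, dict[str, str]] = {}
    for fid, channels in sorted(by_field.items()):
        if set(channels) == set(channel_tokens) and all(
            len(v) == 1 for v in channels.values()
        ):
            complete[fid] = {ch: paths[0] for ch, paths in channels.items()}
    return complete


def _condition_for(field_id: str, condition_map: dict[str, dict[str, str]]) -> dict[str, str]:
    for pattern, labels in condition_map.items():
        if fnmatch.fnmatch(field_id, pattern):
            return dict(labels)
    return {"condition": "unspecified"}


def _pairs_frame(field_id, spots_a, spots_b, pairs) -> pd.DataFrame:
    rows = [
        {
            "field_id": field_id,
            "row_a": float(spots_a[i].row),
            "col_a": float(spots_a[i].col),
            "row_b": float(spots_b[j].row),
            "col_b": float(spots_b[j].col),
            "distance": float(d),
            "chromosome_label": int(spots_a[i].chromosome_label),
        }
        for i, j, d in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def analyze_field(
    stack: ImageStack,
    config: RunConfig,
    *,
    mask: LabelMask | None = None,
    adapter=None,
    spots_only: bool = False,
) -> FieldResult:
    """Run the single-field pipeline on an in-memory stack.

    ``mask`` short-circuits segmentation (used for ground-truth analyses);
    ``spots_only`` skips segmentation entirely and leaves all chromosome
    labels at 0.
    """
    fid = stack.field_id
    condition = _condition_for(fid, config.condition_map)

    if not spots_only and mask is None:
        dapi = stack.channel(config.dapi_channel)
        if config.segmentation.method == "model":
            mask = segment_with_model(dapi, adapter, config.segmentation)
        else:
            mask = segment_watershed(dapi, config.segmentation)

    spots_by_channel: dict[str, list] = {}
    for channel, params in config.spots.items():
        detected = detect_spots(stack.channel(channel), params, channel_name=channel)
        if mask is not None:
            detected = assign_spots(detected, mask, snap_radius=config.snap_radius)
        spots_by_channel[channel] = detected
        logger.info("field %s: channel %s -> %d spots", fid, channel, len(detected))

    spots_a = spots_by_channel.get(config.coloc.channel_a, [])
    spots_b = spots_by_channel.get(config.coloc.channel_b, [])
    pairs = pair_spots(spots_a, spots_b, config.coloc.max_distance)

    all_spots = [s for ch in sorted(spots_by_channel) for s in spots_by_channel[ch]]
    spot_table = spots_frame(all_spots, fid)
    pair_table = _pairs_frame(fid, spots_a, spots_b, pairs)

    if mask is None:
        return FieldResult(fid, condition, spot_table, pair_table, None, None, None)

    records = []
    for prop in regionprops(np.asarray(mask.labels)):
        counts = {
            ch: sum(1 for s in spots_by_channel[ch] if s.chromosome_label == prop.label)
            for ch in config.spots
        }
        records.append(
            ChromosomeRecord(
                field_id=fid,
                label=int(prop.label),
                area_px=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                spot_counts=counts,
            )
        )
    records = flag_colocalized_chromosomes(records, spots_a, pairs)

    n_chrom = len(records)
    n_with_a = sum(1 for r in records if r.spot_counts.get(config.coloc.channel_a, 0) > 0)
    n_coloc = sum(1 for r in records if r.colocalized)
    summary = ColocSummary(
        field_id=fid,
        condition=condition.get("condition", "unspecified"),
        n_chromosomes=n_chrom,
        n_with_a=n_with_a,
        n_coloc=n_coloc,
        coloc_ratio=coloc_ratio(
            n_coloc, n_with_a, n_chrom, config.coloc.denominator_mode
        ),
    )
    logger.info(
        "field %s: %d chromosomes, %d with %s, %d colocalized",
        fid, n_chrom, n_with_a, config.coloc.channel_a, n_coloc,
    )
    return FieldResult(
        fid, condition, spot_table, pair_table, chromosomes_frame(records), summary, mask
    )


def _summary_frame(summaries: list[ColocSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "field_id": s.field_id,
                "condition": s.condition,
                "n_chromosomes": s.n_chromosomes,
                "n_with_a": s.n_with_a,
                "n_coloc": s.n_coloc,
                "coloc_ratio": s.coloc_ratio,
            }
            for s in summaries
        ],
        columns=SUMMARY_COLUMNS,
    )


def _run(config: RunConfig, *, spots_only: bool, adapter=None) -> dict:
    fields = discover_fields(config.input_dir, config.channel_tokens)
    if not fields:
        raise EmptyInputError(
            f"no complete fields (all of {sorted(config.channel_tokens.values())}) "
            f"found in {config.input_dir}"
        )
    os.makedirs(config.output_dir, exist_ok=True)
    logger.info("batch: %d fields, config hash %s", len(fields), config.config_hash())

    statuses: dict[str, str] = {}
    spot_tables, pair_tables, chrom_tables, summaries = [], [], [], []
    master_rows = []
    for fid in sorted(fields):
        paths = list(fields[fid].values())
        try:
            stack = load_field(paths, config.channel_tokens)
            stack.field_id = fid
            result = analyze_field(stack, config, adapter=adapter, spots_only=spots_only)
        except (MetaspreadError, OSError, ValueError) as exc:
            if isinstance(exc, ModelUnavailableError):
                raise
            logger.error("field %s failed: %s", fid, exc)
            statuses[fid] = f"failed: {exc}"
            continue
        statuses[fid] = "ok"
        spot_tables.append(result.spots)
        pair_tables.append(result.pairs)
        if result.chromosomes is not None:
            chrom_tables.append(result.chromosomes)
            master = result.chromosomes.copy()
            for key, value in result.condition.items():
                master[key] = value
            master_rows.append(master)
        if result.summary is not None:
            summaries.append(result.summary)

    if not any(s == "ok" for s in statuses.values()):
        raise EmptyInputError("every field in the batch failed")

    spot_table = pd.concat(spot_tables, ignore_index=True)
    pair_table = pd.concat(pair_tables, ignore_index=True)
    written = write_results(
        config.output_dir,
        spots=spot_table,
        chromosomes=pd.concat(chrom_tables, ignore_index=True) if chrom_tables else None,
        summary=_summary_frame(summaries) if summaries else None,
    )
    pair_path = os.path.join(config.output_dir, "pairs.csv")
    pair_table.to_csv(pair_path, index=False, lineterminator="\n")
    written["pairs"] = pair_path
    if master_rows:
        master_path = os.path.join(config.output_dir, "master_table.csv")
        pd.concat(master_rows, ignore_index=True).to_csv(
            master_path, index=False, lineterminator="\n"
        )
        written["master_table"] = master_path

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "mode": "spots_only" if spots_only else "analyze",
        "n_fields": len(fields),
        "fields": statuses,
        "outputs": {k: os.path.basename(v) for k, v in written.items()},
    }
    manifest_path = os.path.join(config.output_dir, "run_manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = manifest_path
    return manifest


def run_batch(config: RunConfig, adapter=None) -> dict:
    """Full pipeline over a folder; returns the run manifest."""
    return _run(config, spots_only=False, adapter=adapter)


def run_spots_only(config: RunConfig) -> dict:
    """Spot/pair/intensity analysis with no segmentation.

    Chromosome-level tables are omitted; spot and pair tables are emitted
    with all chromosome labels at 0.
    """
    return _run(config, spots_only=True)
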