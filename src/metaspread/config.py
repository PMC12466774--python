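"""Run configuration: a single declarative YAML file that fixes every
analysis-affecting parameter, so one parameter set can be applied
identically across datasets and audited later."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping

import yaml

from .coloc import ColocParams
from .errors import ConfigError
from .segmentation import SegmentationParams
from .spots import SpotParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything a batch run needs.

    ``channel_tokens`` maps channel names to filename substrings;
    ``dapi_channel`` names the segmentation channel; ``spots`` holds one
    :class:`SpotParams` per analysis channel; ``condition_map`` maps
    fnmatch-style field-id patterns to metadata labels (condition,
    timepoint, replicate).
    """

    input_dir: str = "."
    output_dir: str = "results"
    channel_tokens: dict[str, str] = field(
        default_factory=lambda: {"DAPI": "435", "FISH": "525", "IF": "679"}
    )
    dapi_channel: str = "DAPI"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    spots: dict[str, SpotParams] = field(
        default_factory=lambda: {"FISH": SpotParams(), "IF": SpotParams()}
    )
    coloc: ColocParams = field(default_factory=ColocParams)
    snap_radius: float = 3.0
    condition_map: dict[str, dict[str, str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dapi_channel not in self.channel_tokens:
            raise ConfigError(
                f"dapi_channel {self.dapi_channel!r} not in channel_tokens"
            )
        for ch in (self.coloc.channel_a, self.coloc.channel_b):
            if ch not in self.channel_tokens:
                raise ConfigError(
                    f"colocalization channel {ch!r} not in channel_tokens"
                )

    def analysis_dict(self) -> dict:
        """The analysis-affecting parameters (paths excluded)."""
        d = asdict(self)
        d.pop("input_dir")
        d.pop("output_dir")
        return d

    def config_hash(self) -> str:
        """Stable hash of the analysis-affecting parameters."""
        payload = json.dumps(self.analysis_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_config(config: RunConfig, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def _coerce(d: Mapping) -> RunConfig:
    d = dict(d)
    try:
        if "segmentation" in d:
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if "spots" in d:
            d["spots"] = {ch: SpotParams(**p) for ch, p in d["spots"].items()}
        if "coloc" in d:
            d["coloc"] = ColocParams(**d["coloc"])
        cfg = RunConfig(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    return cfg


def load_config(path: str | os.PathLike) -> RunConfig:
    try:
        with open(os.fspath(path), encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    # YAML round-trips tuples as lists
    for key in ("channel_tokens", "condition_map"):
        if key in raw and raw[key] is None:
            raw[key] = {}
    return _coerce(raw)
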