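"""Synthetic metaphase-spread fields with exact ground truth.

The generator emulates the three channels of a typical metaphase
FISH/immunofluorescence experiment:

* ``DAPI`` — bent-rod chromosome bodies (thickened quadratic Bezier
  ribbons) on a flat background,
* ``FISH`` — one punctate locus signal on a chosen fraction of
  chromosomes,
* ``IF``   — a protein signal placed at a controlled distance from the
  FISH spot, so that the planted colocalization fraction is known exactly.

All randomness flows through one ``numpy`` Generator seeded from the spec,
so identical specs produce bit-identical fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from .errors import CapacityError, MissingLabelError
from .types import ImageStack, LabelMask, round_half_away

__all__ = ["SyntheticSpec", "SyntheticField", "generate_field", "generate_degraded_mask", "write_field"]

#: Truth-table header emitted alongside each synthetic field.
TRUTH_COLUMNS = ["channel", "row", "col", "chromosome_label", "colocalized", "pair_id"]

#: Default channel-name -> filename-token mapping used by the fixture writer
#: (tokens mimic excitation wavelengths).
DEFAULT_TOKENS = {"DAPI": "435", "FISH": "525", "IF": "679"}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic field of view.

    Geometry is in pixels at a nominal 60x / 1024x1024 sampling, where a
    condensed human chromosome spans roughly 30-60 px in length and
    8-14 px in width.
    """

    n_chromosomes: int = 46
    image_shape: tuple[int, int] = (1024, 1024)
    chromosome_length_range: tuple[float, float] = (30.0, 60.0)
    chromosome_width_range: tuple[float, float] = (8.0, 14.0)
    curvature_range: tuple[float, float] = (0.0, 0.9)  # radians of bend
    dapi_intensity: float = 3000.0
    background_level: float = 100.0
    noise_sd: float = 20.0
    fish_spot_fraction: float = 0.25
    coloc_fraction: float = 0.5
    spot_sigma: float = 2.0
    spot_amplitude: float = 2000.0
    offset_coloc: float = 6.0
    offset_noncoloc: float = 30.0
    noncoloc_if: bool = True  # place an IF spot for non-colocalized FISH chromosomes
    allow_touching: bool = False  # place objects at 1-px gaps to stress separation
    seed: int = 0

    # placement details (rarely changed)
    min_gap: float = 6.0  # clearance between chromosome footprints, px
    border_margin: float = 10.0
    interior_margin: float = 2.0  # spot distance from the instance boundary, px
    min_fish_separation: float = 15.0  # within-channel spot spacing, px
    min_if_separation: float = 12.0
    pair_clearance: float = 13.0  # min distance between spots that must NOT pair
    max_retries: int = 400

    def __post_init__(self) -> None:
        for name in ("fish_spot_fraction", "coloc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "chromosome_length_range",
            "chromosome_width_range",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered, got ({lo}, {hi})")
        if self.offset_coloc >= self.offset_noncoloc:
            raise ValueError("offset_coloc must be smaller than offset_noncoloc")
        if self.n_chromosomes < 0:
            raise ValueError("n_chromosomes must be non-negative")


@dataclass
class SyntheticField:
    """A generated field: images, ground-truth mask, and planted-spot table."""

    stack: ImageStack
    mask: LabelMask
    truth: pd.DataFrame
    spec: SyntheticSpec = dc_field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_planted_fish(self) -> int:
        return int((self.truth["channel"] == "FISH").sum())

    @property
    def n_planted_coloc(self) -> int:
        fish = self.truth[self.truth["channel"] == "FISH"]
        return int(fish["colocalized"].sum())


def _bezier_points(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _place_chromosomes(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.image_shape
    mask = np.zeros((rows, cols), dtype=np.int32)
    occupied = np.zeros((rows, cols), dtype=bool)
    gap = 1.0 if spec.allow_touching else spec.min_gap

    for label in range(1, spec.n_chromosomes + 1):
        placed = False
        for _ in range(spec.max_retries):
            length = rng.uniform(*spec.chromosome_length_range)
            width = rng.uniform(*spec.chromosome_width_range)
            bend = rng.uniform(*spec.curvature_range) * rng.choice([-1.0, 1.0])
            phi = rng.uniform(0.0, math.pi)
            cr = rng.uniform(spec.border_margin, rows - spec.border_margin)
            cc = rng.uniform(spec.border_margin, cols - spec.border_margin)

            direction = np.array([math.sin(phi), math.cos(phi)])
            perp = np.array([-direction[1], direction[0]])
            center = np.array([cr, cc])
            p0 = center - 0.5 * length * direction
            p2 = center + 0.5 * length * direction
            sagitta = length * bend / 8.0
            p1 = center + 2.0 * sagitta * perp

            npts = max(int(3 * length), 8)
            pts = _bezier_points(p0, p1, p2, npts)

            pad = width / 2 + gap + 1
            rmin = int(np.floor(pts[:, 0].min() - pad))
            rmax = int(np.ceil(pts[:, 0].max() + pad))
            cmin = int(np.floor(pts[:, 1].min() - pad))
            cmax = int(np.ceil(pts[:, 1].max() + pad))
            if rmin < 0 or cmin < 0 or rmax >= rows or cmax >= cols:
                continue

            rr, cc_grid = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
            grid = np.column_stack([rr.ravel(), cc_grid.ravel()]).astype(float)
            dist, _ = cKDTree(pts).query(grid)
            dist = dist.reshape(rr.shape)
            core = dist <= width / 2
            guard = dist <= width / 2 + gap
            window = occupied[rmin : rmax + 1, cmin : cmax + 1]
            if window[guard].any():
                continue

            mask[rmin : rmax + 1, cmin : cmax + 1][core] = label
            window[core] = True
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place chromosome {label}/{spec.n_chromosomes} after "
                f"{spec.max_retries} attempts; use fewer or smaller chromosomes"
            )
    return mask


def _interior_candidates(mask: np.ndarray, label: int, margin: float) -> np.ndarray:
    """Pixels of one instance at least ``margin`` px inside its boundary."""
    sl = ndi.find_objects((mask == label).astype(np.int8))[0]
    footprint = mask[sl] == label
    edt = ndi.distance_transform_edt(footprint)
    cand = np.argwhere(edt >= margin)
    if cand.size == 0:
        cand = np.argwhere(edt == edt.max())
    return cand + np.array([sl[0].start, sl[1].start])


def _stamp_gaussian(
    img: np.ndarray, row: float, col: float, amplitude: float, sigma: float
) -> None:
    rows, cols = img.shape
    half = int(math.ceil(5 * sigma))
    r0, r1 = max(0, int(row) - half), min(rows, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(cols, int(col) + half + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma**2)
    )


def _plant_spots(
    spec: SyntheticSpec, rng: np.random.Generator, mask: np.ndarray
) -> pd.DataFrame:
    rows, cols = spec.image_shape
    labels = np.arange(1, spec.n_chromosomes + 1)
    n_fish = round_half_away(spec.fish_spot_fraction * spec.n_chromosomes)
    fish_chroms = rng.choice(labels, size=n_fish, replace=False) if n_fish else np.array([], int)
    n_coloc = round_half_away(spec.coloc_fraction * n_fish)

    fish_pos: list[tuple[float, float]] = []
    for lab in fish_chroms:
        cand = _interior_candidates(mask, int(lab), spec.interior_margin)
        pos = None
        for _ in range(spec.max_retries):
            pr, pc = cand[rng.integers(len(cand))]
            jr, jc = rng.uniform(-0.4, 0.4, size=2)
            p = (float(pr + jr), float(pc + jc))
            if all(
                math.hypot(p[0] - q[0], p[1] - q[1]) >= spec.min_fish_separation
                for q in fish_pos
            ):
                pos = p
                break
        if pos is None:
            raise CapacityError(
                "could not place FISH spots at the requested separation; "
                "use fewer chromosomes or a larger image"
            )
        fish_pos.append(pos)

    records: list[dict] = []
    if_pos: list[tuple[float, float]] = []
    for i, (lab, fpos) in enumerate(zip(fish_chroms, fish_pos)):
        is_coloc = i < n_coloc
        records.append(
            {
                "channel": "FISH",
                "row": fpos[0],
                "col": fpos[1],
                "chromosome_label": int(lab),
                "colocalized": bool(is_coloc),
                "pair_id": i,
            }
        )
        offset = spec.offset_coloc if is_coloc else spec.offset_noncoloc
        if not is_coloc and not spec.noncoloc_if:
            continue
        target = None
        for _ in range(spec.max_retries):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            p = (fpos[0] + offset * math.sin(theta), fpos[1] + offset * math.cos(theta))
            if not (3 <= p[0] < rows - 3 and 3 <= p[1] < cols - 3):
                continue
            # keep every unintended FISH/IF pair clearly beyond the
            # colocalization threshold
            others = [q for j, q in enumerate(fish_pos) if j != i]
            if any(
                math.hypot(p[0] - q[0], p[1] - q[1]) < spec.pair_clearance for q in others
            ):
                continue
            if not is_coloc and math.hypot(p[0] - fpos[0], p[1] - fpos[1]) < spec.pair_clearance:
                continue
            if any(
                math.hypot(p[0] - q[0], p[1] - q[1]) < spec.min_if_separation
                for q in if_pos
            ):
                continue
            target = p
            break
        if target is None:
            raise CapacityError(
                "could not place an IF spot satisfying the clearance rules; "
                "reduce spot density or enlarge the image"
            )
        if_pos.append(target)
        records.append(
            {
                "channel": "IF",
                "row": target[0],
                "col": target[1],
                "chromosome_label": int(lab) if is_coloc else 0,
                "colocalized": bool(is_coloc),
                "pair_id": i,
            }
        )
    return pd.DataFrame(records, columns=TRUTH_COLUMNS)


def generate_field(spec: SyntheticSpec) -> SyntheticField:
    """Render one synthetic field of view.

    Returns
    -------
    SyntheticField
        ``stack`` with channels DAPI/FISH/IF, the ground-truth ``mask``
        (exactly ``spec.n_chromosomes`` instances), and the ``truth`` table
        of planted spots with their colocalization flags.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _place_chromosomes(spec, rng)
    truth = _plant_spots(spec, rng, mask)

    dapi = np.where(mask > 0, spec.dapi_intensity, spec.background_level).astype(float)
    fish = np.full(spec.image_shape, spec.background_level, dtype=float)
    ifch = np.full(spec.image_shape, spec.background_level, dtype=float)
    for rec in truth.itertuples():
        img = fish if rec.channel == "FISH" else ifch
        _stamp_gaussian(img, rec.row, rec.col, spec.spot_amplitude, spec.spot_sigma)

    channels = {"DAPI": dapi, "FISH": fish, "IF": ifch}
    if spec.noise_sd > 0:
        for name in channels:
            channels[name] = np.clip(
                channels[name] + rng.normal(0.0, spec.noise_sd, spec.image_shape), 0.0, None
            )
    stack = ImageStack(field_id=f"synthetic_seed{spec.seed}", channels=channels)
    return SyntheticField(stack=stack, mask=LabelMask(mask), truth=truth, spec=spec)


def generate_degraded_mask(
    truth: LabelMask | np.ndarray, ops: Sequence[tuple]
) -> LabelMask:
    """Apply controlled corruptions to a copy of a ground-truth mask.

    Supported ops (applied in order):

    * ``("drop", label)`` — remove one instance,
    * ``("merge", a, b)`` — give both instances the smaller label,
    * ``("split", label)`` — cut the instance through its centroid,
      perpendicular to its major axis,
    * ``("erode", k)`` — erode every instance by ``k`` iterations
      (instances eroded to nothing disappear).

    The input mask is never modified.
    """
    from . import editing  # local import: editing also imports types

    out = truth.copy() if isinstance(truth, LabelMask) else LabelMask(np.asarray(truth).copy())
    for op in ops:
        kind = op[0]
        if kind == "drop":
            out = editing.delete_label(out, int(op[1]))
        elif kind == "merge":
            targets = [int(v) for v in op[1:]] if len(op) > 2 else [int(v) for v in op[1]]
            out = editing.merge_labels(out, targets)
        elif kind == "split":
            label = int(op[1])
            if label not in out.areas():
                raise MissingLabelError(f"label {label} not present in mask")
            props = {p.label: p for p in regionprops(out.labels)}[label]
            r0, c0 = props.centroid
            theta = props.orientation  # angle of major axis vs row axis
            # perpendicular to the major axis, long enough to cross the body
            half = props.major_axis_length
            dr, dc = math.cos(theta), math.sin(theta)
            path = [(r0 - half * dr, c0 - half * dc), (r0 + half * dr, c0 + half * dc)]
            out = editing.split_label(out, label, path, split_width=1)
        elif kind == "erode":
            k = int(op[1])
            arr = out.labels
            new = np.zeros_like(arr)
            for lab in np.unique(arr[arr > 0]):
                eroded = ndi.binary_erosion(arr == lab, iterations=k)
                new[eroded] = lab
            out = LabelMask(new)
        else:
            raise ValueError(f"unknown degradation op {kind!r}")
    return out


def write_field(
    out_dir,
    field: SyntheticField,
    tokens: dict[str, str] | None = None,
) -> dict[str, str]:
    """Write a field as per-channel 16-bit TIFFs plus truth mask and CSV.

    The files are named ``{field_id}_{token}.tif`` so they can be fed back
    through :func:`metaspread.io.load_field` unchanged.
    """
    import os

    import tifffile

    from .io import write_label_mask

    tokens = dict(DEFAULT_TOKENS if tokens is None else tokens)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    fid = field.stack.field_id
    written: dict[str, str] = {}
    for name, token in tokens.items():
        arr = np.clip(np.round(field.stack.channel(name)), 0, 65535).astype(np.uint16)
        path = os.path.join(out_dir, f"{fid}_{token}.tif")
        tifffile.imwrite(path, arr)
        written[name] = path
    mask_path = os.path.join(out_dir, f"{fid}_mask.tif")
    write_label_mask(field.mask, mask_path)
    written["mask"] = mask_path
    truth_path = os.path.join(out_dir, f"{fid}_truth.csv")
    field.truth.to_csv(truth_path, index=False, lineterminator="\n")
    written["truth"] = truth_path
    return written
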