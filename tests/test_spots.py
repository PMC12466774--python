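import math

import numpy as np
import pytest

from metaspread.spots import (
    SpotParams,
    assign_spots,
    delete_spots,
    detect_spots,
    measure_intensity,
)
from metaspread.types import Spot

from conftest import make_blobs


def render(positions, shape=(128, 128), amplitude=1000.0, sigma=2.0, background=100.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background)
    for r, c in positions:
        img += amplitude * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))
    return img


def test_flat_image_has_no_spots():
    assert detect_spots(np.full((64, 64), 100.0), SpotParams()) == []


def test_single_gaussian_is_localized():
    img = render([(50.0, 70.0)])
    spots = detect_spots(img, SpotParams(), channel_name="FISH")
    assert len(spots) == 1
    s = spots[0]
    assert math.hypot(s.row - 50, s.col - 70) <= 1.0
    assert s.channel == "FISH"


def test_subpixel_refinement_beats_quarter_pixel():
    rng = np.random.default_rng(0)
    errs_refined, errs_integer = [], []
    for _ in range(25):
        r = 40 + rng.uniform(-0.5, 0.5)
        c = 60 + rng.uniform(-0.5, 0.5)
        img = render([(r, c)])
        (s,) = detect_spots(img, SpotParams(subpixel_refine=True))
        errs_refined.append(math.hypot(s.row - r, s.col - c))
        (s,) = detect_spots(img, SpotParams(subpixel_refine=False))
        errs_integer.append(math.hypot(s.row - r, s.col - c))
    assert np.mean(errs_refined) < 0.25
    assert np.mean(errs_refined) < np.mean(errs_integer)


def test_close_peaks_are_suppressed():
    img = render([(50.0, 50.0), (50.0, 53.0)])
    spots = detect_spots(img, SpotParams(min_peak_distance=5))
    assert len(spots) == 1


def test_raising_threshold_never_adds_spots():
    rng = np.random.default_rng(3)
    img = render([(30.0, 30.0), (80.0, 90.0)], amplitude=500.0) + rng.normal(
        0, 40, (128, 128)
    ).clip(-90)
    counts = [
        len(detect_spots(img, SpotParams(threshold_mode="relative", threshold_value=v)))
        for v in (0.05, 0.1, 0.2, 0.4, 0.8, 1.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_detection_is_translation_equivariant():
    img = render([(40.0, 40.0), (70.0, 90.0)])
    shifted = np.roll(img, (7, -5), axis=(0, 1))
    base = detect_spots(img, SpotParams())
    moved = detect_spots(shifted, SpotParams())
    got = sorted((s.row, s.col) for s in moved)
    expected = sorted((s.row + 7, s.col - 5) for s in base)
    assert got == pytest.approx(expected, abs=1e-9)


def test_spots_sorted_by_descending_peak():
    img = render([(30.0, 30.0)], amplitude=500.0) + render(
        [(90.0, 90.0)], amplitude=2000.0, background=0.0
    )
    spots = detect_spots(img, SpotParams())
    assert [round(s.row) for s in spots] == [90, 30]
    assert spots[0].peak_intensity > spots[1].peak_intensity


class TestAssign:
    mask = make_blobs((10, 20, 10, 20), (40, 50, 40, 50))

    def test_interior_spot_gets_its_label(self):
        (s,) = assign_spots([Spot("FISH", (15.0, 15.0))], self.mask)
        assert s.chromosome_label == 1

    def test_deep_background_stays_unassigned(self):
        (s,) = assign_spots([Spot("FISH", (30.0, 30.0))], self.mask, snap_radius=3)
        assert s.chromosome_label == 0

    def test_snap_to_nearest_instance_within_radius(self):
        # 2 px above instance 2's top edge
        (s,) = assign_spots([Spot("IF", (38.0, 45.0))], self.mask, snap_radius=3)
        assert s.chromosome_label == 2
        # brute-force oracle: nearest foreground pixel distance
        fg = np.argwhere(self.mask > 0)
        dmin = min(math.hypot(r - 38.0, c - 45.0) for r, c in fg)
        assert dmin <= 3

    def test_assignment_preserves_other_fields(self):
        (s,) = assign_spots([Spot("IF", (15.0, 15.0), 7.0, 5.0)], self.mask)
        assert (s.peak_intensity, s.aperture_intensity) == (7.0, 5.0)


class TestDelete:
    spots = [Spot("FISH", (float(r), float(c))) for r, c in [(5, 5), (10, 40), (60, 60)]]

    def test_delete_by_index(self):
        out = delete_spots(self.spots, indices=[1])
        assert [s.position for s in out] == [(5.0, 5.0), (60.0, 60.0)]
        with pytest.raises(IndexError):
            delete_spots(self.spots, indices=[3])

    def test_empty_region_is_noop(self):
        assert delete_spots(self.spots, region=(100, 100, 120, 120)) == self.spots

    def test_region_equals_indices_inside_region(self):
        region = (0, 0, 20, 50)
        inside = [
            i
            for i, s in enumerate(self.spots)
            if region[0] <= s.row <= region[2] and region[1] <= s.col <= region[3]
        ]
        assert delete_spots(self.spots, region=region) == delete_spots(
            self.spots, indices=inside
        )


class TestMeasure:
    def test_constant_image(self):
        img = np.full((32, 32), 100.0)
        assert measure_intensity(img, (16.0, 16.0), 4.0) == (100.0, 100.0)

    def test_gaussian_peak_is_amplitude_plus_background(self):
        img = render([(64.0, 64.0)], amplitude=1000.0, background=100.0)
        peak, aperture = measure_intensity(img, (64.0, 64.0), 3.0)
        assert peak == pytest.approx(1100.0, abs=1e-6)
        assert 100.0 < aperture < peak

    def test_aperture_on_half_plane_matches_enumeration(self):
        img = np.full((64, 64), 50.0)
        img[:, 32:] = 250.0
        pos, radius = (20.0, 32.0), 4.0
        _, aperture = measure_intensity(img, pos, radius)
        vals = [
            img[r, c]
            for r in range(64)
            for c in range(64)
            if (r - pos[0]) ** 2 + (c - pos[1]) ** 2 <= radius**2
        ]
        assert aperture == pytest.approx(np.mean(vals))

    def test_aperture_clipped_at_border(self):
        img = np.full((32, 32), 7.0)
        peak, aperture = measure_intensity(img, (0.0, 0.0), 5.0)
        assert (peak, aperture) == (7.0, 7.0)
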