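import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaspread.coloc import (
    ColocParams,
    coloc_ratio,
    compare_timepoints,
    consolidate,
    flag_colocalized_chromosomes,
    normalize_intensities,
    pair_spots,
)
from metaspread.errors import ConsolidationError, NormalizationError, StatisticsError
from metaspread.types import ChromosomeRecord, Spot


def brute_force_min_total_distance(pos_a, pos_b, max_distance):
    """Best one-to-one matching by exhaustive enumeration: maximum pair
    count first, then minimum total distance."""
    best = (0, 0.0, [])
    na, nb = len(pos_a), len(pos_b)
    k = min(na, nb)
    for size in range(k, -1, -1):
        candidates = []
        for a_sub in itertools.combinations(range(na), size):
            for b_perm in itertools.permutations(range(nb), size):
                ds = [
                    math.dist(pos_a[i], pos_b[j]) for i, j in zip(a_sub, b_perm)
                ]
                if all(d < max_distance for d in ds):
                    candidates.append((sum(ds), list(zip(a_sub, b_perm))))
        if candidates:
            total, pairs = min(candidates, key=lambda x: x[0])
            return size, total, pairs
    return 0, 0.0, []


def test_pairing_threshold_is_strict():
    pairs = pair_spots([(10.0, 10.0)], [(10.0, 21.9)], max_distance=12.0)
    assert len(pairs) == 1 and pairs[0][2] == pytest.approx(11.9)
    assert pair_spots([(10.0, 10.0)], [(10.0, 22.0)], max_distance=12.0) == []


def test_greedy_matches_brute_force_on_cluster():
    pos_a = [(10.0, 10.0), (10.0, 16.0), (18.0, 12.0)]
    pos_b = [(11.0, 11.0), (13.0, 15.0)]
    pairs = pair_spots(pos_a, pos_b, max_distance=12.0)
    size, total, _ = brute_force_min_total_distance(pos_a, pos_b, 12.0)
    assert len(pairs) == size
    assert sum(d for _, _, d in pairs) == pytest.approx(total)


def test_pairing_is_one_to_one_and_count_bounded():
    rng = np.random.default_rng(5)
    for _ in range(20):
        pos_a = [tuple(p) for p in rng.uniform(0, 50, (6, 2))]
        pos_b = [tuple(p) for p in rng.uniform(0, 50, (4, 2))]
        pairs = pair_spots(pos_a, pos_b, max_distance=15.0)
        assert len({i for i, _, _ in pairs}) == len(pairs)
        assert len({j for _, j, _ in pairs}) == len(pairs)
        assert len(pairs) <= min(len(pos_a), len(pos_b))


def test_pairing_distances_are_symmetric_in_channel_roles():
    rng = np.random.default_rng(9)
    pos_a = [tuple(p) for p in rng.uniform(0, 40, (5, 2))]
    pos_b = [tuple(p) for p in rng.uniform(0, 40, (5, 2))]
    fwd = {(pos_a[i], pos_b[j]) for i, j, _ in pair_spots(pos_a, pos_b, 12.0)}
    rev = {(pos_a[j], pos_b[i]) for i, j, _ in pair_spots(pos_b, pos_a, 12.0)}
    assert fwd == rev


def test_increasing_max_distance_never_loses_pairs():
    rng = np.random.default_rng(2)
    pos_a = [tuple(p) for p in rng.uniform(0, 60, (8, 2))]
    pos_b = [tuple(p) for p in rng.uniform(0, 60, (8, 2))]
    counts = [len(pair_spots(pos_a, pos_b, d)) for d in (2, 5, 10, 20, 50)]
    assert counts == sorted(counts)


coords = st.tuples(
    st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)
)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    pos_a=st.lists(coords, max_size=6),
    pos_b=st.lists(coords, max_size=6),
    max_distance=st.floats(0.5, 60),
)
def test_pairing_invariants_hold_for_arbitrary_clouds(pos_a, pos_b, max_distance):
    pairs = pair_spots(pos_a, pos_b, max_distance)
    assert len({i for i, _, _ in pairs}) == len(pairs)
    assert len({j for _, j, _ in pairs}) == len(pairs)
    assert len(pairs) <= min(len(pos_a), len(pos_b))
    for i, j, d in pairs:
        assert d == pytest.approx(math.dist(pos_a[i], pos_b[j]))
        assert d < max_distance
    # best matching count agrees with exhaustive enumeration
    size, _, _ = brute_force_min_total_distance(pos_a, pos_b, max_distance)
    assert len(pairs) <= size


def test_flagging_follows_accepted_pairs():
    records = [
        ChromosomeRecord("f", label, 100, (0.0, 0.0), {"FISH": 1, "IF": 1})
        for label in (1, 2)
    ]
    spots_a = [
        Spot("FISH", (10.0, 10.0), chromosome_label=1),
        Spot("FISH", (60.0, 60.0), chromosome_label=2),
    ]
    spots_b = [Spot("IF", (13.0, 14.0)), Spot("IF", (90.0, 60.0))]  # 5 px and 30 px
    pairs = pair_spots(spots_a, spots_b, 12.0)
    flagged = flag_colocalized_chromosomes(records, spots_a, pairs)
    assert [r.colocalized for r in flagged] == [True, False]
    assert [r.colocalized for r in records] == [False, False]  # input untouched


def test_ratio_arithmetic_and_missing_denominator():
    assert coloc_ratio(4, 10, 46) == pytest.approx(40.0)
    assert coloc_ratio(0, 10, 46) == 0.0
    assert coloc_ratio(4, 10, 46, "all_chromosomes") == pytest.approx(100 * 4 / 46)
    assert math.isnan(coloc_ratio(0, 0, 0))


def test_normalization_identities():
    out = normalize_intensities({"ctrl": [10.0, 10.0], "kd": [5.0]}, "ctrl")
    assert out["kd"][0] == pytest.approx(0.5)
    assert out["ctrl"].mean() == pytest.approx(1.0)
    rng = np.random.default_rng(1)
    raw = {"ctrl": rng.lognormal(5, 1, 20), "kd": rng.lognormal(4.5, 1, 20)}
    scaled = {k: 3.7 * v for k, v in raw.items()}
    a = normalize_intensities(raw, "ctrl")
    b = normalize_intensities(scaled, "ctrl")
    for key in raw:
        np.testing.assert_allclose(a[key], b[key])
    with pytest.raises(NormalizationError):
        normalize_intensities({"ctrl": [0.0, 0.0], "kd": [1.0]}, "ctrl")
    with pytest.raises(NormalizationError):
        normalize_intensities({"kd": [1.0]}, "ctrl")


def test_t_test_identities_and_closed_form():
    t, p = compare_timepoints([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (t, p) == (0.0, 1.0)
    # pooled-variance closed form for {1,2,3,4} vs {2,3,4,5}:
    # means 2.5 / 3.5, SS = 5 each, s2p = 10/6, t = -1 / sqrt(s2p * 1/2)
    t, p = compare_timepoints([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])
    expected = -1.0 / math.sqrt((10.0 / 6.0) * 0.5)
    assert t == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(-math.sqrt(6.0 / 5.0), rel=1e-12)
    assert 0 < p < 1
    with pytest.raises(StatisticsError):
        compare_timepoints([1.0], [1.0, 2.0])


def test_t_test_log2_transform_matches_manual():
    a, b = [2.0, 4.0, 8.0], [4.0, 8.0, 16.0]
    t_log, _ = compare_timepoints(a, b, log2=True)
    t_manual, _ = compare_timepoints(np.log2(a), np.log2(b))
    assert t_log == pytest.approx(t_manual, rel=1e-12)


def test_consolidate_counts_metadata_and_schema():
    tables = [
        pd.DataFrame({"field_id": [f"f{k}{i}" for i in range(5)], "coloc_ratio": [10.0 * k] * 5})
        for k in range(3)
    ]
    meta = [{"condition": "ctrl"}, {"condition": "kd"}, {"condition": "kd"}]
    master = consolidate(tables, meta)
    assert len(master) == 15
    means = master.groupby("condition")["coloc_ratio"].mean()
    assert means["ctrl"] == pytest.approx(0.0)
    assert means["kd"] == pytest.approx((10.0 + 20.0) / 2)
    assert consolidate([], columns=["a", "b"]).columns.tolist() == ["a", "b"]
    with pytest.raises(ConsolidationError):
        consolidate([tables[0], tables[1].rename(columns={"coloc_ratio": "x"})])


def test_coloc_params_validation():
    with pytest.raises(ValueError):
        ColocParams(max_distance=0.0)
    with pytest.raises(ValueError):
        ColocParams(denominator_mode="everything")
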