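"""Aggregation, significance screen and mean-rank scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ciliaquant import (
    aggregate,
    overall_performance,
    performance_report,
    rank_entities,
    screen_parameters,
)
from ciliaquant.scoring import DEFAULT_DIRECTIONS, condition_antibody_means


def make_slide_table(values_by_condition, parameter="AreaShape_Area",
                     antibody="DNAH5"):
    rows = []
    for condition, values in values_by_condition.items():
        for i, v in enumerate(values):
            rows.append({"donor": f"D{i+1}", "condition": condition,
                         "antibody": antibody, "parameter": parameter,
                         "value": float(v)})
    return pd.DataFrame(rows)


def _features(areas, donor="D1", condition="-80_28d", antibody="DNAH5"):
    return pd.DataFrame([{
        "donor": donor, "condition": condition, "antibody": antibody,
        "image_id": "img000", "object_id": i + 1, "channel": "test",
        "AreaShape_Area": a, "AreaShape_Compactness": 1.0,
        "AreaShape_Eccentricity": 0.5, "Intensity_MassDisplacement": 0.1,
    } for i, a in enumerate(areas)])


EMPTY = pd.DataFrame()


def test_aggregate_slide_mean():
    table = aggregate(_features([10.0, 20.0, 30.0]), EMPTY, EMPTY,
                      unique_only=False)
    area = table[table.parameter == "AreaShape_Area"]
    assert len(area) == 1 and area.value.iloc[0] == pytest.approx(20.0)


def test_aggregate_across_donors_and_missing_donor():
    feats = pd.concat([_features([v], donor=f"D{i+1}")
                       for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0])])
    table = aggregate(feats, EMPTY, EMPTY, unique_only=False)
    means = condition_antibody_means(table)
    assert means.value.iloc[0] == pytest.approx(3.0)
    # dropping one donor: mean over the remaining four
    table4 = aggregate(feats[feats.donor != "D5"], EMPTY, EMPTY, unique_only=False)
    assert condition_antibody_means(table4).value.iloc[0] == pytest.approx(2.5)


def test_aggregate_unique_pair_filter_restricts_objects():
    feats = _features([10.0, 1000.0])
    pairs = pd.DataFrame([
        {"donor": "D1", "condition": "-80_28d", "antibody": "DNAH5",
         "image_id": "img000", "red_id": 1, "green_id": 1,
         "green_multiplicity": 1, "distance_um": 0.5},
        {"donor": "D1", "condition": "-80_28d", "antibody": "DNAH5",
         "image_id": "img000", "red_id": 2, "green_id": 2,
         "green_multiplicity": 2, "distance_um": 9.9},
    ])
    table = aggregate(feats, pairs, EMPTY, unique_only=True)
    area = table[table.parameter == "AreaShape_Area"]
    assert area.value.iloc[0] == pytest.approx(10.0)  # object 2 filtered out
    dist = table[table.parameter == "Distance_Centroid_mCilia"]
    assert dist.value.iloc[0] == pytest.approx(0.5)


def test_screen_flat_parameter_not_significant():
    table = make_slide_table({c: [5.0] * 4 for c in ("A", "B", "C")})
    significant, pvals = screen_parameters(table, alpha=0.001)
    assert significant == set()
    assert pvals["AreaShape_Area"] == 1.0


def test_screen_alpha_one_passes_everything():
    rng = np.random.default_rng(0)
    table = make_slide_table({c: rng.normal(size=4) for c in ("A", "B", "C")})
    significant, pvals = screen_parameters(table, alpha=1.0)
    assert significant == set(pvals) == {"AreaShape_Area"}


def test_screen_strong_separation_is_significant():
    rng = np.random.default_rng(1)
    table = make_slide_table({
        f"C{k}": 10.0 * k + rng.normal(0, 0.1, size=8) for k in range(7)
    })
    significant, pvals = screen_parameters(table, alpha=0.001)
    assert "AreaShape_Area" in significant
    assert pvals["AreaShape_Area"] < 1e-6


def test_screen_skips_insufficient_groups(caplog):
    table = make_slide_table({"A": [1.0, 2.0]})
    significant, pvals = screen_parameters(table)
    assert pvals == {} and significant == set()


def test_rank_direction_and_reversal():
    table = make_slide_table({"A": [3.0], "B": [1.0], "C": [2.0]})
    rm_low = rank_entities(table, {"AreaShape_Area": "lower"}, axis="condition")
    assert rm_low.ranks.loc["AreaShape_Area", ["A", "B", "C"]].tolist() == [3, 1, 2]
    rm_high = rank_entities(table, {"AreaShape_Area": "higher"}, axis="condition")
    assert rm_high.ranks.loc["AreaShape_Area", ["A", "B", "C"]].tolist() == [1, 3, 2]


def test_rank_ties_get_midranks():
    table = make_slide_table({"A": [1.0], "B": [1.0], "C": [5.0]})
    rm = rank_entities(table, {"AreaShape_Area": "lower"}, axis="condition")
    assert rm.ranks.loc["AreaShape_Area", ["A", "B", "C"]].tolist() == [1.5, 1.5, 3]


def test_rank_missing_direction_raises():
    table = make_slide_table({"A": [1.0], "B": [2.0]}, parameter="Mystery")
    with pytest.raises(ValueError, match="Mystery"):
        rank_entities(table, {"AreaShape_Area": "lower"}, axis="condition")


def test_rank_condition_subset():
    rows = []
    for ab, vals in (("X", {"A": 1.0, "B": 2.0, "C": 0.0}),
                     ("Y", {"A": 2.0, "B": 1.0, "C": 0.0})):
        for cond, v in vals.items():
            rows.append({"donor": "D1", "condition": cond, "antibody": ab,
                         "parameter": "AreaShape_Area", "value": v})
    table = pd.DataFrame(rows)
    rm_all = rank_entities(table, {"AreaShape_Area": "lower"}, axis="antibody")
    assert rm_all.ranks.loc["AreaShape_Area", ["X", "Y"]].tolist() == [1.5, 1.5]
    rm_sub = rank_entities(table, {"AreaShape_Area": "lower"}, axis="antibody",
                           condition_subset=["A", "C"])
    assert rm_sub.ranks.loc["AreaShape_Area", ["X", "Y"]].tolist() == [1, 2]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_rank_rows_are_valid_permutations(seed):
    """Without ties every per-parameter rank row is a permutation of 1..n and
    the overall mean rank lies in [1, n]."""
    rng = np.random.default_rng(seed)
    n_cond = int(rng.integers(2, 8))
    params = list(DEFAULT_DIRECTIONS)[: int(rng.integers(1, 7))]
    rows = []
    for parameter in params:
        vals = rng.permutation(n_cond) + rng.uniform(0.001, 0.4, n_cond)
        for c in range(n_cond):
            rows.append({"donor": "D1", "condition": f"C{c}", "antibody": "X",
                         "parameter": parameter, "value": float(vals[c])})
    rm = rank_entities(pd.DataFrame(rows), axis="condition")
    for _, row in rm.ranks.iterrows():
        assert sorted(row.tolist()) == list(range(1, n_cond + 1))
    overall = overall_performance(rm)
    assert ((overall >= 1) & (overall <= n_cond)).all()
    assert overall.is_monotonic_increasing


def test_overall_performance_all_equal_ranks():
    frame = pd.DataFrame(3.0, index=["p1", "p2"], columns=["A", "B"])
    assert overall_performance(frame).tolist() == [3.0, 3.0]


def test_performance_report_outputs_and_determinism(tmp_path):
    rng = np.random.default_rng(5)
    rows = []
    for donor in ("D1", "D2", "D3"):
        for cond in ("A", "B"):
            for ab in ("X", "Y"):
                for parameter in DEFAULT_DIRECTIONS:
                    rows.append({"donor": donor, "condition": cond,
                                 "antibody": ab, "parameter": parameter,
                                 "value": float(rng.uniform(1, 5))})
    table = pd.DataFrame(rows)
    paths = performance_report(table, tmp_path / "r1", condition_subset=["A"])
    names = sorted(p.name for p in (tmp_path / "r1").iterdir())
    assert sum(n.startswith("parameter__") for n in names) == 6
    assert "ranks__condition.csv" in names and "ranks__antibody.csv" in names
    assert "ranks__antibody_subset.csv" in names and "screen.json" in names

    performance_report(table, tmp_path / "r2", condition_subset=["A"])
    for p in (tmp_path / "r1").iterdir():
        assert p.read_bytes() == (tmp_path / "r2" / p.name).read_bytes()
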