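"""Exchange matrices, the randomized null and level summaries."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record

from enzevol.ec import compare_level, parse_ec
from enzevol.exchange_matrix import (
    ExchangeMatrix,
    aggregate,
    build_tree_matrix,
    compare_matrices_chi2,
    count_allbyall,
    expected_matrix,
    level_proportions,
    strip_within_class,
    summarize_superfamily,
    tally_levels,
)
from enzevol.model import SuperfamilyDataset
from enzevol.tree_exchange import ExchangeEvent

E = parse_ec

# the nine functions of the Ntn-type amide hydrolase superfamily
NTN_ECS = [
    "2.4.2.14", "6.3.5.4", "6.3.3.4", "2.6.1.16",
    "3.4.25.1", "3.4.25.2", "1.4.1.13", "1.4.1.14", "1.4.7.1",
]


def test_allbyall_phosphodiesterase_pairs():
    """Hand-enumerated six unordered pairs of the four-function set."""
    res = count_allbyall({E("3.1.4.11"), E("3.1.4.41"), E("4.6.1.13"), E("4.6.1.14")})
    m = res.matrix
    assert m.counts[2, 3] == 4  # hydrolase-lyase cross pairs
    assert m.diag_levels[2].tolist() == [0, 0, 1]  # class 3, level 4
    assert m.diag_levels[3].tolist() == [0, 0, 1]  # class 4, level 4
    assert m.total == 6
    assert res.uncounted == []


def test_allbyall_ntn_touches_four_classes():
    res = count_allbyall({E(t) for t in NTN_ECS})
    touched = {
        i + 1
        for i in range(6)
        if res.matrix.counts[i].sum() > 0 or res.matrix.diag_levels[i].sum() > 0
    }
    assert touched == {1, 2, 3, 6}


def test_allbyall_degenerate_sets():
    assert count_allbyall(set()).matrix.total == 0
    assert count_allbyall({E("1.1.1.1")}).matrix.total == 0


def test_allbyall_total_is_pair_count_minus_identical():
    ecs = {E(t) for t in NTN_ECS}
    res = count_allbyall(ecs)
    n = len(ecs)
    assert res.matrix.total + len(res.uncounted) == n * (n - 1) // 2


def test_allbyall_wildcard_pair_uncounted():
    res = count_allbyall({E("3.4.25.1"), E("3.4.25.-")})
    assert res.matrix.total == 0
    assert len(res.uncounted) == 1


def _event(a, b):
    return ExchangeEvent(("p", "c"), E(a), E(b), compare_level(E(a), E(b)))


def test_build_tree_matrix_counts_repeats():
    events = [_event("3.1.4.11", "4.6.1.13")] * 3 + [_event("1.1.1.1", "1.1.1.2")]
    m = build_tree_matrix(events)
    assert m.counts[2, 3] == 3
    assert m.diag_levels[0, 2] == 1
    assert m.total == 4
    assert build_tree_matrix([]).total == 0


def test_matrix_symmetry_and_validation():
    m = build_tree_matrix([_event("3.1.4.11", "4.6.1.13")])
    assert np.allclose(m.counts, m.counts.T)
    m.validate()


def test_aggregate_doubles_and_percentages_sum():
    m = count_allbyall({E(t) for t in NTN_ECS}).matrix
    agg, pct = aggregate([m, m])
    assert agg.total == 2 * m.total
    assert abs(sum(pct.values()) - 100.0) < 1e-9
    with pytest.raises(ValueError):
        aggregate([m, build_tree_matrix([])])


def test_aggregate_equals_pooled_events(small_cohort):
    """Summing per-superfamily tree matrices equals one matrix over the
    pooled event list."""
    from enzevol.pipeline import analyze_trees

    per_sf = []
    pooled = []
    for ds in small_cohort.datasets[:10]:
        events = analyze_trees(ds)
        pooled.extend(events)
        per_sf.append(build_tree_matrix(events))
    agg, _ = aggregate(per_sf)
    assert agg.allclose(build_tree_matrix(pooled))


# ---------------------------------------------------------------------------
# randomized null
# ---------------------------------------------------------------------------


def test_expected_matrix_single_class_pool():
    pool = [E("3.1.1.1"), E("3.1.1.2"), E("3.2.1.1")] * 5
    res = expected_matrix(pool, 1000, seed=7)
    assert np.triu(res.monte_carlo.counts, k=1).sum() == 0
    assert res.monte_carlo.counts[2, 2] > 0


def test_expected_matrix_closed_form_two_classes():
    """50/50 two-class pool: exact without-replacement pair probability."""
    pool = [E("3.1.1.1")] * 10 + [E("4.1.1.1")] * 10
    res = expected_matrix(pool, 1000, seed=0)
    p_cross = 2 * 100 / (20 * 19)
    assert res.closed_form.counts[2, 3] == pytest.approx(1000 * p_cross)
    # same-value pairs are level-0 and carry no matrix mass
    assert res.closed_form.total == pytest.approx(1000 * p_cross)


def test_expected_matrix_is_seed_deterministic():
    pool = [E(t) for t in NTN_ECS] * 3
    a = expected_matrix(pool, 500, seed=42)
    b = expected_matrix(pool, 500, seed=42)
    assert a.monte_carlo.allclose(b.monte_carlo)
    c = expected_matrix(pool, 500, seed=43)
    assert not a.monte_carlo.allclose(c.monte_carlo)


def test_expected_matrix_rejects_tiny_pool():
    with pytest.raises(ValueError):
        expected_matrix([E("1.1.1.1")], 10, seed=0)


def test_monte_carlo_tracks_closed_form():
    pool = [E(t) for t in NTN_ECS] * 4
    n = 20000
    res = expected_matrix(pool, n, seed=3)
    for (name, mc), (_, cf) in zip(res.monte_carlo.cells(), res.closed_form.cells()):
        p = cf / n
        se = np.sqrt(n * p * (1 - p))
        assert abs(mc - cf) <= max(3 * se, 1e-9), name


# ---------------------------------------------------------------------------
# χ²
# ---------------------------------------------------------------------------


def test_chi2_identical_matrices():
    m = count_allbyall({E(t) for t in NTN_ECS}).matrix
    exp = m.copy()
    exp.mode = "expected"
    res = compare_matrices_chi2(m, exp)
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi2_hand_computation():
    """Four cells O=[10,20,20,10] vs uniform E=15 gives 20/3."""
    obs = ExchangeMatrix("allbyall")
    exp = ExchangeMatrix("expected")
    cells = [("1.1.1.1", "2.1.1.1", 10), ("1.1.1.1", "3.1.1.1", 20),
             ("1.1.1.1", "4.1.1.1", 20), ("1.1.1.1", "5.1.1.1", 10)]
    for a, b, o in cells:
        obs.add_exchange(E(a), E(b), weight=o)
        exp.add_exchange(E(a), E(b), weight=15)
    res = compare_matrices_chi2(obs, exp)
    assert res.statistic == pytest.approx(20 / 3)
    assert res.dof == 3


def test_chi2_excludes_zero_expectation_cells():
    obs = ExchangeMatrix("allbyall")
    obs.add_exchange(E("1.1.1.1"), E("2.1.1.1"), weight=5)
    obs.add_exchange(E("1.1.1.1"), E("1.2.1.1"), weight=5)
    exp = ExchangeMatrix("expected")
    exp.add_exchange(E("1.1.1.1"), E("2.1.1.1"), weight=1)
    with pytest.warns(UserWarning, match="zero-expectation"):
        res = compare_matrices_chi2(obs, exp)
    assert "EC1:L2" in res.excluded_cells


def test_chi2_invariant_under_class_permutation():
    perm = {1: 4, 2: 5, 3: 6, 4: 1, 5: 2, 6: 3}

    def permute(m):
        out = ExchangeMatrix(m.mode)
        idx = [perm[i + 1] - 1 for i in range(6)]
        for i in range(6):
            for j in range(6):
                out.counts[idx[i], idx[j]] = m.counts[i, j]
            out.diag_levels[idx[i]] = m.diag_levels[i]
        return out

    obs = count_allbyall({E(t) for t in NTN_ECS}).matrix
    exp = expected_matrix([E(t) for t in NTN_ECS] * 2, 200, seed=5).closed_form
    r1 = compare_matrices_chi2(obs, exp)
    r2 = compare_matrices_chi2(permute(obs), permute(exp))
    assert r1.statistic == pytest.approx(r2.statistic)
    assert r1.dof == r2.dof


# ---------------------------------------------------------------------------
# level summaries and stripping
# ---------------------------------------------------------------------------


def test_level_proportions_worked_example():
    assert level_proportions({1: 2, 4: 3}) == {1: 0.4, 4: 0.6}


def test_level_proportions_degenerate():
    assert level_proportions({4: 7}) == {4: 1.0}
    assert level_proportions({}) is None  # missing, not zero


@given(st.dictionaries(st.integers(1, 4), st.integers(0, 50), min_size=1))
def test_level_proportions_sum_to_one(tally):
    props = level_proportions(tally)
    if props is not None:
        assert sum(props.values()) == pytest.approx(1.0)


def test_strip_within_class():
    m = count_allbyall({E("3.1.4.11"), E("3.1.4.41"), E("4.6.1.13")}).matrix
    stripped, pct = strip_within_class(m)
    assert np.trace(stripped.counts) == 0
    assert pct["EC3:EC4"] == pytest.approx(100.0)
    diag_only = count_allbyall({E("3.1.4.11"), E("3.1.4.41")}).matrix
    with pytest.raises(ValueError):
        strip_within_class(diag_only)


def test_tally_levels_from_events():
    events = [_event("3.1.4.11", "4.6.1.13"), _event("1.1.1.1", "1.1.1.2")]
    assert tally_levels(events) == {1: 1, 2: 0, 3: 0, 4: 1}


# ---------------------------------------------------------------------------
# superfamily summary
# ---------------------------------------------------------------------------


def test_summarize_superfamily_census():
    records = [
        make_record("s1", ecs="1.1.1.1", mda="C", ssg="SSG1", has_structure=True),
        make_record("s2", ecs="1.1.1.1", mda="A-C", ssg="SSG1"),
        make_record("s3", ecs="1.1.1.2", mda="C", ssg="SSG2"),
        make_record("s4", ecs="1.1.1.1", mda="C", ssg="SSG1"),
    ]
    ds = SuperfamilyDataset("SF000", records)
    s = summarize_superfamily(ds)
    assert s["n_ssgs"] == 2
    assert s["n_mdas"] == 2
    assert s["n_unique_ecs"] == 2
    assert s["largest_ec_fraction"] == pytest.approx(3 / 4)
    assert s["level4_only"] is True


def test_summarize_level4_only_false_with_class_change():
    records = [
        make_record("s1", ecs="1.1.1.1"),
        make_record("s2", ecs="2.1.1.1"),
    ]
    s = summarize_superfamily(SuperfamilyDataset("SF000", records))
    assert s["level4_only"] is False


def test_matrix_round_trip_via_dict():
    m = count_allbyall({E(t) for t in NTN_ECS}).matrix
    again = ExchangeMatrix.from_dict(m.to_dict())
    assert m.allclose(again)
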