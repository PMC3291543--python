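"""Parsimony exchange inference on annotated gene trees."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_record, make_tree
from oracles import brute_force_min_changes, random_binary_newick

from enzevol.ec import ECNumber, parse_ec
from enzevol.model import AlignmentBlock
from enzevol.tree_exchange import (
    ExchangeEvent,
    classify_all_events,
    classify_exchange_context,
    count_tree_exchanges,
    find_clean_bifurcations,
    infer_ancestral_functions,
    reconcile_counts,
    resolve_ancestral_functions,
)

# the three-clade phosphodiesterase topology: a hydrolase clade with
# substrate diversification, a lyase clade, and an outlying hydrolase leaf
PI_TREE = "(((h1,h2,h3),(l1,l2)),s1);"
PI_LEAVES = {
    "h1": "3.1.4.11", "h2": "3.1.4.46", "h3": "3.1.4.3",
    "l1": "4.6.1.13", "l2": "4.6.1.14",
    "s1": "3.1.4.41",
}


def test_identical_leaves_give_no_events():
    tree = make_tree("((a,b),c);", {"a": "1.1.1.1", "b": "1.1.1.1", "c": "1.1.1.1"})
    assert count_tree_exchanges(tree) == []
    resolved = resolve_ancestral_functions(tree)
    assert set(resolved.values()) == {parse_ec("1.1.1.1")}


def test_two_state_cherry_has_one_event():
    tree = make_tree("(a,b);", {"a": "1.1.1.1", "b": "2.1.1.1"})
    sets = infer_ancestral_functions(tree)
    assert sets["N0"] == frozenset({parse_ec("1.1.1.1"), parse_ec("2.1.1.1")})
    events = count_tree_exchanges(tree)
    assert len(events) == 1
    assert events[0].change_level == 1


def test_hydrolase_lyase_worked_topology():
    """Single class-level transition, no sub-class changes, substrate
    diversification within the hydrolases."""
    tree = make_tree(PI_TREE, PI_LEAVES)
    events = count_tree_exchanges(tree)
    by_level = {k: sum(1 for e in events if e.change_level == k) for k in (1, 2, 3, 4)}
    assert by_level[1] == 1
    assert by_level[2] == 0
    assert by_level[3] == 0
    assert by_level[4] == 4


def test_empty_leaf_annotation_rejected():
    tree = make_tree("(a,b);", {"a": "1.1.1.1", "b": "1.1.1.1"})
    tree.records["b"] = make_record("b", ecs="")
    with pytest.raises(ValueError):
        count_tree_exchanges(tree)


def test_multifunctional_leaf_costs_nothing_when_parent_matches():
    tree = make_tree("((a,b),c);", {
        "a": "3.4.25.1;3.4.25.2", "b": "3.4.25.1", "c": "3.4.25.1",
    })
    assert count_tree_exchanges(tree) == []


def _random_instance(rng, n_leaves, alphabet, polymorphic=False):
    newick = random_binary_newick(n_leaves, rng)
    leaf_ecs = {}
    for i in range(n_leaves):
        k = 1 + (polymorphic and int(rng.integers(0, 2)))
        chosen = rng.choice(len(alphabet), size=k, replace=False)
        leaf_ecs[f"x{i}"] = ";".join(alphabet[c] for c in chosen)
    return make_tree(newick, leaf_ecs)


ALPHABET = ["1.1.1.1", "1.1.1.2", "2.1.1.1", "1.2.1.1"]


def test_event_count_matches_exhaustive_minimum(rng):
    """Fitch with deterministic resolution attains the brute-force
    parsimony minimum on random binary trees."""
    for trial in range(120):
        n = int(rng.integers(4, 8))
        tree = _random_instance(rng, n, ALPHABET, polymorphic=trial % 3 == 0)
        events = count_tree_exchanges(tree)
        assert len(events) == brute_force_min_changes(tree)


def test_event_count_at_least_states_minus_one(rng):
    for _ in range(40):
        n = int(rng.integers(4, 8))
        tree = _random_instance(rng, n, ALPHABET)
        distinct = {ec for lid in tree.leaf_ids() for ec in tree.records[lid].ec_set}
        assert len(count_tree_exchanges(tree)) >= len(distinct) - 1


def test_event_count_invariant_under_state_relabeling(rng):
    """Parsimony counts depend only on the equality structure of states."""
    mapping = {
        "1.1.1.1": "6.9.9.99", "1.1.1.2": "3.4.25.1",
        "2.1.1.1": "1.1.1.1", "1.2.1.1": "5.5.5.5",
    }
    for _ in range(30):
        n = int(rng.integers(4, 8))
        newick = random_binary_newick(n, rng)
        leaf_ecs = {
            f"x{i}": ALPHABET[int(rng.integers(0, len(ALPHABET)))] for i in range(n)
        }
        t1 = make_tree(newick, leaf_ecs)
        t2 = make_tree(newick, {k: mapping[v] for k, v in leaf_ecs.items()})
        assert len(count_tree_exchanges(t1)) == len(count_tree_exchanges(t2))


# ---------------------------------------------------------------------------
# clean bifurcations
# ---------------------------------------------------------------------------


def test_clean_bifurcation_found():
    tree = make_tree("((a,b),(c,d));", {
        "a": "3.1.4.11", "b": "3.1.4.11", "c": "4.6.1.13", "d": "4.6.1.13",
    })
    bifs = find_clean_bifurcations(tree)
    assert {b.node_id for b in bifs} == {"N0"}
    bif = bifs[0]
    assert {bif.left_function, bif.right_function} == {
        parse_ec("3.1.4.11"), parse_ec("4.6.1.13")
    }


def test_cherry_of_two_distinct_functions_is_clean():
    tree = make_tree("((a,b),(c,d));", {
        "a": "3.1.4.11", "b": "3.1.4.12", "c": "4.6.1.13", "d": "4.6.1.13",
    })
    # N1 = (a, b): one function on each side; N0's left side is polymorphic
    assert {b.node_id for b in find_clean_bifurcations(tree)} == {"N1"}


def test_polymorphic_side_is_not_clean():
    # a multifunctional leaf breaks single-function-per-side on every
    # ancestor; (c, d) share one function so their cherry is not clean either
    tree = make_tree("((a,b),(c,d));", {
        "a": "3.1.4.11;3.1.4.12", "b": "3.1.4.12", "c": "4.6.1.13", "d": "4.6.1.13",
    })
    assert find_clean_bifurcations(tree) == []


def test_multifurcation_excluded_from_clean_bifurcations():
    tree = make_tree("(a,b,c);", {"a": "1.1.1.1", "b": "2.1.1.1", "c": "2.1.1.1"})
    assert find_clean_bifurcations(tree) == []


def test_clean_bifurcation_yields_exactly_one_event_on_a_child_edge():
    tree = make_tree("((a,b),(c,d));", {
        "a": "3.1.4.11", "b": "3.1.4.11", "c": "4.6.1.13", "d": "4.6.1.13",
    })
    events = count_tree_exchanges(tree)
    assert len(events) == 1
    assert events[0].edge[0] == "N0"


# ---------------------------------------------------------------------------
# context flags
# ---------------------------------------------------------------------------


def test_mda_change_flag_tracks_local_architecture_change():
    tree = make_tree(
        "((a,b),(c,d));",
        {"a": "3.1.4.11", "b": "3.1.4.11", "c": "4.6.1.13", "d": "4.6.1.13"},
        leaf_mdas={"a": "A-C", "b": "A-C", "c": "C", "d": "C"},
    )
    events = classify_all_events(tree)
    assert len(events) == 1
    assert events[0].mda_change is True


def test_uniform_mda_not_flagged():
    tree = make_tree(
        "((a,b),(c,d));",
        {"a": "3.1.4.11", "b": "3.1.4.11", "c": "4.6.1.13", "d": "4.6.1.13"},
    )
    events = classify_all_events(tree)
    assert events[0].mda_change is False


def test_loop_flag_unset_without_clean_bifurcation():
    tree = make_tree("((a,b),(c,d));", {
        "a": "3.1.4.11;3.1.4.12", "b": "3.1.4.12", "c": "4.6.1.13", "d": "4.6.1.13",
    })
    aln = AlignmentBlock(
        {k: "AAAAAAAAAA" for k in ("a", "b", "c", "d")}, frozenset({5})
    )
    events = classify_all_events(tree, alignment=aln)
    assert all(ev.loop_indel is None for ev in events)


def test_loop_flag_set_on_clean_bifurcation_with_gap():
    seqs = {
        "a": "AAAAAAAAAA", "b": "AAAAAAAAAA",
        "c": "AAAA---AAA", "d": "AAAA---AAA",
    }
    tree = make_tree("((a,b),(c,d));", {
        "a": "3.1.4.11", "b": "3.1.4.11", "c": "4.6.1.13", "d": "4.6.1.13",
    })
    aln = AlignmentBlock(seqs, frozenset({5}))
    events = classify_all_events(tree, alignment=aln)
    assert events[0].loop_indel is True


# ---------------------------------------------------------------------------
# reconciliation
# ---------------------------------------------------------------------------


def test_reconcile_worked_example():
    assert reconcile_counts(646, 651, 85) == 1212


@pytest.mark.parametrize("args, expected", [((10, 0, 0), 10), ((0, 0, 0), 0)])
def test_reconcile_identity_cases(args, expected):
    assert reconcile_counts(*args) == expected


def test_reconcile_rejects_inconsistent_inputs():
    with pytest.raises(ValueError):
        reconcile_counts(10, 0, 20)
    with pytest.raises(ValueError):
        reconcile_counts(-1, 0, 0)


def test_event_validation():
    with pytest.raises(ValueError):
        ExchangeEvent(("p", "c"), parse_ec("1.1.1.1"), parse_ec("1.1.1.1"), 0)
    with pytest.raises(ValueError):
        ExchangeEvent(("p", "c"), parse_ec("1.1.1.1"), parse_ec("1.1.1.2"), 1)
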