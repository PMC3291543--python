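"""Infer and count E.C. exchanges on annotated gene trees.

The evolutionary route by which a superfamily exchanged one enzyme
function for another is reconstructed with set-valued small parsimony
(Fitch): a bottom-up intersection-else-union pass over each node's
children, then a deterministic top-down resolution that keeps the
parent's resolved state whenever it is admissible and otherwise picks
the smallest member in the package's canonical E.C. ordering.  On binary
trees this attains the parsimony minimum number of changes; the
resolution rule makes counts reproducible run to run.

Every edge whose resolved parent and child states differ yields one
:class:`ExchangeEvent` at the first differing E.C. level.  The same
(from, to) pair occurring on several edges is counted each time —
tree-based counts are therefore *observations*, reconciled with the
all-by-all unique-pair count via :func:`reconcile_counts`.

Multifunctional leaves contribute their full annotation set as a
polymorphic leaf state (any member satisfiable at no cost), so
annotation promiscuity is not mistaken for evolutionary change.
Multifurcations run through the same bottom-up rule but are excluded
from clean-bifurcation and loop analyses, which the wording of the
procedure restricts to bifurcations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Hashable, Mapping, Optional, TypeVar

from .ec import ECNumber, compare_level
from .model import AlignmentBlock, AnnotatedTree, DomainRecord

S = TypeVar("S", bound=Hashable)


@dataclass(frozen=True)
class ExchangeEvent:
    """One inferred functional change on a tree edge."""

    edge: tuple[str, str]  # (parent node id, child node id)
    from_ec: ECNumber
    to_ec: ECNumber
    change_level: int
    mda_change: bool = False
    loop_indel: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.change_level < 1:
            raise ValueError("an exchange event must differ at some level")
        if compare_level(self.from_ec, self.to_ec) != self.change_level:
            raise ValueError(
                f"{self.from_ec} -> {self.to_ec} is not a level-{self.change_level} change"
            )


@dataclass(frozen=True)
class CleanBifurcation:
    """A binary node with a single function on each side of the divide."""

    node_id: str
    left_function: ECNumber
    right_function: ECNumber
    left_leaves: tuple[str, ...]
    right_leaves: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.left_function == self.right_function:
            raise ValueError("clean bifurcation requires two distinct functions")

    def side_map(self) -> dict[str, str]:
        """Leaf id -> 'left' | 'right' membership map."""
        sides = {lid: "left" for lid in self.left_leaves}
        sides.update({lid: "right" for lid in self.right_leaves})
        return sides


# ---------------------------------------------------------------------------
# generic set-valued small parsimony (shared by E.C. and MDA labelings)
# ---------------------------------------------------------------------------


def fitch_sets(
    tree: AnnotatedTree, leaf_states: Mapping[str, frozenset[S]]
) -> dict[str, frozenset[S]]:
    """Bottom-up pass: intersection of the children's sets if non-empty,
    else their union.  Leaf sets come straight from ``leaf_states``."""
    sets: dict[str, frozenset[S]] = {}
    for node in tree.postorder():
        nid = tree.node_id(node)
        if node.is_leaf():
            states = leaf_states[nid]
            if not states:
                raise ValueError(f"leaf {nid} has an empty state set")
            sets[nid] = frozenset(states)
        else:
            child_sets = [sets[tree.node_id(c)] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            sets[nid] = inter if inter else frozenset.union(*child_sets)
    return sets


def resolve_states(
    tree: AnnotatedTree,
    sets: Mapping[str, frozenset[S]],
    key: Callable[[S], object],
) -> dict[str, S]:
    """Top-down resolution: keep the parent's resolved state when it is in
    the node's set, else take the set's smallest member under ``key``."""
    resolved: dict[str, S] = {}
    for node in tree.preorder():
        nid = tree.node_id(node)
        options = sets[nid]
        if node.parent_node is None:
            resolved[nid] = min(options, key=key)
        else:
            parent_state = resolved[tree.node_id(node.parent_node)]
            resolved[nid] = (
                parent_state if parent_state in options else min(options, key=key)
            )
    return resolved


# ---------------------------------------------------------------------------
# E.C.-specific operations
# ---------------------------------------------------------------------------


def infer_ancestral_functions(tree: AnnotatedTree) -> dict[str, frozenset[ECNumber]]:
    """Set-valued parsimony state sets for every node (leaves included)."""
    leaf_states = tree.leaf_ec_sets()
    for lid, states in leaf_states.items():
        if not states:
            raise ValueError(f"leaf {lid} has an empty E.C. set")
    return fitch_sets(tree, leaf_states)


def resolve_ancestral_functions(tree: AnnotatedTree) -> dict[str, ECNumber]:
    """Deterministically resolved single E.C. state per node."""
    sets = infer_ancestral_functions(tree)
    return resolve_states(tree, sets, key=lambda ec: ec.sort_key())


def count_tree_exchanges(tree: AnnotatedTree) -> list[ExchangeEvent]:
    """One event per edge whose resolved parent and child states differ.

    Pairs that differ only past a wildcard (compare level 0) cannot be
    placed at a definite level and produce no event.
    """
    resolved = resolve_ancestral_functions(tree)
    events: list[ExchangeEvent] = []
    for node in tree.preorder():
        if node.parent_node is None:
            continue
        pid = tree.node_id(node.parent_node)
        cid = tree.node_id(node)
        a, b = resolved[pid], resolved[cid]
        if a != b:
            level = compare_level(a, b)
            if level >= 1:
                events.append(ExchangeEvent((pid, cid), a, b, level))
    return events


def _monomorphic_function(
    tree: AnnotatedTree, node
) -> Optional[ECNumber]:
    """The single fully specified E.C. carried by *every* leaf under
    ``node`` (each leaf annotated with exactly that function), or None."""
    function: Optional[ECNumber] = None
    for leaf in node.leaf_iter():
        rec = tree.records.get(tree.node_id(leaf))
        if rec is None or len(rec.ec_set) != 1:
            return None
        (ec,) = rec.ec_set
        if not ec.is_fully_specified:
            return None
        if function is None:
            function = ec
        elif ec != function:
            return None
    return function


def find_clean_bifurcations(tree: AnnotatedTree) -> list[CleanBifurcation]:
    """Internal binary nodes with exactly one function on each side."""
    out: list[CleanBifurcation] = []
    for node in tree.preorder():
        children = node.child_nodes()
        if node.is_leaf() or len(children) != 2:
            continue
        left, right = children
        f_left = _monomorphic_function(tree, left)
        f_right = _monomorphic_function(tree, right)
        if f_left is None or f_right is None or f_left == f_right:
            continue
        out.append(
            CleanBifurcation(
                node_id=tree.node_id(node),
                left_function=f_left,
                right_function=f_right,
                left_leaves=tuple(tree.subtree_leaf_ids(left)),
                right_leaves=tuple(tree.subtree_leaf_ids(right)),
            )
        )
    return out


def resolve_ancestral_mdas(tree: AnnotatedTree) -> dict[str, str]:
    """Parsimony-resolved MDA string per node (same machinery as E.C.s)."""
    leaf_states = {
        lid: frozenset({tree.leaf_record(lid).mda_string}) for lid in tree.leaf_ids()
    }
    sets = fitch_sets(tree, leaf_states)
    return resolve_states(tree, sets, key=lambda s: s)


def classify_exchange_context(
    event: ExchangeEvent,
    tree: AnnotatedTree,
    alignment: Optional[AlignmentBlock] = None,
    mda_states: Optional[Mapping[str, str]] = None,
    clean_bifurcations: Optional[list[CleanBifurcation]] = None,
    min_gap: int = 3,
) -> ExchangeEvent:
    """Attach context flags to an exchange event.

    ``mda_change`` is true iff the parsimony-reconstructed architecture
    differs across the event's edge, so only architecture changes local
    to the exchange are flagged, not independent changes elsewhere in
    the tree.  ``loop_indel`` is assessed only when the event sits under
    a clean bifurcation and an alignment is supplied; otherwise it is
    left unset.
    """
    if mda_states is None:
        mda_states = resolve_ancestral_mdas(tree)
    pid, cid = event.edge
    mda_change = mda_states[pid] != mda_states[cid]

    loop_indel: Optional[bool] = None
    if alignment is not None:
        if clean_bifurcations is None:
            clean_bifurcations = find_clean_bifurcations(tree)
        by_node = {b.node_id: b for b in clean_bifurcations}
        bif = by_node.get(pid)
        if bif is not None:
            from .signals import detect_catalytic_gap

            loop_indel = detect_catalytic_gap(
                alignment, bif, bif.side_map(), min_gap=min_gap
            )
    return replace(event, mda_change=mda_change, loop_indel=loop_indel)


def classify_all_events(
    tree: AnnotatedTree,
    events: Optional[list[ExchangeEvent]] = None,
    alignment: Optional[AlignmentBlock] = None,
    min_gap: int = 3,
) -> list[ExchangeEvent]:
    """Count (if needed) and context-classify all exchanges on one tree."""
    if events is None:
        events = count_tree_exchanges(tree)
    if not events:
        return []
    mda_states = resolve_ancestral_mdas(tree)
    bifs = find_clean_bifurcations(tree) if alignment is not None else None
    return [
        classify_exchange_context(
            ev, tree, alignment=alignment, mda_states=mda_states,
            clean_bifurcations=bifs, min_gap=min_gap,
        )
        for ev in events
    ]


def reconcile_counts(
    allbyall: int, repeat_surplus: int, cross_ssg_missed: int
) -> int:
    """Total tree-based observations implied by the all-by-all count.

    Tree counting sees repeated exchanges more than once (surplus) but
    misses exchanges across SSG boundaries; the three quantities relate
    by ``observations = allbyall + repeat_surplus - cross_ssg_missed``.
    """
    if min(allbyall, repeat_surplus, cross_ssg_missed) < 0:
        raise ValueError("reconciliation inputs must be non-negative")
    total = allbyall + repeat_surplus - cross_ssg_missed
    if total < 0:
        raise ValueError(
            f"inconsistent reconciliation inputs: {allbyall}+{repeat_surplus}"
            f"-{cross_ssg_missed} < 0"
        )
    return total
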