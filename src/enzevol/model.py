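"""In-memory dataset model: domain records, annotated trees, alignments.

A *superfamily* is a set of protein domains sharing a detectable common
ancestor.  Within a superfamily, *structurally similar groups* (SSGs)
collect domains that superimpose pairwise below an RMSD threshold, and
*multi-domain architecture* (MDA) groups collect proteins whose ordered
domain content is identical.  Each SSG carries its own gene tree and
alignment; exchange inference runs per SSG tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import dendropy

from .ec import ECNumber

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass(frozen=True)
class DomainRecord:
    """One domain sequence with its annotations.

    ``mda`` is the ordered tuple of domain identifiers along the parent
    protein (it must contain the superfamily's focus domain); ``ec_set``
    may hold several E.C. numbers (multifunctional annotations are kept
    as sets, never duplicated into extra leaves); ``lineage`` is the
    ordered taxonomic path.
    """

    sequence_id: str
    superfamily_id: str
    ssg_id: Optional[str]
    mda: tuple[str, ...]
    ec_set: frozenset[ECNumber]
    lineage: tuple[str, ...]
    has_structure: bool = False

    def __post_init__(self) -> None:
        if not self.mda:
            raise ValueError(f"record {self.sequence_id}: empty MDA")

    @property
    def mda_string(self) -> str:
        return "-".join(self.mda)


class AnnotatedTree:
    """A rooted phylogeny whose leaves map to :class:`DomainRecord`s.

    Thin wrapper around a :class:`dendropy.Tree`.  Leaf identifiers are
    taxon labels (sequence ids); internal nodes get stable preorder ids
    ``N0, N1, ...`` so that exchange events can name edges
    deterministically.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        records: Optional[Mapping[str, DomainRecord]] = None,
    ) -> None:
        if tree.seed_node is None or len(tree.leaf_nodes()) < 1:
            raise ValueError("tree has no leaves")
        self.tree = tree
        self._label_internal_nodes()
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and len(node.child_nodes()) < 2:
                raise ValueError(
                    f"internal node {self.node_id(node)} has fewer than 2 children"
                )
        self.records: dict[str, DomainRecord] = {}
        if records is not None:
            self.attach_records(records)

    def _label_internal_nodes(self) -> None:
        i = 0
        for node in self.tree.preorder_node_iter():
            if not node.is_leaf():
                node.label = f"N{i}"
                i += 1

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(
        cls, newick: str, records: Optional[Mapping[str, DomainRecord]] = None
    ) -> "AnnotatedTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls(tree, records)

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_internal_node_labels=True,
            unquoted_underscores=True,
        ).strip()

    # -- node bookkeeping --------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def node_id(self, node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label if node.taxon is not None else node.label
        return node.label

    def leaf_ids(self) -> list[str]:
        return [self.node_id(leaf) for leaf in self.tree.leaf_node_iter()]

    def postorder(self) -> Iterator[dendropy.Node]:
        return self.tree.postorder_node_iter()

    def preorder(self) -> Iterator[dendropy.Node]:
        return self.tree.preorder_node_iter()

    def subtree_leaf_ids(self, node: dendropy.Node) -> list[str]:
        return [self.node_id(leaf) for leaf in node.leaf_iter()]

    # -- record resolution -------------------------------------------------

    def attach_records(self, records: Mapping[str, DomainRecord]) -> list[str]:
        """Resolve leaves against a record map; returns unresolved leaf ids."""
        self.records = dict(records)
        unresolved = [lid for lid in self.leaf_ids() if lid not in self.records]
        if unresolved:
            logger.warning("unresolved tree leaves: %s", ", ".join(unresolved))
        return unresolved

    def leaf_record(self, leaf_id: str) -> DomainRecord:
        return self.records[leaf_id]

    def leaf_ec_sets(self) -> dict[str, frozenset[ECNumber]]:
        return {lid: self.records[lid].ec_set for lid in self.leaf_ids()}


@dataclass
class AlignmentBlock:
    """A gapped alignment with a set of catalytic column indices.

    Columns are 0-based.  Catalytic columns mark positions of known
    catalytic-site residues, the anchors for the loop-indel analysis.
    """

    sequences: dict[str, str]
    catalytic_columns: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        n = self.length
        bad = [c for c in self.catalytic_columns if not 0 <= c < n]
        if bad:
            raise ValueError(f"catalytic columns out of range [0, {n}): {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def column(self, i: int) -> list[str]:
        return [s[i] for s in self.sequences.values()]


@dataclass
class SuperfamilyDataset:
    """Everything known about one superfamily: records, per-SSG trees and
    alignments, and (optionally) a structural distance matrix."""

    superfamily_id: str
    records: list[DomainRecord]
    trees: dict[str, AnnotatedTree] = field(default_factory=dict)
    alignments: dict[str, "AlignmentBlock"] = field(default_factory=dict)
    distances: Optional[object] = None  # grouping.StructuralDistanceMatrix

    def __post_init__(self) -> None:
        ids = [r.sequence_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate sequence ids in {self.superfamily_id}")
        for ssg_id, tree in self.trees.items():
            for lid in tree.leaf_ids():
                rec = self.record_map.get(lid)
                if rec is None:
                    raise ValueError(f"tree leaf {lid} has no record")
                if rec.ssg_id != ssg_id:
                    raise ValueError(
                        f"leaf {lid} in tree {ssg_id} but record says {rec.ssg_id}"
                    )

    @property
    def record_map(self) -> dict[str, DomainRecord]:
        return {r.sequence_id: r for r in self.records}

    def unique_ecs(self, fully_specified_only: bool = True) -> set[ECNumber]:
        out: set[ECNumber] = set()
        for r in self.records:
            for ec in r.ec_set:
                if not fully_specified_only or ec.is_fully_specified:
                    out.add(ec)
        return out

    def ec_pool(self) -> list[ECNumber]:
        """Multiset of all E.C. annotations over records (null-model pool)."""
        pool: list[ECNumber] = []
        for r in self.records:
            pool.extend(sorted(r.ec_set))
        return pool
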