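"""Synthetic superfamily cohorts with known evolutionary history.

The generator realizes the statistical structure the analysis assumes:
per SSG, a Yule-process rooted binary tree whose root carries a random
fully specified E.C. number; along each branch, an independent change
at E.C. level k (probability ``p_change[k-1]``) resamples level k and
everything below it — the classification is hierarchical, so a class
change cannot meaningfully preserve the serial.  Given a change, the
multi-domain architecture mutates (a partner domain appended or removed
adjacent to the focus domain) with probability ``p_mda_coupling``, and
with probability ``p_loop_coupling`` a gap run of length >= 3 is laid
over a catalytic column throughout the derived clade.  Alignments
otherwise evolve by independent point substitutions from a root
sequence.  Every realized change is written to a ground-truth log, the
oracle against which parsimony inference is checked.

All draws come from a seeded generator; identical config and seed give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ec import ECNumber
from .grouping import StructuralDistanceMatrix
from .model import AA_ALPHABET, GAP, AlignmentBlock, AnnotatedTree, DomainRecord, SuperfamilyDataset

#: the focus (superfamily) domain identifier used in simulated MDAs
FOCUS_DOMAIN = "C"

#: simulated E.C. alphabet bounds: subclass/sub-subclass 1-9, serial 1-99
_L2_MAX, _L3_MAX, _L4_MAX = 9, 9, 99

_KINGDOMS = ("Bacteria", "Eukaryota", "Archaea")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    ``p_change`` holds the four per-branch change probabilities for E.C.
    levels 1-4; coupling probabilities are conditional on a change
    having occurred on the branch.
    """

    n_superfamilies: int = 200
    leaves_per_tree: tuple[int, int] = (8, 24)
    p_change: tuple[float, float, float, float] = (0.01, 0.01, 0.01, 0.10)
    p_mda_coupling: float = 0.3
    p_loop_coupling: float = 0.05
    n_ssg: tuple[int, int] = (1, 3)
    alignment_length: int = 60
    n_catalytic: int = 3
    p_substitution: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (*self.p_change, self.p_mda_coupling, self.p_loop_coupling,
                 self.p_substitution)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (self.leaves_per_tree, self.n_ssg):
            if lo > hi or lo < 1:
                raise ValueError("empty or degenerate range")
        if self.leaves_per_tree[0] < 2:
            raise ValueError("trees need at least 2 leaves")
        if self.n_superfamilies < 0:
            raise ValueError("negative cohort size")
        if not 0 < self.n_catalytic <= self.alignment_length:
            raise ValueError("catalytic columns must fit in the alignment")

    def level_fractions(self) -> dict[int, float]:
        """Analytic per-level share of events implied by ``p_change``:
        the smallest triggered level wins on a branch, so level k's rate
        is p_k * prod_{j<k} (1 - p_j)."""
        rates = {}
        survive = 1.0
        for k, p in enumerate(self.p_change, start=1):
            rates[k] = survive * p
            survive *= 1.0 - p
        total = sum(rates.values())
        if total == 0:
            return {k: 0.0 for k in rates}
        return {k: r / total for k, r in rates.items()}


@dataclass(frozen=True)
class GroundTruthEvent:
    """One realized E.C. change on a simulated branch."""

    superfamily_id: str
    ssg_id: str
    branch: tuple[str, str]  # (parent node id, child node id)
    level: int
    from_ec: ECNumber
    to_ec: ECNumber
    mda_coupled: bool
    loop_coupled: bool


@dataclass
class GroundTruthLog:
    """All true events of a dataset (or cohort), with level summaries."""

    events: list[GroundTruthEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def level_share(self, level: int) -> Optional[float]:
        if not self.events:
            return None
        return sum(1 for e in self.events if e.level == level) / len(self.events)

    def coupled_fraction(self, kind: str) -> Optional[float]:
        if not self.events:
            return None
        attr = {"mda": "mda_coupled", "loop": "loop_coupled"}[kind]
        return sum(1 for e in self.events if getattr(e, attr)) / len(self.events)


# ---------------------------------------------------------------------------
# tree and state machinery
# ---------------------------------------------------------------------------


def _yule_newick(n_leaves: int, rng: np.random.Generator, prefix: str) -> str:
    """Yule topology by uniform random leaf splitting; leaves named
    ``{prefix}t0 .. {prefix}t{n-1}`` in creation order."""
    # each node is either a leaf index or a [left, right] pair
    tree: list = [0, 1]
    leaves: list[list] = [tree]  # parent containers holding leaf ints
    counter = 2
    # track positions of leaf ints as (container, slot)
    slots: list[tuple[list, int]] = [(tree, 0), (tree, 1)]
    while counter < n_leaves:
        k = int(rng.integers(0, len(slots)))
        container, slot = slots.pop(k)
        old = container[slot]
        new_pair = [old, counter]
        container[slot] = new_pair
        slots.append((new_pair, 0))
        slots.append((new_pair, 1))
        counter += 1

    def render(node) -> str:
        if isinstance(node, int):
            return f"{prefix}t{node}"
        return f"({render(node[0])},{render(node[1])})"

    return render(tree) + ";"


def _random_ec(rng: np.random.Generator) -> ECNumber:
    return ECNumber(
        (
            int(rng.integers(1, 7)),
            int(rng.integers(1, _L2_MAX + 1)),
            int(rng.integers(1, _L3_MAX + 1)),
            int(rng.integers(1, _L4_MAX + 1)),
        )
    )


def _resample_below(ec: ECNumber, level: int, rng: np.random.Generator) -> ECNumber:
    """Resample level ``level`` (forced to change) and everything below."""
    maxima = {1: 6, 2: _L2_MAX, 3: _L3_MAX, 4: _L4_MAX}
    levels = list(ec.levels)
    old = levels[level - 1]
    hi = maxima[level]
    new = old
    while new == old:
        new = int(rng.integers(1, hi + 1))
    levels[level - 1] = new
    for k in range(level + 1, 5):
        levels[k - 1] = int(rng.integers(1, maxima[k] + 1))
    return ECNumber(tuple(levels))


def _mutate_mda(
    mda: tuple[str, ...], rng: np.random.Generator, domain_counter: list[int]
) -> tuple[str, ...]:
    """Append or remove a partner domain adjacent to the focus domain."""
    mda = list(mda)
    focus_at = mda.index(FOCUS_DOMAIN)
    removable = [
        i for i in (focus_at - 1, focus_at + 1)
        if 0 <= i < len(mda) and mda[i] != FOCUS_DOMAIN
    ]
    if removable and rng.random() < 0.5:
        mda.pop(removable[int(rng.integers(0, len(removable)))])
    else:
        domain_counter[0] += 1
        new_domain = f"D{domain_counter[0]}"
        at = focus_at if rng.random() < 0.5 else focus_at + 1
        mda.insert(at, new_domain)
    return tuple(mda)


def _mutate_sequence(
    seq: list[str], rng: np.random.Generator, p_sub: float
) -> list[str]:
    out = list(seq)
    if p_sub > 0:
        for i, ch in enumerate(out):
            if ch != GAP and rng.random() < p_sub:
                new = ch
                while new == ch:
                    new = AA_ALPHABET[int(rng.integers(0, len(AA_ALPHABET)))]
                out[i] = new
    return out


def _apply_loop(
    seq: list[str], catalytic: Sequence[int], rng: np.random.Generator
) -> Optional[list[str]]:
    """Gap run of length 3 laid over a not-yet-gapped catalytic column;
    None when every catalytic column is already gapped."""
    open_cols = [c for c in catalytic if seq[c] != GAP]
    if not open_cols:
        return None
    c = open_cols[int(rng.integers(0, len(open_cols)))]
    start = min(max(c - 1, 0), len(seq) - 3)
    out = list(seq)
    for i in range(start, start + 3):
        out[i] = GAP
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_superfamily(
    config: SimulationConfig, index: int
) -> tuple[SuperfamilyDataset, GroundTruthLog]:
    """Generate one superfamily dataset and its ground-truth event log."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, index)))
    sf_id = f"SF{index:03d}"
    n_ssgs = int(rng.integers(config.n_ssg[0], config.n_ssg[1] + 1))
    domain_counter = [0]
    records: list[DomainRecord] = []
    trees: dict[str, AnnotatedTree] = {}
    alignments: dict[str, AlignmentBlock] = {}
    log = GroundTruthLog()
    structure_ids_by_ssg: dict[str, list[str]] = {}

    L = config.alignment_length
    catalytic = sorted(
        int(c) for c in rng.choice(np.arange(1, L - 1), config.n_catalytic, replace=False)
    )

    for s in range(n_ssgs):
        ssg_id = f"SSG{s + 1}"
        n_leaves = int(
            rng.integers(config.leaves_per_tree[0], config.leaves_per_tree[1] + 1)
        )
        prefix = f"{sf_id}_{ssg_id}_"
        tree = AnnotatedTree.from_newick(_yule_newick(n_leaves, rng, prefix))

        root_state = {
            "ec": _random_ec(rng),
            "mda": (FOCUS_DOMAIN,),
            "seq": [AA_ALPHABET[int(rng.integers(0, len(AA_ALPHABET)))] for _ in range(L)],
        }
        states: dict[str, dict] = {}
        for node in tree.preorder():
            nid = tree.node_id(node)
            if node.parent_node is None:
                states[nid] = root_state
                continue
            parent = states[tree.node_id(node.parent_node)]
            ec = parent["ec"]
            mda = parent["mda"]
            seq = _mutate_sequence(parent["seq"], rng, config.p_substitution)
            triggered = [
                k for k in range(1, 5) if rng.random() < config.p_change[k - 1]
            ]
            if triggered:
                level = min(triggered)
                new_ec = _resample_below(ec, level, rng)
                mda_coupled = rng.random() < config.p_mda_coupling
                if mda_coupled:
                    mda = _mutate_mda(mda, rng, domain_counter)
                loop_coupled = rng.random() < config.p_loop_coupling
                if loop_coupled:
                    gapped = _apply_loop(seq, catalytic, rng)
                    if gapped is None:
                        loop_coupled = False
                    else:
                        seq = gapped
                log.events.append(
                    GroundTruthEvent(
                        superfamily_id=sf_id,
                        ssg_id=ssg_id,
                        branch=(tree.node_id(node.parent_node), nid),
                        level=level,
                        from_ec=ec,
                        to_ec=new_ec,
                        mda_coupled=mda_coupled,
                        loop_coupled=loop_coupled,
                    )
                )
                ec = new_ec
            states[nid] = {"ec": ec, "mda": mda, "seq": seq}

        structure_ids: list[str] = []
        leaf_ids = tree.leaf_ids()
        for i, lid in enumerate(leaf_ids):
            st = states[lid]
            has_structure = i == 0 or rng.random() < 0.15
            if has_structure:
                structure_ids.append(lid)
            records.append(
                DomainRecord(
                    sequence_id=lid,
                    superfamily_id=sf_id,
                    ssg_id=ssg_id,
                    mda=st["mda"],
                    ec_set=frozenset({st["ec"]}),
                    lineage=(
                        _KINGDOMS[int(rng.integers(0, len(_KINGDOMS)))],
                        f"{sf_id}_genus{int(rng.integers(0, max(2, n_leaves // 2)))}",
                    ),
                    has_structure=has_structure,
                )
            )
        structure_ids_by_ssg[ssg_id] = structure_ids
        alignments[ssg_id] = AlignmentBlock(
            {lid: "".join(states[lid]["seq"]) for lid in leaf_ids},
            frozenset(catalytic),
        )
        trees[ssg_id] = tree

    # structural distances: tight within SSGs, far between them
    all_structs = [
        (ssg, sid) for ssg in sorted(structure_ids_by_ssg)
        for sid in structure_ids_by_ssg[ssg]
    ]
    ids = [sid for _, sid in all_structs]
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = all_structs[i][0] == all_structs[j][0]
            d = rng.uniform(1.0, 7.0) if same else rng.uniform(10.0, 16.0)
            dm[i, j] = dm[j, i] = d
    distances = StructuralDistanceMatrix(ids, dm) if n else None

    record_map = {r.sequence_id: r for r in records}
    for tree in trees.values():
        tree.attach_records(record_map)
    dataset = SuperfamilyDataset(
        superfamily_id=sf_id,
        records=records,
        trees=trees,
        alignments=alignments,
        distances=distances,
    )
    return dataset, log


@dataclass
class CohortResult:
    datasets: list[SuperfamilyDataset]
    log: GroundTruthLog
    expected_summary: dict


def generate_cohort(config: SimulationConfig) -> CohortResult:
    """Independent superfamilies plus the merged log and the analytic
    per-level change fractions implied by ``p_change``."""
    datasets: list[SuperfamilyDataset] = []
    merged = GroundTruthLog()
    for i in range(config.n_superfamilies):
        ds, log = generate_superfamily(config, i)
        datasets.append(ds)
        merged.events.extend(log.events)
    summary = {
        "level_fractions": config.level_fractions(),
        "p_mda_coupling": config.p_mda_coupling,
        "p_loop_coupling": config.p_loop_coupling,
        "n_events": len(merged),
    }
    return CohortResult(datasets, merged, summary)
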