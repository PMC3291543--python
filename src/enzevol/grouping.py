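"""Grouping stages upstream of tree analysis.

Structurally similar groups (SSGs) are formed by complete-linkage
agglomeration of pairwise structural superposition distances below an
RMSD threshold (default 9 Å), so that *every* intra-group pair satisfies
the superposability criterion — single linkage could chain far beyond
it.  Sequence relatives are assigned to SSGs by a pluggable best-hit
similarity scorer.  MDA groups key on the exact ordered architecture
string.  Large families are reduced by keeping one representative per
(taxonomic lineage, functional annotation) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import DomainRecord

#: sequence-identity threshold for redundancy removal before SSG formation
IDENTITY_THRESHOLD = 0.35
#: RMSD threshold (Å) below which structures belong in one SSG
RMSD_THRESHOLD = 9.0
#: family size above which the lineage/function redundancy filter kicks in
MAX_FAMILY_SIZE = 300


@dataclass
class StructuralDistanceMatrix:
    """Symmetric matrix of pairwise superposition distances (RMSD, Å)."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError(f"matrix shape {m.shape} does not match {len(self.ids)} ids")
        if (m < 0).any():
            raise ValueError("negative structural distances")
        if not np.allclose(np.diag(m), 0.0, atol=1e-9):
            raise ValueError("non-zero diagonal in distance matrix")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("asymmetric distance matrix")
        self.matrix = m


@dataclass
class SSGPartition:
    """A partition of structure ids into structurally similar groups."""

    by_id: dict[str, str]  # structure id -> ssg id
    members: dict[str, list[str]]  # ssg id -> member ids

    def __post_init__(self) -> None:
        flat = [m for ms in self.members.values() for m in ms]
        if sorted(flat) != sorted(self.by_id) or any(
            self.by_id[m] != g for g, ms in self.members.items() for m in ms
        ):
            raise ValueError("members and by_id are not a consistent partition")

    @property
    def n_groups(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# default pluggable scorers (Biopython global/local alignment)
# ---------------------------------------------------------------------------


def global_identity(a: str, b: str) -> float:
    """Fraction of identical positions over the global alignment length."""
    from Bio import Align

    if not a or not b:
        return 0.0
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=0, open_gap_score=-0.5,
        extend_gap_score=-0.1,
    )
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return matches / len(sa)


def local_similarity(a: str, b: str) -> float:
    """BLOSUM62 local-alignment score (default best-hit assignment scorer)."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner(
        mode="local", open_gap_score=-11, extend_gap_score=-1,
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
    )
    return float(aligner.score(a, b))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def deduplicate_by_identity(
    sequences: Mapping[str, str],
    threshold: float = IDENTITY_THRESHOLD,
    identity: Optional[Callable[[str, str], float]] = None,
) -> dict[str, list[str]]:
    """Greedy leader clustering at a pairwise-identity threshold.

    Sequences are scanned in input order; each joins the first existing
    representative with identity > ``threshold``, otherwise it founds a
    new cluster.  Returns ``representative id -> member ids`` with the
    first-seen member of each cluster as representative.
    """
    if identity is None:
        identity = global_identity
    clusters: dict[str, list[str]] = {}
    for sid, seq in sequences.items():
        for rep in clusters:
            if identity(sequences[rep], seq) > threshold:
                clusters[rep].append(sid)
                break
        else:
            clusters[sid] = [sid]
    return clusters


def cluster_ssgs(
    distances: StructuralDistanceMatrix, threshold: float = RMSD_THRESHOLD
) -> SSGPartition:
    """Complete-linkage agglomeration of structures at RMSD < ``threshold``.

    Every intra-group pair is guaranteed to sit strictly below the
    threshold.  Group ids are ``SSG1, SSG2, ...`` in order of first
    member appearance, so labels are deterministic given input order.
    """
    ids = distances.ids
    if len(ids) == 1:
        return SSGPartition({ids[0]: "SSG1"}, {"SSG1": [ids[0]]})
    condensed = squareform(distances.matrix, checks=False)
    Z = linkage(condensed, method="complete")
    # strict "< threshold": cut just below it
    labels = fcluster(Z, t=np.nextafter(threshold, -np.inf), criterion="distance")
    by_id: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    relabel: dict[int, str] = {}
    for sid, lab in zip(ids, labels):
        if lab not in relabel:
            relabel[lab] = f"SSG{len(relabel) + 1}"
        g = relabel[lab]
        by_id[sid] = g
        members.setdefault(g, []).append(sid)
    return SSGPartition(by_id, members)


def assign_sequence_to_ssg(
    sequence: str,
    ssg_representatives: Mapping[str, Sequence[str]],
    scorer: Optional[Callable[[str, str], float]] = None,
) -> str:
    """Assign a sequence to the SSG of its best-scoring representative.

    ``ssg_representatives`` maps ssg id -> representative sequences; the
    group score is the maximum over its representatives.  Ties break to
    the lexicographically smallest ssg id.
    """
    if not ssg_representatives:
        raise ValueError("no SSG representatives to assign against")
    if scorer is None:
        scorer = local_similarity
    best_id: Optional[str] = None
    best_score = -np.inf
    for ssg_id in sorted(ssg_representatives):
        score = max(scorer(rep, sequence) for rep in ssg_representatives[ssg_id])
        if score > best_score:
            best_id, best_score = ssg_id, score
    assert best_id is not None
    return best_id


def group_mdas(records: Iterable[DomainRecord]) -> dict[str, list[DomainRecord]]:
    """Group records by exact ordered multi-domain architecture string."""
    groups: dict[str, list[DomainRecord]] = {}
    for rec in records:
        groups.setdefault(rec.mda_string, []).append(rec)
    return groups


def filter_redundant(
    records: Sequence[DomainRecord], max_n: int = MAX_FAMILY_SIZE
) -> list[DomainRecord]:
    """Reduce oversized families by taxonomic lineage and uniqueness of function.

    If the family holds at most ``max_n`` records it is returned
    unchanged.  Otherwise one representative is kept per (full lineage
    string, E.C. set) pair, preferring records with a known structure and
    then earliest input order.  Idempotent.
    """
    if len(records) <= max_n:
        return list(records)
    best: dict[tuple, tuple[int, int, DomainRecord]] = {}
    for i, rec in enumerate(records):
        key = (";".join(rec.lineage), frozenset(rec.ec_set))
        rank = (0 if rec.has_structure else 1, i)
        if key not in best or rank < best[key][:2]:
            best[key] = (*rank, rec)
    kept = sorted(best.values(), key=lambda t: t[1])
    return [rec for _, _, rec in kept]
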