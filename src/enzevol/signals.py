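"""Structural signals: loop indels at catalytic sites, column conservation.

Functional shifts found at clean bifurcations (a single function on
each side of the divide) are tested for association with loop
gain/loss: a catalytic-site column where one whole side of the
bifurcation is gapped, inside a maximal run of at least three
consecutive gap columns, while the other side is not.  Requiring the
contrast between the sides ties the indel to this bifurcation rather
than to an ancestral event shared by both sides.

Column diversity is summarized by a normalized-entropy conservation
score over the 20 amino acids plus gap (1 for invariant columns, 0 for
a uniform column).  It is a descriptive stand-in for published
conservation scores and is used only for diversity summaries.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .ec import compare_level
from .model import GAP, AlignmentBlock
from .tree_exchange import AnnotatedTree, CleanBifurcation

#: minimum length of a gap run for it to count as a loop indel
MIN_GAP_RUN = 3
#: alphabet size for the entropy normalization (20 amino acids + gap)
_N_SYMBOLS = 21


def _gap_run_length(seq: str, col: int) -> int:
    """Length of the maximal run of gap columns containing ``col`` (0 if
    the position is not a gap)."""
    if seq[col] != GAP:
        return 0
    lo = col
    while lo > 0 and seq[lo - 1] == GAP:
        lo -= 1
    hi = col
    n = len(seq)
    while hi < n - 1 and seq[hi + 1] == GAP:
        hi += 1
    return hi - lo + 1


def detect_catalytic_gap(
    alignment: AlignmentBlock,
    bifurcation: CleanBifurcation,
    members: dict[str, str],
    min_gap: int = MIN_GAP_RUN,
) -> bool:
    """True iff some catalytic column is gapped across one whole side.

    A side qualifies at column ``c`` when every one of its members has a
    gap at ``c`` lying in a maximal run of at least ``min_gap``
    consecutive gap columns, and the opposite side is not itself
    entirely gapped at ``c`` (a gap shared by both sides is an ancestral
    indel, not one associated with this bifurcation).
    """
    if not alignment.catalytic_columns:
        raise ValueError("alignment has no catalytic columns")
    sides: dict[str, list[str]] = {}
    for leaf in (*bifurcation.left_leaves, *bifurcation.right_leaves):
        if leaf not in alignment.sequences:
            raise ValueError(f"bifurcation leaf {leaf} missing from alignment")
        sides.setdefault(members[leaf], []).append(leaf)
    side_names = sorted(sides)
    for c in sorted(alignment.catalytic_columns):
        for side in side_names:
            this = all(
                _gap_run_length(alignment.sequences[leaf], c) >= min_gap
                for leaf in sides[side]
            )
            if not this:
                continue
            others = [s for s in side_names if s != side]
            opposite_all_gapped = all(
                alignment.sequences[leaf][c] == GAP
                for s in others
                for leaf in sides[s]
            )
            if not opposite_all_gapped:
                return True
    return False


@dataclass(frozen=True)
class BifurcationAssessment:
    """One clean bifurcation's change level and loop-indel flag."""

    node_id: str
    change_level: int
    loop_gap: bool


def assess_clean_bifurcations(
    tree: AnnotatedTree,
    alignment: AlignmentBlock,
    min_gap: int = MIN_GAP_RUN,
) -> list[BifurcationAssessment]:
    """Find clean bifurcations on a tree and test each for a catalytic
    gap signature."""
    from .tree_exchange import find_clean_bifurcations

    out: list[BifurcationAssessment] = []
    for bif in find_clean_bifurcations(tree):
        level = compare_level(bif.left_function, bif.right_function)
        if level < 1:
            continue
        flag = detect_catalytic_gap(alignment, bif, bif.side_map(), min_gap=min_gap)
        out.append(BifurcationAssessment(bif.node_id, level, flag))
    return out


@dataclass
class LoopAssociation:
    """Loop-associated share of clean-bifurcation functional shifts."""

    fraction: Optional[float]
    n_assessed: int
    n_flagged: int
    flagged_between_class: int  # change at E.C. level 1
    flagged_within_class: int  # change at levels 2-4


def loop_associated_fraction(
    assessments: Iterable[BifurcationAssessment],
) -> LoopAssociation:
    """Fraction of single-function-per-side functional shifts whose
    catalytic site shows a loop indel, split within/between class."""
    assessments = list(assessments)
    n = len(assessments)
    flagged = [a for a in assessments if a.loop_gap]
    between = sum(1 for a in flagged if a.change_level == 1)
    within = len(flagged) - between
    fraction = len(flagged) / n if n else None
    return LoopAssociation(fraction, n, len(flagged), between, within)


def conservation_score(column: Iterable[str]) -> float:
    """Normalized-entropy conservation of one alignment column.

    ``1 - H / log(21)`` with ``H`` the Shannon entropy of the observed
    symbol distribution over the 20 amino acids plus gap; 1 for an
    invariant column, 0 for a column uniform over all 21 symbols.
    """
    counts = Counter(column)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty column")
    h = -sum((c / n) * math.log(c / n) for c in counts.values())
    return 1.0 - h / math.log(_N_SYMBOLS)


def alignment_mean_conservation(alignment: AlignmentBlock) -> float:
    """Mean column conservation over a whole alignment block."""
    if alignment.length == 0:
        raise ValueError("empty alignment")
    return sum(
        conservation_score(alignment.column(i)) for i in range(alignment.length)
    ) / alignment.length
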