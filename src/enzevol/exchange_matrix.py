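"""Exchange matrices: observed (tree and all-by-all), randomized null, χ².

The exchange matrix is a 6×6 class-level summary of functional change
within superfamilies.  Off-diagonal cells count exchanges *between*
E.C. classes (first-level changes); each diagonal cell counts exchanges
*within* a class, subdivided by the level (2, 3 or 4) at which the two
numbers first differ.  Matrices are unordered by default — cell (i, j)
and (j, i) are the same count — since an exchange between two extant
functions has no preferred direction; an ordered (parent→derived)
variant is available for tree-based counts.

The randomized null draws pairs of E.C. numbers uniformly from the
dataset's annotation pool and classifies them identically, yielding the
expected matrix against which the observed one is compared with a
Pearson χ² test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .ec import ECNumber, N_CLASSES, compare_level
from .model import SuperfamilyDataset
from .tree_exchange import ExchangeEvent

_DIAG_LEVELS = (2, 3, 4)


class ExchangeMatrix:
    """6×6 class-exchange counts with per-level diagonal subdivision.

    ``counts[i, j]`` (0-based classes) holds between-class exchanges for
    i ≠ j; ``counts[i, i]`` holds the within-class total for class i+1,
    which always equals the sum of ``diag_levels[i]`` (levels 2, 3, 4).
    ``mode`` is one of ``tree``, ``allbyall``, ``expected``.
    """

    MODES = ("tree", "allbyall", "expected")

    def __init__(self, mode: str, ordered: bool = False, n_classes: int = N_CLASSES):
        if mode not in self.MODES:
            raise ValueError(f"unknown matrix mode {mode!r}")
        self.mode = mode
        self.ordered = ordered
        self.n_classes = n_classes
        self.counts = np.zeros((n_classes, n_classes), dtype=float)
        self.diag_levels = np.zeros((n_classes, len(_DIAG_LEVELS)), dtype=float)

    # -- filling -----------------------------------------------------------

    def add_exchange(
        self, a: ECNumber, b: ECNumber, weight: float = 1.0, level: Optional[int] = None
    ) -> None:
        """Record one exchange between two E.C. numbers at its change level."""
        if level is None:
            level = compare_level(a, b)
        if level < 1:
            raise ValueError(f"{a} vs {b}: no definite change level to record")
        i, j = a.ec_class - 1, b.ec_class - 1
        if level == 1:
            if self.ordered:
                self.counts[i, j] += weight
            else:
                lo, hi = min(i, j), max(i, j)
                self.counts[lo, hi] += weight
                self.counts[hi, lo] = self.counts[lo, hi]
        else:
            assert i == j
            self.counts[i, i] += weight
            self.diag_levels[i, level - 2] += weight

    def add_event(self, event: ExchangeEvent) -> None:
        if self.ordered:
            self.add_exchange(event.from_ec, event.to_ec, level=event.change_level)
        else:
            self.add_exchange(event.from_ec, event.to_ec, level=event.change_level)

    # -- interrogation -----------------------------------------------------

    @property
    def total(self) -> float:
        """Sum over all distinct cells (off-diagonal counted once when
        unordered) plus the within-class diagonal totals."""
        if self.ordered:
            off = self.counts.sum() - np.trace(self.counts)
        else:
            off = np.triu(self.counts, k=1).sum()
        return float(off + np.trace(self.counts))

    def cells(self) -> list[tuple[str, float]]:
        """Flat cell list: 15 unordered between-class cells and, per
        class, the three within-class level cells.  Used for χ² and
        percentage tables."""
        out: list[tuple[str, float]] = []
        for i in range(self.n_classes):
            for j in range(i + 1, self.n_classes):
                v = self.counts[i, j] + (self.counts[j, i] if self.ordered else 0.0)
                out.append((f"EC{i + 1}:EC{j + 1}", float(v)))
        for i in range(self.n_classes):
            for k, lvl in enumerate(_DIAG_LEVELS):
                out.append((f"EC{i + 1}:L{lvl}", float(self.diag_levels[i, k])))
        return out

    def percentage_table(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            raise ValueError("cannot compute percentages of an empty matrix")
        return {name: 100.0 * v / total for name, v in self.cells()}

    def within_class_fraction(self) -> float:
        """Share of all exchanges that stay within one E.C. class."""
        total = self.total
        if total == 0:
            raise ValueError("empty matrix")
        return float(np.trace(self.counts)) / total

    def copy(self) -> "ExchangeMatrix":
        m = ExchangeMatrix(self.mode, self.ordered, self.n_classes)
        m.counts = self.counts.copy()
        m.diag_levels = self.diag_levels.copy()
        return m

    def allclose(self, other: "ExchangeMatrix", atol: float = 1e-9) -> bool:
        return (
            self.mode == other.mode
            and self.ordered == other.ordered
            and np.allclose(self.counts, other.counts, atol=atol)
            and np.allclose(self.diag_levels, other.diag_levels, atol=atol)
        )

    def validate(self) -> None:
        if (self.counts < 0).any() or (self.diag_levels < 0).any():
            raise ValueError("negative matrix entries")
        if not np.allclose(np.diag(self.counts), self.diag_levels.sum(axis=1)):
            raise ValueError("diagonal totals disagree with per-level sub-counts")
        if not self.ordered and not np.allclose(self.counts, self.counts.T):
            raise ValueError("unordered matrix is not symmetric")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "ordered": self.ordered,
            "counts": self.counts.tolist(),
            "diag_levels": self.diag_levels.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExchangeMatrix":
        m = cls(d["mode"], d.get("ordered", False), len(d["counts"]))
        m.counts = np.asarray(d["counts"], dtype=float)
        m.diag_levels = np.asarray(d["diag_levels"], dtype=float)
        m.validate()
        return m


# ---------------------------------------------------------------------------
# observed matrices
# ---------------------------------------------------------------------------


@dataclass
class AllByAllResult:
    matrix: ExchangeMatrix
    unique_pairs: list[tuple[ECNumber, ECNumber, int]]
    uncounted: list[tuple[ECNumber, ECNumber]]


def count_allbyall(ecs: Iterable[ECNumber]) -> AllByAllResult:
    """Classify every unordered pair of distinct E.C. numbers in a set.

    Each pair contributes once: first-level differences to the
    between-class cell, deeper differences to the shared class's
    diagonal at that level.  Distinct pairs whose comparison stops at a
    wildcard (level 0) cannot be placed and are reported as uncounted.
    """
    unique = sorted(set(ecs))
    matrix = ExchangeMatrix("allbyall")
    pairs: list[tuple[ECNumber, ECNumber, int]] = []
    uncounted: list[tuple[ECNumber, ECNumber]] = []
    for i in range(len(unique)):
        for j in range(i + 1, len(unique)):
            a, b = unique[i], unique[j]
            level = compare_level(a, b)
            if level >= 1:
                matrix.add_exchange(a, b, level=level)
                pairs.append((a, b, level))
            else:
                uncounted.append((a, b))
    return AllByAllResult(matrix, pairs, uncounted)


def build_tree_matrix(
    events: Sequence[ExchangeEvent], ordered: bool = False
) -> ExchangeMatrix:
    """Accumulate tree-inferred exchange events into a matrix; repeated
    identical exchanges on different edges each count."""
    matrix = ExchangeMatrix("tree", ordered=ordered)
    for ev in events:
        matrix.add_event(ev)
    return matrix


def aggregate(
    matrices: Sequence[ExchangeMatrix],
) -> tuple[ExchangeMatrix, Optional[dict[str, float]]]:
    """Cellwise sum of same-mode matrices plus the cohort percentage table
    (None when the sum is empty)."""
    if not matrices:
        raise ValueError("nothing to aggregate")
    modes = {m.mode for m in matrices}
    if len(modes) > 1:
        raise ValueError(f"mixed matrix modes {sorted(modes)}")
    if len({m.ordered for m in matrices}) > 1:
        raise ValueError("mixed ordered/unordered matrices")
    out = matrices[0].copy()
    for m in matrices[1:]:
        out.counts += m.counts
        out.diag_levels += m.diag_levels
    pct = out.percentage_table() if out.total > 0 else None
    return out, pct


# ---------------------------------------------------------------------------
# randomized null model
# ---------------------------------------------------------------------------


def _encode_pool(pool: Sequence[ECNumber]) -> np.ndarray:
    """Pool as a (4, n) int array; wildcard -> -1, preliminary serials get
    stable per-level codes above the numeric range."""
    arr = np.full((4, len(pool)), -1, dtype=np.int64)
    codes: list[dict[str, int]] = [dict() for _ in range(4)]
    for n, ec in enumerate(pool):
        for k, v in enumerate(ec.levels):
            if v is None:
                continue
            if isinstance(v, int):
                arr[k, n] = v
            else:
                arr[k, n] = codes[k].setdefault(v, 10**6 + len(codes[k]))
    return arr


def _classify_pairs(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    """Vectorized first-differing-level over mutually specified levels."""
    n = la.shape[1]
    level = np.zeros(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    for k in range(4):
        mutual = (la[k] >= 0) & (lb[k] >= 0)
        diff = la[k] != lb[k]
        hit = active & mutual & diff
        level[hit] = k + 1
        active &= mutual & ~diff
    return level


@dataclass
class ExpectedResult:
    """Monte Carlo expected matrix plus its closed-form expectation."""

    monte_carlo: ExchangeMatrix
    closed_form: ExchangeMatrix
    n_draws: int
    n_uncounted: int  # MC draws whose pair had no definite level
    seed: int


def expected_matrix(
    pool: Sequence[ECNumber], n_draws: int, seed: int
) -> ExpectedResult:
    """Randomized null: ``n_draws`` pairs picked uniformly from the pool
    (the two members of a pair are distinct pool entries), classified
    exactly as the all-by-all counting.

    The closed form sums, over distinct value pairs (u, v) with pool
    multiplicities, ``n_draws * n_u * n_v / C(N, 2)`` into the cell the
    pair classifies to; Monte Carlo converges to it as draws grow.
    """
    N = len(pool)
    if N < 2:
        raise ValueError("null-model pool needs at least 2 entries")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    arr = _encode_pool(pool)

    # Monte Carlo draws: unordered pairs of distinct positions
    i = rng.integers(0, N, size=n_draws)
    j = rng.integers(0, N - 1, size=n_draws)
    j = np.where(j >= i, j + 1, j)
    levels = _classify_pairs(arr[:, i], arr[:, j])
    ci, cj = arr[0, i], arr[0, j]
    mc = ExchangeMatrix("expected")
    for lvl in (1, 2, 3, 4):
        mask = levels == lvl
        if lvl == 1:
            lo = np.minimum(ci[mask], cj[mask]) - 1
            hi = np.maximum(ci[mask], cj[mask]) - 1
            np.add.at(mc.counts, (lo, hi), 1.0)
        else:
            np.add.at(mc.diag_levels, (ci[mask] - 1, lvl - 2), 1.0)
    mc.counts = np.triu(mc.counts, k=1)
    mc.counts = mc.counts + mc.counts.T
    np.fill_diagonal(mc.counts, mc.diag_levels.sum(axis=1))
    n_uncounted = int((levels == 0).sum())

    # closed form over distinct values
    values: dict[ECNumber, int] = {}
    for ec in pool:
        values[ec] = values.get(ec, 0) + 1
    uniq = sorted(values)
    denom = N * (N - 1) / 2.0
    cf = ExchangeMatrix("expected")
    for a_idx in range(len(uniq)):
        for b_idx in range(a_idx + 1, len(uniq)):
            a, b = uniq[a_idx], uniq[b_idx]
            level = compare_level(a, b)
            if level >= 1:
                w = n_draws * values[a] * values[b] / denom
                cf.add_exchange(a, b, weight=w, level=level)
    mc.validate()
    cf.validate()
    return ExpectedResult(mc, cf, n_draws, n_uncounted, seed)


# ---------------------------------------------------------------------------
# χ² comparison and summaries
# ---------------------------------------------------------------------------


@dataclass
class Chi2Result:
    statistic: float
    dof: int
    p_value: float
    excluded_cells: list[str] = field(default_factory=list)


def compare_matrices_chi2(
    observed: ExchangeMatrix, expected: ExchangeMatrix
) -> Chi2Result:
    """Pearson χ² of observed vs expected cell counts.

    The expected matrix is rescaled to the observed total.  Cells with
    zero expectation are excluded (with a warning) and the degrees of
    freedom reduced accordingly; dof = compared cells − 1.
    """
    obs_cells = observed.cells()
    exp_cells = dict(expected.cells())
    obs_total = sum(v for _, v in obs_cells)
    exp_total = sum(exp_cells.values())
    if obs_total == 0:
        raise ValueError("observed matrix is empty")
    if exp_total == 0:
        raise ValueError("expected matrix is empty")
    scale = obs_total / exp_total
    stat = 0.0
    excluded: list[str] = []
    n_cells = 0
    for name, o in obs_cells:
        e = exp_cells[name] * scale
        if e == 0:
            excluded.append(name)
            continue
        stat += (o - e) ** 2 / e
        n_cells += 1
    if excluded:
        warnings.warn(
            f"χ² comparison excluded {len(excluded)} zero-expectation cells: "
            + ", ".join(excluded)
        )
    dof = n_cells - 1
    p = float(stats.chi2.sf(stat, dof))
    return Chi2Result(float(stat), dof, p, excluded)


def tally_levels(events_or_levels: Iterable) -> dict[int, int]:
    """Per-level change counts for one superfamily (a LevelTally)."""
    tally = {1: 0, 2: 0, 3: 0, 4: 0}
    for item in events_or_levels:
        level = item.change_level if isinstance(item, ExchangeEvent) else int(item)
        tally[level] += 1
    return tally


def level_proportions(tally: dict[int, int]) -> Optional[dict[int, float]]:
    """Fraction of a superfamily's changes at each E.C. level.

    A superfamily with 2 first-level and 3 fourth-level changes
    contributes 2/5 at level 1 and 3/5 at level 4.  An empty tally has
    no defined proportions and returns None (missing, not zero).
    """
    if any(v < 0 for v in tally.values()):
        raise ValueError("negative level tally")
    total = sum(tally.values())
    if total == 0:
        return None
    return {lvl: n / total for lvl, n in tally.items() if n > 0}


def strip_within_class(
    matrix: ExchangeMatrix,
) -> tuple[ExchangeMatrix, dict[str, float]]:
    """Zero the diagonal and renormalize percentages to the between-class
    total (the interchanges-between-classes view)."""
    out = matrix.copy()
    np.fill_diagonal(out.counts, 0.0)
    out.diag_levels[:] = 0.0
    total = out.total
    if total == 0:
        raise ValueError("no between-class exchanges to renormalize")
    pct = {
        name: 100.0 * v / total
        for name, v in out.cells()
        if ":L" not in name
    }
    return out, pct


def summarize_superfamily(dataset: SuperfamilyDataset) -> dict:
    """Census of one superfamily: group counts, functional diversity and
    whether its functional changes are confined to substrate specificity
    (level 4)."""
    ssgs = {r.ssg_id for r in dataset.records if r.ssg_id is not None}
    mdas = {r.mda_string for r in dataset.records}
    uniq = sorted(dataset.unique_ecs(fully_specified_only=True))
    carriers = {
        ec: sum(1 for r in dataset.records if ec in r.ec_set) for ec in uniq
    }
    n_classified = sum(
        1 for r in dataset.records if any(ec.is_fully_specified for ec in r.ec_set)
    )
    largest_fraction = (
        max(carriers.values()) / n_classified if carriers and n_classified else None
    )
    levels = set()
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            lvl = compare_level(uniq[i], uniq[j])
            if lvl >= 1:
                levels.add(lvl)
    return {
        "superfamily_id": dataset.superfamily_id,
        "n_records": len(dataset.records),
        "n_ssgs": len(ssgs),
        "n_mdas": len(mdas),
        "n_unique_ecs": len(uniq),
        "largest_ec_fraction": largest_fraction,
        "level4_only": levels == {4},
    }
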