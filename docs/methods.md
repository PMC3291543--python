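# Methods

## Scope and model

`enzevol` analyses how enzyme function — encoded as a four-level Enzyme
Commission (E.C.) number — changes within structurally defined protein
domain superfamilies. The package takes per-superfamily annotation
tables, rooted gene trees (one per structurally similar group, SSG),
aligned sequences with known catalytic columns, and pairwise structural
distance matrices; it produces exchange matrices, a randomized null
comparison, attribution of functions to domains within multi-domain
architectures (MDAs), and loop-indel/architecture-change associations.
The only comparison ever made between two E.C. numbers is the first
level at which they differ (1 = class, 2 = sub-class, 3 =
sub-sub-class, 4 = serial/substrate); the E.C. hierarchy carries no
finer similarity metric and none is imposed.

Wildcard handling: a wildcard at level *k* implies wildcards at all
deeper levels, and wildcard levels are excluded from comparison. A
partial annotation cannot witness a change, so `3.4.25.1` vs `3.4.25.-`
compares equal; distinct pairs whose comparison stops at a wildcard are
dropped from matrices and reported as uncounted. Preliminary serials
(`n1`-style) are ordinary distinct tokens: they denote distinct
activities. The class range is fixed at 1–6 (the six-class E.C. era in
which the analysed data were annotated); all matrices are 6×6.

## Ancestral inference and exchange counting

Functional changes on a tree are inferred by set-valued small parsimony
(Fitch): a bottom-up intersection-else-union pass over children's state
sets, then a deterministic top-down resolution — the root takes the
smallest member of its set in the package's canonical E.C. ordering,
and every other node keeps its parent's resolved state when admissible,
otherwise its set's smallest member. On binary trees this attains the
parsimony minimum number of changes (verified against an exhaustive
enumeration oracle in the test suite); the deterministic tie-break
makes counts exactly reproducible. Multifurcating nodes pass through
the same bottom-up rule but carry no optimality guarantee and are
excluded from the clean-bifurcation analyses. Multifunctional leaves
contribute their whole annotation set as a polymorphic state, so a
promiscuous annotation is never itself counted as a change.

Every edge whose resolved parent and child states differ at a definite
level yields one exchange event; identical exchanges on different edges
each count. Events are directional internally (parent → derived) but
matrices symmetrize by default, since the direction of an exchange
between two extant functions is rarely identifiable; an ordered matrix
is available on request.

Tree-based counts relate to the all-by-all unique-pair count by

    observations = allbyall + repeat_surplus − cross_ssg_missed

(repeats inflate tree counts, exchanges across SSG boundaries are
invisible to per-SSG trees). The pipeline computes all three terms at
E.C.-pair resolution and verifies the identity on simulated cohorts.

## Exchange matrices and the randomized null

Off-diagonal cells count unique E.C.-number pairs (not merely class
pairs) whose first difference is the class; diagonal cells count
within-class pairs, subdivided by the level (2, 3, 4) of the first
difference. The null model draws pairs uniformly from the multiset of
all E.C. annotations in the cohort (the two members of a pair are
distinct pool entries — without replacement within a pair), classifies
them exactly as the observed counting, and is compared with a Pearson
χ² over the 33 matrix cells (15 between-class + 6×3 within-class
levels). Cells with zero expectation are excluded and the degrees of
freedom reduced; dof = compared cells − 1. The number of draws defaults
to the observed total, making the rescaling the identity. A closed-form
expectation (summing exact pair probabilities over distinct pool
values) accompanies every Monte Carlo matrix; the suite checks 3σ
agreement at 10⁵ draws and uniformity of null-on-null χ² p-values.

## Grouping

SSGs are formed by complete-linkage agglomeration of pairwise RMSD at a
strict < 9 Å threshold, so *every* intra-group pair satisfies the
superposability criterion — single linkage could chain well past it.
Sequence relatives join the SSG of their best-scoring representative
under a pluggable similarity scorer (default: BLOSUM62 local alignment
via Biopython); ties break to the lexicographically smallest group id.
Redundancy removal before SSG formation is greedy leader clustering at
> 35% pairwise identity (identity = identical positions over global
alignment length). MDA groups key on the exact ordered architecture
string; order matters (`A-C` ≠ `C-A`). Families larger than `max_n`
(default 300, a "few hundred" made concrete and configurable) are
reduced to one representative per (full lineage string, E.C. set) pair,
preferring records with a structure, then input order; the filter is
idempotent.

## Confusion domains and attribution

For each in-family architecture and each of its functions, the focus
domain is removed and every contiguous, order-preserving
sub-architecture of the remainder is looked up in the annotation table;
a hit in any context flags the (architecture, function) pair as
ambiguous. "Linear combinations" is read as contiguous runs because
gene order is preserved in architectures; non-contiguous subsets would
both explode combinatorially and contradict linearity. A function is
attributed *single* if any carrier is the bare focus domain, *ambiguous*
if every in-family carrier architecture is flagged for it (partner-only
architectures are not focus-domain contexts and do not vote), else
*mda*. Ambiguous functions are excluded from the headline matrices and
from both numerator and denominator of the single-domain fraction.

## Context flags

An event's `mda_change` flag is true iff the parsimony-reconstructed
architecture (same Fitch machinery, architecture strings as states)
differs across the event's own edge. Comparing whole-side MDA censuses
instead would flag any edge in a tree containing an architecture change
anywhere, conflating independent events; the local rule recovers the
generating coupling probability on simulated data.

`loop_indel` is assessed only at clean bifurcations — binary nodes with
exactly one fully specified function on each side — as true when some
catalytic column is gapped in *every* member of one side within a
maximal run of ≥ 3 consecutive gap columns, while the opposite side is
not entirely gapped there. The contrast condition matters: a gap shared
by both sides is an ancestral indel and would otherwise be attributed
to every bifurcation nested beneath it.

## Synthetic cohorts

The generator realizes the structure the analysis assumes. Per SSG: a
Yule topology (uniform random leaf splitting), root function drawn
uniformly (class 1–6, sub-levels 1–9/1–9/1–99 — a bounded, realistic
E.C. alphabet), and on each branch an independent level-k change with
probability `p_change[k]`; the smallest triggered level wins and
resamples that level and everything below it, because the hierarchy
makes a class change incompatible with a preserved serial. Given a
change, the MDA mutates (partner appended/removed adjacent to the
focus domain) with probability `p_mda_coupling`, and with probability
`p_loop_coupling` a 3-column gap run is laid over a catalytic column
throughout the derived clade. Alignments otherwise evolve by
independent per-site substitutions (default 0.02 per branch) from a
random root sequence of length 60 with 3 catalytic columns. Structural
distances are drawn at 1–7 Å within SSGs and 10–16 Å between, so the
partition is recoverable at the 9 Å cut. Defaults — 200 superfamilies,
8–24 leaves per tree, 1–3 SSGs, `p_change = (0.01, 0.01, 0.01, 0.10)`,
`p_mda_coupling = 0.3`, `p_loop_coupling = 0.05` — are the study
conditions used throughout the tests and the acceptance script; tree
and SSG ranges are chosen once as realistic for redundancy-filtered
structural groups.

What the generator does *not* emulate: rate heterogeneity, realistic
substitution models, indels other than the coupled gap runs,
reticulation, annotation error, or correlated function change across
superfamilies. Passing recovery tests therefore demonstrates the
pipeline's correctness under its own model assumptions, not robustness
to the messiness of curated databases.

Every simulated change is written to a ground-truth log. Parsimony can
only undercount (reversals and repeated changes along a path merge), so
inferred events per tree never exceed logged events — a tested
invariant. At the default conditions this produces known, documented
biases in recovered summaries: the inferred level-4 share runs ~0.03–
0.04 below the log's share (multi-change paths collapse to the highest-
level difference), and the MDA-coupled fraction ~0.04–0.05 below the
generating 0.3 (about 15% of inferred events land on a neighbouring
edge of the true one, decoupling them from the reconstructed
architecture change). Both sit within the ±0.05 recovery bands the
package holds itself to; the loop-associated fraction, measured on
clean bifurcations, is essentially unbiased.

## Numerical and interface conventions

Alignment columns are 0-based and ranges half-open everywhere. E.C.
lists use `;`, architectures `-` (both configurable in the readers).
All randomness flows from explicit integer seeds through
`numpy.random.Generator`; per-superfamily streams derive from
`SeedSequence((seed, index))`, so cohorts are reproducible and
parallel-safe. Reports are JSON with sorted keys — reruns with the same
config and seed are byte-identical. The conservation score is a
normalized Shannon entropy over the 20 amino acids plus gap
(1 − H/log 21), used only for descriptive diversity summaries and never
compared against published conservation scores. χ² p-values come from
`scipy.stats.chi2.sf`.

## Known limitations

- No structural superposition, profile alignment, homology search or
  HMM domain assignment: distances, alignments, trees and architecture
  strings are inputs (or simulated), and the sequence scorers are
  deliberately pluggable stand-ins for such machinery.
- Parsimony is branch-length-blind; no likelihood or Bayesian
  reconstruction is offered.
- The within-class diagonal requires pair-level resolution, so matrices
  silently drop wildcard-truncated pairs (they are reported in the
  `uncounted` channel rather than guessed at a level).
- Ambiguity detection is only as good as the annotation table's
  coverage of partner-only architectures; it is monotone in added
  annotations, never self-correcting.
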