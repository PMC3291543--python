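"""Attributing functions to domains within multi-domain architectures.

A function annotated to a multi-domain protein need not come from the
superfamily domain under scrutiny: a domain partner may perform it
alone.  Such partners are *confusion domains*.  For every in-family
architecture and each of its functions, all contiguous ordered
sub-architectures of the architecture with the focus domain removed are
checked for that function in any other context; a hit flags the
(architecture, function) pair as ambiguous.  Ambiguous functions are
excluded from the headline exchange matrices and from the single-domain
versus MDA attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .ec import ECNumber
from .model import DomainRecord


@dataclass
class MDAFunctionTable:
    """Architecture string -> set of fully specified functions, with the
    focus (superfamily) domain identifier."""

    focus: str
    table: dict[str, frozenset[ECNumber]] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: Iterable[DomainRecord], focus: str
    ) -> "MDAFunctionTable":
        table: dict[str, set[ECNumber]] = {}
        for rec in records:
            ecs = {ec for ec in rec.ec_set if ec.is_fully_specified}
            table.setdefault(rec.mda_string, set()).update(ecs)
        return cls(focus, {k: frozenset(v) for k, v in table.items()})

    def in_family_architectures(self) -> list[str]:
        return [a for a in self.table if self.focus in a.split("-")]

    def merge(self, other: "MDAFunctionTable") -> "MDAFunctionTable":
        """Union annotation contexts (e.g. across superfamilies)."""
        merged = {k: set(v) for k, v in self.table.items()}
        for k, v in other.table.items():
            merged.setdefault(k, set()).update(v)
        return MDAFunctionTable(self.focus, {k: frozenset(v) for k, v in merged.items()})


def _contiguous_subarchitectures(domains: Sequence[str]) -> set[str]:
    """All contiguous ordered runs of length >= 1."""
    out: set[str] = set()
    for i in range(len(domains)):
        for j in range(i + 1, len(domains) + 1):
            out.add("-".join(domains[i:j]))
    return out


def detect_confusion_domains(
    table: MDAFunctionTable,
) -> set[tuple[str, ECNumber]]:
    """Flag (architecture, function) pairs attributable to domain partners.

    For each in-family architecture, the focus domain is removed and all
    contiguous ordered sub-architectures of the remainder ("linear
    combinations" of the partner domains) are looked up in the table; if
    any carries the same function in another context, the pair is
    ambiguous.  Monotone: adding annotations never un-flags a pair.
    """
    flagged: set[tuple[str, ECNumber]] = set()
    for arch in table.in_family_architectures():
        domains = arch.split("-")
        remainder = [d for d in domains if d != table.focus]
        if not remainder:
            continue  # single-domain architecture: never ambiguous
        subs = _contiguous_subarchitectures(remainder)
        for ec in table.table[arch]:
            for sub in subs:
                if sub == arch:
                    continue
                if ec in table.table.get(sub, frozenset()):
                    flagged.add((arch, ec))
                    break
    return flagged


@dataclass
class AttributionResult:
    """Partition of a superfamily's unique functions by their carrier
    context: performed by the single domain, only in multi-domain
    context, or ambiguous (confusion-domain) and excluded."""

    single_fraction: Optional[float]
    attribution: dict[ECNumber, str]  # 'single' | 'mda' | 'ambiguous'

    def ecs_with(self, kind: str) -> list[ECNumber]:
        return sorted(ec for ec, k in self.attribution.items() if k == kind)


def single_domain_fraction(
    records: Sequence[DomainRecord],
    focus: str,
    context_table: Optional[MDAFunctionTable] = None,
) -> AttributionResult:
    """Attribute each unique function of a superfamily to single-domain or
    multi-domain carriers.

    A function carried by any single-domain protein is 'single'.  A
    function whose every in-family carrier architecture is flagged by
    :func:`detect_confusion_domains` is 'ambiguous' and excluded from
    the fraction's denominator.  Everything else is 'mda'.  The fraction
    is #single / (#single + #mda), or None when no function qualifies.

    ``context_table`` may supply additional annotation contexts (other
    superfamilies) for the ambiguity lookup.
    """
    table = MDAFunctionTable.from_records(records, focus)
    lookup = table if context_table is None else table.merge(context_table)
    flagged = detect_confusion_domains(lookup)
    carriers: dict[ECNumber, list[str]] = {}
    for rec in records:
        for ec in rec.ec_set:
            if ec.is_fully_specified:
                carriers.setdefault(ec, []).append(rec.mda_string)
    attribution: dict[ECNumber, str] = {}
    for ec, archs in carriers.items():
        in_family = {a for a in archs if focus in a.split("-")}
        if any(a == focus for a in archs):
            attribution[ec] = "single"
        elif in_family and all((a, ec) in flagged for a in in_family):
            attribution[ec] = "ambiguous"
        else:
            attribution[ec] = "mda"
    n_single = sum(1 for k in attribution.values() if k == "single")
    n_mda = sum(1 for k in attribution.values() if k == "mda")
    fraction = n_single / (n_single + n_mda) if (n_single + n_mda) else None
    return AttributionResult(fraction, attribution)


def mda_coupled_fraction(events: Sequence) -> tuple[Optional[float], int]:
    """Fraction of exchange events coinciding with an architecture change.

    Returns ``(fraction, n_events)``; the fraction is an upper estimate
    (acquisition of function by domain addition is included) and is None
    when there are no events to assess.
    """
    events = list(events)
    if not events:
        return None, 0
    n_coupled = sum(1 for ev in events if ev.mda_change)
    return n_coupled / len(events), len(events)


def correlate(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a series")
    return float(np.corrcoef(x, y)[0, 1])
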