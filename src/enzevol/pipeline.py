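"""End-to-end cohort analysis: grouping → tree counting → all-by-all →
null model → attribution → summaries.

The pipeline output is a pure function of (inputs, config, seed): every
random draw flows from the configured seed and reports are written with
sorted keys, so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io
from .ec import ECNumber
from .exchange_matrix import (
    AllByAllResult,
    ExchangeMatrix,
    aggregate,
    build_tree_matrix,
    compare_matrices_chi2,
    count_allbyall,
    expected_matrix,
    level_proportions,
    summarize_superfamily,
    tally_levels,
)
from .mda import mda_coupled_fraction, correlate, single_domain_fraction
from .model import SuperfamilyDataset
from .signals import assess_clean_bifurcations, loop_associated_fraction
from .simulate import FOCUS_DOMAIN, GroundTruthLog, SimulationConfig, generate_cohort
from .tree_exchange import ExchangeEvent, classify_all_events, reconcile_counts

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        wrapped.__name__ = fn.__name__
        return wrapped

    return deco


def _pair_key(a: ECNumber, b: ECNumber) -> tuple[str, str]:
    return tuple(sorted((str(a), str(b))))  # type: ignore[return-value]


@_stage("count-tree")
def analyze_trees(
    dataset: SuperfamilyDataset,
    ambiguous: frozenset[ECNumber] = frozenset(),
    min_gap: int = 3,
) -> list[ExchangeEvent]:
    """Infer, context-classify and confusion-filter exchange events over
    every SSG tree of one superfamily."""
    events: list[ExchangeEvent] = []
    for ssg_id in sorted(dataset.trees):
        tree = dataset.trees[ssg_id]
        alignment = dataset.alignments.get(ssg_id)
        if alignment is not None and not alignment.catalytic_columns:
            alignment = None
        for ev in classify_all_events(tree, alignment=alignment, min_gap=min_gap):
            if ev.from_ec in ambiguous or ev.to_ec in ambiguous:
                continue
            events.append(ev)
    return events


def analyze_cohort(
    datasets: Sequence[SuperfamilyDataset],
    seed: int,
    n_draws: Optional[int] = None,
    exclude_confusion: bool = True,
    focus_domain: str = FOCUS_DOMAIN,
    min_gap: int = 3,
    ground_truth: Optional[GroundTruthLog] = None,
) -> dict:
    """Run every analysis stage over a cohort and return the report dict."""
    summaries = []
    per_sf_proportions = []
    all_events: list[ExchangeEvent] = []
    tree_matrices: list[ExchangeMatrix] = []
    allbyall_results: list[AllByAllResult] = []
    assessments = []
    attributions = []
    pool: list[ECNumber] = []
    surplus_total = 0
    missed_total = 0

    for ds in datasets:
        attribution = single_domain_fraction(ds.records, focus_domain)
        ambiguous = (
            frozenset(attribution.ecs_with("ambiguous"))
            if exclude_confusion
            else frozenset()
        )
        attributions.append((ds.superfamily_id, attribution))

        events = analyze_trees(ds, ambiguous, min_gap=min_gap)
        all_events.extend(events)
        tree_matrices.append(build_tree_matrix(events))

        ecs = {ec for ec in ds.unique_ecs(fully_specified_only=False) if ec not in ambiguous}
        aba = count_allbyall(ecs)
        allbyall_results.append(aba)

        # reconciliation bookkeeping at E.C.-pair resolution
        tree_pairs = [_pair_key(ev.from_ec, ev.to_ec) for ev in events]
        seen = set(tree_pairs)
        aba_pairs = {_pair_key(a, b) for a, b, _ in aba.unique_pairs}
        surplus_total += len(tree_pairs) - len(seen)
        missed_total += len(aba_pairs - seen)

        pool.extend(ds.ec_pool())
        summaries.append(summarize_superfamily(ds))
        tally = tally_levels(events)
        props = level_proportions(tally)
        per_sf_proportions.append(
            {"superfamily_id": ds.superfamily_id, "proportions": props}
        )

        for ssg_id in sorted(ds.trees):
            alignment = ds.alignments.get(ssg_id)
            if alignment is None or not alignment.catalytic_columns:
                continue
            assessments.extend(
                assess_clean_bifurcations(ds.trees[ssg_id], alignment, min_gap=min_gap)
            )

    tree_agg, tree_pct = aggregate(tree_matrices) if tree_matrices else (None, None)
    aba_agg, aba_pct = (
        aggregate([r.matrix for r in allbyall_results]) if allbyall_results else (None, None)
    )

    # randomized null + χ²
    null_section = None
    if aba_agg is not None and aba_agg.total >= 1 and len(pool) >= 2:
        draws = n_draws if n_draws is not None else max(1, int(aba_agg.total))
        expected = expected_matrix(pool, draws, seed)
        chi2 = compare_matrices_chi2(aba_agg, expected.closed_form)
        null_section = {
            "n_draws": draws,
            "seed": seed,
            "n_uncounted_draws": expected.n_uncounted,
            "expected_matrix": expected.closed_form.to_dict(),
            "monte_carlo_matrix": expected.monte_carlo.to_dict(),
            "chi2_statistic": chi2.statistic,
            "chi2_dof": chi2.dof,
            "chi2_p_value": chi2.p_value,
            "excluded_cells": chi2.excluded_cells,
        }

    mda_fraction, mda_n = mda_coupled_fraction(all_events)
    loops = loop_associated_fraction(assessments)

    cohort_tally = tally_levels(all_events)
    cohort_props = level_proportions(cohort_tally)

    # cross-superfamily correlations
    def _corr(xs, ys):
        try:
            return correlate(xs, ys)
        except ValueError:
            return None

    n_ssgs = [s["n_ssgs"] for s in summaries]
    n_mdas = [s["n_mdas"] for s in summaries]
    n_ecs = [s["n_unique_ecs"] for s in summaries]
    correlations = {
        "ssg_vs_mda": _corr(n_ssgs, n_mdas),
        "mda_vs_ec": _corr(n_mdas, n_ecs),
    }

    aba_total = int(aba_agg.total) if aba_agg is not None else 0
    reconciliation = {
        "allbyall_unique_pairs": aba_total,
        "repeat_surplus": surplus_total,
        "cross_ssg_missed": missed_total,
        "reconciled_observations": reconcile_counts(
            aba_total, surplus_total, missed_total
        ),
        "tree_observations": len(all_events),
    }

    report = {
        "n_superfamilies": len(datasets),
        "grouping": {
            "n_superfamilies": len(datasets),
            "total_records": sum(s["n_records"] for s in summaries),
            "total_ssgs": sum(n_ssgs),
            "total_mdas": sum(n_mdas),
            "level4_only_superfamilies": sum(1 for s in summaries if s["level4_only"]),
        },
        "tree_counts": {
            "n_events": len(all_events),
            "matrix": tree_agg.to_dict() if tree_agg is not None else None,
            "percentages": tree_pct,
            "level_tally": {str(k): v for k, v in cohort_tally.items()},
            "level_proportions": (
                {str(k): v for k, v in cohort_props.items()} if cohort_props else None
            ),
            "within_class_fraction": (
                tree_agg.within_class_fraction()
                if tree_agg is not None and tree_agg.total > 0
                else None
            ),
        },
        "allbyall": {
            "total_unique_pairs": aba_total,
            "matrix": aba_agg.to_dict() if aba_agg is not None else None,
            "percentages": aba_pct,
            "uncounted_pairs": sum(len(r.uncounted) for r in allbyall_results),
            "within_class_fraction": (
                aba_agg.within_class_fraction()
                if aba_agg is not None and aba_agg.total > 0
                else None
            ),
        },
        "null_model": null_section,
        "attribution": {
            "mda_coupled_fraction": mda_fraction,
            "mda_coupled_n_events": mda_n,
            "single_domain_fractions": {
                sf: a.single_fraction for sf, a in attributions
            },
            "ambiguous_ecs": {
                sf: [str(e) for e in a.ecs_with("ambiguous")] for sf, a in attributions
            },
        },
        "signals": {
            "loop_associated_fraction": loops.fraction,
            "n_clean_bifurcations": loops.n_assessed,
            "n_loop_flagged": loops.n_flagged,
            "flagged_between_class": loops.flagged_between_class,
            "flagged_within_class": loops.flagged_within_class,
        },
        "reconciliation": reconciliation,
        "correlations": correlations,
        "superfamily_summaries": summaries,
        "superfamily_level_proportions": [
            {
                "superfamily_id": d["superfamily_id"],
                "proportions": (
                    {str(k): v for k, v in d["proportions"].items()}
                    if d["proportions"]
                    else None
                ),
            }
            for d in per_sf_proportions
        ],
    }

    if ground_truth is not None:
        report["ground_truth"] = {
            "n_events": len(ground_truth),
            "level_shares": {
                str(k): ground_truth.level_share(k) for k in (1, 2, 3, 4)
            },
            "mda_coupled_fraction": ground_truth.coupled_fraction("mda"),
            "loop_coupled_fraction": ground_truth.coupled_fraction("loop"),
        }
    return report


def write_events(events: Sequence[ExchangeEvent], path) -> None:
    rows = [
        {
            "parent": ev.edge[0],
            "child": ev.edge[1],
            "from_ec": str(ev.from_ec),
            "to_ec": str(ev.to_ec),
            "level": ev.change_level,
            "mda_change": int(ev.mda_change),
            "loop_indel": "" if ev.loop_indel is None else int(ev.loop_indel),
        }
        for ev in events
    ]
    pd.DataFrame(
        rows,
        columns=["parent", "child", "from_ec", "to_ec", "level", "mda_change", "loop_indel"],
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the full pipeline from a configuration mapping.

    ``config`` must provide a ``seed`` plus either a ``simulate`` section
    (synthetic cohort parameters) or an ``inputs`` path to a cohort
    directory.  Writes ``report.json`` and matrix TSVs under ``out_dir``
    when given.
    """
    if "seed" not in config:
        raise PipelineError("stage 'config' failed: missing 'seed'")
    seed = int(config["seed"])
    options = config.get("options", {}) or {}

    ground_truth = None
    if "simulate" in config:
        sim_args = dict(config["simulate"] or {})
        sim_args.setdefault("seed", seed)
        try:
            sim_config = SimulationConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in sim_args.items()
            })
        except (TypeError, ValueError) as exc:
            raise PipelineError(f"stage 'simulate' failed: {exc}") from exc
        cohort = generate_cohort(sim_config)
        datasets = cohort.datasets
        ground_truth = cohort.log
    elif "inputs" in config:
        try:
            datasets = io.read_cohort(config["inputs"])
        except Exception as exc:
            raise PipelineError(f"stage 'load' failed: {exc}") from exc
        if not datasets:
            raise PipelineError(f"stage 'load' failed: no datasets in {config['inputs']}")
    else:
        raise PipelineError(
            "stage 'config' failed: need a 'simulate' section or an 'inputs' path"
        )

    report = analyze_cohort(
        datasets,
        seed=seed,
        n_draws=options.get("n_draws"),
        exclude_confusion=options.get("exclude_confusion", True),
        focus_domain=options.get("focus_domain", FOCUS_DOMAIN),
        min_gap=options.get("min_gap", 3),
        ground_truth=ground_truth,
    )
    report["seed"] = seed
    report["config_hash"] = io.config_hash(config)
    logger.info("pipeline done: seed=%s config_hash=%s", seed, report["config_hash"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_report(report, out / "report.json")
        for key, name in (("tree_counts", "tree_matrix.tsv"), ("allbyall", "allbyall_matrix.tsv")):
            md = report[key]["matrix"]
            if md is not None:
                io.write_matrix(ExchangeMatrix.from_dict(md), out / name, with_percentages=True)
        if report["null_model"] is not None:
            io.write_matrix(
                ExchangeMatrix.from_dict(report["null_model"]["expected_matrix"]),
                out / "expected_matrix.tsv",
            )
    return report
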