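"""Readers and writers for every on-disk format the pipeline touches.

Formats: annotation tables and distance matrices as TSV, trees as
Newick, alignments as aligned FASTA with a plain-text catalytic-column
sidecar (0-based indices, one per line), exchange matrices as labelled
TSV grids, reports as JSON, configuration as YAML key-value files.
Alignment columns are 0-based throughout; ranges half-open.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ec import ECNumber, parse_ec
from .exchange_matrix import ExchangeMatrix, _DIAG_LEVELS
from .grouping import StructuralDistanceMatrix
from .model import AlignmentBlock, AnnotatedTree, DomainRecord, SuperfamilyDataset
from .simulate import GroundTruthEvent, GroundTruthLog

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

EC_SEPARATOR = ";"
MDA_SEPARATOR = "-"
LINEAGE_SEPARATOR = ";"

_ANNOTATION_COLUMNS = [
    "sequence_id", "superfamily_id", "ssg_id", "mda", "ec_set", "lineage",
    "has_structure",
]


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------


def read_annotations(
    path: PathLike,
    ec_sep: str = EC_SEPARATOR,
    mda_sep: str = MDA_SEPARATOR,
) -> list[DomainRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    records: list[DomainRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sequence_id"]
        if sid in seen:
            raise ValueError(f"{path}: duplicate sequence_id {sid!r}")
        seen.add(sid)
        ec_field = row["ec_set"].strip()
        if ec_field:
            ecs = frozenset(parse_ec(t) for t in ec_field.split(ec_sep) if t.strip())
        else:
            ecs = frozenset()
            logger.warning("record %s has an empty E.C. field", sid)
        records.append(
            DomainRecord(
                sequence_id=sid,
                superfamily_id=row["superfamily_id"],
                ssg_id=row["ssg_id"] or None,
                mda=tuple(row["mda"].split(mda_sep)),
                ec_set=ecs,
                lineage=tuple(t for t in row["lineage"].split(LINEAGE_SEPARATOR) if t),
                has_structure=row["has_structure"].strip() in ("1", "true", "True"),
            )
        )
    return records


def write_annotations(
    records: Sequence[DomainRecord],
    path: PathLike,
    ec_sep: str = EC_SEPARATOR,
    mda_sep: str = MDA_SEPARATOR,
) -> None:
    rows = [
        {
            "sequence_id": r.sequence_id,
            "superfamily_id": r.superfamily_id,
            "ssg_id": r.ssg_id or "",
            "mda": mda_sep.join(r.mda),
            "ec_set": ec_sep.join(str(e) for e in sorted(r.ec_set)),
            "lineage": LINEAGE_SEPARATOR.join(r.lineage),
            "has_structure": int(r.has_structure),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def read_tree(path: PathLike, records: Optional[dict] = None) -> AnnotatedTree:
    text = Path(path).read_text()
    return AnnotatedTree.from_newick(text, records)


def write_tree(tree: AnnotatedTree, path: PathLike) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def read_alignment(path: PathLike, catalytic_path: Optional[PathLike] = None) -> AlignmentBlock:
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }
    if not sequences:
        raise ValueError(f"{path}: no sequences")
    catalytic: frozenset[int] = frozenset()
    if catalytic_path is not None:
        lines = Path(catalytic_path).read_text().split()
        catalytic = frozenset(int(t) for t in lines)
    return AlignmentBlock(sequences, catalytic)


def write_alignment(
    block: AlignmentBlock, path: PathLike, catalytic_path: Optional[PathLike] = None
) -> None:
    seqs = [
        SeqRecord(Seq(s), id=sid, description="") for sid, s in block.sequences.items()
    ]
    SeqIO.write(seqs, str(path), "fasta")
    if catalytic_path is not None:
        Path(catalytic_path).write_text(
            "".join(f"{c}\n" for c in sorted(block.catalytic_columns))
        )


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


def read_distance_matrix(path: PathLike) -> StructuralDistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return StructuralDistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_distance_matrix(dm: StructuralDistanceMatrix, path: PathLike) -> None:
    pd.DataFrame(dm.matrix, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# exchange matrices
# ---------------------------------------------------------------------------


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_matrix(
    matrix: ExchangeMatrix, path: PathLike, with_percentages: bool = False
) -> None:
    """Labelled 6×6 TSV grid; diagonal cells carry per-level sub-counts as
    ``total(l2/l3/l4)``.  Percentage lines (prefixed ``%``) are optional
    and ignored by the reader."""
    n = matrix.n_classes
    lines = [f"# exchange-matrix mode={matrix.mode} ordered={str(matrix.ordered).lower()}"]
    labels = [f"EC{i + 1}" for i in range(n)]
    lines.append("\t" + "\t".join(labels))
    for i in range(n):
        row = [labels[i]]
        for j in range(n):
            if i == j:
                subs = "/".join(_fmt(matrix.diag_levels[i, k]) for k in range(len(_DIAG_LEVELS)))
                row.append(f"{_fmt(matrix.counts[i, i])}({subs})")
            else:
                row.append(_fmt(matrix.counts[i, j]))
        lines.append("\t".join(row))
    if with_percentages and matrix.total > 0:
        for name, pct in matrix.percentage_table().items():
            lines.append(f"%\t{name}\t{pct:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path: PathLike) -> ExchangeMatrix:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    header = lines[0]
    if not header.startswith("# exchange-matrix"):
        raise ValueError(f"{path}: not an exchange-matrix file")
    meta = dict(tok.split("=") for tok in header.split()[2:])
    body = [l for l in lines[1:] if not l.startswith("%")]
    n = len(body[0].split("\t")) - 1
    m = ExchangeMatrix(meta["mode"], ordered=meta.get("ordered") == "true", n_classes=n)
    for i, line in enumerate(body[1:]):
        cells = line.split("\t")[1:]
        for j, cell in enumerate(cells):
            if i == j:
                total, subs = cell.rstrip(")").split("(")
                m.counts[i, i] = float(total)
                for k, v in enumerate(subs.split("/")):
                    m.diag_levels[i, k] = float(v)
            else:
                m.counts[i, j] = float(cell)
    m.validate()
    return m


def plot_matrix(matrix: ExchangeMatrix, path: PathLike, title: str = "") -> None:
    """Optional heatmap of the class-exchange grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix.counts, cmap="YlOrRd")
    labels = [f"EC{i + 1}" for i in range(matrix.n_classes)]
    ax.set_xticks(range(matrix.n_classes), labels)
    ax.set_yticks(range(matrix.n_classes), labels)
    ax.set_title(title or f"{matrix.mode} exchange matrix")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# ground-truth logs
# ---------------------------------------------------------------------------

_LOG_COLUMNS = [
    "superfamily_id", "ssg_id", "parent", "child", "level", "from_ec", "to_ec",
    "mda_coupled", "loop_coupled",
]


def write_ground_truth(log: GroundTruthLog, path: PathLike) -> None:
    rows = [
        {
            "superfamily_id": e.superfamily_id,
            "ssg_id": e.ssg_id,
            "parent": e.branch[0],
            "child": e.branch[1],
            "level": e.level,
            "from_ec": str(e.from_ec),
            "to_ec": str(e.to_ec),
            "mda_coupled": int(e.mda_coupled),
            "loop_coupled": int(e.loop_coupled),
        }
        for e in log.events
    ]
    pd.DataFrame(rows, columns=_LOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ground_truth(path: PathLike) -> GroundTruthLog:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    events = [
        GroundTruthEvent(
            superfamily_id=row["superfamily_id"],
            ssg_id=row["ssg_id"],
            branch=(row["parent"], row["child"]),
            level=int(row["level"]),
            from_ec=parse_ec(row["from_ec"]),
            to_ec=parse_ec(row["to_ec"]),
            mda_coupled=row["mda_coupled"] == "1",
            loop_coupled=row["loop_coupled"] == "1",
        )
        for _, row in df.iterrows()
    ]
    return GroundTruthLog(events)


# ---------------------------------------------------------------------------
# dataset directories (the layout `enzevol simulate` writes)
# ---------------------------------------------------------------------------


def write_dataset(dataset: SuperfamilyDataset, out_dir: PathLike) -> Path:
    """Write one superfamily as a directory of the standard text formats."""
    root = Path(out_dir) / dataset.superfamily_id
    root.mkdir(parents=True, exist_ok=True)
    write_annotations(dataset.records, root / "annotations.tsv")
    for ssg_id, tree in dataset.trees.items():
        write_tree(tree, root / f"{ssg_id}.nwk")
    for ssg_id, block in dataset.alignments.items():
        write_alignment(
            block, root / f"{ssg_id}.afa", root / f"{ssg_id}.catalytic.txt"
        )
    if dataset.distances is not None:
        write_distance_matrix(dataset.distances, root / "distances.tsv")
    return root


def read_dataset(path: PathLike) -> SuperfamilyDataset:
    root = Path(path)
    records = read_annotations(root / "annotations.tsv")
    record_map = {r.sequence_id: r for r in records}
    trees = {}
    alignments = {}
    for nwk in sorted(root.glob("*.nwk")):
        ssg_id = nwk.stem
        trees[ssg_id] = read_tree(nwk, record_map)
        afa = root / f"{ssg_id}.afa"
        if afa.exists():
            sidecar = root / f"{ssg_id}.catalytic.txt"
            alignments[ssg_id] = read_alignment(afa, sidecar if sidecar.exists() else None)
    dist_path = root / "distances.tsv"
    distances = read_distance_matrix(dist_path) if dist_path.exists() else None
    sf_id = records[0].superfamily_id if records else root.name
    return SuperfamilyDataset(sf_id, records, trees, alignments, distances)


def write_cohort(
    datasets: Sequence[SuperfamilyDataset], log: GroundTruthLog, out_dir: PathLike
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        write_dataset(ds, out)
    write_ground_truth(log, out / "ground_truth.tsv")


def read_cohort(path: PathLike) -> list[SuperfamilyDataset]:
    root = Path(path)
    return [read_dataset(p) for p in sorted(root.iterdir()) if p.is_dir()]


# ---------------------------------------------------------------------------
# configuration and reports
# ---------------------------------------------------------------------------


def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return cfg


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_report(report: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
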