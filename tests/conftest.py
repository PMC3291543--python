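from __future__ import annotations

import numpy as np
import pytest

from enzevol.ec import parse_ec
from enzevol.model import AnnotatedTree, DomainRecord
from enzevol.simulate import SimulationConfig, generate_cohort


def make_record(
    sequence_id: str,
    ecs: str = "1.1.1.1",
    mda: str = "C",
    sf: str = "SF000",
    ssg: str | None = "SSG1",
    lineage: str = "Bacteria;Genus1",
    has_structure: bool = False,
) -> DomainRecord:
    return DomainRecord(
        sequence_id=sequence_id,
        superfamily_id=sf,
        ssg_id=ssg,
        mda=tuple(mda.split("-")),
        ec_set=frozenset(parse_ec(t) for t in ecs.split(";") if t),
        lineage=tuple(lineage.split(";")),
        has_structure=has_structure,
    )


def make_tree(newick: str, leaf_ecs: dict[str, str], leaf_mdas: dict[str, str] | None = None) -> AnnotatedTree:
    """Annotated tree from newick plus per-leaf EC (';'-joined) strings."""
    records = {
        lid: make_record(lid, ecs=ecs, mda=(leaf_mdas or {}).get(lid, "C"))
        for lid, ecs in leaf_ecs.items()
    }
    return AnnotatedTree.from_newick(newick, records)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-superfamily synthetic cohort under the default study conditions."""
    config = SimulationConfig(n_superfamilies=30, seed=11)
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
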