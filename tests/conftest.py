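import numpy as np
import pandas as pd
import pytest

from vitaprof import load_default_ruleset
from vitaprof.rules import VITAMINS, BinaryPhenotypeMatrix
from vitaprof.synthetic import SimulationConfig, simulate_community, simulate_reference


@pytest.fixture(scope="session")
def ruleset():
    return load_default_ruleset()


@pytest.fixture(scope="session")
def small_reference():
    """A compact seeded reference collection with planted ground truth."""
    return simulate_reference(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_community(small_reference):
    return simulate_community(SimulationConfig(seed=11), small_reference)


def make_bpm(rows: dict[str, list[int]]) -> BinaryPhenotypeMatrix:
    """Hand-rolled BPM from genome_id -> nine 0/1 values."""
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(VITAMINS))
    frame.index.name = "genome_id"
    return BinaryPhenotypeMatrix(phenotypes=frame)


def flat_taxonomy(genomes: dict[str, tuple]) -> pd.DataFrame:
    """Taxonomy frame from genome_id -> (species, genus, family[, order,
    class, phylum])."""
    rows = {}
    for g, lineage in genomes.items():
        lineage = tuple(lineage) + ("O1", "C1", "P1")[len(lineage) - 3 :]
        rows[g] = lineage
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["species", "genus", "family", "order", "class", "phylum"],
    )
    df.index.name = "genome_id"
    return df
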