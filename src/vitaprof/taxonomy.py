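"""Taxonomic aggregation of binary vitamin phenotypes.

Averaged prototrophy values at any rank are computed hierarchically: a
species mean averages its strains' binary phenotypes, a genus mean averages
its species means, and so on up to phylum. This gives equal weight to each
child taxon rather than each genome, so heavily sequenced species do not
dominate their genus. A ``pooled`` mode (flat mean over all member genomes)
is available for sensitivity analysis.

Within-taxon phenotype variability is summarised by two metrics:

* NVP — number of variable phenotypes: vitamins whose values differ among the
  taxon's aggregation units (0–9).
* OPVS — overall phenotype variability score: the sum over vitamins of the
  unbiased sample variance of unit values (0–4.5; a two-unit taxon
  contributes exactly 0.5 per variable phenotype).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rules import VITAMINS, BinaryPhenotypeMatrix

#: Taxonomic ranks from most to least specific (column names of the
#: taxonomy table, besides the genome_id index).
RANKS: tuple[str, ...] = ("species", "genus", "family", "order", "class", "phylum")

_EQUAL_TOL = 1e-12


def effective_species(taxonomy: pd.DataFrame) -> pd.Series:
    """Species labels with unnamed isolates kept as singleton pseudo-species
    keyed by genome id."""
    species = taxonomy["species"].astype("string")
    missing = species.isna() | (species.str.strip() == "")
    return species.mask(missing, taxonomy.index.to_series().astype("string")).astype(str)


def _validate(bpm: BinaryPhenotypeMatrix, taxonomy: pd.DataFrame, rank: str) -> None:
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    missing = bpm.genome_ids.difference(taxonomy.index)
    if len(missing):
        raise ValueError(f"genomes absent from taxonomy: {sorted(missing)[:5]} ...")


def aggregation_units(
    bpm: BinaryPhenotypeMatrix,
    taxonomy: pd.DataFrame,
    rank: str,
    mode: str = "hierarchical",
) -> pd.DataFrame:
    """Per-genome or per-child-taxon phenotype vectors grouped under ``rank``.

    Returns a frame indexed by (taxon, unit) whose rows are the aggregation
    units entering the mean/variance at that rank: genomes at species rank,
    child-rank mean vectors above it (hierarchical mode), or member genomes
    directly (pooled mode).
    """
    _validate(bpm, taxonomy, rank)
    if mode not in ("hierarchical", "pooled"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    tax = taxonomy.loc[bpm.genome_ids].copy()
    tax["species"] = effective_species(tax)
    values = bpm.phenotypes.astype(float)

    if rank == "species" or mode == "pooled":
        labels = tax[rank]
        usable = labels.notna() & (labels.astype(str).str.strip() != "")
        out = values.loc[usable.index[usable]].copy()
        out.index = pd.MultiIndex.from_arrays(
            [labels[usable], out.index], names=[rank, "unit"]
        )
        return out.sort_index()

    # Hierarchical: fold genome values up one rank at a time.
    chain = RANKS[: RANKS.index(rank) + 1]
    current = values.groupby(tax["species"]).mean()
    lineage = tax.drop_duplicates("species").set_index("species")[list(chain[1:])]
    for parent in chain[1:]:
        parent_of = lineage[parent]
        if parent == rank:
            units = current.loc[parent_of.index]
            units.index = pd.MultiIndex.from_arrays(
                [parent_of.values, parent_of.index], names=[rank, "unit"]
            )
            return units.sort_index()
        current = current.groupby(parent_of).mean()
        lineage = lineage.drop_duplicates(parent).set_index(parent)
    raise AssertionError("unreachable")


def average_phenotypes(
    bpm: BinaryPhenotypeMatrix,
    taxonomy: pd.DataFrame,
    rank: str,
    mode: str = "hierarchical",
) -> pd.DataFrame:
    """Averaged vitamin prototrophy values (in [0, 1]) per taxon at ``rank``.

    The mean estimates the probability that an organism drawn from the taxon
    is a prototroph for each vitamin.
    """
    units = aggregation_units(bpm, taxonomy, rank, mode=mode)
    return units.groupby(level=0).mean()


def variability(
    bpm: BinaryPhenotypeMatrix,
    taxonomy: pd.DataFrame,
    rank: str,
    mode: str = "hierarchical",
) -> pd.DataFrame:
    """Per-taxon variability report at ``rank``.

    Columns: ``n_members`` (aggregation units), per-vitamin means
    (``mean_<v>``), per-vitamin unbiased sample variances (``var_<v>``),
    ``NVP`` and ``OPVS``. Taxa with a single unit report NVP = OPVS = 0.
    """
    units = aggregation_units(bpm, taxonomy, rank, mode=mode)
    grouped = units.groupby(level=0)
    n = grouped.size()
    means = grouped.mean()
    var = grouped.var(ddof=1).fillna(0.0)
    spread = grouped.max() - grouped.min()
    nvp = (spread > _EQUAL_TOL).sum(axis=1)

    report = pd.DataFrame({"rank": rank, "n_members": n})
    for v in means.columns:
        report[f"mean_{v}"] = means[v]
    for v in var.columns:
        report[f"var_{v}"] = var[v]
    report["NVP"] = nvp.astype(int)
    report["OPVS"] = var.sum(axis=1)
    report.index.name = "taxon"
    return report


def read_taxonomy(path) -> pd.DataFrame:
    """Read a seven-column taxonomy TSV (genome_id, species..phylum).

    Greengenes-style lineage strings in a two-column file
    (``genome_id<TAB>k__...;p__...;...``) are split into ranks.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] == 2 and df.iloc[:, 1].str.contains("__").any():
        df = pd.concat(
            [df.iloc[:, [0]], df.iloc[:, 1].apply(_split_lineage)], axis=1
        )
    df.columns = ["genome_id", *RANKS][: df.shape[1]]
    missing = set(RANKS) - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy file lacks rank column(s): {sorted(missing)}")
    return df.set_index("genome_id")


_GG_PREFIXES = {"k": None, "p": "phylum", "c": "class", "o": "order",
                "f": "family", "g": "genus", "s": "species"}


def _split_lineage(lineage: str) -> pd.Series:
    fields: dict[str, str] = {}
    for part in str(lineage).split(";"):
        part = part.strip()
        if "__" not in part:
            continue
        prefix, _, name = part.partition("__")
        rank = _GG_PREFIXES.get(prefix)
        if rank:
            fields[rank] = name
    return pd.Series({r: fields.get(r, "") for r in RANKS})


def write_variability(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", na_rep="NA")
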