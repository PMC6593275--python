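"""16S rRNA gene copy-number renormalization of OTU read counts.

Marker-gene read counts over-represent taxa carrying many rRNA operons.
Dividing each OTU's counts by the mean 16S copy number of its assigned taxon
(rrnDB-style pan-taxon means) before closing to relative abundances removes
the strongest of these biases. Lookup follows the OTU's assignment rank and
falls back species -> genus -> family -> global table mean; genus and family
of a species-level assignment are resolved through the reference taxonomy
when available.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)


def read_copy_numbers(path) -> pd.DataFrame:
    """Read a (taxon, rank, mean_copies) TSV into a validated table."""
    df = pd.read_csv(path, sep="\t", dtype={"taxon": str, "rank": str})
    return validate_copy_numbers(df)


def validate_copy_numbers(table: pd.DataFrame) -> pd.DataFrame:
    required = {"taxon", "rank", "mean_copies"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"copy-number table lacks column(s): {sorted(missing)}")
    if (table["mean_copies"] <= 0).any():
        bad = table.loc[table["mean_copies"] <= 0, "taxon"].tolist()
        raise ValueError(f"non-positive copy number for taxa: {bad[:5]}")
    dupes = table.duplicated(["taxon", "rank"])
    if dupes.any():
        raise ValueError(
            f"duplicate (taxon, rank) records: "
            f"{table.loc[dupes, ['taxon', 'rank']].values.tolist()[:5]}"
        )
    return table


def _lineage_lookup(taxonomy: pd.DataFrame | None):
    """species -> (genus, family) and genus -> family maps from the
    reference taxonomy, used to walk the fallback chain."""
    if taxonomy is None:
        return {}, {}
    from .taxonomy import effective_species

    tax = taxonomy.copy()
    tax["species"] = effective_species(tax)
    sp = tax.drop_duplicates("species").set_index("species")
    species_up = {s: (str(r["genus"]), str(r["family"])) for s, r in sp.iterrows()}
    gen = tax.drop_duplicates("genus").set_index("genus")
    genus_up = {g: str(r["family"]) for g, r in gen.iterrows()}
    return species_up, genus_up


def resolve_copy_number(
    taxon: str,
    rank: str,
    cn_index: dict[tuple[str, str], float],
    default: float,
    species_up: dict,
    genus_up: dict,
) -> float:
    """Copy number for one assignment, walking species -> genus -> family
    -> global default."""
    chain: list[tuple[str, str]] = [(taxon, rank)]
    if rank == "species":
        genus, family = species_up.get(
            taxon, (taxon.split()[0] if taxon.split() else taxon, None)
        )
        chain.append((genus, "genus"))
        if family is None:
            family = genus_up.get(genus)
        if family is not None:
            chain.append((family, "family"))
    elif rank == "genus":
        family = genus_up.get(taxon)
        if family is not None:
            chain.append((family, "family"))
    for key in chain:
        if key in cn_index:
            return cn_index[key]
    return default


def renormalize_counts(
    counts: pd.DataFrame,
    copy_numbers: pd.DataFrame,
    assignments: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Divide each OTU's read counts by its taxon's mean 16S copy number.

    Returns the weighted count table (same shape as ``counts``); relative
    abundances are recomputed downstream from these weighted counts. Taxa
    absent from the table at every fallback rank receive the global mean of
    the table, so that uncorrected OTUs are not systematically over-weighted
    relative to corrected ones.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    copy_numbers = validate_copy_numbers(copy_numbers)
    cn_index = {
        (str(r["taxon"]), str(r["rank"])): float(r["mean_copies"])
        for _, r in copy_numbers.iterrows()
    }
    default = float(copy_numbers["mean_copies"].mean())
    species_up, genus_up = _lineage_lookup(taxonomy)

    divisors = {}
    fallbacks = []
    for otu_id in counts.index:
        if otu_id in assignments.index:
            rank = str(assignments.loc[otu_id, "rank"])
            taxon = str(assignments.loc[otu_id, "taxon"])
            cn = resolve_copy_number(
                taxon, rank, cn_index, default, species_up, genus_up
            )
            if cn == default and (taxon, rank) not in cn_index:
                fallbacks.append(taxon)
        else:
            cn = default
            fallbacks.append(str(otu_id))
        divisors[otu_id] = cn
    if fallbacks:
        logger.info(
            "%d taxa missing from the copy-number table; used the global "
            "mean %.3f (e.g. %s)",
            len(set(fallbacks)), default, ", ".join(sorted(set(fallbacks))[:5]),
        )
    return counts.div(pd.Series(divisors), axis=0)
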