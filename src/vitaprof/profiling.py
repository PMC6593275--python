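"""Community phenotype profiling from taxonomically assigned OTU tables.

OTU taxonomic assignments are mapped onto the reference genome collection at
species, genus or family rank by hierarchical averaging: a species-level OTU
spreads its weight equally over the species' strains; a genus-level OTU
splits weight equally over the genus' species and then equally over each
species' strains (a mean of species means); family level nests one level
deeper. OTUs that cannot be mapped at family rank or below are excluded from
phenotype prediction and reported as unmapped coverage.

For each mapped OTU *i* the Community Phenotype Matrix holds

    P_i = sum_m w_im * p_m

the mapping-weighted mean of reference binary phenotypes, and per sample the
Community Phenotype Index

    CPI = 100 * sum_i A_i * P_i

with relative abundances A re-closed over mapped OTUs, plus the prediction
error sigma = 100 * sqrt(sum_i A_i^2 * P_i * (1 - P_i)), which vanishes when
every OTU's phenotype is unambiguous and quantifies mapping imprecision and
phenotype heterogeneity otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rules import BinaryPhenotypeMatrix
from .taxonomy import effective_species

#: Ranks at which an OTU assignment can be mapped onto the reference.
MAPPABLE_RANKS: tuple[str, ...] = ("species", "genus", "family")


@dataclass
class OTUMapping:
    """Mapping of one OTU onto reference genomes."""

    otu_id: str
    rank_used: str | None
    weights: pd.Series  # genome_id -> w, sums to 1 for mapped OTUs
    unmapped: bool = False

    def __post_init__(self) -> None:
        if not self.unmapped:
            total = float(self.weights.sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"weights of OTU {self.otu_id} sum to {total}, not 1"
                )
            if (self.weights <= 0).any():
                raise ValueError(f"non-positive weight for OTU {self.otu_id}")


@dataclass
class MappingWeights:
    """Per-OTU genome weights for a whole assignment table."""

    mappings: dict[str, OTUMapping] = field(default_factory=dict)

    @property
    def mapped_ids(self) -> list[str]:
        return [o for o, m in self.mappings.items() if not m.unmapped]

    def __getitem__(self, otu_id: str) -> OTUMapping:
        return self.mappings[otu_id]

    def rank_of(self, otu_id: str) -> str | None:
        m = self.mappings.get(otu_id)
        return None if m is None or m.unmapped else m.rank_used


@dataclass
class CPIReport:
    """Per-sample community phenotype indices and bookkeeping.

    All index/error values are on the percentage scale except ``sigma_raw``,
    which is the unrooted variance-form sum on the 0–1 scale.
    """

    cpi: pd.DataFrame           # sample x vitamin, prototrophy CPI (%)
    auxotrophy: pd.DataFrame    # sample x vitamin, 100 - CPI (%)
    sigma: pd.DataFrame         # sample x vitamin, sqrt form (%)
    sigma_raw: pd.DataFrame     # sample x vitamin, raw sum (0-1 scale)
    coverage: pd.DataFrame      # sample x {species, genus, family, unmapped}


def _index_reference(taxonomy: pd.DataFrame, bpm: BinaryPhenotypeMatrix):
    """Nested family -> genus -> species -> [genomes] index of the reference."""
    tax = taxonomy.loc[taxonomy.index.intersection(bpm.genome_ids)].copy()
    tax["species"] = effective_species(tax)
    nested: dict[str, dict[str, dict[str, list[str]]]] = {}
    for genome, row in tax.iterrows():
        fam = nested.setdefault(str(row["family"]), {})
        gen = fam.setdefault(str(row["genus"]), {})
        gen.setdefault(str(row["species"]), []).append(genome)
    by_species = {s: g for fam in nested.values() for gen in fam.values()
                  for s, g in gen.items()}
    by_genus = {g: gen for fam in nested.values() for g, gen in fam.items()}
    return nested, by_genus, by_species


def _species_weights(genomes: list[str]) -> dict[str, float]:
    w = 1.0 / len(genomes)
    return {g: w for g in genomes}


def _genus_weights(genus: dict[str, list[str]], mode: str) -> dict[str, float]:
    if mode == "flat":
        genomes = [g for gg in genus.values() for g in gg]
        return _species_weights(genomes)
    out: dict[str, float] = {}
    per_species = 1.0 / len(genus)
    for genomes in genus.values():
        for g in genomes:
            out[g] = per_species / len(genomes)
    return out


def _family_weights(family: dict[str, dict[str, list[str]]], mode: str) -> dict[str, float]:
    if mode == "flat":
        genomes = [g for gen in family.values() for gg in gen.values() for g in gg]
        return _species_weights(genomes)
    out: dict[str, float] = {}
    per_genus = 1.0 / len(family)
    for genus in family.values():
        for genome, w in _genus_weights(genus, mode).items():
            out[genome] = per_genus * w
    return out


def map_otus(
    assignments: pd.DataFrame,
    taxonomy: pd.DataFrame,
    bpm: BinaryPhenotypeMatrix,
    mode: str = "hierarchical",
) -> MappingWeights:
    """Map OTU taxonomic assignments onto reference genomes.

    ``assignments`` is indexed by OTU id with columns ``rank`` and ``taxon``.
    A species assignment absent from the reference falls back to its genus
    (first whitespace-separated token of the binomial) when that genus is
    known; assignments above family rank, or naming unknown taxa, are marked
    unmapped — never an error.
    """
    if mode not in ("hierarchical", "flat"):
        raise ValueError(f"unknown weighting mode {mode!r}")
    by_family, by_genus, by_species = _index_reference(taxonomy, bpm)
    out = MappingWeights()
    for otu_id, row in assignments.iterrows():
        rank, taxon = str(row["rank"]), str(row["taxon"])
        weights, rank_used = _resolve(
            rank, taxon, by_family, by_genus, by_species, mode
        )
        if weights is None:
            out.mappings[str(otu_id)] = OTUMapping(
                otu_id=str(otu_id), rank_used=None,
                weights=pd.Series(dtype=float), unmapped=True,
            )
        else:
            out.mappings[str(otu_id)] = OTUMapping(
                otu_id=str(otu_id), rank_used=rank_used,
                weights=pd.Series(weights, name=otu_id),
            )
    return out


def _resolve(rank, taxon, by_family, by_genus, by_species, mode):
    if rank == "species":
        if taxon in by_species:
            return _species_weights(by_species[taxon]), "species"
        genus = taxon.split()[0] if taxon.split() else taxon
        if genus in by_genus:
            return _genus_weights(by_genus[genus], mode), "genus"
        return None, None
    if rank == "genus":
        if taxon in by_genus:
            return _genus_weights(by_genus[taxon], mode), "genus"
        return None, None
    if rank == "family":
        if taxon in by_family:
            return _family_weights(by_family[taxon], mode), "family"
        return None, None
    return None, None  # above-family or unassigned


def compute_cpm(
    weights: MappingWeights, bpm: BinaryPhenotypeMatrix
) -> pd.DataFrame:
    """Community Phenotype Matrix: P_i = sum_m w_im p_m per mapped OTU."""
    rows = {}
    pheno = bpm.phenotypes.astype(float)
    for otu_id in weights.mapped_ids:
        w = weights[otu_id].weights
        missing = w.index.difference(pheno.index)
        if len(missing):
            raise KeyError(
                f"OTU {otu_id} weighted onto genomes absent from BPM: "
                f"{sorted(missing)[:5]}"
            )
        rows[otu_id] = pheno.loc[w.index].mul(w, axis=0).sum(axis=0)
    cpm = pd.DataFrame(rows).T.reindex(columns=pheno.columns)
    cpm.index.name = "otu_id"
    return cpm


def _closure(counts: pd.Series) -> pd.Series:
    total = counts.sum()
    return counts / total if total > 0 else counts * np.nan


def mapped_abundances(
    counts: pd.DataFrame, cpm: pd.DataFrame
) -> pd.DataFrame:
    """Relative abundances re-closed over mapped OTUs, per sample
    (columns: samples; rows: mapped OTUs). Samples with zero mapped
    abundance come back as all-NaN columns."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    mapped = counts.reindex(cpm.index).fillna(0.0)
    return mapped.apply(_closure, axis=0)


def compute_cpi(
    cpm: pd.DataFrame,
    counts: pd.DataFrame,
    weights: MappingWeights | None = None,
) -> CPIReport:
    """Per-sample CPI (%), auxotrophy CPI, prediction errors and coverage.

    ``counts`` is an OTU x sample table of (possibly copy-number-weighted)
    read counts; rows missing from the CPM are treated as unmapped. A sample
    with no mapped abundance yields NaN indices rather than zeros.
    """
    abund = mapped_abundances(counts, cpm)
    cpi = 100.0 * abund.T @ cpm
    raw = (abund.T ** 2) @ (cpm * (1.0 - cpm))
    sigma = 100.0 * np.sqrt(raw)
    cpi.index.name = sigma.index.name = "sample"

    cov_rows = {}
    for sample in counts.columns:
        rel = _closure(counts[sample])
        fractions = {r: 0.0 for r in (*MAPPABLE_RANKS, "unmapped")}
        for otu_id, a in rel.items():
            rank = weights.rank_of(str(otu_id)) if weights is not None else (
                "species" if otu_id in cpm.index else None
            )
            fractions[rank or "unmapped"] += float(a)
        cov_rows[sample] = fractions
    coverage = pd.DataFrame(cov_rows).T
    coverage.index.name = "sample"

    return CPIReport(
        cpi=cpi, auxotrophy=100.0 - cpi, sigma=sigma, sigma_raw=raw,
        coverage=coverage,
    )


def compute_error(cpm: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Prediction error sigma (%) per sample x vitamin:
    100 * sqrt(sum_i A_i^2 P_i (1-P_i))."""
    abund = mapped_abundances(counts, cpm)
    return 100.0 * np.sqrt((abund.T ** 2) @ (cpm * (1.0 - cpm)))
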