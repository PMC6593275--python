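"""Seeded synthetic reference collections and 16S community profiles.

Every pipeline stage is testable without any external download: the
generator plants known pathway variants in gene-presence profiles (so the
rules engine must recover them exactly), known intraspecies phenotype
heterogeneity, and known per-sample community composition from which
ground-truth community phenotype indices are computed analytically.

The default parameters mirror the statistical structure of real gut
reference collections and amplicon surveys: per-vitamin variant frequencies
follow the composition of a curated 2,228-genome human gut collection, the
assignment-rank mixture targets ~77% species-level coverage by abundance
(with 19% genus, 3% family, 1% unmapped), abundances are drawn from a
sparse symmetric Dirichlet, and 16S copy numbers are uniform on 1–15.
Read-level sampling noise and taxonomic misassignment are deliberately not
modelled; emitted counts are expected values on the read scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rules import (
    VITAMINS,
    BinaryPhenotypeMatrix,
    GenePresenceProfile,
    RuleSet,
    assign_variant,
    build_bpm,
    load_default_ruleset,
)

#: Default pathway-variant frequencies (relative genome counts of each
#: variant in a curated human gut reference collection of 2,228 genomes).
DEFAULT_VARIANT_COUNTS: dict[str, dict[str, int]] = {
    "B1": {"P1": 975, "P1*": 89, "P2": 45, "Ah": 199, "Az": 114, "Ahz": 452, "A": 354},
    "B2": {"P": 1644, "A": 584},
    "B3": {"P1": 1170, "P1*": 34, "P2": 12, "A": 895, "Aq": 86, "Ar": 31},
    "B5": {"P": 1168, "P*": 95, "Apt": 39, "Apt*": 17, "A": 793, "Apn": 91, "A*": 25},
    "B6": {"P1": 862, "P2": 711, "A": 541, "A*": 114},
    "B7": {"P1": 797, "P2": 246, "P*": 74, "A3": 68, "A2": 38, "A1": 169, "A": 836},
    "B9": {"P": 1471, "P*": 415, "A": 342},
    "B12": {"P1": 628, "P2": 97, "Aba": 32, "Acbr": 43, "Acbi": 193, "A": 1235},
    "Q": {"P": 1109, "Ac": 62, "Ao": 42, "Ap": 601, "Aq": 297, "A": 117},
}


class ConfigError(ValueError):
    """Raised for unsatisfiable or inconsistent simulation configurations."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic reference and community generator."""

    seed: int = 0
    # Reference collection shape.
    n_phyla: int = 2
    n_families_per_phylum: int = 2
    n_genera_per_family: int = 3
    n_species_per_genus: int = 3
    strains_per_species: tuple[int, int] = (1, 4)  # inclusive range
    variant_freqs: Mapping[str, Mapping[str, float]] | None = None
    flip_rate: float = 0.01  # P(strain deviates from species consensus)
    decoy_rate: float = 3.0  # Poisson mean of non-vocabulary decoy roles
    # Community shape.
    n_samples: int = 5
    n_otus: int = 60
    dirichlet_alpha: float = 0.3
    depth: float = 50_000.0
    rank_mixture: tuple[float, float, float, float] = (0.77, 0.19, 0.03, 0.01)
    copy_number_range: tuple[float, float] = (1.0, 15.0)

    def __post_init__(self) -> None:
        if abs(sum(self.rank_mixture) - 1.0) > 1e-9:
            raise ConfigError("rank_mixture must sum to 1")
        if not 0.0 <= self.flip_rate <= 1.0:
            raise ConfigError("flip_rate must lie in [0, 1]")
        lo, hi = self.strains_per_species
        if lo < 1 or hi < lo:
            raise ConfigError("invalid strains_per_species range")
        if self.copy_number_range[0] <= 0:
            raise ConfigError("copy numbers must be positive")


@dataclass
class SyntheticReference:
    """Reference collection with planted ground truth."""

    profiles: list[GenePresenceProfile]
    taxonomy: pd.DataFrame               # genome_id x 6 ranks
    true_variants: pd.DataFrame          # genome_id x vitamin, planted codes
    true_phenotypes: pd.DataFrame        # genome_id x vitamin, planted 0/1
    ruleset: RuleSet = field(repr=False, default=None)  # type: ignore[assignment]

    def bpm(self) -> BinaryPhenotypeMatrix:
        return build_bpm(self.profiles, self.ruleset)


@dataclass
class SyntheticCommunity:
    """Community profiles plus analytic ground truth."""

    counts: pd.DataFrame        # OTU x sample weighted read counts
    abundances: pd.DataFrame    # OTU x sample generating (cell) abundances
    assignments: pd.DataFrame   # otu_id -> (rank, taxon)
    copy_numbers: pd.DataFrame  # (taxon, rank, mean_copies)
    true_genomes: pd.Series     # otu_id -> generating genome
    truth_cpi: pd.DataFrame     # sample x vitamin, % over mapped abundance
    truth_unmapped: pd.Series   # sample -> unmapped abundance fraction


def _normalized_freqs(
    config: SimulationConfig, ruleset: RuleSet
) -> dict[str, tuple[list[str], np.ndarray]]:
    out = {}
    for vitamin in VITAMINS:
        base: Mapping[str, float] = DEFAULT_VARIANT_COUNTS[vitamin]
        if config.variant_freqs and vitamin in config.variant_freqs:
            base = config.variant_freqs[vitamin]
        known = ruleset.codes(vitamin)
        unknown = set(base) - set(known)
        if unknown:
            raise ConfigError(
                f"variant code(s) {sorted(unknown)} not defined for {vitamin}"
            )
        codes = [c for c in known if base.get(c, 0) > 0]
        if not codes:
            raise ConfigError(f"no positive variant frequency for {vitamin}")
        p = np.array([base[c] for c in codes], dtype=float)
        out[vitamin] = (codes, p / p.sum())
    return out


def _roles_for_variant(
    rng: np.random.Generator, ruleset: RuleSet, vitamin: str, code: str
) -> set[str]:
    """Role set that the rule engine provably assigns the planted variant.

    Required terms contribute one random alternative, optional terms a random
    alternative half of the time; the assignment is re-checked and resampled
    because a particular draw may complete an earlier (more specific) rule.
    """
    rule = ruleset.rule(vitamin, code)
    candidates: list[set[str]] = []
    for _ in range(25):
        roles = set()
        for term in rule.terms:
            if term.required or rng.random() < 0.5:
                roles.add(str(rng.choice(term.alternatives)))
        candidates.append(roles)
    candidates.append(set(rule.minimal_profile()))
    for roles in candidates:
        probe = GenePresenceProfile("probe", frozenset(roles))
        if assign_variant(probe, ruleset, vitamin).variant_code == code:
            return roles
    raise ConfigError(
        f"cannot construct a profile assigned variant {code!r} for {vitamin}"
    )


def simulate_reference(
    config: SimulationConfig, ruleset: RuleSet | None = None
) -> SyntheticReference:
    """Generate a reference collection with planted pathway variants.

    Each species draws a consensus variant per vitamin from the configured
    frequencies; each strain deviates from the consensus with probability
    ``flip_rate`` by drawing a variant of the opposite binary phenotype.
    Emitted profiles carry the planted rule's roles plus decoy roles outside
    the vocabulary; planted-variant recovery is verified exhaustively.
    """
    ruleset = ruleset or load_default_ruleset()
    rng = np.random.default_rng(config.seed)
    freqs = _normalized_freqs(config, ruleset)
    phenotype_of = {
        v: {r.variant_code: r.binary_phenotype for r in ruleset.rules[v]}
        for v in VITAMINS
    }

    profiles: list[GenePresenceProfile] = []
    tax_rows, variant_rows, pheno_rows = [], [], []
    genome_ids = []
    g_idx = 0
    for p in range(config.n_phyla):
        phylum, clazz, order = f"Phylum{p + 1}", f"Class{p + 1}", f"Order{p + 1}"
        for f in range(config.n_families_per_phylum):
            family = f"Family{p + 1}_{f + 1}"
            for _ in range(config.n_genera_per_family):
                g_idx += 1
                genus = f"Genus{g_idx:03d}"
                for s in range(config.n_species_per_genus):
                    species = f"{genus} sp{s + 1}"
                    lo, hi = config.strains_per_species
                    n_strains = int(rng.integers(lo, hi + 1))
                    consensus = {
                        v: str(rng.choice(codes, p=pr))
                        for v, (codes, pr) in freqs.items()
                    }
                    for t in range(n_strains):
                        genome_id = f"{genus}_{s + 1}_strain{t + 1}"
                        planted = {}
                        for v in VITAMINS:
                            code = consensus[v]
                            if rng.random() < config.flip_rate:
                                codes, pr = freqs[v]
                                opposite = [
                                    c for c in codes
                                    if phenotype_of[v][c] != phenotype_of[v][code]
                                ]
                                if opposite:
                                    w = np.array(
                                        [pr[codes.index(c)] for c in opposite]
                                    )
                                    code = str(rng.choice(opposite, p=w / w.sum()))
                            planted[v] = code
                        roles: set[str] = set()
                        for v in VITAMINS:
                            roles |= _roles_for_variant(rng, ruleset, v, planted[v])
                        for _ in range(rng.poisson(config.decoy_rate)):
                            roles.add(f"Unk{rng.integers(0, 1000):03d}")
                        profile = GenePresenceProfile(genome_id, frozenset(roles))
                        # Exhaustive planted-variant recovery check.
                        for v in VITAMINS:
                            got = assign_variant(profile, ruleset, v).variant_code
                            if got != planted[v]:
                                raise AssertionError(
                                    f"planted {planted[v]} for {v} in "
                                    f"{genome_id} but engine assigned {got}"
                                )
                        profiles.append(profile)
                        genome_ids.append(genome_id)
                        tax_rows.append(
                            [species, genus, family, order, clazz, phylum]
                        )
                        variant_rows.append([planted[v] for v in VITAMINS])
                        pheno_rows.append(
                            [phenotype_of[v][planted[v]] for v in VITAMINS]
                        )

    index = pd.Index(genome_ids, name="genome_id")
    taxonomy = pd.DataFrame(
        tax_rows, index=index,
        columns=["species", "genus", "family", "order", "class", "phylum"],
    )
    return SyntheticReference(
        profiles=profiles,
        taxonomy=taxonomy,
        true_variants=pd.DataFrame(variant_rows, index=index, columns=list(VITAMINS)),
        true_phenotypes=pd.DataFrame(pheno_rows, index=index, columns=list(VITAMINS)),
        ruleset=ruleset,
    )


def _hierarchical_genome_draw(
    rng: np.random.Generator, rank: str, taxon: str, taxonomy: pd.DataFrame
) -> str:
    """Draw a true genome from a taxon according to the hierarchical mapping
    weights (uniform species within the taxon, uniform strain within the
    species) so the pipeline's CPM is the exact expectation of the truth."""
    if rank == "species":
        pool = taxonomy.index[taxonomy["species"] == taxon]
        return str(rng.choice(pool))
    if rank == "genus":
        sub = taxonomy[taxonomy["genus"] == taxon]
        species = str(rng.choice(sub["species"].unique()))
        return _hierarchical_genome_draw(rng, "species", species, taxonomy)
    if rank == "family":
        sub = taxonomy[taxonomy["family"] == taxon]
        genus = str(rng.choice(sub["genus"].unique()))
        return _hierarchical_genome_draw(rng, "genus", genus, taxonomy)
    raise ValueError(rank)


def simulate_community(
    config: SimulationConfig, reference: SyntheticReference
) -> SyntheticCommunity:
    """Generate per-sample OTU tables with analytic ground-truth CPIs.

    Each OTU is one true organism: a reference genome drawn from its assigned
    taxon with the hierarchical mapping weights, so the pipeline's
    probabilistic phenotype P_i is the exact expectation of the OTU's true
    binary phenotype. Emitted counts are cell abundances multiplied by the
    taxon's 16S copy number (and sequencing depth), so copy-number
    renormalization recovers the generating abundances exactly.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5EED]).generate_state(1)[0]
    )
    taxonomy = reference.taxonomy
    pools = {
        "species": sorted(taxonomy["species"].unique()),
        "genus": sorted(taxonomy["genus"].unique()),
        "family": sorted(taxonomy["family"].unique()),
    }

    otu_ids, ranks, taxa, true_genomes = [], [], [], []
    labels = ("species", "genus", "family", "unmapped")
    for i in range(config.n_otus):
        otu_id = f"OTU{i + 1:04d}"
        rank = labels[int(rng.choice(4, p=list(config.rank_mixture)))]
        if rank == "unmapped":
            ranks.append("order")
            taxa.append(f"NovelOrder{i + 1}")
            true_genomes.append("")  # excluded from prediction and truth
        else:
            taxon = str(rng.choice(pools[rank]))
            ranks.append(rank)
            taxa.append(taxon)
            true_genomes.append(
                _hierarchical_genome_draw(rng, rank, taxon, taxonomy)
            )
        otu_ids.append(otu_id)

    assignments = pd.DataFrame(
        {"rank": ranks, "taxon": taxa}, index=pd.Index(otu_ids, name="otu_id")
    )
    true_genomes = pd.Series(true_genomes, index=assignments.index, name="genome_id")

    # One copy-number record per assigned mapped taxon.
    lo, hi = config.copy_number_range
    mapped_taxa = sorted(
        {(t, r) for t, r in zip(taxa, ranks) if r in pools}
    )
    copy_numbers = pd.DataFrame(
        {
            "taxon": [t for t, _ in mapped_taxa],
            "rank": [r for _, r in mapped_taxa],
            "mean_copies": rng.uniform(lo, hi, size=len(mapped_taxa)),
        }
    )
    cn_of = {
        (t, r): c
        for t, r, c in zip(
            copy_numbers["taxon"], copy_numbers["rank"], copy_numbers["mean_copies"]
        )
    }
    global_cn = float(copy_numbers["mean_copies"].mean()) if len(cn_of) else 1.0
    otu_cn = np.array(
        [cn_of.get((t, r), global_cn) for t, r in zip(taxa, ranks)]
    )

    abund = rng.dirichlet(
        np.full(config.n_otus, config.dirichlet_alpha), size=config.n_samples
    ).T  # OTU x sample
    samples = [f"S{j + 1:03d}" for j in range(config.n_samples)]
    abundances = pd.DataFrame(abund, index=assignments.index, columns=samples)
    counts = abundances.mul(otu_cn, axis=0) * config.depth

    mapped = true_genomes != ""
    pheno = reference.true_phenotypes.astype(float)
    truth_rows, unmapped_frac = {}, {}
    for sample in samples:
        a = abundances[sample]
        a_mapped = a[mapped]
        total = a_mapped.sum()
        unmapped_frac[sample] = float(1.0 - total)
        if total <= 0:
            truth_rows[sample] = pd.Series(np.nan, index=list(VITAMINS))
            continue
        p_true = pheno.loc[true_genomes[mapped].values]
        p_true.index = a_mapped.index
        truth_rows[sample] = 100.0 * p_true.mul(a_mapped / total, axis=0).sum()
    truth_cpi = pd.DataFrame(truth_rows).T
    truth_cpi.index.name = "sample"

    return SyntheticCommunity(
        counts=counts,
        abundances=abundances,
        assignments=assignments,
        copy_numbers=copy_numbers,
        true_genomes=true_genomes,
        truth_cpi=truth_cpi,
        truth_unmapped=pd.Series(unmapped_frac, name="unmapped_fraction"),
    )
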