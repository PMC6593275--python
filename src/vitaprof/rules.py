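"""Genomic-signature rule engine for vitamin pathway-variant assignment.

A rule file declares a controlled vocabulary of functional roles (signature
genes of biosynthetic and salvage pathways) and, per micronutrient, an ordered
list of pathway-variant rules. Each rule is a conjunction of signature terms;
a term is an any-of group of alternative roles and may be optional. A genome,
represented by the set of functional roles called in its annotation, is
assigned the first rule (most-complete-first order) whose required terms are
all satisfied, yielding a pathway-variant code and a binary phenotype:
1 for prototrophy (de novo biosynthesis capability), 0 for auxotrophy.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical micronutrient order used by every matrix and barcode.
VITAMINS: tuple[str, ...] = ("B1", "B2", "B3", "B5", "B6", "B7", "B9", "B12", "Q")

#: Variant code reserved for genomes matching no rule of a vitamin.
FALLBACK_CODE = "A!"


class RuleParseError(ValueError):
    """Raised when a signature rule document violates the DSL grammar."""


@dataclass(frozen=True)
class SignatureTerm:
    """One conjunct of a pathway signature: an any-of group of roles."""

    alternatives: tuple[str, ...]
    required: bool = True

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValueError("signature term needs at least one alternative")
        if len(set(self.alternatives)) != len(self.alternatives):
            raise ValueError(f"duplicate role within term {self.alternatives}")

    def satisfied_by(self, roles: frozenset[str] | set[str]) -> bool:
        return any(a in roles for a in self.alternatives)

    def render(self) -> str:
        body = "/".join(self.alternatives)
        return body if self.required else f"({body})"


@dataclass(frozen=True)
class VariantRule:
    """An ordered pathway-variant rule for one vitamin."""

    vitamin: str
    variant_code: str
    terms: tuple[SignatureTerm, ...]
    binary_phenotype: int
    order_index: int
    requirements_note: str = ""

    def __post_init__(self) -> None:
        if self.binary_phenotype not in (0, 1):
            raise ValueError("binary phenotype must be 0 or 1")
        # P-codes are prototrophic, A-codes auxotrophic, by construction.
        expected = {"P": 1, "A": 0}.get(self.variant_code[:1])
        if expected is not None and expected != self.binary_phenotype:
            raise ValueError(
                f"variant {self.variant_code!r} has binary phenotype "
                f"{self.binary_phenotype}, inconsistent with its code letter"
            )

    @property
    def required_terms(self) -> tuple[SignatureTerm, ...]:
        return tuple(t for t in self.terms if t.required)

    def minimal_profile(self) -> frozenset[str]:
        """Smallest role set satisfying the rule (first alternative of each
        required term)."""
        return frozenset(t.alternatives[0] for t in self.required_terms)

    def render(self) -> str:
        sig = ", ".join(t.render() for t in self.terms) if self.terms else "-"
        line = f"{self.variant_code} {self.binary_phenotype} : {sig}"
        if self.requirements_note:
            line += f" | {self.requirements_note}"
        return line


@dataclass
class RuleSet:
    """Ordered pathway-variant rules per vitamin plus the role vocabulary."""

    vocabulary: frozenset[str]
    rules: dict[str, list[VariantRule]]

    def __post_init__(self) -> None:
        for vitamin, rules in self.rules.items():
            if not rules:
                raise ValueError(f"vitamin {vitamin} has no rules")
            for i, rule in enumerate(rules):
                if rule.order_index != i:
                    raise ValueError(f"order indices for {vitamin} are not dense")

    @property
    def vitamins(self) -> tuple[str, ...]:
        return tuple(self.rules)

    def codes(self, vitamin: str) -> list[str]:
        return [r.variant_code for r in self.rules[vitamin]]

    def rule(self, vitamin: str, variant_code: str) -> VariantRule:
        for r in self.rules[vitamin]:
            if r.variant_code == variant_code:
                return r
        raise KeyError(f"no variant {variant_code!r} for {vitamin}")


@dataclass(frozen=True)
class GenePresenceProfile:
    """Set of functional roles called in one reference genome."""

    genome_id: str
    roles_present: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")


@dataclass(frozen=True)
class VariantAssignment:
    """Pathway variant assigned to one genome for one vitamin."""

    genome_id: str
    vitamin: str
    variant_code: str
    binary_phenotype: int
    matched_required_roles: frozenset[str] = frozenset()
    matched_optional_roles: frozenset[str] = frozenset()
    is_fallback: bool = False


@dataclass
class BinaryPhenotypeMatrix:
    """Genome x micronutrient binary phenotypes with parallel variant codes.

    ``phenotypes`` holds 0/1 integers (1 = prototroph), ``variants`` the
    pathway-variant code strings; both are indexed by genome id with columns
    in canonical vitamin order.
    """

    phenotypes: pd.DataFrame
    variants: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        bad = set(self.phenotypes.to_numpy().ravel()) - {0, 1}
        if bad:
            raise ValueError(f"non-binary phenotype values: {sorted(bad)}")
        if self.phenotypes.index.has_duplicates:
            dupes = self.phenotypes.index[self.phenotypes.index.duplicated()]
            raise ValueError(f"duplicate genome ids: {sorted(set(dupes))}")

    @property
    def genome_ids(self) -> pd.Index:
        return self.phenotypes.index

    def barcode(self, genome_id: str) -> str:
        return "".join(str(int(v)) for v in self.phenotypes.loc[genome_id])


_RULE_LINE = re.compile(r"^(?P<code>\S+)\s+(?P<bp>[01])\s*:\s*(?P<sig>[^|]*?)\s*(?:\|\s*(?P<note>.*))?$")


def parse_ruleset(rule_text: str) -> RuleSet:
    """Parse a signature-rule document into a :class:`RuleSet`.

    The grammar is line-oriented: a ``[vocabulary]`` block of role names,
    then one ``[VITAMIN]`` block per micronutrient containing ordered variant
    lines ``CODE BP : term, term, ...``. ``(X)`` marks an optional term,
    ``X/Y/Z`` an any-of group, ``-`` an empty signature matching any genome.
    """
    vocabulary: set[str] = set()
    rules: dict[str, list[VariantRule]] = {}
    section: str | None = None

    for lineno, raw in enumerate(rule_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip()
            if section != "vocabulary" and section not in rules:
                rules[section] = []
            continue
        if section is None:
            raise RuleParseError(f"line {lineno}: content before any section header")
        if section == "vocabulary":
            vocabulary.update(line.split())
            continue
        m = _RULE_LINE.match(line)
        if m is None:
            raise RuleParseError(f"line {lineno}: cannot parse rule line {line!r}")
        code = m.group("code")
        if code in {r.variant_code for r in rules[section]}:
            raise RuleParseError(
                f"line {lineno}: duplicate variant code {code!r} for {section}"
            )
        terms = _parse_terms(m.group("sig"), vocabulary, lineno)
        try:
            rule = VariantRule(
                vitamin=section,
                variant_code=code,
                terms=terms,
                binary_phenotype=int(m.group("bp")),
                order_index=len(rules[section]),
                requirements_note=(m.group("note") or "").strip(),
            )
        except ValueError as exc:
            raise RuleParseError(f"line {lineno}: {exc}") from exc
        rules[section].append(rule)

    if not vocabulary:
        raise RuleParseError("document declares no vocabulary")
    empty = [v for v, rr in rules.items() if not rr]
    if empty:
        raise RuleParseError(f"vitamins without rules: {empty}")
    return RuleSet(vocabulary=frozenset(vocabulary), rules=rules)


def _parse_terms(
    signature: str, vocabulary: set[str], lineno: int
) -> tuple[SignatureTerm, ...]:
    signature = signature.strip()
    if signature in ("-", "–", ""):
        return ()
    terms: list[SignatureTerm] = []
    for chunk in signature.split(","):
        chunk = chunk.strip()
        required = True
        if chunk.startswith("(") and chunk.endswith(")"):
            required = False
            chunk = chunk[1:-1].strip()
        alternatives = tuple(a.strip() for a in chunk.split("/"))
        if any(not a for a in alternatives):
            raise RuleParseError(f"line {lineno}: empty any-of group in {chunk!r}")
        unknown = [a for a in alternatives if a not in vocabulary]
        if unknown:
            raise RuleParseError(
                f"line {lineno}: role(s) {unknown} not in vocabulary"
            )
        try:
            terms.append(SignatureTerm(alternatives=alternatives, required=required))
        except ValueError as exc:
            raise RuleParseError(f"line {lineno}: {exc}") from exc
    return tuple(terms)


def render_ruleset(ruleset: RuleSet) -> str:
    """Serialize a rule set back to the DSL (parse ∘ render is the identity
    up to whitespace and comments)."""
    lines = ["[vocabulary]", " ".join(sorted(ruleset.vocabulary)), ""]
    for vitamin, rules in ruleset.rules.items():
        lines.append(f"[{vitamin}]")
        lines.extend(r.render() for r in rules)
        lines.append("")
    return "\n".join(lines)


def load_default_ruleset() -> RuleSet:
    """Load the bundled rule file covering the nine micronutrients."""
    text = (
        resources.files("vitaprof.data").joinpath("vitamin_rules.txt").read_text()
    )
    return parse_ruleset(text)


def match_rule(profile: GenePresenceProfile, rule: VariantRule) -> bool:
    """True iff every required term of the rule has at least one alternative
    present in the profile; optional terms never affect the result."""
    return all(t.satisfied_by(profile.roles_present) for t in rule.required_terms)


def assign_variant(
    profile: GenePresenceProfile, ruleset: RuleSet, vitamin: str
) -> VariantAssignment:
    """Assign the first matching pathway variant for one vitamin.

    Rules are scanned in document order (most complete first, mirroring the
    subsumption structure of the signatures); if none matches, the reserved
    fallback code ``A!`` with auxotrophic phenotype is returned and flagged.
    """
    for rule in ruleset.rules[vitamin]:
        if match_rule(profile, rule):
            req = frozenset(
                a
                for t in rule.required_terms
                for a in t.alternatives
                if a in profile.roles_present
            )
            opt = frozenset(
                a
                for t in rule.terms
                if not t.required
                for a in t.alternatives
                if a in profile.roles_present
            )
            return VariantAssignment(
                genome_id=profile.genome_id,
                vitamin=vitamin,
                variant_code=rule.variant_code,
                binary_phenotype=rule.binary_phenotype,
                matched_required_roles=req,
                matched_optional_roles=opt,
            )
    return VariantAssignment(
        genome_id=profile.genome_id,
        vitamin=vitamin,
        variant_code=FALLBACK_CODE,
        binary_phenotype=0,
        is_fallback=True,
    )


def build_bpm(
    profiles: Sequence[GenePresenceProfile] | Iterable[GenePresenceProfile],
    ruleset: RuleSet,
    vitamins: Sequence[str] = VITAMINS,
) -> BinaryPhenotypeMatrix:
    """Assign variants for every genome and vitamin and assemble the binary
    phenotype matrix (rows: genomes, columns: canonical vitamin order).

    Roles absent from the rule vocabulary are ignored by matching; the union
    of unknown roles seen in a run is reported once through the module logger.
    """
    profiles = list(profiles)
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate genome ids: {dupes}")

    unknown: set[str] = set()
    pheno_rows, code_rows = [], []
    for profile in profiles:
        unknown |= profile.roles_present - ruleset.vocabulary
        assignments = [assign_variant(profile, ruleset, v) for v in vitamins]
        pheno_rows.append([a.binary_phenotype for a in assignments])
        code_rows.append([a.variant_code for a in assignments])
    if unknown:
        logger.info(
            "%d role(s) outside the rule vocabulary were ignored (e.g. %s)",
            len(unknown),
            ", ".join(sorted(unknown)[:5]),
        )
    index = pd.Index(ids, name="genome_id")
    return BinaryPhenotypeMatrix(
        phenotypes=pd.DataFrame(pheno_rows, index=index, columns=list(vitamins)),
        variants=pd.DataFrame(code_rows, index=index, columns=list(vitamins)),
    )
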