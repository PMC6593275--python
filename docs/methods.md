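# Methods

## Phenotype model

The package predicts prototrophy/auxotrophy for eight B-vitamins and
queuosine (canonical order B1, B2, B3, B5, B6, B7, B9, B12, Q; this order is
fixed everywhere, including barcodes). The unit of prediction is a *pathway
variant*: a named combination of biosynthetic and salvage signature genes.
The bundled rule file encodes, per vitamin, an ordered list of variant
signatures over a controlled vocabulary of functional roles. A signature is
a conjunction of terms; a term is an any-of group of alternative roles
(`ThiL/ThiN`) and may be optional (`(ThiF)`), in which case it documents the
canonical pathway but never affects matching. An empty signature (`-`)
matches every genome.

Assignment is strict first-match in file order. The rule lists are ordered
most-complete-first, so subsumed signatures (e.g. the thiamine salvage
variants `Ah`, `Az`, `Ahz`, `A`, each a subset of the one before) are only
reached when every more complete variant fails. One block required a
re-ordering relative to a strictly "by phenotype letter" listing: the niacin
variant `Aq` (which adds `NadC` to the `A` signature) must precede `A`, or
it could never match. Codes beginning with `P` carry binary phenotype 1
(prototroph), codes with `A` carry 0 (auxotroph); this is enforced at parse
time. Genomes matching no rule of a vitamin receive the reserved fallback
code `A!` with phenotype 0 — auxotrophy is the conservative default — and
are flagged. Roles in a genome's annotation that are not in the rule
vocabulary are ignored (real annotation tables carry thousands of irrelevant
roles); the union of ignored roles is logged once per run. Growth-requirement
notes and transporter information are carried as annotations only and never
influence the phenotype.

## Taxonomic aggregation and variability

Averaged prototrophy values at a rank are computed hierarchically: species
means average strains, genus means average species means, and so on. This
gives each child taxon equal weight, so a species with 60 sequenced strains
does not dominate its genus; it also matches the weighting used for
community profiling. A `pooled` mode (flat mean over member genomes) is
exposed for sensitivity analysis, since the alternative convention is also
defensible. Genomes without a species epithet participate as singleton
pseudo-species keyed by genome id.

Variability within a taxon uses the taxon's aggregation units (strains at
species rank, child means above): per vitamin the *unbiased* sample variance
(n−1 denominator), summed over the nine vitamins as OPVS. The unbiased form
is the one consistent with both the worked two-strain anchors (six differing
phenotypes → OPVS 3; a balanced single-vitamin split → score 0.5) and the
metric's stated range 0–4.5; the population variance would give half those
values. NVP counts vitamins whose unit values are not all equal (tolerance
1e−12 to absorb float noise in child means). Singleton taxa report
NVP = OPVS = 0.

## Community profiling

OTU assignments are mapped at species, genus or family rank. Weights are
uniform over a species' strains; at genus rank, 1/(number of species) split
uniformly within each species (a mean of species means); at family rank the
same nesting one level deeper. A species name absent from the reference
falls back to its genus (first token of the binomial) when that genus is
present. Assignments above family rank, or naming unknown taxa, are
unmapped: excluded from prediction but reported in the per-rank coverage
bookkeeping, which always sums to 1. A `flat` weighting mode (uniform over
all genomes under the taxon) is available for sensitivity checks.

Per sample, abundances are re-closed over mapped OTUs, so the prototrophy
and auxotrophy indices are exact complements (CPI_proto + CPI_auxo = 100).
Samples with zero mapped abundance yield missing values, not zeros. The
prediction error is reported in two forms: the variance-form sum
Σ A²P(1−P) (`sigma_raw`, 0–1 scale) and its square root on the percentage
scale (`sigma`). The square root is the primary form: it is the standard
deviation of the community phenotype under the model in which each OTU's
true phenotype is an independent Bernoulli(P_i) draw, and it is the scale on
which single-digit-percent errors are meaningful (a lone OTU with P = 0.5
gives σ = 50%, the Bernoulli standard deviation).

16S copy-number correction divides each OTU's counts by the mean copy
number of its assigned taxon before closure, looked up at the assignment
rank and falling back species → genus → family (resolved through the
reference taxonomy) → the global mean of the table. The global-mean fallback
(rather than 1) avoids systematically over-weighting uncorrected OTUs among
corrected ones; fallbacks are logged per taxon. Correction with all-equal
copy numbers is exactly a no-op on relative abundances.

## Barcodes and the Poisson-binomial null

Observed barcode frequencies use the same weights and re-closed abundances
as the CPIs: P_obs(b) = Σ_i A_i Σ_m w_im [barcode(m) = b]. Collapsing
barcodes by digit sum gives the observed VPR distribution. The null model
treats the nine phenotypes as independent Bernoulli trials with the
sample's CPIs (0–1 scale) as probabilities; the exact Poisson-binomial pmf
over ranks 0–9 is computed by iterative convolution (9 steps, no
approximation). Because both constructions are linear in the same
marginals, the mean observed VPR, the mean expected VPR, and Σ CPI/100
coincide exactly; this identity is asserted in tests to 1e−9.

Log10 observed/expected ratios emit a missing value where P_obs = 0 and an
infinity flag where P_exp = 0 but P_obs > 0 — no pseudocounts, so reported
ratios never contain fabricated mass. Ranks are also reported grouped into
bins 0–3 / 4–6 / 7–9 (configurable); ratios are available both per-rank and
on grouped sums, since the two orders of operations differ.

## Synthetic data generator

The generator emulates the statistical structure of a curated gut reference
collection and an amplicon survey; defaults are fixed once from that
structure:

- **Variant frequencies** per vitamin default to the composition of a
  2,228-genome curated human gut collection (e.g. B2: 74% `P`, 26% `A`).
- **Intraspecies flip rate** 0.01: each strain deviates from its species'
  consensus variant (to a variant of the opposite phenotype) with this
  probability per vitamin, which puts ~15% of two-strain species at one or
  more variable phenotypes, the level seen in curated collections.
- **Assignment-rank mixture** 77/19/3/1 (species/genus/family/unmapped),
  matching typical species-level mapping coverage of gut 16S surveys.
- **Abundances** are symmetric Dirichlet (α = 0.3, a long-tailed gut-like
  profile); **copy numbers** are uniform on 1–15 per assigned taxon.
- Default reference shape: 2 phyla × 2 families × 3 genera × 3 species ×
  1–4 strains (~90 genomes); tests that need more power scale these knobs
  up explicitly (e.g. 1,152 species for the flip-rate calibration).

Profiles are built from the planted rule (one random alternative per
required term, optional roles at 50%) plus decoy roles drawn outside the
vocabulary, and planted-variant recovery by the rule engine is verified
exhaustively at generation time. Each OTU is one true organism: a genome
drawn from its assigned taxon with the hierarchical mapping weights, so the
pipeline's P_i is the exact expectation of the OTU's true phenotype and the
3σ parameter-recovery check is well-posed. Emitted counts are expected
values (cell abundance × copy number × depth), not multinomial reads:
read-sampling noise and taxonomic misassignment are deliberately out of
scope, and σ does not model sequencing depth. Consequently, passing tests
demonstrate correctness of the mapping/averaging arithmetic and calibration
of σ against mapping imprecision and phenotype heterogeneity — not
robustness to sequencing noise, chimeras, or misassigned OTUs in real data.

With a fixed seed the generator is fully deterministic (byte-identical
output files), and the provenance record written by every CLI command
(inputs, parameters, seed, library versions) suffices to re-run a bundle
bit-identically.

## Numerical choices and problem sizes

- Mapping weights must sum to 1 within 1e−9; barcode distributions are
  checked to the same tolerance.
- Exact-equality comparisons on child means use a 1e−12 tolerance.
- Reports render missing values as `NA`; numeric fields are written with 12
  significant digits.
- The calibration suite uses 200 independent communities of 40 OTUs × 2
  samples against one ~90-genome reference; the exhaustive variability
  maxima scan covers all strain configurations up to n = 6 and balanced
  splits up to n = 20.

## Known limitations

- The rule engine consumes already-called functional roles; annotation
  quality is entirely upstream. Negative conditions (absence tests) are not
  expressible in the DSL — starred variants are handled purely by rule
  order, which reproduces the published variant tables but may differ from
  the original curators' tie-breaking in unstated corner cases.
- Genus fallback for unknown species keys on the first token of the
  binomial, which assumes conventional binomial naming.
- BIOM support is import-only and minimal (CSR observation matrix of a
  BIOM 2.x HDF5 file); taxonomy metadata embedded in BIOM files is ignored —
  assignments are a separate input by design.
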