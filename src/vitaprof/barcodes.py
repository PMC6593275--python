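"""Phenotypic barcodes, vitamin prototrophy ranks and the Poisson-binomial
null model.

A phenotypic barcode is the ordered nine-digit binary string of one genome's
vitamin phenotypes (canonical order B1, B2, B3, B5, B6, B7, B9, B12, Q; 512
possible values). Its digit sum is the vitamin prototrophy rank (VPR): 0 for
a complete auxotroph, 9 for a complete prototroph. Per sample, observed
barcode frequencies are computed by the same hierarchical mapping weights
and abundances as the CPIs, each barcode treated as a composite phenotype:

    P_obs(b) = sum_i A_i sum_m w_im [barcode(m) = b]

Under the null hypothesis that the nine phenotypes are independent across
organisms, the VPR follows a Poisson binomial distribution whose nine trial
probabilities are the sample's CPIs (0–1 scale); the exact pmf is obtained by
iterative convolution. Observed/expected ratios are reported as log10 values,
with missing values where P_obs = 0 and +inf flags where an outcome with
P_exp = 0 is nonetheless observed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiling import MappingWeights, mapped_abundances
from .rules import VITAMINS, BinaryPhenotypeMatrix

N_VITAMINS = len(VITAMINS)
BARCODE_SPACE = 2 ** N_VITAMINS  # 512

#: Rank bins used for grouped reporting (extreme auxotrophs, intermediate,
#: extreme prototrophs).
DEFAULT_RANK_BINS: tuple[tuple[int, int], ...] = ((0, 3), (4, 6), (7, 9))


def vpr(barcode: str) -> int:
    """Vitamin prototrophy rank: the digit sum of a nine-digit barcode."""
    if not isinstance(barcode, str) or len(barcode) != N_VITAMINS:
        raise ValueError(f"barcode must be a {N_VITAMINS}-character string: {barcode!r}")
    if set(barcode) - {"0", "1"}:
        raise ValueError(f"barcode may contain only 0/1 digits: {barcode!r}")
    return sum(int(c) for c in barcode)


def genome_barcodes(bpm: BinaryPhenotypeMatrix) -> pd.Series:
    """Barcode string per reference genome."""
    pheno = bpm.phenotypes.astype(int).astype(str)
    return pheno.apply("".join, axis=1).rename("barcode")


def observed_barcodes(
    weights: MappingWeights,
    counts: pd.DataFrame,
    bpm: BinaryPhenotypeMatrix,
    cpm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Observed barcode frequency distribution per sample.

    Returns a barcode x sample frame whose columns sum to 1 over mapped
    abundance; barcodes never observed are omitted. ``cpm`` (if given) only
    fixes the mapped-OTU universe so abundance renormalization matches the
    CPI computation exactly; by default it is derived from ``weights``.
    """
    barcodes = genome_barcodes(bpm)
    # Per-OTU barcode weight vectors (rows: OTUs, columns: barcodes seen).
    rows = {}
    for otu_id in weights.mapped_ids:
        w = weights[otu_id].weights
        rows[otu_id] = w.groupby(barcodes.loc[w.index]).sum()
    otu_by_barcode = pd.DataFrame(rows).T.fillna(0.0)
    otu_by_barcode.index.name = "otu_id"

    universe = cpm if cpm is not None else otu_by_barcode
    abund = mapped_abundances(counts, universe)
    dist = otu_by_barcode.reindex(abund.index).fillna(0.0).T @ abund
    dist = dist.loc[(dist > 0).any(axis=1)].sort_index()
    dist.index.name = "barcode"
    dist.columns.name = "sample"
    return dist


def observed_vpr(barcode_dist: pd.DataFrame) -> pd.DataFrame:
    """Collapse a barcode distribution to the observed VPR distribution
    (ranks 0..9 x samples)."""
    ranks = pd.Index([vpr(b) for b in barcode_dist.index], name="rank")
    out = barcode_dist.groupby(ranks).sum().reindex(range(N_VITAMINS + 1), fill_value=0.0)
    out.index.name = "rank"
    return out


def expected_vpr(cpis: np.ndarray | pd.Series) -> np.ndarray:
    """Exact Poisson-binomial pmf of the VPR under phenotype independence.

    ``cpis`` are the sample's nine prototrophy CPIs on the 0–1 scale, acting
    as the trial probabilities; the pmf over ranks 0..9 is built by
    convolving one Bernoulli factor at a time.
    """
    p = np.asarray(cpis, dtype=float)
    if p.shape != (N_VITAMINS,):
        raise ValueError(f"expected {N_VITAMINS} trial probabilities, got {p.shape}")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError(f"trial probabilities outside [0, 1]: {p}")
    pmf = np.zeros(N_VITAMINS + 1)
    pmf[0] = 1.0
    for k, pv in enumerate(p, start=1):
        pmf[1 : k + 1] = pmf[1 : k + 1] * (1 - pv) + pmf[:k] * pv
        pmf[0] *= 1 - pv
    return pmf


def expected_vpr_table(cpi_pct: pd.DataFrame) -> pd.DataFrame:
    """Expected VPR distributions for a sample x vitamin CPI table on the
    percentage scale (ranks 0..9 x samples)."""
    out = {
        sample: expected_vpr(row.to_numpy() / 100.0)
        for sample, row in cpi_pct.iterrows()
        if not row.isna().any()
    }
    table = pd.DataFrame(out, index=pd.RangeIndex(N_VITAMINS + 1, name="rank"))
    table.columns.name = "sample"
    return table


def obs_exp_log_ratio(
    observed: pd.DataFrame | pd.Series, expected: pd.DataFrame | pd.Series
) -> pd.DataFrame | pd.Series:
    """log10(P_obs / P_exp) per rank.

    NaN where P_obs = 0 (nothing observed, nothing to report); +inf where
    P_exp = 0 but P_obs > 0 (an impossible outcome under the null was
    observed — flagged, not raised).
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected supports differ")
    out = np.full(obs.shape, np.nan)
    both = (obs > 0) & (exp > 0)
    out[both] = np.log10(obs[both] / exp[both])
    out[(obs > 0) & (exp == 0)] = np.inf
    if isinstance(observed, pd.DataFrame):
        return pd.DataFrame(out, index=observed.index, columns=observed.columns)
    if isinstance(observed, pd.Series):
        return pd.Series(out, index=observed.index)
    return out


def group_ranks(
    dist: pd.DataFrame, bins: tuple[tuple[int, int], ...] = DEFAULT_RANK_BINS
) -> pd.DataFrame:
    """Sum a rank distribution into inclusive rank bins (e.g. 0–3, 4–6, 7–9)."""
    rows = {}
    for lo, hi in bins:
        rows[f"{lo}-{hi}"] = dist.loc[lo:hi].sum()
    out = pd.DataFrame(rows).T
    out.index.name = "rank_bin"
    return out


def taxon_rank_contributions(
    weights: MappingWeights,
    counts: pd.DataFrame,
    bpm: BinaryPhenotypeMatrix,
    taxonomy: pd.DataFrame,
    bins: tuple[tuple[int, int], ...] = DEFAULT_RANK_BINS,
) -> pd.DataFrame:
    """Per-genus summed contribution to each rank bin, averaged over samples.

    For every OTU/genome weight cell, the abundance-weighted mass A_i * w_im
    is attributed to the genome's genus and the VPR of its barcode; masses
    are summed within rank bins and normalised per bin.
    """
    barcodes = genome_barcodes(bpm)
    ranks = barcodes.map(vpr)
    genus = taxonomy["genus"]
    abund = mapped_abundances(
        counts, pd.DataFrame(index=pd.Index(weights.mapped_ids, name="otu_id"))
    )
    cells: dict[tuple[str, str], float] = {}
    n_samples = 0
    for sample in abund.columns:
        col = abund[sample]
        if col.isna().all():
            continue
        n_samples += 1
        for otu_id, a in col[col > 0].items():
            for genome, w in weights[str(otu_id)].weights.items():
                rank = int(ranks.loc[genome])
                for lo, hi in bins:
                    if lo <= rank <= hi:
                        key = (f"{lo}-{hi}", str(genus.loc[genome]))
                        cells[key] = cells.get(key, 0.0) + float(a) * float(w)
                        break
    if n_samples == 0:
        raise ValueError("no sample with mapped abundance")
    table = pd.Series(cells).unstack(fill_value=0.0) / n_samples
    table = table.div(table.sum(axis=1), axis=0)
    table.index.name = "rank_bin"
    table.columns.name = "genus"
    return table
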