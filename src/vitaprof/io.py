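"""Readers and writers for the pipeline's tabular interchange formats.

TSV is the canonical dialect (UTF-8, no quoting, '.' decimal, ``NA`` for
missing values); OTU count tables are additionally accepted as CSV or BIOM
2.x (HDF5, import only). Schema violations are reported naming the offending
column and row.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .rules import VITAMINS, BinaryPhenotypeMatrix, GenePresenceProfile
from .taxonomy import read_taxonomy  # noqa: F401  (part of the io surface)

NA = "NA"
FLOAT_FORMAT = "%.12g"


class SchemaError(ValueError):
    """Raised when an input table violates its declared schema."""


def _require_nonempty(df: pd.DataFrame, what: str) -> pd.DataFrame:
    if df.empty:
        raise SchemaError(f"{what} table is empty")
    return df


# ---------------------------------------------------------------- profiles

def read_gene_presence(path) -> list[GenePresenceProfile]:
    """Read genome gene-presence roles from TSV, auto-detecting layout.

    Long form has columns (genome_id, role); wide form has a genome_id
    column followed by one 0/1 column per role.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_nonempty(df, "gene presence")
    cols = [c.lower() for c in df.columns]
    if len(df.columns) == 2 and cols == ["genome_id", "role"]:
        grouped = df.groupby(df.columns[0])[df.columns[1]].apply(set)
        return [
            GenePresenceProfile(str(g), frozenset(map(str, roles)))
            for g, roles in grouped.items()
        ]
    wide = df.set_index(df.columns[0])
    profiles = []
    for genome_id, row in wide.iterrows():
        try:
            present = row.astype(int) > 0
        except ValueError as exc:
            raise SchemaError(
                f"gene presence: non-binary value in row {genome_id!r}: {exc}"
            ) from exc
        profiles.append(
            GenePresenceProfile(str(genome_id), frozenset(present.index[present]))
        )
    return profiles


def write_gene_presence(profiles, path) -> None:
    rows = [
        {"genome_id": p.genome_id, "role": role}
        for p in profiles
        for role in sorted(p.roles_present)
    ]
    pd.DataFrame(rows, columns=["genome_id", "role"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------- BPM

def write_bpm(bpm: BinaryPhenotypeMatrix, pheno_path, variants_path=None) -> None:
    bpm.phenotypes.to_csv(pheno_path, sep="\t")
    if variants_path is not None and bpm.variants is not None:
        bpm.variants.to_csv(variants_path, sep="\t")


def read_bpm(pheno_path, variants_path=None) -> BinaryPhenotypeMatrix:
    pheno = pd.read_csv(pheno_path, sep="\t", index_col="genome_id")
    _require_nonempty(pheno, "BPM")
    bad = pheno.stack()[~pheno.stack().isin([0, 1])]
    if len(bad):
        genome, vitamin = bad.index[0]
        raise SchemaError(
            f"BPM: non-binary value {bad.iloc[0]!r} at genome {genome!r}, "
            f"column {vitamin!r}"
        )
    variants = (
        pd.read_csv(variants_path, sep="\t", index_col="genome_id", dtype=str)
        if variants_path is not None
        else None
    )
    return BinaryPhenotypeMatrix(phenotypes=pheno.astype(int), variants=variants)


# -------------------------------------------------------------- OTU tables

def read_otu_table(path) -> pd.DataFrame:
    """Read an OTU x sample count table (TSV, CSV, or BIOM 2.x HDF5)."""
    path = Path(path)
    if path.suffix == ".biom":
        return _read_biom_hdf5(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    _require_nonempty(df, "OTU")
    df.index = df.index.astype(str)
    df.index.name = "otu_id"
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise SchemaError("OTU table: non-numeric counts")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise SchemaError(
            f"OTU table: negative count at otu {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return df


def _read_biom_hdf5(path) -> pd.DataFrame:
    """Minimal BIOM 2.x (HDF5) importer: CSR observation matrix only."""
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as f:
        otu_ids = [x.decode() for x in f["observation/ids"][:]]
        sample_ids = [x.decode() for x in f["sample/ids"][:]]
        data = f["observation/matrix/data"][:]
        indices = f["observation/matrix/indices"][:]
        indptr = f["observation/matrix/indptr"][:]
    mat = csr_matrix(
        (data, indices, indptr), shape=(len(otu_ids), len(sample_ids))
    )
    return pd.DataFrame(
        mat.toarray(), index=pd.Index(otu_ids, name="otu_id"), columns=sample_ids
    )


def write_otu_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_nonempty(df, "assignment")
    expected = ["otu_id", "rank", "taxon"]
    if list(df.columns[:3]) != expected:
        raise SchemaError(
            f"assignment table must have columns {expected}, got {list(df.columns)}"
        )
    if df["otu_id"].duplicated().any():
        dupes = df.loc[df["otu_id"].duplicated(), "otu_id"].tolist()
        raise SchemaError(f"assignment table: duplicate otu_id(s) {dupes[:5]}")
    return df.set_index("otu_id")


def write_assignments(assignments: pd.DataFrame, path) -> None:
    assignments.to_csv(path, sep="\t")


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", na_rep=NA)


def write_copy_numbers(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ----------------------------------------------------------------- reports

def write_cpi_report(report, outdir, prefix="cpi") -> None:
    """Write a CPIReport as one TSV per component plus a combined JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    parts = {
        "prototrophy": report.cpi,
        "auxotrophy": report.auxotrophy,
        "sigma": report.sigma,
        "sigma_raw": report.sigma_raw,
        "coverage": report.coverage,
    }
    for name, frame in parts.items():
        frame.to_csv(
            outdir / f"{prefix}_{name}.tsv", sep="\t", na_rep=NA,
            float_format=FLOAT_FORMAT,
        )
    combined = {
        name: json.loads(frame.to_json(orient="index"))
        for name, frame in parts.items()
    }
    (outdir / f"{prefix}_report.json").write_text(json.dumps(combined, indent=1))


def write_rank_distributions(observed, expected, log_ratio, outdir, prefix="vpr"):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    observed.to_csv(outdir / f"{prefix}_observed.tsv", sep="\t",
                    na_rep=NA, float_format=FLOAT_FORMAT)
    expected.to_csv(outdir / f"{prefix}_expected.tsv", sep="\t",
                    na_rep=NA, float_format=FLOAT_FORMAT)
    log_ratio.to_csv(outdir / f"{prefix}_log10_obs_exp.tsv", sep="\t",
                     na_rep=NA, float_format=FLOAT_FORMAT)


def write_barcode_distribution(dist: pd.DataFrame, path) -> None:
    """Write per-sample barcode frequencies (zero-only rows omitted)."""
    dist.to_csv(path, sep="\t", na_rep=NA, float_format=FLOAT_FORMAT)


def write_provenance(path, *, inputs: dict, parameters: dict, seed=None) -> None:
    """Machine-readable run record sufficient to re-run bit-identically."""
    from . import __version__

    record = {
        "tool": "vitaprof",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": parameters,
        "vitamin_order": list(VITAMINS),
    }
    Path(path).write_text(json.dumps(record, indent=1, sort_keys=True))
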