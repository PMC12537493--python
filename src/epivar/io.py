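"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversions to
and from the 1-based closed conventions of allc tables and GFF3 happen
only at the I/O boundary.  TSV with a header row is the interchange
format for all matrices (genes x accessions).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_allc",
    "write_allc",
    "read_annotation",
    "write_gff3",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_matrix",
    "write_matrix",
    "write_manifest",
]

ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "reads_meth", "reads_total"]
_CONTEXTS = {"CG", "CHG", "CHH"}


def read_allc(path) -> pd.DataFrame:
    """Read an allc-style site table (TSV: chrom, pos, strand, context,
    mc_count, total_count; 1-based positions).

    Returns a typed frame with internal 0-based positions.  Malformed
    rows raise with the offending line number."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=ALLC_COLUMNS, comment="#",
            dtype={"chrom": str, "strand": str, "context": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=ALLC_COLUMNS)
    if df.empty:
        import warnings

        warnings.warn(f"{path} is empty; returning empty site table")
        return pd.DataFrame(columns=ALLC_COLUMNS)
    for col in ("pos", "reads_meth", "reads_total"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.where(bad)[0][0]) + 1
            raise ValueError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = df[col].astype(int)
    bad = df["reads_meth"] > df["reads_total"]
    if bad.any():
        line = int(np.where(bad)[0][0]) + 1
        raise ValueError(f"{path}: reads_meth > reads_total at line {line}")
    bad = ~df["context"].isin(_CONTEXTS)
    if bad.any():
        line = int(np.where(bad)[0][0]) + 1
        raise ValueError(f"{path}: unknown context at line {line}")
    df["pos"] = df["pos"] - 1  # to internal 0-based
    return df


def write_allc(df: pd.DataFrame, path) -> None:
    out = df[ALLC_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_annotation(path) -> pd.DataFrame:
    """Read gene spans from GFF3 (1-based closed) or BED (0-based
    half-open), unified to internal half-open coordinates with a
    strand-aware TSS column."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        rows = []
        with open(path) as fh:
            for ln in fh:
                if ln.startswith("#") or not ln.strip():
                    continue
                f = ln.rstrip("\n").split("\t")
                if len(f) < 9:
                    raise ValueError(f"{path}: malformed GFF3 line: {ln[:60]!r}")
                if f[2] not in ("gene", "protein_coding_gene"):
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID") or attrs.get("gene_id") or ""
                rows.append(
                    (gid, f[0], int(f[3]) - 1, int(f[4]), f[6])
                )  # GFF3 1-based closed -> half-open
        genes = pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end", "strand"]
        )
    elif suffix == ".bed":
        genes = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            usecols=range(6),
        )[["gene_id", "chrom", "start", "end", "strand"]]
    else:
        raise ValueError(f"unknown annotation dialect for {path} (use .gff3/.bed)")
    dup = genes["gene_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate gene IDs: {sorted(genes.loc[dup, 'gene_id'].unique())}"
        )
    genes["tss"] = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])
    return genes


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\tepivar\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )


def read_genotypes(path, haploid: bool = True) -> dict:
    """Read a genotype matrix from a minimal VCF or a TSV matrix.

    VCF: biallelic records only (multiallelic rows skipped and counted);
    GT fields coded 0/1 (haploid) or 0/1/2 (diploid dosage).  TSV: SNPs
    as rows, accessions as columns, integer codes.  Returns dict with
    ``genotypes`` (accessions x SNPs), ``accessions``, ``positions``,
    ``n_skipped_multiallelic``."""
    path = Path(path)
    if path.suffix.lower() == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, haploid=haploid)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {
        "genotypes": df.to_numpy(dtype=float).T,
        "accessions": list(df.columns),
        "positions": list(df.index),
        "n_skipped_multiallelic": 0,
    }


def _read_vcf(path, haploid: bool = True) -> dict:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, positions = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        codes = []
        for gt in var.genotypes:  # [allele0, (allele1,) phased]
            alleles = [a for a in gt[:-1] if a >= 0]
            if not alleles:
                codes.append(np.nan)
            else:
                dose = float(sum(alleles))
                codes.append(min(dose, 1.0) if haploid else dose)
        rows.append(codes)
        positions.append(f"{var.CHROM}:{var.POS}")
    G = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return {
        "genotypes": G,
        "accessions": samples,
        "positions": positions,
        "n_skipped_multiallelic": skipped,
    }


def write_genotypes_tsv(genotypes: np.ndarray, accessions, positions, path) -> None:
    pd.DataFrame(
        np.asarray(genotypes).T, index=positions, columns=accessions
    ).to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    """Genes x accessions TSV matrix with header and index column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def write_manifest(path, config: dict, seed: int | None = None) -> None:
    """Record the run configuration (and package version) so a run can be
    reproduced exactly."""
    from epivar import __version__

    manifest = {"package": "epivar", "version": __version__, "seed": seed,
                "config": config}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
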