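"""Readers and writers for the pipeline's on-disk formats.

Variant call sets travel either as VCF (one file per subject-region, with
the pipeline's INFO keys) or as a single long-format TSV; expression
tensors as long-format TSV (gene, region, stage, rpkm); gene sets as GMT;
PPI edges and cohort tables as TSV.  VCF access goes through pysam.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "write_calls_tsv", "read_calls_tsv",
    "write_calls_vcf", "read_calls_vcf", "write_callsets_vcf",
    "write_expression_tsv", "read_expression_tsv",
    "write_gmt", "read_gmt",
    "write_ppi_tsv", "read_ppi_tsv",
    "write_cohort_tsv", "read_cohort_tsv",
    "write_error_model_tsv", "read_error_model_tsv",
]

_CONTIGS = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
_CONTIG_LEN = 250_000_000

_INFO_FIELDS = [
    ("VAF", "1", "Float", "Variant allele fraction"),
    ("DP", "1", "Integer", "Read depth at the site"),
    ("ALTC", "1", "Integer", "Alternate-allele read count"),
    ("EB", "1", "Float", "Empirical-Bayes artifact score"),
    ("CADD", "1", "Float", "Phred-scaled CADD deleteriousness score"),
    ("CSQ", "1", "String", "Consequence annotation"),
    ("CLR", "1", "String", "Caller provenance"),
]


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _vcf_header() -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in _CONTIGS:
        header.contigs.add(contig, length=_CONTIG_LEN)
    for name, number, vtype, desc in _INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    return header


def write_calls_vcf(calls: pd.DataFrame, path: str | Path) -> None:
    """Write one call table (typically one subject-region) as a VCF."""
    header = _vcf_header()
    ordered = calls.sort_values(["chrom", "pos"])
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in ordered.itertuples():
            rec = vcf.new_record(
                contig=row.chrom, start=int(row.pos) - 1,
                stop=int(row.pos), alleles=(row.ref, row.alt),
            )
            rec.info["VAF"] = float(row.vaf)
            rec.info["DP"] = int(row.depth)
            rec.info["ALTC"] = int(row.alt_count)
            rec.info["EB"] = float(row.eb_score)
            if hasattr(row, "cadd") and not pd.isna(row.cadd):
                rec.info["CADD"] = float(row.cadd)
            if hasattr(row, "consequence"):
                rec.info["CSQ"] = str(row.consequence)
            if hasattr(row, "caller"):
                rec.info["CLR"] = str(row.caller)
            vcf.write(rec)


def write_callsets_vcf(calls: pd.DataFrame, directory: str | Path) -> list[Path]:
    """Write one VCF per (subject, tissue); returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for (subject, tissue), grp in calls.groupby(["subject", "tissue"]):
        path = directory / f"{subject}_{tissue}.vcf"
        write_calls_vcf(grp, path)
        paths.append(path)
    return paths


def read_calls_vcf(path: str | Path, subject: str | None = None,
                   tissue: str | None = None) -> pd.DataFrame:
    """Read a pipeline VCF back into the long call-table layout."""
    if subject is None or tissue is None:
        stem = Path(path).stem
        parts = stem.rsplit("_", 1)
        subject = subject or parts[0]
        tissue = tissue or (parts[1] if len(parts) > 1 else "unknown")
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            rows.append({
                "subject": subject, "tissue": tissue,
                "chrom": rec.contig, "pos": rec.pos,
                "ref": rec.ref, "alt": rec.alts[0],
                "vaf": float(info["VAF"]), "depth": int(info["DP"]),
                "alt_count": int(info["ALTC"]), "eb_score": float(info["EB"]),
                "cadd": float(info["CADD"]) if "CADD" in info else np.nan,
                "consequence": str(info.get("CSQ", "")),
                "caller": str(info.get("CLR", "")),
            })
    return pd.DataFrame(rows)


def write_expression_tsv(expression: pd.DataFrame, path: str | Path) -> None:
    expression[["gene", "region", "stage", "rpkm"]].to_csv(
        path, sep="\t", index=False
    )


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(genesets: dict[str, list[str]], path: str | Path,
              description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in genesets.items():
            fh.write("\t".join([name, description or name, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    genesets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 2:
                genesets[fields[0]] = [g for g in fields[2:] if g]
    return genesets


def write_ppi_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    edges[["gene_a", "gene_b", "reliability"]].to_csv(path, sep="\t", index=False)


def read_ppi_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    out = cohort.copy()
    out["regions"] = out["regions"].map(lambda rs: ",".join(rs))
    out.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t")
    cohort["regions"] = cohort["regions"].map(lambda s: s.split(","))
    return cohort


def write_error_model_tsv(rates: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"substitution": list(rates), "rate": list(rates.values())}
    ).to_csv(path, sep="\t", index=False)


def read_error_model_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["substitution"], df["rate"]))
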