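"""Small bundled example tables for worked examples and end-to-end checks.

`example_validated_somatic_calls` transcribes the published set of
amplicon-validated damaging brain somatic SNVs from a deep-WES study of 24
ASD and 31 control postmortem brains: seven variants in seven genes across
six ASD subjects, with VAFs from 0.3% to 3.8%.

The germline gene sets and carrier counts below that are labelled
*synthetic* are stand-ins constructed to match only the published summary
counts (11 germline genes in cases, 4 somatic + 9 germline in controls,
carrier totals 14/24 and 8/31); the underlying per-subject gene lists were
not published, so placeholder identifiers are used.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "example_validated_somatic_calls",
    "synthetic_germline_genesets",
    "synthetic_control_somatic_genesets",
    "example_carrier_counts",
]


def example_validated_somatic_calls() -> pd.DataFrame:
    """Validated damaging brain somatic SNVs of the example ASD cohort.

    One row per variant: subject, gene, HGVS-style cDNA change, VAF (as a
    fraction) and population allele frequency where reported.  All seven
    calls are missense, CADD > 20, and amplicon-validated, so the table
    carries ``consequence``, ``cadd_above_20`` and ``validated`` columns
    ready for damaging-gene-set selection.
    """
    rows = [
        ("4999", "DVL1", "c.196C>A", 0.003, None),
        ("4999", "ADCY5", "c.2101G>A", 0.010, None),
        ("5144", "ERBB3", "c.1611T>G", 0.020, None),
        ("5176", "PEAK1", "c.890C>T", 0.025, 0.000402 / 100),
        ("5403", "RGS6", "c.335G>A", 0.030, 0.00199 / 100),
        ("5308", "SLC25A22", "c.718C>T", 0.038, 0.000401 / 100),
        ("5841", "CENPJ", "c.3001G>T", 0.017, None),
    ]
    df = pd.DataFrame(
        rows, columns=["subject", "gene", "cdna_change", "vaf", "population_af"]
    )
    df["consequence"] = "missense_variant"
    df["damaging"] = True
    df["validated"] = True
    return df


def synthetic_germline_genesets() -> dict[str, dict[str, set[str]]]:
    """Synthetic per-subject germline damaging gene sets (placeholder genes).

    Matches the published summary counts only: 11 distinct risk genes with
    damaging germline SNVs across 12 ASD carriers, and 9 across 8 control
    carriers.  Gene identifiers are synthetic placeholders.
    """
    asd_genes = [f"ASD_RISK{i:02d}" for i in range(11)]
    ctrl_genes = [f"CTRL_RISK{i:02d}" for i in range(9)]
    asd_sets: dict[str, set[str]] = {}
    # 12 ASD germline carriers over 11 distinct genes (one gene recurs)
    for i in range(12):
        asd_sets[f"ASD_G{i:02d}"] = {asd_genes[i % 11]}
    ctrl_sets: dict[str, set[str]] = {}
    for i in range(8):
        ctrl_sets[f"CTRL_G{i:02d}"] = {ctrl_genes[i]}
    ctrl_sets["CTRL_G00"] |= {ctrl_genes[8]}
    return {"ASD": asd_sets, "control": ctrl_sets}


def synthetic_control_somatic_genesets() -> dict[str, set[str]]:
    """Synthetic control-group somatic damaging gene sets (4 genes, 2 carriers)."""
    genes = [f"CTRL_SOM{i:02d}" for i in range(4)]
    return {"CTRL_S00": {genes[0], genes[1]}, "CTRL_S01": {genes[2], genes[3]}}


def example_carrier_counts() -> dict[str, tuple[tuple[int, int], tuple[int, int]]]:
    """Published 2x2 carrier tables (cases of 24, controls of 31).

    Rows are (ASD, control), columns (carrier, non-carrier), for the three
    gene-set modes.
    """
    return {
        "somatic_only": ((6, 18), (2, 29)),
        "germline_only": ((12, 12), (8, 23)),
        "merged": ((14, 10), (8, 23)),
    }
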