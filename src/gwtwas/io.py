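"""Readers and writers for the pipeline's plain-text file formats.

Formats (all tab-separated unless noted):

* genotype TSV — rows are variants; columns ``id, chr, pos, ref, alt`` then
  one dosage column per sample (``NA`` for missing). A plain uncompressed
  VCF with ``DS`` or ``GT`` genotype fields is accepted as an alternative
  input dialect (read via cyvcf2 when available).
* expression counts TSV — rows are genes; columns ``gene_id, chr, tss`` then
  one count column per sample.
* GWAS summary TSV — columns ``id, chr, pos, ref, alt, [beta, se,] Z, n``.
* eQTL weight TSV — one row per retained variant of a gene:
  ``gene_id, variant_id, chr, pos, ref, alt, cis_trans, pcp, effect, weight``.
* ground truth / QC reports / manifests — JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypePanel, ExpressionState, validate_gwas_summary

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotype_tsv(panel: GenotypePanel, path: str | Path) -> None:
    df = panel.variants.copy()
    dos = pd.DataFrame(panel.dosages.T, columns=panel.samples)
    df = pd.concat([df.reset_index(drop=True), dos], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=FLOAT_FMT)


def read_genotype_tsv(path: str | Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str}, na_values=["NA"])
    meta_cols = ["id", "chr", "pos", "ref", "alt"]
    samples = [c for c in df.columns if c not in meta_cols]
    dosages = df[samples].to_numpy(dtype=np.float64).T
    return GenotypePanel(dosages=dosages, variants=df[meta_cols], samples=samples)


def read_genotype_vcf(path: str | Path) -> GenotypePanel:
    """Read an (uncompressed or bgzipped) VCF, preferring DS over GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for rec in vcf:
        rows.append(
            {
                "id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "chr": str(rec.CHROM),
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
            }
        )
        try:
            ds = np.asarray(rec.format("DS"), dtype=np.float64).ravel()
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(rec.gt_types, dtype=np.float64)  # 0,1,3 dosage-coded; 2=unknown
            ds = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        rows[-1]["_ds"] = ds
    for r in rows:
        dosage_cols.append(r.pop("_ds"))
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    return GenotypePanel(dosages=dosages, variants=variants, samples=samples)


def write_genotype_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a minimal VCFv4.2 with a DS FORMAT field (uncompressed text)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = panel.variants["chr"].astype(str).unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        for j, row in panel.variants.iterrows():
            vals = [
                "." if np.isnan(d) else (FLOAT_FMT % d)
                for d in panel.dosages[:, j]
            ]
            fh.write(
                f"{row['chr']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tDS\t" + "\t".join(vals) + "\n"
            )


def read_genotypes(path: str | Path) -> GenotypePanel:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` -> VCF reader, else TSV."""
    name = str(path)
    if name.endswith(".vcf") or name.endswith(".vcf.gz"):
        return read_genotype_vcf(path)
    return read_genotype_tsv(path)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def write_expression_counts_tsv(
    counts: np.ndarray, gene_meta: pd.DataFrame, samples: list[str], path: str | Path
) -> None:
    df = gene_meta[["gene_id", "chr", "tss"]].copy()
    df = pd.concat([df, pd.DataFrame(counts, columns=samples)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_expression_counts_tsv(path: str | Path) -> ExpressionState:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    meta_cols = ["gene_id", "chr", "tss"]
    samples = [c for c in df.columns if c not in meta_cols]
    return ExpressionState(
        values=df[samples].to_numpy(dtype=np.float64),
        genes=df[meta_cols],
        samples=samples,
        state_tag="raw",
    )


def write_expression_state_tsv(state: ExpressionState, path: str | Path) -> None:
    df = state.genes[["gene_id", "chr", "tss"]].copy()
    df = pd.concat([df, pd.DataFrame(state.values, columns=state.samples)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_expression_state_tsv(
    path: str | Path, state_tag: str = "adjusted"
) -> ExpressionState:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    meta_cols = ["gene_id", "chr", "tss"]
    samples = [c for c in df.columns if c not in meta_cols]
    return ExpressionState(
        values=df[samples].to_numpy(dtype=np.float64),
        genes=df[meta_cols],
        samples=samples,
        state_tag=state_tag,
        size_factors=np.ones(len(samples)),
    )


# ---------------------------------------------------------------------------
# covariates / GWAS / weights
# ---------------------------------------------------------------------------

def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def select_best_replicate(
    covariates: pd.DataFrame,
    reads_column: str = "reads",
    subject_column: str | None = None,
) -> pd.DataFrame:
    """Keep one row per subject: the replicate with the most reads, ties
    broken lexicographically by sample id."""
    if subject_column is None or subject_column not in covariates.columns:
        return covariates
    df = covariates.sort_values(
        [subject_column, reads_column, "sample_id"],
        ascending=[True, False, True],
    )
    return df.drop_duplicates(subset=subject_column, keep="first").reset_index(drop=True)


def write_gwas_tsv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gwas_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    return validate_gwas_summary(df)


def write_weights_tsv(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_weights_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chr": str})
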