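"""Stage II: summary-statistic gene-based association tests.

Given per-variant eQTL weights w~ (PCP x effect) from Stage I and GWAS
single-variant Z-scores, each gene's burden statistic is

    Z_g = sum_l w~_l * sigma_l * Z_l / sqrt(w~' V w~),

where V is the dosage covariance of an LD reference panel and sigma_l its
diagonal square roots. The two-tailed p-value comes from the standard
normal. The module also classifies genes as trans-driven (>= 50% of the
burden-numerator mass from trans variants), applies Bonferroni calls, and
supports the cis-only re-run used to quantify what trans weights add.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypePanel, validate_gwas_summary


class UntestableGeneError(ValueError):
    """The burden statistic is undefined (no usable weights / zero variance)."""


class EmptyOverlapError(ValueError):
    """No variant overlap between the weight set and the GWAS summary."""


@dataclass
class LDReference:
    """Reference LD: variant ids, dosage covariance V, per-variant SDs."""

    variant_ids: list[str]
    V: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        k = len(self.variant_ids)
        if self.V.shape != (k, k):
            raise ValueError("V must be square over the variant list")

    def subset(self, ids: list[str]) -> "LDReference":
        index = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in ids if v not in index]
        if missing:
            raise KeyError(f"variants absent from LD reference: {missing[:5]}")
        idx = np.array([index[v] for v in ids])
        return LDReference(list(ids), self.V[np.ix_(idx, idx)], self.sigma[idx])


def build_ld_reference(
    panel: GenotypePanel, variant_ids: list[str] | None = None
) -> LDReference:
    """Covariance of mean-imputed reference dosages for the given variants."""
    if variant_ids is not None:
        index = {v: i for i, v in enumerate(panel.variants["id"])}
        missing = [v for v in variant_ids if v not in index]
        if missing:
            raise KeyError(f"variants absent from panel: {missing[:5]}")
        panel = panel.subset_variants([index[v] for v in variant_ids])
    X = panel.mean_imputed()
    if X.shape[1] == 1:
        V = np.array([[np.var(X[:, 0], ddof=1)]])
    else:
        V = np.cov(X, rowvar=False, ddof=1)
    return LDReference(
        variant_ids=list(panel.variants["id"]),
        V=V,
        sigma=np.sqrt(np.diag(V)),
    )


_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def harmonize(
    weights: pd.DataFrame, gwas: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Match a gene's weight table to GWAS summary rows by variant id.

    If ref/alt are swapped between the two sources the GWAS Z sign is
    flipped; strand-ambiguous variants (A/T, C/G) and allele mismatches are
    dropped and counted. Returns the matched table (weight-table columns
    plus ``Z``) and a report of drop counts.
    """
    gwas = validate_gwas_summary(gwas)
    merged = weights.merge(
        gwas[["id", "ref", "alt", "Z"]],
        left_on="variant_id",
        right_on="id",
        suffixes=("", "_gwas"),
        how="inner",
    )
    report = {
        "n_weights": len(weights),
        "n_unmatched_id": len(weights) - len(merged),
        "n_ambiguous": 0,
        "n_allele_mismatch": 0,
        "n_flipped": 0,
        "n_matched": 0,
    }
    keep_rows = []
    for _, row in merged.iterrows():
        pair = frozenset((str(row["ref"]), str(row["alt"])))
        if pair in _AMBIGUOUS:
            report["n_ambiguous"] += 1
            continue
        if row["ref"] == row["ref_gwas"] and row["alt"] == row["alt_gwas"]:
            keep_rows.append(row)
        elif row["ref"] == row["alt_gwas"] and row["alt"] == row["ref_gwas"]:
            row = row.copy()
            row["Z"] = -row["Z"]
            report["n_flipped"] += 1
            keep_rows.append(row)
        else:
            report["n_allele_mismatch"] += 1
    if not keep_rows:
        raise EmptyOverlapError("no usable variant overlap between weights and GWAS")
    matched = pd.DataFrame(keep_rows).drop(columns=["id", "ref_gwas", "alt_gwas"])
    report["n_matched"] = len(matched)
    return matched.reset_index(drop=True), report


@dataclass
class GeneAssociation:
    """One gene-tissue burden-test result."""

    gene_id: str
    tissue: str
    z: float
    p: float
    n_variants_used: int
    trans_fraction: float
    significant: bool = False
    untestable: bool = False
    note: str = ""


def trans_fraction(
    matched: pd.DataFrame, ld: LDReference, method: str = "mass"
) -> float:
    """Fraction of the gene's association driven by trans variants.

    ``mass`` (default): share of the burden numerator's magnitude,
    sum_trans |w~_l| sigma_l / sum_all |w~_l| sigma_l. ``variance``: share of
    the weighted LD quadratic form, w_t' V w_t / (w_c' V w_c + w_t' V w_t).
    """
    if len(matched) == 0:
        raise ValueError("empty weight set")
    ld = ld.subset(list(matched["variant_id"]))
    w = matched["weight"].to_numpy(dtype=float)
    is_trans = (matched["cis_trans"] == "trans").to_numpy()
    if method == "mass":
        mass = np.abs(w) * ld.sigma
        total = mass.sum()
        return float(mass[is_trans].sum() / total) if total > 0 else 0.0
    if method == "variance":
        wt = np.where(is_trans, w, 0.0)
        wc = np.where(is_trans, 0.0, w)
        qt = float(wt @ ld.V @ wt)
        qc = float(wc @ ld.V @ wc)
        return qt / (qt + qc) if (qt + qc) > 0 else 0.0
    raise ValueError(f"unknown trans-fraction method {method!r}")


def burden_z(
    matched: pd.DataFrame,
    ld: LDReference,
    gene_id: str = "gene",
    tissue: str = "tissue",
    trans_method: str = "mass",
) -> GeneAssociation:
    """Burden Z statistic and two-tailed p for one harmonized gene."""
    if len(matched) == 0:
        raise UntestableGeneError(f"{gene_id}: no matched variants")
    ld = ld.subset(list(matched["variant_id"]))
    w = matched["weight"].to_numpy(dtype=float)
    if np.all(w == 0):
        raise UntestableGeneError(f"{gene_id}: all weights zero")
    sigma2_g = float(w @ ld.V @ w)
    if sigma2_g <= 0:
        raise UntestableGeneError(f"{gene_id}: zero weighted LD variance")
    z_l = matched["Z"].to_numpy(dtype=float)
    z = float((w * ld.sigma) @ z_l / np.sqrt(sigma2_g))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return GeneAssociation(
        gene_id=gene_id,
        tissue=tissue,
        z=z,
        p=p,
        n_variants_used=len(matched),
        trans_fraction=trans_fraction(matched, ld, method=trans_method),
    )


def cis_only_rerun(
    matched: pd.DataFrame, ld: LDReference, gene_id: str = "gene", tissue: str = "tissue"
) -> GeneAssociation:
    """Re-test after zeroing all trans weights (the cis-only comparison).

    Genes whose matched weights are all trans are untestable in this mode
    and reported as such rather than raising.
    """
    cis_only = matched.copy()
    cis_only.loc[cis_only["cis_trans"] == "trans", "weight"] = 0.0
    if np.all(cis_only["weight"].to_numpy() == 0):
        return GeneAssociation(
            gene_id=gene_id, tissue=tissue, z=np.nan, p=np.nan,
            n_variants_used=0, trans_fraction=np.nan,
            untestable=True, note="only trans weights; untestable cis-only",
        )
    assoc = burden_z(cis_only, ld, gene_id=gene_id, tissue=tissue)
    assoc.trans_fraction = 0.0
    return assoc


def bonferroni_call(pvalues: pd.Series | np.ndarray, alpha: float = 0.05) -> tuple[float, np.ndarray]:
    """Bonferroni threshold and strict-inequality significance flags.

    The denominator is the number of testable genes (finite p-values);
    untestable genes (NaN) are excluded and never flagged.
    """
    p = np.asarray(pvalues, dtype=float)
    n_tested = int(np.isfinite(p).sum())
    if n_tested == 0:
        raise ValueError("no testable gene")
    threshold = alpha / n_tested
    with np.errstate(invalid="ignore"):
        flags = np.where(np.isfinite(p), p < threshold, False)
    return threshold, flags.astype(bool)


def test_tissue(
    weights_by_gene: dict[str, pd.DataFrame],
    gwas: pd.DataFrame,
    ld_panel: GenotypePanel,
    gene_meta: pd.DataFrame,
    tissue: str = "tissue",
    alpha: float = 0.05,
    cis_only: bool = False,
    trans_method: str = "mass",
) -> pd.DataFrame:
    """Burden-test every gene of a tissue; returns the Manhattan-ready table.

    Columns: gene_id, chr, tss, tissue, Z, p, n_variants, trans_fraction,
    untestable, note, significant. Untestable genes carry NaN statistics and
    are excluded from the Bonferroni denominator.
    """
    ld_full = build_ld_reference(ld_panel)
    meta = gene_meta.set_index("gene_id")
    rows = []
    for gene_id in sorted(weights_by_gene):
        wdf = weights_by_gene[gene_id]
        try:
            matched, _rep = harmonize(wdf, gwas)
            if cis_only:
                assoc = cis_only_rerun(matched, ld_full, gene_id, tissue)
            else:
                assoc = burden_z(matched, ld_full, gene_id, tissue, trans_method)
        except (UntestableGeneError, EmptyOverlapError) as exc:
            assoc = GeneAssociation(
                gene_id=gene_id, tissue=tissue, z=np.nan, p=np.nan,
                n_variants_used=0, trans_fraction=np.nan,
                untestable=True, note=str(exc),
            )
        rows.append(
            {
                "gene_id": gene_id,
                "chr": meta.at[gene_id, "chr"] if gene_id in meta.index else "NA",
                "tss": meta.at[gene_id, "tss"] if gene_id in meta.index else 0,
                "tissue": tissue,
                "Z": assoc.z,
                "p": assoc.p,
                "n_variants": assoc.n_variants_used,
                "trans_fraction": assoc.trans_fraction,
                "untestable": assoc.untestable,
                "note": assoc.note,
            }
        )
    table = pd.DataFrame(rows)
    if np.isfinite(table["p"]).any():
        _thr, flags = bonferroni_call(table["p"], alpha=alpha)
        table["significant"] = flags
    else:
        table["significant"] = False
    table["trans_driven"] = table["trans_fraction"] >= 0.5
    return table
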