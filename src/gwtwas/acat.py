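"""Cauchy combination of per-tissue p-values (the ACAT omnibus test).

K p-values testing the same null are combined through

    T = (1/K) * sum_i tan((0.5 - p_i) * pi),

which under the null approximately follows a standard Cauchy distribution
regardless of the correlation between the tests, so the combined p-value is
the Cauchy upper-tail probability of T. The approximation is most accurate
exactly where it matters — for small p-values — which makes the test well
suited to combining correlated per-tissue TWAS results.

Numerical care: ``tan`` near +pi/2 loses precision, so for p < 1e-15 the
transform is replaced by its asymptotic equivalent 1/(p*pi); inputs equal to
1 are clipped to 1 - 1e-16.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import bonferroni_call

_TINY_P = 1e-15


def acat_o(p_values) -> tuple[float, float]:
    """Combine p-values with equal weights 1/K.

    Returns ``(T, p_combined)``. Each input must lie in (0, 1]; the list
    must be nonempty. Stable down to p ~ 1e-300.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    p = np.minimum(p, 1.0 - 1e-16)
    terms = np.where(
        p < _TINY_P,
        1.0 / (p * np.pi),
        np.tan((0.5 - p) * np.pi),
    )
    T = float(np.mean(terms))
    p_combined = float(stats.cauchy.sf(T))
    return T, p_combined


def acat_o_vectorized(p_matrix: np.ndarray) -> np.ndarray:
    """Row-wise combined p-values for an (m x K) matrix of p-values in (0,1]."""
    p = np.minimum(np.asarray(p_matrix, dtype=float), 1.0 - 1e-16)
    if np.any(p <= 0.0):
        raise ValueError("p-values must be > 0")
    terms = np.where(p < _TINY_P, 1.0 / (p * np.pi), np.tan((0.5 - p) * np.pi))
    T = terms.mean(axis=1)
    return stats.cauchy.sf(T)


def combine_across_tissues(
    tissue_tables: dict[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Combine per-tissue burden p-values per gene into an omnibus table.

    Each table needs columns ``gene_id, chr, tss, p``. A gene contributes
    the p-values of every tissue where it was testable (K adapts per gene);
    genes testable nowhere are absent from the output. The Bonferroni flag
    uses the count of genes with a combined p as denominator (strict <).

    Output columns: gene_id, chr, tss, one ``p_<tissue>`` column per input
    tissue, K, T, p_combined, best_tissue, significant.
    """
    if not tissue_tables:
        raise ValueError("need at least one tissue table")
    tissues = sorted(tissue_tables)
    per_gene: dict[str, dict] = {}
    for tissue in tissues:
        tab = tissue_tables[tissue]
        for _, row in tab.iterrows():
            rec = per_gene.setdefault(
                row["gene_id"], {"chr": row["chr"], "tss": row["tss"], "p": {}}
            )
            if np.isfinite(row["p"]):
                rec["p"][tissue] = float(row["p"])

    rows = []
    for gene_id in sorted(per_gene):
        rec = per_gene[gene_id]
        if not rec["p"]:
            continue  # testable in no tissue
        pvals = [rec["p"][t] for t in tissues if t in rec["p"]]
        T, p_comb = acat_o(pvals)
        best = min(rec["p"], key=rec["p"].get)
        row = {"gene_id": gene_id, "chr": rec["chr"], "tss": rec["tss"]}
        for t in tissues:
            row[f"p_{t}"] = rec["p"].get(t, np.nan)
        row.update({"K": len(pvals), "T": T, "p_combined": p_comb, "best_tissue": best})
        rows.append(row)
    if not rows:
        raise ValueError("no gene testable in any tissue")
    out = pd.DataFrame(rows)
    _thr, flags = bonferroni_call(out["p_combined"], alpha=alpha)
    out["significant"] = flags
    return out
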