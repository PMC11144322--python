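"""Benchmark routines that measure the pipeline's statistical properties.

These functions generate their own study conditions (scenarios, engineered
fixtures) and measure calibration, oracle agreement and recovery quality of
the implementation. They back both the acceptance test suite and
``scripts/acceptance.py``; each returns plain numbers.

Problem sizes are chosen for single-CPU runs: the Monte-Carlo sizes give
binomial/correlation noise well below the margins being checked (see
docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .acat import acat_o, acat_o_vectorized
from .assoc import build_ld_reference, burden_z, cis_only_rerun, harmonize
from .bvsr import BvsrHyperParams, train_gene
from .simulate import (
    GeneArchitecture,
    SimulationScenario,
    gwas_zscores,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas_summary,
)
from .types import GenotypePanel


# ---------------------------------------------------------------------------
# Cauchy combination
# ---------------------------------------------------------------------------

def acat_worked_example() -> float:
    """Combined p for the (0.01, 0.1, 0.9) triplet."""
    _, p = acat_o([0.01, 0.1, 0.9])
    return p


def acat_null_rejection_rates(
    n_draws: int = 1_000_000, k: int = 3, seed: int = 0,
    alphas: tuple[float, ...] = (0.05, 0.01, 1e-3),
) -> dict[float, float]:
    """Empirical rejection rates of the combined p under independent
    uniform inputs."""
    rng = np.random.default_rng([seed, 101])
    rates = {}
    combined = np.empty(n_draws)
    chunk = 200_000
    for start in range(0, n_draws, chunk):
        stop = min(start + chunk, n_draws)
        combined[start:stop] = acat_o_vectorized(rng.random((stop - start, k)))
    for a in alphas:
        rates[a] = float((combined < a).mean())
    return rates


# ---------------------------------------------------------------------------
# burden test
# ---------------------------------------------------------------------------

def _weight_table(panel: GenotypePanel, idx: np.ndarray, w: np.ndarray, flags=None):
    t = panel.variants.iloc[idx].rename(columns={"id": "variant_id"}).copy()
    t.insert(0, "gene_id", "g")
    t["cis_trans"] = "cis" if flags is None else flags
    t["pcp"] = 1.0
    t["effect"] = w
    t["weight"] = w
    return t.reset_index(drop=True)


def burden_oracle_max_rel_error(n_genes: int = 50, seed: int = 0) -> float:
    """Max relative disagreement between the summary-level burden Z and the
    individual-level GReX-regression Z when the LD reference is the GWAS
    cohort itself."""
    sc = SimulationScenario(
        n_ref_samples=100, n_gwas_samples=1500, n_variants=400, n_blocks=8,
        block_ld_rho=0.4, seed=seed,
    )
    panel = simulate_genotypes(sc, "gwas")
    pos = panel.variants["pos"].to_numpy()
    rng = np.random.default_rng([seed, 202])
    worst = 0.0
    for g in range(n_genes):
        tss = int(rng.integers(pos.min(), pos.max()))
        cis = np.nonzero(np.abs(pos - tss) <= 1_000_000)[0]
        trans = np.nonzero(np.abs(pos - tss) > 1_000_000)[0]
        arch = GeneArchitecture(
            f"g{g}", "1", tss,
            cis_causal=[(int(i), float(rng.normal())) for i in rng.choice(cis, 2, replace=False)],
            trans_causal=[(int(i), float(rng.normal())) for i in rng.choice(trans, 1)],
            h2_expr=0.4,
        )
        _, te = simulate_expression(panel, arch, seed=[seed, 203, g])
        summary, y = simulate_gwas_summary(panel, [te], 0.3, 0.1, seed=[seed, 204, g])
        nz = np.nonzero(te.weights)[0]
        matched, _ = harmonize(_weight_table(panel, nz, te.weights[nz]), summary)
        ld = build_ld_reference(panel, list(matched["variant_id"]))
        z_summary = burden_z(matched, ld).z
        grex = panel.mean_imputed() @ te.weights
        z_oracle = float(np.sqrt(len(y) - 1) * np.corrcoef(y, grex)[0, 1])
        worst = max(worst, abs(z_summary - z_oracle) / max(abs(z_oracle), 1e-12))
    return worst


def burden_null_type1_rate(
    n_genes: int = 1000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I error of the burden test: weights fixed, GWAS trait with no
    mediated component, LD from an independent reference panel."""
    sc = SimulationScenario(
        n_ref_samples=800, n_gwas_samples=1500, n_variants=300, n_blocks=6,
        block_ld_rho=0.3, seed=seed,
    )
    ref = simulate_genotypes(sc, "ref")
    gwas_panel = simulate_genotypes(sc, "gwas")
    Xstd = gwas_panel.standardized()
    ld_full = build_ld_reference(ref)
    rng = np.random.default_rng([seed, 301])
    rejections = 0
    for _g in range(n_genes):
        idx = np.sort(rng.choice(sc.n_variants, size=5, replace=False))
        w = rng.standard_normal(5)
        y = rng.standard_normal(sc.n_gwas_samples)
        z_l = gwas_zscores(y, Xstd[:, idx])
        summary = gwas_panel.variants.iloc[idx].copy()
        summary["Z"] = z_l
        summary["n"] = sc.n_gwas_samples
        matched, _ = harmonize(_weight_table(gwas_panel, idx, w), summary)
        assoc = burden_z(matched, ld_full)
        rejections += assoc.p < alpha
    return rejections / n_genes


def cis_only_power_loss_fraction(n_genes: int = 50, seed: int = 0) -> float:
    """Fraction of planted trans-driven genes whose cis-only burden |Z| is
    smaller than the full cis+trans |Z|."""
    sc = SimulationScenario(
        n_ref_samples=100, n_gwas_samples=2000, n_variants=400, n_blocks=8,
        block_ld_rho=0.3, seed=seed,
    )
    panel = simulate_genotypes(sc, "gwas")
    pos = panel.variants["pos"].to_numpy()
    rng = np.random.default_rng([seed, 401])
    ld_full = build_ld_reference(panel)
    losses = 0
    for g in range(n_genes):
        tss = int(rng.integers(pos.min(), pos.max()))
        cis = np.nonzero(np.abs(pos - tss) <= 1_000_000)[0]
        trans = np.nonzero(np.abs(pos - tss) > 1_000_000)[0]
        arch = GeneArchitecture(
            f"g{g}", "1", tss,
            cis_causal=[(int(rng.choice(cis)), 0.4)],
            trans_causal=[(int(i), 1.0) for i in rng.choice(trans, 2, replace=False)],
            h2_expr=0.5,
        )
        _, te = simulate_expression(panel, arch, seed=[seed, 402, g])
        summary, _y = simulate_gwas_summary(panel, [te], 0.4, 0.05, seed=[seed, 403, g])
        nz = np.nonzero(te.weights)[0]
        flags = ["cis" if i in te.cis_indices else "trans" for i in nz]
        matched, _ = harmonize(_weight_table(panel, nz, te.weights[nz], flags), summary)
        full = burden_z(matched, ld_full)
        cis_only = cis_only_rerun(matched, ld_full)
        losses += abs(cis_only.z) < abs(full.z)
    return losses / n_genes


# ---------------------------------------------------------------------------
# Stage-I recovery
# ---------------------------------------------------------------------------

def bvsr_recovery(
    n_reps: int = 20, seed: int = 0,
    mcmc_iters: int = 2500, burn_in: int = 500, em_rounds: int = 2,
) -> dict:
    """Parameter recovery under the reference scenario: n=500 samples,
    1000 variants in 100-variant blocks, 2 cis + 1 trans causal variants
    sharing h2=0.5, screening at p<1e-5.

    A replicate succeeds when every planted variant reaches PCP > 0.5 and
    the estimated weights correlate with the truth at r > 0.8 over the
    fitted variants.
    """
    successes = 0
    corrs = []
    for rep in range(n_reps):
        rep_seed = seed * 10_000 + rep
        sc = SimulationScenario(
            n_ref_samples=500, n_variants=1000, n_blocks=10, block_ld_rho=0.3,
            maf_range=(0.1, 0.5), seed=rep_seed,
        )
        panel = simulate_genotypes(sc)
        arch = GeneArchitecture(
            "g", "1", 5_000_000,
            cis_causal=[(450, 1.0), (520, -1.0)], trans_causal=[(900, 1.0)],
            h2_expr=0.5,
        )
        y, te = simulate_expression(panel, arch, seed=[rep_seed, 11])
        hyper = BvsrHyperParams(
            mcmc_iters=mcmc_iters, burn_in=burn_in, em_rounds=em_rounds,
            seed=rep_seed,
        )
        weights, fit, _sel = train_gene(
            y, panel, "g", "1", 5_000_000, block_size=100, hyper=hyper
        )
        vid = panel.variants["id"]
        pcp_by_id = dict(zip(fit.variants["id"], fit.pcp))
        pcp_ok = all(pcp_by_id.get(vid.iat[i], 0.0) > 0.5 for i in (450, 520, 900))
        w_est = pd.Series(0.0, index=vid)
        w_est[weights["variant_id"].to_numpy()] = weights["weight"].to_numpy()
        truth = pd.Series(te.weights, index=vid)
        fitted = fit.variants["id"]
        r = float(np.corrcoef(w_est[fitted], truth[fitted])[0, 1])
        corrs.append(r)
        successes += pcp_ok and r > 0.8
    return {
        "n_reps": n_reps,
        "successes": successes,
        "mean_weight_truth_corr": float(np.mean(corrs)),
        "min_weight_truth_corr": float(np.min(corrs)),
    }


# ---------------------------------------------------------------------------
# engineered QC fixtures (hand-enumerated truth)
# ---------------------------------------------------------------------------

def _make_panel(dosages: np.ndarray) -> GenotypePanel:
    n, p = dosages.shape
    variants = pd.DataFrame(
        {
            "id": [f"v{i:03d}" for i in range(p)],
            "chr": "1",
            "pos": [(i + 1) * 10_000 for i in range(p)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypePanel(
        dosages=dosages, variants=variants, samples=[f"s{i:03d}" for i in range(n)]
    )


def qc_boundary_panel() -> tuple[GenotypePanel, int]:
    """10 variants x 50 samples; exactly 7 survive the default filters.

    v0 has one heterozygote (MAF exactly 0.01, strict '>' removes it); v1 is
    missing in exactly 10/50 samples (rate exactly 0.20, strict '<' removes
    it); v2 is all homozygotes (HWE chi-square p ~ 1.5e-23); v3..v9 sit near
    HWE at MAF ~ 0.3.
    """
    n = 50
    cols = []
    v0 = np.zeros(n); v0[0] = 1
    cols.append(v0)
    v1 = np.array([0, 1, 2] * 17, dtype=float)[:n]; v1[:10] = np.nan
    cols.append(v1)
    cols.append(np.array([0.0] * 25 + [2.0] * 25))
    good = np.array([0.0] * 25 + [1.0] * 21 + [2.0] * 4)
    rng = np.random.default_rng(0)
    for _ in range(7):
        cols.append(rng.permutation(good))
    return _make_panel(np.column_stack(cols)), 7


def expression_boundary_counts() -> tuple[np.ndarray, int]:
    """20 genes x 50 samples with size factors exactly 1 by construction;
    exactly 7 genes survive normalization.

    Nine constant anchor genes and one all-ones gene pin every sample's
    median count ratio at exactly 1, so the expression filter thresholds are
    hit exactly: one gene exceeds log-value 1 in exactly 10% of samples
    (removed, strict '>'), one in 12% (kept). Constant genes pass the
    expression filter but are unscalable (zero variance) and dropped.
    """
    n = 50
    rng = np.random.default_rng(1)
    rows = [np.full(n, 30.0 + 5 * i) for i in range(9)]          # anchors
    rows += [rng.integers(20, 200, size=n).astype(float) for _ in range(6)]
    rows.append(np.ones(n))                                       # log(2) < 1
    rows += [np.zeros(n), np.zeros(n)]
    boundary = np.zeros(n); boundary[:5] = 2.0                    # exactly 10%
    rows.append(boundary)
    above = np.zeros(n); above[:6] = 2.0                          # 12%
    rows.append(above)
    return np.array(rows), 7
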