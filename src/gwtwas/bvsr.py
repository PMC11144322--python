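"""Stage I: sparse cis/trans eQTL weight estimation.

The gene expression trait is modeled as a sparse linear function of
genome-wide standardized dosages,

    e_g = X_cis w_cis + X_trans w_trans + eps,    eps ~ N(0, sigma_e^2),

with spike-and-slab priors per group: each effect is zero with probability
1 - pi_group and N(0, sigma2_group * sigma_e^2) otherwise. Fitting proceeds
per approximately independent genome block: blocks are selected if they
overlap the gene's cis window or contain a single-variant association with
p < 1e-5, then an EM-MCMC scheme alternates (E) Gibbs sampling of inclusion
indicators and conjugate effect draws within each block with (M) closed-form
updates of the group inclusion probabilities and slab variances from the
pooled posterior summaries. The per-variant posterior causal probability
(PCP, the posterior inclusion frequency) times the posterior mean effect
conditional on inclusion is the eQTL weight handed to Stage II.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .types import EmptyPanelError, GenotypePanel, WEIGHT_COLUMNS
from .simulate import DEFAULT_CIS_WINDOW


# ---------------------------------------------------------------------------
# genome segmentation and screening
# ---------------------------------------------------------------------------

@dataclass
class GenomeBlocks:
    """Contiguous half-open variant-index ranges, one chromosome each."""

    ranges: list[tuple[str, int, int]]  # (chromosome, start, stop)

    def __len__(self) -> int:
        return len(self.ranges)

    def __iter__(self):
        return iter(self.ranges)


def segment_genome(panel: GenotypePanel, block_size: int) -> GenomeBlocks:
    """Cut each chromosome's run of variants into fixed-size blocks (the
    last block of a chromosome may be short)."""
    if panel.n_variants == 0:
        raise EmptyPanelError("cannot segment an empty panel")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    chroms = panel.variants["chr"].to_numpy()
    ranges: list[tuple[str, int, int]] = []
    run_start = 0
    for i in range(1, panel.n_variants + 1):
        if i == panel.n_variants or chroms[i] != chroms[run_start]:
            for s in range(run_start, i, block_size):
                ranges.append((str(chroms[run_start]), s, min(s + block_size, i)))
            run_start = i
    return GenomeBlocks(ranges)


def single_variant_eqtl(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Simple-regression slope, SE and two-sided t-test p-value."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if len(x) != n:
        raise ValueError("y and x must have equal length")
    if n < 3:
        raise ValueError("need n >= 3")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise ValueError("zero-variance genotype vector")
    yc = y - y.mean()
    beta = (xc @ yc) / sxx
    rss = yc @ yc - beta * beta * sxx
    se = np.sqrt(max(rss, 0.0) / ((n - 2) * sxx))
    if se == 0:
        return float(beta), 0.0, 0.0
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(beta), float(se), float(p)


def _marginal_pvalues(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Vectorized two-sided simple-regression p-values, one per column
    (identical to :func:`single_variant_eqtl` up to float rounding)."""
    n = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    sxy = Xc.T @ yc
    syy = yc @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (sxy * sxy) / (sxx * syy)
        r2 = np.clip(np.where(sxx > 0, r2, np.nan), 0.0, 1.0)
        t2 = r2 * (n - 2) / np.maximum(1.0 - r2, 1e-300)
    p = 2.0 * stats.t.sf(np.sqrt(t2), df=n - 2)
    return np.where(np.isnan(r2), 1.0, p)


@dataclass
class BlockSelection:
    """Outcome of the screening step for one gene."""

    blocks: GenomeBlocks                    # the selected blocks
    is_cis_block: list[bool]                # selected because it overlaps the cis window
    report: pd.DataFrame                    # per selected trans block: triggering variant


def screen_blocks(
    y: np.ndarray,
    panel: GenotypePanel,
    blocks: GenomeBlocks,
    gene_chr: str,
    gene_tss: int,
    cis_window: int = DEFAULT_CIS_WINDOW,
    p_threshold: float = 1e-5,
) -> BlockSelection:
    """Select the genome blocks a gene's model is fit on.

    Every block overlapping the cis window (TSS +/- ``cis_window``,
    inclusive) is selected; any other block is selected iff its best
    single-variant p-value is strictly below ``p_threshold``.
    """
    lo, hi = gene_tss - cis_window, gene_tss + cis_window
    pos = panel.variants["pos"].to_numpy()
    pvals = _marginal_pvalues(np.asarray(y, float), panel.mean_imputed())

    sel_ranges, is_cis, rep_rows = [], [], []
    for chrom, start, stop in blocks:
        cis_overlap = chrom == str(gene_chr) and bool(
            np.any((pos[start:stop] >= lo) & (pos[start:stop] <= hi))
        )
        if cis_overlap:
            sel_ranges.append((chrom, start, stop))
            is_cis.append(True)
            continue
        block_p = pvals[start:stop]
        j = int(np.argmin(block_p))
        if block_p[j] < p_threshold:
            sel_ranges.append((chrom, start, stop))
            is_cis.append(False)
            rep_rows.append(
                {
                    "chr": chrom,
                    "block_start": start,
                    "block_stop": stop,
                    "top_variant": panel.variants["id"].iat[start + j],
                    "top_p": block_p[j],
                }
            )
    report = pd.DataFrame(
        rep_rows, columns=["chr", "block_start", "block_stop", "top_variant", "top_p"]
    )
    return BlockSelection(GenomeBlocks(sel_ranges), is_cis, report)


def cis_flags(
    variants: pd.DataFrame, gene_chr: str, gene_tss: int,
    cis_window: int = DEFAULT_CIS_WINDOW,
) -> np.ndarray:
    """Per-variant cis indicator: same chromosome, within the TSS window."""
    lo, hi = gene_tss - cis_window, gene_tss + cis_window
    return (
        (variants["chr"].astype(str) == str(gene_chr))
        & (variants["pos"] >= lo)
        & (variants["pos"] <= hi)
    ).to_numpy()


# ---------------------------------------------------------------------------
# spike-and-slab EM-MCMC
# ---------------------------------------------------------------------------

@dataclass
class BvsrHyperParams:
    """Hyperparameters and run controls of the variable-selection fit.

    ``sigma2_cis``/``sigma2_trans`` are slab variances relative to the
    residual variance ``sigma2_e`` (the slab is N(0, sigma2_group *
    sigma2_e)). ``beta_a``/``beta_b`` are the Beta pseudocounts regularizing
    the inclusion-probability updates.
    """

    pi_cis: float = 1e-3
    pi_trans: float = 1e-5
    sigma2_cis: float = 1.0
    sigma2_trans: float = 1.0
    sigma2_e: float = 1.0
    beta_a: float = 0.1
    beta_b: float = 10.0
    mcmc_iters: int = 10_000
    burn_in: int = 2_000
    em_rounds: int = 3
    em_tol: float = 1e-3
    update_sigma_e: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi_cis", "pi_trans"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("sigma2_cis", "sigma2_trans", "sigma2_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.burn_in >= self.mcmc_iters:
            raise ValueError("burn_in must be smaller than mcmc_iters")


@dataclass
class BvsrFit:
    """Posterior summaries of one gene's fit over its selected variants."""

    pcp: np.ndarray            # posterior inclusion frequency, in [0, 1]
    effect: np.ndarray         # posterior mean effect conditional on inclusion
    is_cis: np.ndarray         # per-variant cis indicator
    hyper: BvsrHyperParams     # hyperparameters after the final M-step
    diagnostics: dict = field(default_factory=dict)
    variants: pd.DataFrame | None = None  # metadata aligned to pcp/effect


@njit(cache=True)
def _gibbs_block(G, Xty, yty, sigma2_e, tau2, logit_pi, u, zn, burn_in):  # pragma: no cover
    iters, p = u.shape
    w = np.zeros(p)
    gamma = np.zeros(p, dtype=np.int64)
    c = np.zeros(p)  # c = G @ w, maintained incrementally
    pcp_acc = np.zeros(p)
    w_acc = np.zeros(p)
    w2_acc = np.zeros(p)
    flips = 0
    sweeps_changed = 0
    kept = 0
    ll_sum = 0.0
    ll_sum2 = 0.0
    for t in range(iters):
        flips_before = flips
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            b = Xty[j] - c[j] + gjj * w[j]
            v = 1.0 / (gjj / sigma2_e + 1.0 / tau2[j])
            m = v * b / sigma2_e
            lo = logit_pi[j] + 0.5 * np.log(v / tau2[j]) + 0.5 * m * m / v
            if lo > 35.0:
                p_inc = 1.0
            elif lo < -35.0:
                p_inc = 0.0
            else:
                p_inc = 1.0 / (1.0 + np.exp(-lo))
            new_w = 0.0
            new_g = 0
            if u[t, j] < p_inc:
                new_g = 1
                new_w = m + np.sqrt(v) * zn[t, j]
            if new_g != gamma[j]:
                flips += 1
            if new_w != w[j]:
                delta = new_w - w[j]
                for k in range(p):
                    c[k] += G[k, j] * delta
                w[j] = new_w
            gamma[j] = new_g
        if flips > flips_before:
            sweeps_changed += 1
        if t >= burn_in:
            kept += 1
            wxty = 0.0
            wgw = 0.0
            for j in range(p):
                if gamma[j] == 1:
                    pcp_acc[j] += 1.0
                    w_acc[j] += w[j]
                    w2_acc[j] += w[j] * w[j]
                wxty += w[j] * Xty[j]
                wgw += w[j] * c[j]
            ll = -0.5 * (yty - 2.0 * wxty + wgw) / sigma2_e
            ll_sum += ll
            ll_sum2 += ll * ll
    return pcp_acc, w_acc, w2_acc, kept, flips, sweeps_changed, ll_sum, ll_sum2


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    return X / np.where(sd > 0, sd, 1.0)


def fit_bvsr(
    y: np.ndarray,
    X: np.ndarray,
    is_cis: np.ndarray,
    hyper: BvsrHyperParams | None = None,
    blocks: list[tuple[int, int]] | None = None,
) -> BvsrFit:
    """Fit the spike-and-slab model by EM-MCMC over the selected variants.

    ``X`` must hold the (concatenated) selected blocks with standardized
    columns; ``blocks`` lists half-open column ranges fit independently
    (default: one block). Each block's Gibbs chain is seeded from the global
    seed plus the block's start column and the EM round, so results do not
    depend on processing order. Returns PCPs (posterior inclusion
    frequencies) and effects (posterior means conditional on inclusion).
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValueError("y and X must be finite")
    hyper = hyper or BvsrHyperParams()
    n, p = X.shape
    is_cis = np.asarray(is_cis, dtype=bool)
    if is_cis.shape != (p,):
        raise ValueError("is_cis must have one flag per column of X")
    if blocks is None:
        blocks = [(0, p)]

    yty = float(y @ y)
    pre = []
    for (start, stop) in blocks:
        Xb = X[:, start:stop]
        pre.append((start, stop, Xb.T @ Xb, Xb.T @ y))

    hp = replace(hyper)
    pcp = np.zeros(p)
    eff = np.zeros(p)
    m2 = np.zeros(p)
    total_flips = 0
    total_updates = 0
    total_sweeps_changed = 0
    total_sweeps = 0
    ll_mean = ll_sd = 0.0
    rounds_run = 0

    for r in range(hp.em_rounds):
        rounds_run = r + 1
        tau2_groups = np.where(is_cis, hp.sigma2_cis, hp.sigma2_trans) * hp.sigma2_e
        logit_pi = np.where(
            is_cis,
            np.log(hp.pi_cis / (1 - hp.pi_cis)),
            np.log(hp.pi_trans / (1 - hp.pi_trans)),
        )
        ll_s = ll_s2 = 0.0
        kept_total = 0
        for (start, stop, G, Xty) in pre:
            pb = stop - start
            rng = np.random.default_rng([hp.seed, 1009 + r, start])
            u = rng.random((hp.mcmc_iters, pb))
            zn = rng.standard_normal((hp.mcmc_iters, pb))
            pcp_acc, w_acc, w2_acc, kept, flips, sw_changed, s, s2 = _gibbs_block(
                G, Xty, yty, hp.sigma2_e, tau2_groups[start:stop],
                logit_pi[start:stop], u, zn, hp.burn_in,
            )
            denom = np.maximum(pcp_acc, 1.0)
            pcp[start:stop] = pcp_acc / kept
            eff[start:stop] = w_acc / denom
            m2[start:stop] = w2_acc / denom
            total_flips += flips
            total_updates += hp.mcmc_iters * pb
            total_sweeps_changed += sw_changed
            total_sweeps += hp.mcmc_iters
            ll_s += s
            ll_s2 += s2
            kept_total += kept
        ll_mean = ll_s / kept_total
        ll_sd = float(np.sqrt(max(ll_s2 / kept_total - ll_mean**2, 0.0)))

        if r == hp.em_rounds - 1:
            break
        new_hp = _m_step(hp, pcp, eff, m2, is_cis, pre, yty, n)
        changes = [
            abs(getattr(new_hp, f) - getattr(hp, f)) / max(abs(getattr(hp, f)), 1e-12)
            for f in ("pi_cis", "pi_trans", "sigma2_cis", "sigma2_trans", "sigma2_e")
        ]
        hp = new_hp
        if max(changes) < hp.em_tol:
            break

    # "acceptance rate": fraction of sweeps in which the inclusion state moved
    acceptance_rate = total_sweeps_changed / max(total_sweeps, 1)
    diagnostics = {
        "acceptance_rate": acceptance_rate,
        "flip_rate": total_flips / max(total_updates, 1),
        "em_rounds_run": rounds_run,
        "logpost_mean": ll_mean,
        "logpost_sd": ll_sd,
        "n_blocks": len(blocks),
    }
    if not 0.01 <= acceptance_rate <= 0.99:
        diagnostics["acceptance_warning"] = (
            f"MCMC acceptance rate {acceptance_rate:.4g} outside [0.01, 0.99]"
        )
        warnings.warn(diagnostics["acceptance_warning"], RuntimeWarning, stacklevel=2)
    return BvsrFit(pcp=pcp, effect=eff, is_cis=is_cis, hyper=hp, diagnostics=diagnostics)


def _m_step(hp, pcp, eff, m2, is_cis, pre, yty, n):
    """Closed-form hyperparameter updates from pooled posterior summaries."""
    def update_pi(mask, current):
        k = int(mask.sum())
        if k == 0:
            return current
        val = (pcp[mask].sum() + hp.beta_a) / (k + hp.beta_a + hp.beta_b)
        return float(np.clip(val, 1e-8, 1 - 1e-8))

    def update_sigma2(mask, current):
        mass = pcp[mask].sum()
        if mass < 1e-8:
            return current
        val = float((pcp[mask] * m2[mask]).sum() / (hp.sigma2_e * mass))
        return max(val, 1e-6)

    new_pi_cis = update_pi(is_cis, hp.pi_cis)
    new_pi_trans = update_pi(~is_cis, hp.pi_trans)
    new_s2_cis = update_sigma2(is_cis, hp.sigma2_cis)
    new_s2_trans = update_sigma2(~is_cis, hp.sigma2_trans)

    new_sigma_e = hp.sigma2_e
    if hp.update_sigma_e:
        w_hat = pcp * eff
        rss = yty
        for (start, stop, G, Xty) in pre:
            wb = w_hat[start:stop]
            rss -= 2.0 * wb @ Xty[: stop - start] - wb @ G @ wb
        new_sigma_e = max(float(rss / n), 1e-6 * yty / n)

    return replace(
        hp,
        pi_cis=new_pi_cis,
        pi_trans=new_pi_trans,
        sigma2_cis=new_s2_cis,
        sigma2_trans=new_s2_trans,
        sigma2_e=new_sigma_e,
    )


def compute_weights(
    fit: BvsrFit, pcp_floor: float = 0.01, gene_id: str = "gene"
) -> pd.DataFrame:
    """Turn a fit into the per-variant weight table w~ = PCP x effect.

    Variants with PCP strictly below ``pcp_floor`` are dropped. Requires
    variant metadata on the fit to emit the full table.
    """
    keep = fit.pcp >= pcp_floor
    idx = np.nonzero(keep)[0]
    meta = fit.variants
    if meta is None:
        meta = pd.DataFrame(
            {
                "id": [f"col{i}" for i in range(len(fit.pcp))],
                "chr": "NA", "pos": 0, "ref": "N", "alt": "N",
            }
        )
    out = pd.DataFrame(
        {
            "gene_id": gene_id,
            "variant_id": meta["id"].to_numpy()[idx],
            "chr": meta["chr"].to_numpy()[idx],
            "pos": meta["pos"].to_numpy()[idx],
            "ref": meta["ref"].to_numpy()[idx],
            "alt": meta["alt"].to_numpy()[idx],
            "cis_trans": np.where(fit.is_cis[idx], "cis", "trans"),
            "pcp": fit.pcp[idx],
            "effect": fit.effect[idx],
            "weight": fit.pcp[idx] * fit.effect[idx],
        }
    )[WEIGHT_COLUMNS]
    return out


def train_gene(
    y: np.ndarray,
    panel: GenotypePanel,
    gene_id: str,
    gene_chr: str,
    gene_tss: int,
    block_size: int = 1000,
    cis_window: int = DEFAULT_CIS_WINDOW,
    p_threshold: float = 1e-5,
    hyper: BvsrHyperParams | None = None,
    pcp_floor: float = 0.01,
) -> tuple[pd.DataFrame, BvsrFit, BlockSelection]:
    """Screen, fit and weight one gene against a filtered reference panel."""
    blocks = segment_genome(panel, block_size)
    selection = screen_blocks(
        y, panel, blocks, gene_chr, gene_tss, cis_window, p_threshold
    )
    col_idx = np.concatenate(
        [np.arange(start, stop) for (_c, start, stop) in selection.blocks.ranges]
    ) if len(selection.blocks) else np.array([], dtype=int)
    if col_idx.size == 0:
        raise EmptyPanelError(f"no blocks selected for gene {gene_id}")

    sub = panel.subset_variants(col_idx)
    X = _standardize_columns(sub.mean_imputed())
    flags = cis_flags(sub.variants, gene_chr, gene_tss, cis_window)
    # column ranges of the selected blocks inside the concatenated matrix
    local_blocks: list[tuple[int, int]] = []
    off = 0
    for (_c, start, stop) in selection.blocks.ranges:
        local_blocks.append((off, off + (stop - start)))
        off += stop - start

    fit = fit_bvsr(y, X, flags, hyper=hyper, blocks=local_blocks)
    fit.variants = sub.variants
    weights = compute_weights(fit, pcp_floor=pcp_floor, gene_id=gene_id)
    return weights, fit, selection
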