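"""Reference-panel QC and expression normalization.

Implements the panel-preparation rules applied before eQTL weight training:

* variant filters — missing rate < 20%, MAF > 0.01, Hardy-Weinberg
  equilibrium p > 1e-5 (all strict inequalities);
* expression normalization — median-of-ratios size factors, natural-log
  transform with an offset of 1, retention of genes with value > 1 in > 10%
  of samples, then per-gene centering and scaling;
* outlier-sample detection — average-linkage hierarchical clustering on
  cosine distance, per-sample chi-square p-values from a regularized
  Mahalanobis distance, and exclusion of clusters in which >= 60% of samples
  are Bonferroni-flagged;
* covariate adjustment — per-gene least-squares residuals on genotype
  principal components, hidden expression factors (top PCs of the normalized
  matrix, a deterministic stand-in for probabilistic factor models) and
  supplied covariates, re-standardized to mean 0, SD 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .types import EmptyPanelError, ExpressionState, GenotypePanel


@dataclass
class VariantQCThresholds:
    """Strict-inequality variant retention thresholds."""

    max_missing: float = 0.20
    min_maf: float = 0.01
    min_hwe_p: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("max_missing", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against Hardy-Weinberg
    proportions expected from the sample allele frequency.

    Monomorphic variants (allele frequency 0 or 1) return p = 1: no
    departure is testable.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    q = (2 * n_hom_alt + n_het) / (2 * n)  # alt allele frequency
    if q == 0.0 or q == 1.0:
        return 1.0
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = np.sum((observed - expected) ** 2 / expected)
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype class counts; non-integral (imputed) entries are
    ignored so that filtering stays idempotent after mean imputation."""
    obs = column[~np.isnan(column)]
    integral = obs[np.isclose(obs, np.rint(obs))]
    g = np.rint(integral)
    return int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2))


def filter_variants(
    panel: GenotypePanel, thresholds: VariantQCThresholds | None = None
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Apply the variant QC filters and mean-impute surviving missing dosages.

    Returns the filtered panel and a per-variant report with the measured
    statistics and pass/fail flags. Raises :class:`EmptyPanelError` if no
    variant survives.
    """
    if panel.n_variants == 0:
        raise EmptyPanelError("input panel has no variants")
    thresholds = thresholds or VariantQCThresholds()

    missing = panel.missing_rate()
    maf = panel.maf()
    hwe_p = np.array(
        [hwe_test(*_genotype_counts(panel.dosages[:, j])) for j in range(panel.n_variants)]
    )

    pass_missing = missing < thresholds.max_missing
    pass_maf = maf > thresholds.min_maf
    pass_hwe = hwe_p > thresholds.min_hwe_p
    kept = pass_missing & pass_maf & pass_hwe

    reasons = []
    for pm, pf, ph in zip(pass_missing, pass_maf, pass_hwe):
        fails = [
            tag for tag, ok in (("missing", pm), ("maf", pf), ("hwe", ph)) if not ok
        ]
        reasons.append(",".join(fails) if fails else "pass")
    report = pd.DataFrame(
        {
            "id": panel.variants["id"],
            "missing_rate": missing,
            "maf": maf,
            "hwe_p": hwe_p,
            "pass_missing": pass_missing,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
            "kept": kept,
            "reason": reasons,
        }
    )

    if not kept.any():
        raise EmptyPanelError(
            f"all {panel.n_variants} variants removed by QC filters"
        )
    filtered = panel.subset_variants(np.nonzero(kept)[0])
    filtered = GenotypePanel(
        dosages=filtered.mean_imputed(),
        variants=filtered.variants,
        samples=filtered.samples,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# expression normalization
# ---------------------------------------------------------------------------

def size_factors_median_of_ratios(counts: np.ndarray, samples: list[str]) -> np.ndarray:
    """Median-of-ratios size factors (the DESeq2 estimator).

    Per sample: median over reference genes of count / geometric mean of
    that gene across samples, where reference genes are those with a nonzero
    geometric mean (i.e. no zero count in any sample).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    zero_samples = np.nonzero(counts.sum(axis=0) == 0)[0]
    if zero_samples.size:
        raise ValueError(
            f"all counts are zero for sample(s): {[samples[i] for i in zero_samples]}"
        )
    all_positive = np.all(counts > 0, axis=1)
    if not all_positive.any():
        raise ValueError("no gene with a nonzero geometric mean; cannot size-factor")
    log_gm = np.mean(np.log(counts[all_positive]), axis=1)
    ratios = counts[all_positive] / np.exp(log_gm)[:, None]
    sf = np.median(ratios, axis=0)
    bad = np.nonzero(sf <= 0)[0]
    if bad.size:
        raise ValueError(
            f"size factor undefined for sample(s): {[samples[i] for i in bad]}"
        )
    return sf


def normalize_expression(
    raw: ExpressionState,
    min_log_value: float = 1.0,
    min_sample_frac: float = 0.10,
) -> ExpressionState:
    """Size-factor normalize, log-transform (offset 1, natural log), filter
    lowly expressed genes, then center/scale per gene.

    A gene is retained iff its log value exceeds ``min_log_value`` in
    strictly more than ``min_sample_frac`` of samples. Genes with zero
    variance after the transform are also dropped (unscalable).
    """
    if raw.state_tag != "raw":
        raise ValueError(f"expected raw counts, got state {raw.state_tag!r}")
    sf = size_factors_median_of_ratios(raw.values, raw.samples)
    logged = np.log(raw.values / sf[None, :] + 1.0)

    expressed_frac = np.mean(logged > min_log_value, axis=1)
    keep = expressed_frac > min_sample_frac
    # constant genes are unscalable; 1e-12 tolerance absorbs log() rounding
    sd = logged.std(axis=1, ddof=1)
    keep &= sd > 1e-12
    if not keep.any():
        raise ValueError("no gene passes the expression filter")

    vals = logged[keep]
    vals = vals - vals.mean(axis=1, keepdims=True)
    vals = vals / vals.std(axis=1, ddof=1, keepdims=True)
    return ExpressionState(
        values=vals,
        genes=raw.genes.iloc[np.nonzero(keep)[0]],
        samples=list(raw.samples),
        state_tag="normalized",
        size_factors=sf,
    )


# ---------------------------------------------------------------------------
# outlier samples
# ---------------------------------------------------------------------------

def detect_outlier_samples(
    normalized: ExpressionState,
    n_clusters: int = 10,
    subspace_dim: int | None = 10,
    alpha: float = 0.05,
    cluster_flag_frac: float = 0.60,
) -> set[str]:
    """Flag whole clusters of aberrant samples.

    Samples are hierarchically clustered (average linkage, cosine distance
    between expression profiles). Each sample gets a chi-square p-value from
    a regularized squared Mahalanobis distance to the sample center: scores
    on the top ``subspace_dim`` principal components, each axis standardized
    by its median and scaled MAD. The robust center/scale keeps a compact
    block of aberrant samples from inflating its own covariance and masking
    itself, and the subspace keeps the estimate well-conditioned when genes
    outnumber samples. ``subspace_dim=None`` requests the classical
    full-covariance distance, which needs more samples than genes. Samples
    with Bonferroni-corrected p < ``alpha`` are flagged; any cluster with
    >= ``cluster_flag_frac`` flagged samples is returned wholesale.
    """
    X = normalized.values.T  # samples x genes
    n, g = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for outlier detection")

    if subspace_dim is None:
        if g >= n:
            raise ValueError(
                "more genes than samples: full-covariance Mahalanobis is "
                "singular; use the regularized mode (subspace_dim=<int>)"
            )
        dim = g
        centered = X - X.mean(axis=0)
        cov = np.cov(centered, rowvar=False, ddof=1)
        d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.pinv(cov), centered)
    else:
        dim = min(subspace_dim, n - 1, g)
        pca = PCA(n_components=dim, svd_solver="full")
        scores = pca.fit_transform(X)
        med = np.median(scores, axis=0)
        mad = stats.median_abs_deviation(scores, axis=0, scale="normal")
        sd = scores.std(axis=0, ddof=1)
        scale = np.where(mad > 1e-12, mad, sd)  # MAD=0: fall back to SD
        usable = scale > 1e-12
        dim = int(usable.sum())
        if dim == 0:
            return set()  # no variation at all: nothing can be an outlier
        z = (scores[:, usable] - med[usable]) / scale[usable]
        d2 = np.sum(z**2, axis=1)

    pvals = stats.chi2.sf(d2, df=dim)
    flagged = pvals < alpha / n  # Bonferroni over samples

    dist = pdist(X, metric="cosine")
    labels = fcluster(linkage(dist, method="average"), t=min(n_clusters, n), criterion="maxclust")

    outliers: set[str] = set()
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        if flagged[members].mean() >= cluster_flag_frac:
            outliers.update(normalized.samples[i] for i in members)
    return outliers


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def genotype_pcs(panel: GenotypePanel, n_components: int) -> np.ndarray:
    """Top principal components of the standardized dosage matrix."""
    if n_components == 0:
        return np.empty((panel.n_samples, 0))
    n_components = min(n_components, panel.n_samples - 1, panel.n_variants)
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(panel.standardized())


def hidden_expression_factors(normalized: ExpressionState, n_factors: int) -> np.ndarray:
    """Top principal components of the normalized expression matrix (over
    samples) — the deterministic hidden-factor surrogate."""
    if n_factors == 0:
        return np.empty((normalized.n_samples, 0))
    n_factors = min(n_factors, normalized.n_samples - 1, normalized.n_genes)
    pca = PCA(n_components=n_factors, svd_solver="full")
    return pca.fit_transform(normalized.values.T)


def _encode_covariates(covariates: pd.DataFrame, samples: list[str]) -> tuple[np.ndarray, list[str]]:
    df = covariates.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id").reindex(samples)
        if df.isna().all(axis=1).any():
            missing = [s for s in samples if s not in covariates["sample_id"].values]
            raise ValueError(f"covariates missing for samples: {missing[:5]}")
    elif len(df) != len(samples):
        raise ValueError("covariate rows do not align with samples")
    cols, names = [], []
    for c in df.columns:
        col = df[c]
        if col.dtype.kind in "OUSb":  # categorical: one-hot, drop first level
            dummies = pd.get_dummies(col, prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
                names.append(dc)
        else:
            v = col.to_numpy(dtype=float)
            sd = v.std()
            cols.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
            names.append(c)
    if not cols:
        return np.empty((len(samples), 0)), []
    return np.column_stack(cols), names


def adjust_covariates(
    normalized: ExpressionState,
    covariates: pd.DataFrame | None = None,
    n_hidden_factors: int = 0,
    n_genotype_pcs: int = 0,
    genotype_panel: GenotypePanel | None = None,
) -> ExpressionState:
    """Regress out covariates per gene and re-standardize the residuals.

    The design is [intercept | genotype PCs | hidden expression factors |
    encoded covariates]; residuals are the quantitative traits passed to
    eQTL weight training. With no covariates and no factors the output
    equals the (already standardized) input.
    """
    if normalized.state_tag == "raw":
        raise ValueError("adjust_covariates expects normalized expression")
    n = normalized.n_samples
    parts = [np.ones((n, 1))]
    names = ["intercept"]
    if n_genotype_pcs > 0:
        if genotype_panel is None:
            raise ValueError("genotype_panel required when n_genotype_pcs > 0")
        gp = genotype_pcs(genotype_panel, n_genotype_pcs)
        parts.append(gp)
        names += [f"geno_pc{i+1}" for i in range(gp.shape[1])]
    if n_hidden_factors > 0:
        hf = hidden_expression_factors(normalized, n_hidden_factors)
        parts.append(hf)
        names += [f"factor{i+1}" for i in range(hf.shape[1])]
    if covariates is not None and len(covariates.columns):
        enc, enc_names = _encode_covariates(covariates, normalized.samples)
        parts.append(enc)
        names += enc_names
    D = np.column_stack(parts)

    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        _, R = np.linalg.qr(D)
        collinear = [names[j] for j in range(D.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {collinear}")

    Y = normalized.values.T  # samples x genes
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = (Y - D @ beta).T  # genes x samples
    sd = resid.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    resid = (resid - resid.mean(axis=1, keepdims=True)) / sd
    return ExpressionState(
        values=resid,
        genes=normalized.genes,
        samples=list(normalized.samples),
        state_tag="adjusted",
        size_factors=normalized.size_factors,
    )
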