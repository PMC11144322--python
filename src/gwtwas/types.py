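"""Core in-memory containers shared across the pipeline stages.

The package moves three kinds of data between stages: a reference genotype
panel (dosages plus variant metadata), gene expression matrices at successive
processing states (raw counts -> normalized -> covariate-adjusted residuals),
and per-variant GWAS summary statistics. Tabular payloads are pandas
DataFrames; dense numerics are numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: columns every variant-metadata table must carry, in canonical order
VARIANT_COLUMNS = ["id", "chr", "pos", "ref", "alt"]

#: minimal GWAS summary-statistic columns (beta/se are optional extras)
GWAS_COLUMNS = ["id", "chr", "pos", "ref", "alt", "Z", "n"]

#: per-variant eQTL weight table emitted by Stage I
WEIGHT_COLUMNS = [
    "gene_id", "variant_id", "chr", "pos", "ref", "alt",
    "cis_trans", "pcp", "effect", "weight",
]


class EmptyPanelError(ValueError):
    """Raised when an operation would leave (or receive) a panel with no variants."""


@dataclass
class GenotypePanel:
    """Dosage matrix (samples x variants) with per-variant metadata.

    ``dosages`` holds additive allele counts in {0, 1, 2}; missing entries
    are ``NaN``. ``variants`` is a DataFrame with columns ``id, chr, pos,
    ref, alt`` aligned to the dosage columns.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        n, p = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} dosage rows")
        if len(self.variants) != p:
            raise ValueError(f"{len(self.variants)} variant rows for {p} dosage columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def missing_rate(self) -> np.ndarray:
        """Per-variant fraction of missing dosages."""
        return np.mean(np.isnan(self.dosages), axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency over observed dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency."""
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, index: np.ndarray | list[int]) -> "GenotypePanel":
        idx = np.asarray(index)
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )

    def mean_imputed(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by the variant mean."""
        X = self.dosages.copy()
        if np.isnan(X).any():
            col_mean = np.nanmean(X, axis=0)
            nan_r, nan_c = np.nonzero(np.isnan(X))
            X[nan_r, nan_c] = col_mean[nan_c]
        return X

    def standardized(self) -> np.ndarray:
        """Mean-imputed dosages scaled to column mean 0, SD 1 (ddof=1).

        Monomorphic columns (zero variance) are returned as all-zero rather
        than raising, so callers can screen them out explicitly.
        """
        X = self.mean_imputed()
        X -= X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd_safe = np.where(sd > 0, sd, 1.0)
        return X / sd_safe


@dataclass
class ExpressionState:
    """Gene x sample expression matrix tagged with its processing state.

    ``state_tag`` is one of ``raw`` (counts), ``normalized`` (size-factor
    scaled, log1p-transformed, centered/standardized) or ``adjusted``
    (covariate-regression residuals, re-standardized).
    """

    values: np.ndarray
    genes: pd.DataFrame  # columns: gene_id, chr, tss
    samples: list[str]
    state_tag: str = "raw"
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} != (n_genes={len(self.genes)}, "
                f"n_samples={len(self.samples)})"
            )
        if self.state_tag not in ("raw", "normalized", "adjusted"):
            raise ValueError(f"unknown state_tag {self.state_tag!r}")
        if self.state_tag != "raw":
            if self.size_factors is None:
                raise ValueError(f"state {self.state_tag!r} requires size_factors")
            if np.any(np.asarray(self.size_factors) <= 0):
                raise ValueError("size factors must be positive")
        self.genes = self.genes.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, index) -> "ExpressionState":
        idx = np.asarray(index)
        return replace(
            self,
            values=self.values[idx],
            genes=self.genes.iloc[idx].reset_index(drop=True),
        )

    def subset_samples(self, index) -> "ExpressionState":
        idx = np.asarray(index)
        sf = self.size_factors[idx] if self.size_factors is not None else None
        return replace(
            self,
            values=self.values[:, idx],
            samples=[self.samples[i] for i in idx],
            size_factors=sf,
        )


@dataclass
class TrueEffects:
    """Ground-truth eQTL effects realized for one simulated gene.

    ``weights`` is the full-length per-variant effect vector on the
    standardized-genotype scale (zero off the causal set); ``sigma2_e`` the
    residual variance of the expression trait.
    """

    gene_id: str
    weights: np.ndarray
    sigma2_e: float
    cis_indices: list[int] = field(default_factory=list)
    trans_indices: list[int] = field(default_factory=list)


def validate_gwas_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Check a GWAS summary table, deriving Z from beta/se if needed."""
    df = df.copy()
    if "Z" not in df.columns:
        if {"beta", "se"}.issubset(df.columns):
            df["Z"] = df["beta"] / df["se"]
        else:
            raise ValueError("GWAS summary needs a Z column or beta+se columns")
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS summary missing columns: {missing}")
    return df
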