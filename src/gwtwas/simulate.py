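"""Synthetic reference panels, expression traits and GWAS summaries.

Every downstream stage of the pipeline is exercised on data from this module,
so the generative model mirrors the assumed data-generating process end to
end:

* genotypes come in approximately independent LD blocks — within a block a
  latent Gaussian AR(1) chain is thresholded at Hardy-Weinberg quantiles for
  the drawn minor-allele frequency, giving dosages in {0, 1, 2} whose
  adjacent-variant correlation is calibrated to ``block_ld_rho``;
* a gene's expression trait is ``X_cis w_cis + X_trans w_trans + eps`` with
  Gaussian noise, the sparse causal set and heritability fixed by a
  :class:`GeneArchitecture`;
* the GWAS trait is partially mediated by the genes' genetically regulated
  expression, plus a polygenic background and noise, and is summarized to
  per-variant Z-scores so harmonization and the summary-level burden test can
  be tested against an individual-level oracle.

All randomness flows from ``numpy.random.default_rng`` seeded from the
scenario seed plus a fixed stream label per output, so identical scenarios
give bitwise-identical data regardless of call order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .types import GenotypePanel, TrueEffects, VARIANT_COLUMNS

DEFAULT_CIS_WINDOW = 1_000_000  # bp, inclusive on both sides of the TSS

# internal RNG stream labels (second word of the seed sequence)
_STREAM_VARIANTS = 10
_STREAM_REF = 0
_STREAM_GWAS = 1
_STREAM_EXPR = 2
_STREAM_TRAIT = 3
_STREAM_FIXTURE = 4

_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


def _stable_hash(text: str) -> int:
    """Deterministic 32-bit hash for seeding per-gene/tissue streams."""
    return zlib.crc32(text.encode("utf-8"))


@dataclass
class GeneArchitecture:
    """Sparse causal architecture of one simulated gene.

    ``cis_causal`` / ``trans_causal`` are lists of ``(variant_index,
    effect_size)`` pairs; effects are relative — they are rescaled at
    simulation time so the genetic component explains ``h2_expr`` of the
    expression variance.
    """

    gene_id: str
    chr: str
    tss: int
    cis_causal: list[tuple[int, float]] = field(default_factory=list)
    trans_causal: list[tuple[int, float]] = field(default_factory=list)
    h2_expr: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_expr < 1.0:
            raise ValueError(f"h2_expr must be in [0, 1), got {self.h2_expr}")
        causal = [i for i, _ in self.cis_causal] + [i for i, _ in self.trans_causal]
        if len(causal) != len(set(causal)):
            raise ValueError("duplicate causal variant index")


@dataclass
class SimulationScenario:
    """Full description of one synthetic study.

    The scenario owns every generative quantity: cohort sizes, LD structure,
    per-gene causal architectures, the mediation effect of genetically
    regulated expression on the GWAS trait, and the global seed.
    """

    n_ref_samples: int = 500
    n_gwas_samples: int = 5000
    n_variants: int = 1000
    n_blocks: int = 10
    block_ld_rho: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    genes: list[GeneArchitecture] = field(default_factory=list)
    mediation_alpha: float = 0.3
    trait_h2_background: float = 0.1
    seed: int = 0
    # --- secondary knobs -------------------------------------------------
    chromosomes: tuple[str, ...] = ("1",)
    variant_spacing: int = 10_000  # bp between adjacent variants
    missing_rate: float = 0.0
    tissues: tuple[str, ...] = ("tissue1",)
    n_null_genes: int = 0  # extra h2=0 filler genes added by write_fixture_set
    cis_window: int = DEFAULT_CIS_WINDOW

    def __post_init__(self) -> None:
        if not 0.0 <= self.block_ld_rho < 1.0:
            raise ValueError(f"block_ld_rho must be in [0, 1), got {self.block_ld_rho}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_variants % self.n_blocks != 0:
            raise ValueError(
                f"n_variants={self.n_variants} not divisible into "
                f"{self.n_blocks} equal blocks"
            )
        if not 0.0 <= self.trait_h2_background < 1.0:
            raise ValueError("trait_h2_background must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def block_size(self) -> int:
        return self.n_variants // self.n_blocks


# ---------------------------------------------------------------------------
# bivariate-normal machinery for LD calibration
# ---------------------------------------------------------------------------

def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal, via Owen's T.

    Valid for h, k < 0 (the only case the calibration needs: thresholds are
    Hardy-Weinberg quantiles of MAFs <= 0.5); zero thresholds are nudged.
    """
    if rho == 0.0:
        return stats.norm.cdf(h) * stats.norm.cdf(k)
    if rho >= 1.0 - 1e-12:
        return stats.norm.cdf(min(h, k))
    h = min(h, -1e-10)
    k = min(k, -1e-10)
    r = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * r)
    a_k = (h - rho * k) / (k * r)
    # h*k > 0 here, so the Owen correction term is zero
    return (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, a_h)
        - special.owens_t(k, a_k)
    )


def _dosage_corr(rho: float, f1: float, f2: float) -> float:
    """Dosage correlation induced by latent correlation ``rho`` after
    thresholding at the HW quantiles of allele frequencies ``f1``, ``f2``."""
    t1 = stats.norm.ppf(f1)
    t2 = stats.norm.ppf(f2)
    p11 = _bvn_cdf(t1, t2, rho)
    return (p11 - f1 * f2) / np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))


_LATENT_RHO_CAP = 0.999


def _calibrate_latent_rho(target: float, f1: float, f2: float) -> float:
    """Latent AR(1) parameter whose thresholded dosage correlation is
    ``target``; capped when the target exceeds the attainable maximum for
    the pair of allele frequencies (Frechet bound for binary margins)."""
    if target <= 0.0:
        return 0.0
    if _dosage_corr(_LATENT_RHO_CAP, f1, f2) <= target:
        return _LATENT_RHO_CAP
    return optimize.brentq(
        lambda r: _dosage_corr(r, f1, f2) - target, 0.0, _LATENT_RHO_CAP, xtol=1e-6
    )


# ---------------------------------------------------------------------------
# variant map (shared between the reference and GWAS cohorts)
# ---------------------------------------------------------------------------

def _block_chromosomes(scenario: SimulationScenario) -> list[str]:
    """Assign each block a chromosome, splitting blocks as evenly as possible."""
    n_chr = len(scenario.chromosomes)
    per = np.full(n_chr, scenario.n_blocks // n_chr)
    per[: scenario.n_blocks % n_chr] += 1
    out: list[str] = []
    for c, m in zip(scenario.chromosomes, per):
        out.extend([c] * int(m))
    return out


def _variant_map(scenario: SimulationScenario) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Variant metadata, per-variant MAFs and per-pair latent AR(1) rhos.

    Deterministic in the scenario seed and identical for every cohort drawn
    from the scenario.
    """
    rng = np.random.default_rng([scenario.seed, _STREAM_VARIANTS])
    p = scenario.n_variants
    mafs = rng.uniform(scenario.maf_range[0], scenario.maf_range[1], size=p)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=p)
    refs = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    alts = [_ALLELE_PAIRS[i][1] for i in pair_idx]

    block_chr = _block_chromosomes(scenario)
    bs = scenario.block_size
    chroms: list[str] = []
    pos = np.empty(p, dtype=np.int64)
    offset: dict[str, int] = {}
    for b in range(scenario.n_blocks):
        c = block_chr[b]
        start = offset.get(c, 0)
        for j in range(bs):
            chroms.append(c)
            pos[b * bs + j] = (start + j + 1) * scenario.variant_spacing
        offset[c] = start + bs

    variants = pd.DataFrame(
        {
            "id": [f"v{i:06d}" for i in range(p)],
            "chr": chroms,
            "pos": pos,
            "ref": refs,
            "alt": alts,
        }
    )

    # latent correlation between each variant and its predecessor (0 at block
    # starts — blocks are independent)
    latent_rho = np.zeros(p)
    if scenario.block_ld_rho > 0:
        for b in range(scenario.n_blocks):
            for j in range(1, bs):
                i = b * bs + j
                latent_rho[i] = _calibrate_latent_rho(
                    scenario.block_ld_rho, mafs[i - 1], mafs[i]
                )
    return variants, mafs, latent_rho


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_genotypes(
    scenario: SimulationScenario, cohort: str = "ref"
) -> GenotypePanel:
    """Draw a genotype panel for the reference or GWAS cohort.

    Two independent haplotypes per sample are generated from latent AR(1)
    Gaussian chains (one chain restart per block) and thresholded at the
    Hardy-Weinberg quantile of each variant's MAF; the dosage is their sum.
    Variant metadata and MAFs are shared between cohorts.
    """
    if cohort not in ("ref", "gwas"):
        raise ValueError(f"cohort must be 'ref' or 'gwas', got {cohort!r}")
    n = scenario.n_ref_samples if cohort == "ref" else scenario.n_gwas_samples
    stream = _STREAM_REF if cohort == "ref" else _STREAM_GWAS
    rng = np.random.default_rng([scenario.seed, stream])

    variants, mafs, latent_rho = _variant_map(scenario)
    p = scenario.n_variants
    thresholds = stats.norm.ppf(mafs)

    dosage = np.zeros((n, p), dtype=np.float64)
    for _hap in range(2):
        z = np.empty((n, p))
        e = rng.standard_normal((n, p))
        for j in range(p):
            r = latent_rho[j]
            if r == 0.0:
                z[:, j] = e[:, j]
            else:
                z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * e[:, j]
        dosage += (z < thresholds[None, :]).astype(np.float64)

    if scenario.missing_rate > 0:
        mask = rng.random((n, p)) < scenario.missing_rate
        dosage[mask] = np.nan

    samples = [f"{cohort}_s{i:05d}" for i in range(n)]
    return GenotypePanel(dosages=dosage, variants=variants, samples=samples)


def _check_architecture(
    panel: GenotypePanel, arch: GeneArchitecture, cis_window: int
) -> None:
    p = panel.n_variants
    var = panel.variants
    for idx, _ in arch.cis_causal + arch.trans_causal:
        if not 0 <= idx < p:
            raise IndexError(f"causal variant index {idx} out of range [0, {p})")
    lo, hi = arch.tss - cis_window, arch.tss + cis_window
    for idx, _ in arch.cis_causal:
        if not (
            var.at[idx, "chr"] == arch.chr and lo <= var.at[idx, "pos"] <= hi
        ):
            raise ValueError(
                f"cis causal index {idx} falls outside the cis window of {arch.gene_id}"
            )
    for idx, _ in arch.trans_causal:
        if var.at[idx, "chr"] == arch.chr and lo <= var.at[idx, "pos"] <= hi:
            raise ValueError(
                f"trans causal index {idx} falls inside the cis window of {arch.gene_id}"
            )


def simulate_expression(
    panel: GenotypePanel,
    arch: GeneArchitecture,
    seed: int | Sequence[int],
    sigma2_e: float | None = None,
    cis_window: int = DEFAULT_CIS_WINDOW,
) -> tuple[np.ndarray, TrueEffects]:
    """Simulate one gene's expression trait on a panel.

    The genetic component (on standardized dosages) is rescaled so that its
    sample variance is exactly ``h2_expr``; noise variance is ``1 - h2_expr``
    unless ``sigma2_e`` overrides it (0 gives a noiseless trait). Returns the
    trait vector and the realized :class:`~gwtwas.types.TrueEffects`.
    """
    _check_architecture(panel, arch, cis_window)
    rng = np.random.default_rng(seed)
    n, p = panel.dosages.shape
    w = np.zeros(p)
    for idx, eff in arch.cis_causal + arch.trans_causal:
        w[idx] = eff

    Xstd = panel.standardized()
    g = Xstd @ w
    if arch.h2_expr > 0 and np.any(w != 0):
        sd_g = g.std(ddof=1)
        if sd_g == 0:
            raise ValueError(f"genetic component of {arch.gene_id} has zero variance")
        scale = np.sqrt(arch.h2_expr) / sd_g
        w = w * scale
        g = g * scale
    else:
        w = np.zeros(p)
        g = np.zeros(n)

    s2 = (1.0 - arch.h2_expr) if sigma2_e is None else float(sigma2_e)
    if s2 < 0:
        raise ValueError("sigma2_e must be nonnegative")
    expr = g + (rng.normal(0.0, np.sqrt(s2), size=n) if s2 > 0 else 0.0)

    truth = TrueEffects(
        gene_id=arch.gene_id,
        weights=w,
        sigma2_e=s2,
        cis_indices=[i for i, _ in arch.cis_causal],
        trans_indices=[i for i, _ in arch.trans_causal],
    )
    return expr, truth


def gwas_zscores(y: np.ndarray, Xstd: np.ndarray) -> np.ndarray:
    """Per-variant association Z-scores of trait ``y`` on standardized dosages.

    Uses the asymptotic Wald form with the trait variance as the
    residual-variance estimate, ``Z_l = sqrt(n-1) * cor(y, x_l)`` — the
    convention under which the summary-level burden statistic is algebraically
    identical to the individual-level GReX regression Z when the LD reference
    equals the cohort.
    """
    n = len(y)
    yc = y - y.mean()
    sy = yc.std(ddof=1)
    if sy == 0:
        raise ValueError("trait has zero variance")
    corr = (Xstd.T @ yc) / ((n - 1) * sy)
    return np.sqrt(n - 1) * corr


def simulate_gwas_summary(
    panel_gwas: GenotypePanel,
    true_weight_sets: Sequence[TrueEffects] | Mapping[str, TrueEffects],
    mediation_alpha: float,
    trait_h2_background: float,
    seed: int | Sequence[int],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate the GWAS cohort trait and summarize it to per-variant stats.

    The trait is ``alpha * sum_genes GReX_g`` plus a polygenic background
    scaled to ``trait_h2_background`` of the background+noise variance, plus
    Gaussian noise. Returns the summary table (columns ``id, chr, pos, ref,
    alt, beta, se, Z, n``) and the raw trait vector (for oracle tests).
    """
    if not 0.0 <= trait_h2_background < 1.0:
        raise ValueError("trait_h2_background must be in [0, 1)")
    rng = np.random.default_rng(seed)
    Xstd = panel_gwas.standardized()
    n, p = Xstd.shape

    effects = list(true_weight_sets.values()) if isinstance(true_weight_sets, Mapping) \
        else list(true_weight_sets)
    mediated = np.zeros(n)
    for te in effects:
        mediated += Xstd @ te.weights
    mediated *= mediation_alpha

    background = np.zeros(n)
    if trait_h2_background > 0:
        u = Xstd @ rng.standard_normal(p)
        sd_u = u.std(ddof=1)
        if sd_u > 0:
            background = u * (np.sqrt(trait_h2_background) / sd_u)
    noise_sd = np.sqrt(1.0 - trait_h2_background)
    y = mediated + background + rng.normal(0.0, noise_sd, size=n)

    Z = gwas_zscores(y, Xstd)
    sy = (y - y.mean()).std(ddof=1)
    se = sy / np.sqrt(n - 1)
    summary = panel_gwas.variants[VARIANT_COLUMNS].copy()
    summary["beta"] = Z * se
    summary["se"] = se
    summary["Z"] = Z
    summary["n"] = n
    return summary, y


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def _filler_genes(scenario: SimulationScenario) -> list[GeneArchitecture]:
    """Deterministic h2=0 filler genes used to stabilize normalization."""
    rng = np.random.default_rng([scenario.seed, _STREAM_FIXTURE, 1])
    variants, _, _ = _variant_map(scenario)
    out = []
    for i in range(scenario.n_null_genes):
        row = variants.iloc[int(rng.integers(0, len(variants)))]
        out.append(
            GeneArchitecture(
                gene_id=f"null{i:03d}", chr=str(row["chr"]), tss=int(row["pos"]),
            )
        )
    return out


def scenario_genes(scenario: SimulationScenario) -> list[GeneArchitecture]:
    """The declared gene architectures plus the deterministic fillers."""
    return list(scenario.genes) + _filler_genes(scenario)


def simulate_reference_expression(
    scenario: SimulationScenario, panel_ref: GenotypePanel
) -> tuple[dict[str, np.ndarray], dict[str, TrueEffects]]:
    """Per-tissue trait matrices (genes x samples) and the per-gene truth.

    True eQTL weights are shared across tissues; the noise draw is
    independent per tissue.
    """
    genes = scenario_genes(scenario)
    traits: dict[str, np.ndarray] = {}
    truth: dict[str, TrueEffects] = {}
    for t_idx, tissue in enumerate(scenario.tissues):
        mat = np.empty((len(genes), panel_ref.n_samples))
        for g_idx, arch in enumerate(genes):
            expr, te = simulate_expression(
                panel_ref,
                arch,
                seed=[scenario.seed, _STREAM_EXPR, t_idx, _stable_hash(arch.gene_id)],
                cis_window=scenario.cis_window,
            )
            mat[g_idx] = expr
            if t_idx == 0:
                truth[arch.gene_id] = te
        traits[tissue] = mat
    return traits, truth


_COUNT_SHIFT = 5.0  # log-scale offset making synthetic counts positive and large


def traits_to_counts(
    traits: np.ndarray, size_factors: np.ndarray, shift: float = _COUNT_SHIFT
) -> np.ndarray:
    """Invert the size-factor/log1p normalization: counts whose normalized
    log value reproduces ``traits + shift`` up to integer rounding."""
    return np.rint(size_factors[None, :] * np.expm1(traits + shift)).clip(min=0)


def write_fixture_set(scenario: SimulationScenario, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a complete study on disk: genotypes, per-tissue raw counts,
    covariates, GWAS summary and ground-truth JSON.

    Returns a mapping of logical names to file paths. All files are plain TSV
    (JSON for the truth) and round-trip through :mod:`gwtwas.io`.
    """
    from . import io as gio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel_ref = simulate_genotypes(scenario, "ref")
    panel_gwas = simulate_genotypes(scenario, "gwas")
    genes = scenario_genes(scenario)
    traits, truth = simulate_reference_expression(scenario, panel_ref)

    rng = np.random.default_rng([scenario.seed, _STREAM_FIXTURE, 2])
    paths: dict[str, Path] = {}

    paths["genotype_ref"] = out / "genotype_ref.tsv"
    gio.write_genotype_tsv(panel_ref, paths["genotype_ref"])
    paths["genotype_gwas"] = out / "genotype_gwas.tsv"
    gio.write_genotype_tsv(panel_gwas, paths["genotype_gwas"])

    gene_meta = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes],
         "chr": [g.chr for g in genes],
         "tss": [g.tss for g in genes]}
    )
    for tissue in scenario.tissues:
        sf = np.exp(rng.normal(0.0, 0.3, size=panel_ref.n_samples))
        counts = traits_to_counts(traits[tissue], sf)
        path = out / f"expression_{tissue}_counts.tsv"
        gio.write_expression_counts_tsv(counts, gene_meta, panel_ref.samples, path)
        paths[f"expression_{tissue}"] = path

    covars = pd.DataFrame(
        {
            "sample_id": panel_ref.samples,
            "sex": rng.choice(["M", "F"], size=panel_ref.n_samples),
            "batch": rng.choice(["b1", "b2", "b3"], size=panel_ref.n_samples),
            "reads": rng.integers(20_000_000, 80_000_000, size=panel_ref.n_samples),
        }
    )
    paths["covariates"] = out / "covariates.tsv"
    covars.to_csv(paths["covariates"], sep="\t", index=False)

    summary, _ = simulate_gwas_summary(
        panel_gwas,
        truth,
        scenario.mediation_alpha,
        scenario.trait_h2_background,
        seed=[scenario.seed, _STREAM_TRAIT],
    )
    paths["gwas_summary"] = out / "gwas_summary.tsv"
    gio.write_gwas_tsv(summary, paths["gwas_summary"])

    vid = panel_ref.variants["id"]
    truth_doc = {
        "seed": scenario.seed,
        "mediation_alpha": scenario.mediation_alpha,
        "trait_h2_background": scenario.trait_h2_background,
        "tissues": list(scenario.tissues),
        "genes": {
            gid: {
                "cis_indices": te.cis_indices,
                "trans_indices": te.trans_indices,
                "cis_variant_ids": [vid.iat[i] for i in te.cis_indices],
                "trans_variant_ids": [vid.iat[i] for i in te.trans_indices],
                "weights": {
                    vid.iat[i]: float(te.weights[i])
                    for i in np.nonzero(te.weights)[0]
                },
                "sigma2_e": te.sigma2_e,
            }
            for gid, te in truth.items()
        },
    }
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps(truth_doc, indent=1))
    return paths
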