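"""End-to-end orchestration: simulate -> preprocess -> train -> test -> combine.

A single :class:`RunConfig` carries every stage's thresholds and the global
seed; :func:`run_pipeline` executes the stages in order, writes all artifacts
under the configured output directory and records a manifest (seeds, input
digests, per-stage record counts). Re-running with the same config reproduces
every output byte for byte: all randomness is derived from the global seed
plus stable per-gene/tissue labels, and gene-level parallelism changes only
wall time, never results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import io as gio
from .acat import combine_across_tissues
from .assoc import test_tissue
from .bvsr import BvsrHyperParams, train_gene
from .preprocess import (
    VariantQCThresholds,
    adjust_covariates,
    detect_outlier_samples,
    filter_variants,
    normalize_expression,
)
from .simulate import GeneArchitecture, SimulationScenario, write_fixture_set
from .types import GenotypePanel

log = logging.getLogger("gwtwas")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending context."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    block_size: int = 100
    cis_window: int = 1_000_000
    screen_p: float = 1e-5
    mcmc_iters: int = 10_000
    burn_in: int = 2_000
    em_rounds: int = 3
    pcp_floor: float = 0.01
    pi_cis: float = 1e-3
    pi_trans: float = 1e-5


@dataclass
class PreprocessConfig:
    max_missing: float = 0.20
    min_maf: float = 0.01
    min_hwe_p: float = 1e-5
    min_log_value: float = 1.0
    min_sample_frac: float = 0.10
    n_hidden_factors: int = 2
    n_genotype_pcs: int = 2
    detect_outliers: bool = True
    outlier_clusters: int = 10
    outlier_subspace_dim: int = 10


@dataclass
class TestConfig:
    alpha: float = 0.05
    cis_only: bool = False
    trans_method: str = "mass"


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML."""

    out_dir: str = "gwtwas_run"
    seed: int = 0
    jobs: int = 1
    scenario: SimulationScenario = field(default_factory=SimulationScenario)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    test: TestConfig = field(default_factory=TestConfig)
    combine_alpha: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scen = dict(d.get("scenario", {}))
        genes = [
            GeneArchitecture(
                gene_id=g["gene_id"], chr=str(g["chr"]), tss=int(g["tss"]),
                cis_causal=[tuple(x) for x in g.get("cis_causal", [])],
                trans_causal=[tuple(x) for x in g.get("trans_causal", [])],
                h2_expr=float(g.get("h2_expr", 0.0)),
            )
            for g in scen.pop("genes", [])
        ]
        for key in ("maf_range", "chromosomes", "tissues"):
            if key in scen and scen[key] is not None:
                scen[key] = tuple(scen[key])
        d["scenario"] = SimulationScenario(genes=genes, **scen)
        d["preprocess"] = PreprocessConfig(**d.get("preprocess", {}))
        d["train"] = TrainConfig(**d.get("train", {}))
        d["test"] = TestConfig(**d.get("test", {}))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def mini_scenario(seed: int = 0) -> SimulationScenario:
    """The bundled miniature study: 600 variants on two chromosomes, three
    architected genes (cis-driven, mixed, trans-driven) plus null fillers,
    two tissues."""
    genes = [
        GeneArchitecture(
            gene_id="geneA_cis", chr="1", tss=500_000,
            cis_causal=[(45, 1.0), (52, -0.8)], h2_expr=0.6,
        ),
        GeneArchitecture(
            gene_id="geneB_mixed", chr="1", tss=2_500_000,
            cis_causal=[(245, 1.0)], trans_causal=[(520, 1.0)], h2_expr=0.6,
        ),
        GeneArchitecture(
            gene_id="geneC_trans", chr="2", tss=400_000,
            trans_causal=[(120, 1.0), (200, -1.0)], h2_expr=0.7,
        ),
    ]
    return SimulationScenario(
        n_ref_samples=400,
        n_gwas_samples=3000,
        n_variants=600,
        n_blocks=12,
        block_ld_rho=0.3,
        maf_range=(0.1, 0.5),
        genes=genes,
        mediation_alpha=0.5,
        trait_h2_background=0.05,
        chromosomes=("1", "2"),
        variant_spacing=10_000,
        tissues=("tissueA", "tissueB"),
        n_null_genes=12,
        seed=seed,
    )


def mini_config(out_dir: str, seed: int = 0) -> RunConfig:
    """RunConfig for the bundled mini scenario, sized for a fast smoke run."""
    return RunConfig(
        out_dir=out_dir,
        seed=seed,
        scenario=mini_scenario(seed),
        train=TrainConfig(block_size=50, mcmc_iters=1200, burn_in=300, em_rounds=2),
        preprocess=PreprocessConfig(n_hidden_factors=0, n_genotype_pcs=2),
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _gene_seed(global_seed: int, tissue: str, gene_id: str) -> int:
    return (global_seed * 1_000_003 + zlib.crc32(f"{tissue}:{gene_id}".encode())) % (2**31)


def _subset_panel_samples(panel: GenotypePanel, keep: list[str]) -> GenotypePanel:
    index = {s: i for i, s in enumerate(panel.samples)}
    rows = [index[s] for s in keep]
    return GenotypePanel(
        dosages=panel.dosages[rows], variants=panel.variants, samples=list(keep)
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    scen = config.scenario

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        paths = write_fixture_set(scen, out / "fixture")
        manifest["stages"][stage] = {
            "n_variants": scen.n_variants,
            "n_ref_samples": scen.n_ref_samples,
            "n_gwas_samples": scen.n_gwas_samples,
            "tissues": list(scen.tissues),
        }
        log.info("simulate: %d variants, %d genes declared", scen.n_variants, len(scen.genes))
    except Exception as exc:
        raise PipelineError(f"stage simulate: {exc}") from exc

    # --- preprocess -------------------------------------------------------
    stage = "preprocess"
    pp = config.preprocess
    try:
        panel_raw = gio.read_genotypes(paths["genotype_ref"])
        thresholds = VariantQCThresholds(pp.max_missing, pp.min_maf, pp.min_hwe_p)
        panel, vreport = filter_variants(panel_raw, thresholds)
        covars = gio.read_covariates(paths["covariates"])
        adjusted_paths: dict[str, Path] = {}
        pp_counts: dict[str, dict] = {
            "variants_in": panel_raw.n_variants,
            "variants_kept": panel.n_variants,
        }
        vreport.to_csv(out / "variant_qc.tsv", sep="\t", index=False)
        for tissue in scen.tissues:
            raw = gio.read_expression_counts_tsv(paths[f"expression_{tissue}"])
            norm = normalize_expression(raw, pp.min_log_value, pp.min_sample_frac)
            outliers = (
                detect_outlier_samples(
                    norm, n_clusters=pp.outlier_clusters,
                    subspace_dim=pp.outlier_subspace_dim,
                )
                if pp.detect_outliers
                else set()
            )
            keep_idx = [i for i, s in enumerate(norm.samples) if s not in outliers]
            norm = norm.subset_samples(keep_idx)
            tissue_covars = covars[covars["sample_id"].isin(norm.samples)]
            tissue_panel = _subset_panel_samples(panel, norm.samples)
            adjusted = adjust_covariates(
                norm,
                covariates=tissue_covars[["sample_id", "sex", "batch"]]
                if {"sex", "batch"}.issubset(tissue_covars.columns) else None,
                n_hidden_factors=pp.n_hidden_factors,
                n_genotype_pcs=pp.n_genotype_pcs,
                genotype_panel=tissue_panel,
            )
            apath = out / f"expression_{tissue}_adjusted.tsv"
            gio.write_expression_state_tsv(adjusted, apath)
            adjusted_paths[tissue] = apath
            pp_counts[tissue] = {
                "genes_raw": raw.n_genes,
                "genes_kept": adjusted.n_genes,
                "samples_kept": adjusted.n_samples,
                "outlier_samples": sorted(outliers),
            }
            log.info(
                "preprocess[%s]: %d/%d genes kept, %d samples (%d outliers removed)",
                tissue, adjusted.n_genes, raw.n_genes, adjusted.n_samples, len(outliers),
            )
        manifest["stages"][stage] = pp_counts
        (out / "qc_summary.json").write_text(json.dumps(pp_counts, indent=1, default=str))
    except Exception as exc:
        raise PipelineError(f"stage preprocess: {exc}") from exc

    # --- train ------------------------------------------------------------
    stage = "train"
    tc = config.train
    try:
        weight_dir = out / "weights"
        train_counts: dict[str, dict] = {}
        for tissue in scen.tissues:
            adjusted = gio.read_expression_state_tsv(adjusted_paths[tissue])
            tissue_panel = _subset_panel_samples(panel, adjusted.samples)

            def _one(g_idx: int):
                row = adjusted.genes.iloc[g_idx]
                hyper = BvsrHyperParams(
                    pi_cis=tc.pi_cis, pi_trans=tc.pi_trans,
                    mcmc_iters=tc.mcmc_iters, burn_in=tc.burn_in,
                    em_rounds=tc.em_rounds,
                    seed=_gene_seed(config.seed, tissue, row["gene_id"]),
                )
                weights, fit, selection = train_gene(
                    adjusted.values[g_idx], tissue_panel,
                    gene_id=row["gene_id"], gene_chr=row["chr"], gene_tss=row["tss"],
                    block_size=tc.block_size, cis_window=tc.cis_window,
                    p_threshold=tc.screen_p, hyper=hyper, pcp_floor=tc.pcp_floor,
                )
                return row["gene_id"], weights, fit, selection

            results = Parallel(n_jobs=config.jobs)(
                delayed(_one)(i) for i in range(adjusted.n_genes)
            )
            tdir = weight_dir / tissue
            tdir.mkdir(parents=True, exist_ok=True)
            for gene_id, weights, fit, selection in sorted(results, key=lambda r: r[0]):
                gio.write_weights_tsv(weights, tdir / f"{gene_id}.weights.tsv")
                sidecar = {
                    "gene_id": gene_id,
                    "hyper": {
                        "pi_cis": fit.hyper.pi_cis, "pi_trans": fit.hyper.pi_trans,
                        "sigma2_cis": fit.hyper.sigma2_cis,
                        "sigma2_trans": fit.hyper.sigma2_trans,
                        "sigma2_e": fit.hyper.sigma2_e,
                    },
                    "diagnostics": fit.diagnostics,
                    "n_selected_blocks": len(selection.blocks),
                }
                (tdir / f"{gene_id}.json").write_text(
                    json.dumps(sidecar, indent=1, default=float)
                )
            train_counts[tissue] = {
                "genes_trained": len(results),
                "genes_with_weights": sum(1 for _g, w, _f, _s in results if len(w) > 0),
            }
            log.info("train[%s]: %d genes trained", tissue, len(results))
        manifest["stages"][stage] = train_counts
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage train: {exc}") from exc

    # --- test -------------------------------------------------------------
    stage = "test"
    try:
        gwas = gio.read_gwas_tsv(paths["gwas_summary"])
        assoc_paths: dict[str, Path] = {}
        tissue_tables: dict[str, pd.DataFrame] = {}
        for tissue in scen.tissues:
            tdir = weight_dir / tissue
            weights_by_gene = {
                f.stem.replace(".weights", ""): gio.read_weights_tsv(f)
                for f in sorted(tdir.glob("*.weights.tsv"))
            }
            weights_by_gene = {g: w for g, w in weights_by_gene.items() if len(w) > 0}
            adjusted = gio.read_expression_state_tsv(adjusted_paths[tissue])
            table = test_tissue(
                weights_by_gene, gwas, panel, adjusted.genes,
                tissue=tissue, alpha=config.test.alpha,
                cis_only=config.test.cis_only, trans_method=config.test.trans_method,
            )
            apath = out / f"association_{tissue}.tsv"
            table.to_csv(apath, sep="\t", index=False, float_format="%.10g")
            assoc_paths[tissue] = apath
            tissue_tables[tissue] = table
            log.info(
                "test[%s]: %d genes tested, %d significant",
                tissue, int(np.isfinite(table["p"]).sum()), int(table["significant"].sum()),
            )
        manifest["stages"][stage] = {
            t: {
                "genes_tested": int(np.isfinite(tab["p"]).sum()),
                "significant": int(tab["significant"].sum()),
                "trans_driven_significant": int(
                    (tab["significant"] & tab["trans_driven"]).sum()
                ),
            }
            for t, tab in tissue_tables.items()
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage test: {exc}") from exc

    # --- combine ----------------------------------------------------------
    stage = "combine"
    try:
        omnibus = combine_across_tissues(tissue_tables, alpha=config.combine_alpha)
        opath = out / "omnibus.tsv"
        omnibus.to_csv(opath, sep="\t", index=False, float_format="%.10g")
        manifest["stages"][stage] = {
            "genes_combined": len(omnibus),
            "significant": int(omnibus["significant"].sum()),
        }
        log.info("combine: %d genes, %d significant", len(omnibus),
                 int(omnibus["significant"].sum()))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage combine: {exc}") from exc

    for name, p in {**paths, **adjusted_paths, **assoc_paths, "omnibus": opath}.items():
        manifest["outputs"][str(name)] = {"path": str(p), "sha256": _sha256(Path(p))}
    manifest["config"] = config.to_dict()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(manifest: dict, out_dir: str | Path | None = None) -> tuple[str, dict]:
    """Human-readable run summary: per-tissue counts, trans-driven genes,
    cross-tissue overlap of significant genes, omnibus counts."""
    out = Path(out_dir or manifest["config"]["out_dir"])
    tissues = manifest["config"]["scenario"]["tissues"]
    sig_sets: dict[str, set] = {}
    trans_driven: dict[str, list[str]] = {}
    lines = ["gwtwas run report", "================="]
    for tissue in tissues:
        tab = pd.read_csv(out / f"association_{tissue}.tsv", sep="\t")
        sig = tab[tab["significant"].astype(bool)]
        sig_sets[tissue] = set(sig["gene_id"])
        trans_driven[tissue] = sorted(
            sig[sig["trans_driven"].astype(bool)]["gene_id"]
        )
        counts = manifest["stages"]["train"][tissue]
        lines.append(
            f"{tissue}: trained={counts['genes_trained']} "
            f"tested={int(pd.to_numeric(tab['p'], errors='coerce').notna().sum())} "
            f"significant={len(sig)} trans_driven_significant={len(trans_driven[tissue])}"
        )
        if trans_driven[tissue]:
            lines.append(f"  trans-driven: {', '.join(trans_driven[tissue])}")
    overlaps = {}
    ts = list(tissues)
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            overlaps[f"{ts[i]}&{ts[j]}"] = len(sig_sets[ts[i]] & sig_sets[ts[j]])
    if len(ts) > 1:
        overlaps["all"] = len(set.intersection(*sig_sets.values()))
    for key, v in overlaps.items():
        lines.append(f"overlap[{key}] = {v}")
    omn = pd.read_csv(out / "omnibus.tsv", sep="\t")
    lines.append(
        f"omnibus: combined={len(omn)} significant={int(omn['significant'].sum())}"
    )
    summary = {
        "per_tissue": {
            t: {
                "significant": sorted(sig_sets[t]),
                "trans_driven_significant": trans_driven[t],
            }
            for t in tissues
        },
        "overlaps": overlaps,
        "omnibus_significant": sorted(
            omn[omn["significant"].astype(bool)]["gene_id"]
        ),
    }
    text = "\n".join(lines)
    (out / "report.txt").write_text(text + "\n")
    (out / "report.json").write_text(json.dumps(summary, indent=1))
    return text, summary
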