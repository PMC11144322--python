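"""Shared fixtures: hand-constructed panels and weight tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gwtwas.types import GenotypePanel


def make_panel(
    dosages: np.ndarray,
    chrom: str | list[str] = "1",
    spacing: int = 10_000,
    ref: str = "A",
    alt: str = "G",
) -> GenotypePanel:
    """Panel with explicit dosages and simple deterministic metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    chroms = [chrom] * p if isinstance(chrom, str) else list(chrom)
    variants = pd.DataFrame(
        {
            "id": [f"v{i:03d}" for i in range(p)],
            "chr": chroms,
            "pos": [(i + 1) * spacing for i in range(p)],
            "ref": ref,
            "alt": alt,
        }
    )
    return GenotypePanel(
        dosages=dosages, variants=variants, samples=[f"s{i:03d}" for i in range(n)]
    )


def make_weight_table(
    variant_ids: list[str],
    weights: list[float],
    cis_trans: list[str] | None = None,
    gene_id: str = "gene",
    ref: str = "A",
    alt: str = "G",
) -> pd.DataFrame:
    """Minimal Stage-I weight table for Stage-II tests."""
    k = len(variant_ids)
    w = np.asarray(weights, dtype=float)
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "variant_id": variant_ids,
            "chr": "1",
            "pos": [(i + 1) * 10_000 for i in range(k)],
            "ref": ref,
            "alt": alt,
            "cis_trans": cis_trans if cis_trans is not None else ["cis"] * k,
            "pcp": 1.0,
            "effect": w,
            "weight": w,
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)
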