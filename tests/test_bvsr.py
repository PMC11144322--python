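"""Genome segmentation, screening and spike-and-slab fitting."""

import numpy as np
import pandas as pd
import pytest

from gwtwas.bvsr import (
    BvsrHyperParams,
    compute_weights,
    fit_bvsr,
    screen_blocks,
    segment_genome,
    single_variant_eqtl,
    train_gene,
)
from gwtwas.simulate import (
    GeneArchitecture,
    SimulationScenario,
    simulate_expression,
    simulate_genotypes,
)
from gwtwas.types import EmptyPanelError

from conftest import make_panel


FAST = BvsrHyperParams(mcmc_iters=1500, burn_in=300, em_rounds=2, seed=0)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "chroms, block_size, expected",
    [
        (["1"] * 100, 25, 4),           # even split
        (["1"] * 10 + ["2"] * 10, 15, 2),  # blocks never span chromosomes
        (["1"] * 5, 1, 5),              # one block per variant
        (["1"] * 10 + ["2"] * 4, 4, 4),  # short final blocks per chromosome
    ],
)
def test_segment_genome_block_counts(chroms, block_size, expected):
    panel = make_panel(np.zeros((3, len(chroms))), chrom=chroms)
    blocks = segment_genome(panel, block_size)
    assert len(blocks) == expected
    for chrom, start, stop in blocks:
        assert start < stop
        assert len(set(chroms[start:stop])) == 1


def test_segment_empty_panel_errors():
    panel = make_panel(np.zeros((3, 2)))
    panel.dosages = panel.dosages[:, :0]
    panel.variants = panel.variants.iloc[:0]
    with pytest.raises(EmptyPanelError):
        segment_genome(panel, 10)


# ---------------------------------------------------------------------------
# single-variant regression
# ---------------------------------------------------------------------------

def test_single_variant_perfect_fit():
    x = np.array([0.0, 1, 2, 1, 0, 2, 1, 0])
    beta, se, p = single_variant_eqtl(x, x)
    assert beta == pytest.approx(1.0)
    assert p < 1e-12


def test_single_variant_matches_statsmodels():
    """5-point slope/SE agree with an independent OLS implementation."""
    import statsmodels.api as sm

    x = np.array([0.0, 1, 2, 0, 1])
    y = np.array([0.3, 1.1, 2.2, -0.2, 0.9])
    beta, se, p = single_variant_eqtl(y, x)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    assert beta == pytest.approx(fit.params[1], rel=1e-10)
    assert se == pytest.approx(fit.bse[1], rel=1e-10)
    assert p == pytest.approx(fit.pvalues[1], rel=1e-10)


def test_single_variant_null_type_one_error():
    rng = np.random.default_rng(42)
    x = rng.integers(0, 3, size=50).astype(float)
    rejections = 0
    for _ in range(1000):
        y = rng.standard_normal(50)
        _, _, p = single_variant_eqtl(y, x)
        rejections += p < 0.05
    # binomial 95% CI around 50/1000
    assert 37 <= rejections <= 64


def test_single_variant_errors():
    with pytest.raises(ValueError, match="zero-variance"):
        single_variant_eqtl(np.arange(5.0), np.ones(5))
    with pytest.raises(ValueError):
        single_variant_eqtl(np.arange(2.0), np.arange(2.0))


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def screen_panel():
    sc = SimulationScenario(
        n_ref_samples=400, n_variants=300, n_blocks=6, block_ld_rho=0.3, seed=77
    )
    return simulate_genotypes(sc)


def test_screen_cis_blocks_always_selected(screen_panel):
    """A gene with no trans signal selects exactly the cis-overlapping
    blocks."""
    rng = np.random.default_rng(1)
    y = rng.standard_normal(screen_panel.n_samples)
    blocks = segment_genome(screen_panel, 50)
    sel = screen_blocks(y, screen_panel, blocks, "1", 500_000, p_threshold=1e-12)
    # cis window 1.5 Mb wide in variant space: positions 1e4..3e6
    assert all(sel.is_cis_block)
    pos = screen_panel.variants["pos"]
    for _c, start, stop in sel.blocks:
        assert pos[start:stop].min() <= 1_500_000


def test_screen_trans_block_threshold_is_strict(screen_panel):
    """A trans block is selected iff its best p is strictly below the
    threshold."""
    arch = GeneArchitecture(
        "g", "1", 500_000, trans_causal=[(250, 1.0)], h2_expr=0.3
    )
    y, _ = simulate_expression(screen_panel, arch, seed=5)
    blocks = segment_genome(screen_panel, 50)
    sel = screen_blocks(y, screen_panel, blocks, "1", 500_000, p_threshold=1e-5)
    trans_sel = [r for r, c in zip(sel.blocks.ranges, sel.is_cis_block) if not c]
    assert any(start <= 250 < stop for _c, start, stop in trans_sel)
    top_p = sel.report["top_p"].min()
    # exactly at the triggering variant's p the block must NOT be selected
    sel_eq = screen_blocks(y, screen_panel, blocks, "1", 500_000, p_threshold=top_p)
    assert not any(
        start <= 250 < stop
        for (_c, start, stop), c in zip(sel_eq.blocks.ranges, sel_eq.is_cis_block)
        if not c
    )


# ---------------------------------------------------------------------------
# spike-and-slab fit
# ---------------------------------------------------------------------------

def _standardize(X):
    X = X - X.mean(axis=0)
    return X / X.std(axis=0, ddof=1)


def test_fit_null_rarely_confident():
    """Pure-noise traits: max PCP stays below 0.5 in >= 90% of replicates."""
    sc = SimulationScenario(
        n_ref_samples=500, n_variants=200, n_blocks=2, block_ld_rho=0.2, seed=9
    )
    panel = simulate_genotypes(sc)
    X = _standardize(panel.mean_imputed())
    ok = 0
    for rep in range(20):
        y = np.random.default_rng(500 + rep).standard_normal(500)
        hyper = BvsrHyperParams(
            mcmc_iters=1500, burn_in=300, em_rounds=2, seed=rep
        )
        fit = fit_bvsr(y, X, np.ones(200, bool), hyper, blocks=[(0, 100), (100, 200)])
        ok += fit.pcp.max() < 0.5
    assert ok >= 18


def test_fit_recovers_single_strong_causal():
    sc = SimulationScenario(
        n_ref_samples=500, n_variants=200, n_blocks=2, block_ld_rho=0.2, seed=19
    )
    panel = simulate_genotypes(sc)
    arch = GeneArchitecture("g", "1", 500_000, cis_causal=[(50, 1.0)], h2_expr=0.5)
    y, te = simulate_expression(panel, arch, seed=3)
    X = _standardize(panel.mean_imputed())
    fit = fit_bvsr(y, X, np.ones(200, bool), FAST, blocks=[(0, 100), (100, 200)])
    assert fit.pcp[50] > 0.9
    assert fit.effect[50] == pytest.approx(te.weights[50], abs=0.1)


def test_fit_label_symmetry():
    """With equal cis/trans priors, the cis/trans flags are irrelevant."""
    rng = np.random.default_rng(23)
    X = _standardize(rng.integers(0, 3, size=(300, 50)).astype(float))
    y = X[:, 7] * 0.8 + rng.standard_normal(300)
    hyper = BvsrHyperParams(
        pi_cis=1e-3, pi_trans=1e-3, mcmc_iters=1000, burn_in=200,
        em_rounds=1, seed=4,
    )
    fit_cis = fit_bvsr(y, X, np.ones(50, bool), hyper)
    fit_trans = fit_bvsr(y, X, np.zeros(50, bool), hyper)
    np.testing.assert_array_equal(fit_cis.pcp, fit_trans.pcp)
    np.testing.assert_array_equal(fit_cis.effect, fit_trans.effect)


def test_fit_vanishing_slab_kills_effects():
    rng = np.random.default_rng(29)
    X = _standardize(rng.integers(0, 3, size=(200, 30)).astype(float))
    y = X[:, 3] + 0.2 * rng.standard_normal(200)
    hyper = BvsrHyperParams(
        sigma2_cis=1e-8, sigma2_trans=1e-8, mcmc_iters=1000, burn_in=200,
        em_rounds=1, seed=1,
    )
    fit = fit_bvsr(y, X, np.ones(30, bool), hyper)
    assert np.abs(fit.pcp * fit.effect).max() < 1e-3


def test_fit_seeded_determinism_and_block_order():
    rng = np.random.default_rng(31)
    X = _standardize(rng.integers(0, 3, size=(300, 60)).astype(float))
    y = X[:, 10] * 0.7 + X[:, 40] * 0.5 + rng.standard_normal(300)
    flags = np.ones(60, bool)
    a = fit_bvsr(y, X, flags, FAST, blocks=[(0, 30), (30, 60)])
    b = fit_bvsr(y, X, flags, FAST, blocks=[(0, 30), (30, 60)])
    np.testing.assert_array_equal(a.pcp, b.pcp)
    np.testing.assert_array_equal(a.effect, b.effect)
    # permuting block processing order changes PCPs only within MC error
    perm = np.r_[np.arange(30, 60), np.arange(0, 30)]
    c = fit_bvsr(y[:], X[:, perm], flags, FAST, blocks=[(0, 30), (30, 60)])
    np.testing.assert_allclose(c.pcp[perm.argsort()], a.pcp, atol=0.05)


def test_fit_rejects_nonfinite():
    with pytest.raises(ValueError):
        fit_bvsr(np.array([1.0, np.nan, 0.0]), np.zeros((3, 2)), np.ones(2, bool))


def test_compute_weights_product_and_floor():
    fit_stub = type("F", (), {})()
    fit_stub.pcp = np.array([1.0, 0.0, 0.5, 0.005])
    fit_stub.effect = np.array([0.3, 0.0, -0.4, 1.0])
    fit_stub.is_cis = np.array([True, True, False, True])
    fit_stub.variants = pd.DataFrame(
        {
            "id": ["a", "b", "c", "d"],
            "chr": "1",
            "pos": [1, 2, 3, 4],
            "ref": "A",
            "alt": "G",
        }
    )
    w = compute_weights(fit_stub, pcp_floor=0.01, gene_id="g")
    assert list(w["variant_id"]) == ["a", "c"]   # PCP 0 and PCP<floor dropped
    assert w.loc[w["variant_id"] == "a", "weight"].iloc[0] == pytest.approx(0.3)
    assert w.loc[w["variant_id"] == "c", "weight"].iloc[0] == pytest.approx(-0.2)
    assert list(w["cis_trans"]) == ["cis", "trans"]


def test_train_gene_recovers_cis_and_trans():
    """2 cis + 1 trans causal variants are all assigned high PCP and the
    weight vector correlates strongly with the truth."""
    sc = SimulationScenario(
        n_ref_samples=500, n_variants=1000, n_blocks=10, block_ld_rho=0.3,
        maf_range=(0.1, 0.5), seed=101,
    )
    panel = simulate_genotypes(sc)
    arch = GeneArchitecture(
        "g", "1", 5_000_000,
        cis_causal=[(450, 1.0), (520, -1.0)], trans_causal=[(900, 1.0)],
        h2_expr=0.5,
    )
    y, te = simulate_expression(panel, arch, seed=[101, 7])
    hyper = BvsrHyperParams(mcmc_iters=2500, burn_in=500, em_rounds=2, seed=101)
    weights, fit, sel = train_gene(
        y, panel, "g", "1", 5_000_000, block_size=100, hyper=hyper
    )
    pcp_by_id = dict(zip(fit.variants["id"], fit.pcp))
    vid = panel.variants["id"]
    for idx in (450, 520, 900):
        assert pcp_by_id[vid.iat[idx]] > 0.5
    assert set(weights.loc[weights["pcp"] > 0.5, "cis_trans"]) == {"cis", "trans"}
    w_est = pd.Series(0.0, index=vid)
    w_est[weights["variant_id"].to_numpy()] = weights["weight"].to_numpy()
    fitted_ids = fit.variants["id"]
    truth = pd.Series(te.weights, index=vid)
    r = np.corrcoef(w_est[fitted_ids], truth[fitted_ids])[0, 1]
    assert r > 0.8
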