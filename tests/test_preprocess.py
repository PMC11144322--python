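"""Variant QC, normalization, outlier detection and covariate adjustment."""

import numpy as np
import pandas as pd
import pytest

from gwtwas.preprocess import (
    VariantQCThresholds,
    adjust_covariates,
    detect_outlier_samples,
    filter_variants,
    hwe_test,
    normalize_expression,
    size_factors_median_of_ratios,
)
from gwtwas.types import EmptyPanelError, ExpressionState

from conftest import make_panel


# ---------------------------------------------------------------------------
# Hardy-Weinberg test
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts, expected_p, tol",
    [
        ((25, 50, 25), 1.0, 1e-12),        # exact HWE proportions, chi2 = 0
        ((50, 0, 50), 1.523970605e-23, 1e-3),  # chi2 = 100; erfc(sqrt(50))
        ((100, 0, 0), 1.0, 1e-12),         # monomorphic convention
        ((0, 0, 80), 1.0, 1e-12),
    ],
)
def test_hwe_known_values(counts, expected_p, tol):
    assert hwe_test(*counts) == pytest.approx(expected_p, rel=tol)


def test_hwe_requires_samples():
    with pytest.raises(ValueError):
        hwe_test(0, 0, 0)


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------

def qc_fixture_panel():
    """10 variants x 50 samples; exactly 3 engineered failures.

    v0: one het in 50 samples -> MAF exactly 0.01 (removed, strict >).
    v1: exactly 10/50 missing -> missing rate exactly 0.20 (removed, strict <).
    v2: 25 hom-ref / 0 het / 25 hom-alt -> HWE p ~ 1.5e-23 (removed).
    v3..v9: near-HWE, MAF ~ 0.3, fully observed (kept).
    """
    n = 50
    cols = []
    v0 = np.zeros(n); v0[0] = 1
    cols.append(v0)
    v1 = np.array([0, 1, 2] * 17)[:n].astype(float); v1[:10] = np.nan
    cols.append(v1)
    v2 = np.array([0.0] * 25 + [2.0] * 25)
    cols.append(v2)
    good = np.array([0.0] * 25 + [1.0] * 21 + [2.0] * 4)  # chi2 ~ 0.07
    rng = np.random.default_rng(0)
    for _ in range(7):
        cols.append(rng.permutation(good))
    return make_panel(np.column_stack(cols))


def test_filter_removes_engineered_boundary_failures():
    panel = qc_fixture_panel()
    filtered, report = filter_variants(panel, VariantQCThresholds())
    assert filtered.n_variants == 7
    failed = report[~report["kept"]]
    assert dict(zip(failed["id"], failed["reason"])) == {
        "v000": "maf", "v001": "missing", "v002": "hwe",
    }
    # boundary values measured exactly
    assert report.loc[0, "maf"] == pytest.approx(0.01, abs=1e-15)
    assert report.loc[1, "missing_rate"] == pytest.approx(0.20, abs=1e-15)
    # surviving missing dosages were mean-imputed
    assert not np.isnan(filtered.dosages).any()


def test_filter_is_idempotent():
    panel = qc_fixture_panel()
    once, _ = filter_variants(panel)
    twice, rep = filter_variants(once)
    assert twice.n_variants == once.n_variants
    assert rep["kept"].all()
    np.testing.assert_array_equal(once.dosages, twice.dosages)


def test_filter_all_removed_raises():
    panel = qc_fixture_panel()
    with pytest.raises(EmptyPanelError):
        filter_variants(panel, VariantQCThresholds(min_maf=0.49))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_size_factors_identical_samples_are_one():
    counts = np.tile([[10.0], [55.0], [7.0], [120.0]], (1, 6))
    sf = size_factors_median_of_ratios(counts, [f"s{i}" for i in range(6)])
    np.testing.assert_allclose(sf, 1.0)


def test_size_factor_doubles_with_depth_toy_matrix():
    """5x4 toy matrix checked against a brute-force median-of-ratios."""
    counts = np.array(
        [
            [10, 20, 10, 12],
            [100, 210, 95, 130],
            [5, 9, 6, 4],
            [40, 85, 38, 41],
            [7, 15, 8, 9],
        ],
        dtype=float,
    )
    doubled = counts.copy()
    doubled[:, 1] *= 2
    sf = size_factors_median_of_ratios(counts, list("abcd"))
    sf2 = size_factors_median_of_ratios(doubled, list("abcd"))
    # brute force, written out long-hand as the independent oracle
    expected = []
    for s in range(4):
        ratios = []
        for g in range(5):
            gm = np.prod(counts[g]) ** (1 / 4)
            ratios.append(counts[g, s] / gm)
        expected.append(np.median(ratios))
    np.testing.assert_allclose(sf, expected, rtol=1e-12)
    assert sf2[1] == pytest.approx(2 * sf[1] * (sf2[0] / sf[0]), rel=1e-9)


def test_size_factor_error_names_zero_sample():
    counts = np.array([[5.0, 0.0, 7.0], [8.0, 0.0, 9.0]])
    with pytest.raises(ValueError, match="sB"):
        size_factors_median_of_ratios(counts, ["sA", "sB", "sC"])


def _expression_state(counts, gene_ids=None):
    counts = np.asarray(counts, dtype=float)
    g, n = counts.shape
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids or [f"g{i:02d}" for i in range(g)],
            "chr": "1",
            "tss": np.arange(g) * 100_000 + 1,
        }
    )
    return ExpressionState(
        values=counts, genes=genes, samples=[f"s{i:03d}" for i in range(n)]
    )


def expression_fixture_counts():
    """20 genes x 50 samples with size factors exactly 1 by construction.

    9 anchor genes (constant, ratio exactly 1 in every sample) plus one
    all-ones gene pin the median ratio at 1. Survivors: 6 varying expressed
    genes + 1 gene expressed in 12% of samples = 7.
    """
    n = 50
    rng = np.random.default_rng(1)
    rows = []
    for i in range(9):                      # anchors: pass filter, zero variance
        rows.append(np.full(n, 30.0 + 5 * i))
    for _ in range(6):                      # clearly expressed, varying -> kept
        rows.append(rng.integers(20, 200, size=n).astype(float))
    rows.append(np.ones(n))                 # log(2) < 1 everywhere -> removed
    for _ in range(2):                      # all-zero -> removed
        rows.append(np.zeros(n))
    boundary = np.zeros(n); boundary[:5] = 2.0   # >1 in exactly 10% -> removed
    rows.append(boundary)
    above = np.zeros(n); above[:6] = 2.0         # >1 in 12% -> kept
    rows.append(above)
    return np.array(rows)


def test_gene_filter_boundary_is_strict():
    state = _expression_state(expression_fixture_counts())
    norm = normalize_expression(state)
    np.testing.assert_allclose(norm.size_factors, 1.0)
    kept = set(norm.genes["gene_id"])
    assert "g18" not in kept   # exactly 10% of samples above threshold
    assert "g19" in kept       # 12%
    assert norm.n_genes == 7


def test_normalization_removes_depth_differences():
    """Rescaling per-sample depth is absorbed entirely by the size factors
    (depth multipliers with geometric mean 1, so the count/size-factor ratio
    is reproduced exactly and the +1 offset sees identical arguments)."""
    counts = np.random.default_rng(3).integers(50, 500, size=(12, 8)).astype(float)
    depth = np.array([2, 0.5, 4, 0.25, 1, 1, 8, 0.125])  # prod = 1
    a = normalize_expression(_expression_state(counts))
    b = normalize_expression(_expression_state(counts * depth[None, :]))
    np.testing.assert_allclose(a.values, b.values, atol=1e-9)


def test_normalized_values_standardized():
    norm = normalize_expression(_expression_state(expression_fixture_counts()))
    np.testing.assert_allclose(norm.values.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(norm.values.std(axis=1, ddof=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# outlier detection
# ---------------------------------------------------------------------------

def _normalized_state(values):
    g, n = values.shape
    return ExpressionState(
        values=values,
        genes=pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(g)], "chr": "1",
             "tss": np.arange(g) + 1}
        ),
        samples=[f"s{i:03d}" for i in range(n)],
        state_tag="normalized",
        size_factors=np.ones(n),
    )


def test_outliers_null_rate():
    """Homogeneous Gaussian expression yields an empty outlier set in at
    least 95 of 100 seeds at the Bonferroni level."""
    empty = 0
    for seed in range(100):
        vals = np.random.default_rng(seed).standard_normal((80, 50))
        out = detect_outlier_samples(_normalized_state(vals), n_clusters=8)
        empty += len(out) == 0
    assert empty >= 95


def test_outliers_planted_cluster_recovered():
    """Five samples shifted 10 SD form their own cluster and are all
    returned. Inliers share a common expression factor (as real profiles
    do), which is what makes them mutually closer than to the aberrant
    block under cosine distance."""
    rng = np.random.default_rng(7)
    common = rng.standard_normal((100, 1))
    vals = 1.5 * common + rng.standard_normal((100, 60))
    vals[:, 55:] += 10.0
    out = detect_outlier_samples(_normalized_state(vals), n_clusters=8)
    assert out == {f"s{i:03d}" for i in range(55, 60)}


def test_outliers_tiny_identical_input():
    vals = np.tile(np.arange(5.0)[:, None], (1, 3))
    assert detect_outlier_samples(_normalized_state(vals)) == set()


def test_outliers_full_covariance_requires_samples():
    vals = np.random.default_rng(0).standard_normal((50, 10))
    with pytest.raises(ValueError, match="regularized"):
        detect_outlier_samples(_normalized_state(vals), subspace_dim=None)


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def test_adjust_identity_with_no_covariates():
    rng = np.random.default_rng(5)
    norm = _normalized_state(rng.standard_normal((10, 40)))
    vals = norm.values - norm.values.mean(axis=1, keepdims=True)
    vals /= vals.std(axis=1, ddof=1, keepdims=True)
    norm.values = vals
    adjusted = adjust_covariates(norm)
    np.testing.assert_allclose(adjusted.values, vals, atol=1e-10)


def test_adjust_removes_planted_batch_effect():
    rng = np.random.default_rng(9)
    n = 200
    batch = np.repeat([0, 1], n // 2)
    vals = rng.standard_normal((20, n)) + 2.0 * batch[None, :]  # ~50% batch variance
    norm = _normalized_state(vals)
    covars = pd.DataFrame(
        {"sample_id": norm.samples, "batch": np.where(batch == 0, "a", "b")}
    )
    adjusted = adjust_covariates(norm, covariates=covars)
    for g in range(20):
        r2 = np.corrcoef(adjusted.values[g], batch)[0, 1] ** 2
        assert r2 < 0.01
    # least-squares residuals are orthogonal to the covariate
    bc = batch - batch.mean()
    corr = adjusted.values @ bc / (
        np.linalg.norm(adjusted.values, axis=1) * np.linalg.norm(bc)
    )
    assert np.abs(corr).max() < 1e-10


def test_adjust_output_standardized_and_hidden_factors_used():
    rng = np.random.default_rng(11)
    norm = _normalized_state(rng.standard_normal((30, 60)))
    adjusted = adjust_covariates(norm, n_hidden_factors=5)
    assert np.abs(adjusted.values.mean(axis=1)).max() < 1e-12
    np.testing.assert_allclose(adjusted.values.std(axis=1, ddof=1), 1.0, atol=1e-12)
    assert adjusted.state_tag == "adjusted"


def test_adjust_collinear_design_reports_columns():
    rng = np.random.default_rng(13)
    norm = _normalized_state(rng.standard_normal((5, 30)))
    covars = pd.DataFrame(
        {
            "sample_id": norm.samples,
            "x1": np.arange(30.0),
            "x2": 2.0 * np.arange(30.0),  # collinear with x1
        }
    )
    with pytest.raises(ValueError, match="collinear"):
        adjust_covariates(norm, covariates=covars)


def test_best_replicate_selection_by_reads_then_id():
    from gwtwas.io import select_best_replicate

    covars = pd.DataFrame(
        {
            "sample_id": ["s1a", "s1b", "s2a", "s2b"],
            "subject": ["p1", "p1", "p2", "p2"],
            "reads": [10, 30, 20, 20],
        }
    )
    kept = select_best_replicate(covars, subject_column="subject")
    # p1: most reads wins; p2: tie broken lexicographically by sample id
    assert list(kept["sample_id"]) == ["s1b", "s2a"]
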