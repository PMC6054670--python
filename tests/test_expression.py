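"""Expression transforms and the CN-dosage analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pnetloh.expression import (ExpressionMatrix, batch_center,
                                chromosome_mean_expression,
                                cn_expression_correlation,
                                cohort_cn_expression_correlations,
                                compare_loss_vs_intact,
                                segment_mean_expression, zscore)
from pnetloh.simulate import SimConfig, simulate_cohort, simulate_expression
from tests.conftest import tiny_config


def small_matrix(values, batches=None, chrom="chr1"):
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    info = pd.DataFrame({"chrom": chrom,
                         "start": np.arange(len(genes)) * 1000 + 1,
                         "end": np.arange(len(genes)) * 1000 + 500},
                        index=genes)
    if batches is None:
        batches = pd.Series("frozen", index=samples)
    else:
        batches = pd.Series(batches, index=samples)
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes,
                                                columns=samples),
                            gene_info=info, batches=batches)


def test_batch_center_removes_additive_offset():
    base = np.array([[1.0, 2.0, 1.0, 2.0], [5.0, 6.0, 5.0, 6.0]])
    shifted = base.copy()
    shifted[:, 2:] += 2.0   # batch B offset
    m = small_matrix(shifted, batches=["A", "A", "B", "B"])
    out = batch_center(m)
    ref = batch_center(small_matrix(base, batches=["A", "A", "B", "B"]))
    np.testing.assert_allclose(out.values.to_numpy(), ref.values.to_numpy())
    for b in ("A", "B"):
        cols = out.batches.index[out.batches == b]
        np.testing.assert_allclose(out.values[cols].mean(axis=1), 0.0, atol=1e-12)


def test_batch_center_single_sample_batch_errors():
    m = small_matrix(np.ones((2, 3)), batches=["A", "A", "B"])
    with pytest.raises(ValueError):
        batch_center(m)


def test_zscore_definition_and_degenerate_gene():
    m = small_matrix(np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]))
    z, flat = zscore(m)
    np.testing.assert_allclose(z.values.iloc[0], [-1.0, 0.0, 1.0])
    np.testing.assert_allclose(z.values.iloc[1], 0.0)
    assert flat.tolist() == [False, True]
    with pytest.raises(ValueError):
        zscore(small_matrix(np.ones((2, 2))))


def test_zscore_after_batch_center_invariant_to_batch_constants():
    rng = np.random.default_rng(0)
    base = rng.normal(5, 1, (10, 6))
    m1 = small_matrix(base.copy(), batches=list("AAABBB"))
    shifted = base.copy()
    shifted[:, 3:] += 7.3
    m2 = small_matrix(shifted, batches=list("AAABBB"))
    z1, _ = zscore(batch_center(m1))
    z2, _ = zscore(batch_center(m2))
    np.testing.assert_allclose(z1.values.to_numpy(), z2.values.to_numpy(),
                               atol=1e-10)


def test_chromosome_means_and_flags():
    vals = np.vstack([np.full((4, 2), 3.0), np.full((2, 2), 7.0)])
    genes = [f"g{i}" for i in range(6)]
    info = pd.DataFrame({
        "chrom": ["chr1"] * 4 + ["chr2"] * 2,
        "start": np.arange(6) * 100 + 1, "end": np.arange(6) * 100 + 50,
    }, index=genes)
    m = ExpressionMatrix(values=pd.DataFrame(vals, index=genes,
                                             columns=["s0", "s1"]),
                         gene_info=info,
                         batches=pd.Series("frozen", index=["s0", "s1"]))
    with pytest.warns(UserWarning):
        means, counts = chromosome_mean_expression(m, min_genes=5)
    assert means.loc["s0", "chr1"] == pytest.approx(3.0)
    assert means.loc["s0", "chr2"] == pytest.approx(7.0)
    assert counts["chr2"] == 2


def test_noiseless_dosage_gives_perfect_correlation():
    # noiseless limit: no expression noise, no baseline spread, no batch offset
    cfg = tiny_config(n_group1=2, n_group2=2, n_group3=2,
                      expr_sigma=1e-9, expr_baseline_sd=0.0,
                      dosage_beta=1.0, batch_offset=0.0)
    cohort = simulate_cohort(cfg)
    means, _ = chromosome_mean_expression(cohort.expression)
    order = cohort.genome.chrom_names
    for truth in cohort.truths:
        k = truth.to_karyotype(order)
        r = cn_expression_correlation(k, means.loc[truth.tumor_id])
        cn = [truth.chrom_states[c][0] for c in order]
        if len(set(cn)) > 1:
            assert r == pytest.approx(1.0, abs=1e-6)
        else:
            assert np.isnan(r)   # euploid: undefined, not zero


def test_null_beta_correlations_center_at_zero():
    cfg = tiny_config(n_group1=16, n_group2=16, n_group3=18,
                      n_chromosomes=22, dosage_beta=0.0, seed=5)
    cohort = simulate_cohort(cfg)
    means, _ = chromosome_mean_expression(cohort.expression)
    order = cohort.genome.chrom_names
    karyos = [t.to_karyotype(order) for t in cohort.truths]
    rs = cohort_cn_expression_correlations(karyos, means).dropna()
    assert len(rs) >= 40
    assert abs(rs.mean()) < 0.1


def test_segment_mean_expression_tracks_cn():
    cfg = tiny_config(expr_sigma=0.05, dosage_beta=1.0, batch_offset=0.0)
    cohort = simulate_cohort(cfg)
    truth = cohort.truths[0]
    # synthetic segments: chr11 (lost) vs chr4 (diploid)
    segs = pd.DataFrame([
        {"chrom": "chr11", "start": 0, "end": 300_000},
        {"chrom": "chr4", "start": 0, "end": 300_000},
        {"chrom": "chr4", "start": 299_000, "end": 300_000},  # no gene midpoint
    ])
    out = segment_mean_expression(segs, cohort.expression, truth.tumor_id)
    assert out["n_genes"].iloc[0] >= 3
    assert bool(out["few_genes"].iloc[2]) and np.isnan(out["mean_expr"].iloc[2])
    cn11 = truth.chrom_states["chr11"][0]
    if cn11 < 2:
        assert out["mean_expr"].iloc[0] < out["mean_expr"].iloc[1]


def brute_force_u(x, y):
    return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)


def test_mannwhitney_u_matches_pairwise_count():
    rng = np.random.default_rng(7)
    x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert res.statistic == pytest.approx(brute_force_u(x, y))


def test_compare_loss_vs_intact_powered_case():
    cfg = tiny_config(n_group1=0, n_group2=6, n_group3=8,
                      group3_max_aneuploidy=0.0, dosage_beta=1.0,
                      expr_sigma=0.3, seed=8)
    cohort = simulate_cohort(cfg)   # 6 tumors with chr11 loss, 8 intact
    means, _ = chromosome_mean_expression(batch_center(cohort.expression))
    order = cohort.genome.chrom_names
    karyos = [t.to_karyotype(order) for t in cohort.truths]
    out = compare_loss_vs_intact(means, karyos, "chr11")
    assert out["n_loss"] == 6 and out["n_intact"] == 8
    assert out["direction"] == "loss_lower"
    assert out["p"] <= 0.01
    with pytest.raises(ValueError):
        compare_loss_vs_intact(means, karyos, "chr1")   # no loss group


def test_correlation_invariant_to_global_affine_rescale():
    cfg = tiny_config(dosage_beta=0.8, seed=9)
    cohort = simulate_cohort(cfg)
    order = cohort.genome.chrom_names
    truth = cohort.truths[0]
    k = truth.to_karyotype(order)
    m = cohort.expression
    means1, _ = chromosome_mean_expression(m)
    scaled = ExpressionMatrix(values=m.values * 2.0 + 5.0,
                              gene_info=m.gene_info, batches=m.batches)
    means2, _ = chromosome_mean_expression(scaled)
    r1 = cn_expression_correlation(k, means1.loc[truth.tumor_id])
    r2 = cn_expression_correlation(k, means2.loc[truth.tumor_id])
    assert r1 == pytest.approx(r2, abs=1e-12)
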