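"""Recurrent-set mining, group classification, exact Fisher tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from pnetloh.genome import RECURRENT_LOH_CHROMS
from pnetloh.groups import (associate_clinical, classify_groups,
                            fisher_exact_2xk, mine_recurrent_loh)
from pnetloh.simulate import simulate_cohort
from tests.conftest import tiny_config


def truth_karyotypes(cohort):
    order = cohort.genome.chrom_names
    return [t.to_karyotype(order) for t in cohort.truths]


@pytest.fixture(scope="module")
def cohort39():
    return simulate_cohort(tiny_config(n_group1=6, n_group2=8, n_group3=6,
                                       n_chromosomes=22, seed=3))


def test_mine_recurrent_recovers_truth_set(cohort39):
    karyos = truth_karyotypes(cohort39)
    rec = mine_recurrent_loh(karyos)
    assert rec.chromosomes == RECURRENT_LOH_CHROMS
    assert rec.support >= 6
    # all-euploid cohort -> empty set
    empty = simulate_cohort(tiny_config(n_group1=0, n_group2=0, n_group3=4,
                                        group3_max_aneuploidy=0.0, seed=4))
    rec0 = mine_recurrent_loh(truth_karyotypes(empty))
    assert rec0.chromosomes == () and rec0.support == 0


def test_single_high_loh_tumor_defines_the_set(cohort39):
    karyos = truth_karyotypes(cohort39)
    g1 = next(k for k, t in zip(karyos, cohort39.truths) if t.group_label == 1)
    g2 = [k for k, t in zip(karyos, cohort39.truths) if t.group_label == 2]
    rec = mine_recurrent_loh([g1] + g2[:3])
    assert set(rec.chromosomes) == g1.loh_chromosomes()


def test_classify_groups_round_trip(cohort39):
    karyos = truth_karyotypes(cohort39)
    men1 = {t.tumor_id: t.men1_somatic for t in cohort39.truths}
    rec = mine_recurrent_loh(karyos)
    out = classify_groups(karyos, men1, rec)
    truth = {t.tumor_id: t.group_label for t in cohort39.truths}
    assert (out["group"] == out["tumor_id"].map(truth)).all()
    # partition: each tumor exactly one group
    assert out["group"].isin([1, 2, 3]).all()
    assert len(out) == len(karyos)


def test_classify_groups_requires_men1_status(cohort39):
    karyos = truth_karyotypes(cohort39)
    rec = mine_recurrent_loh(karyos)
    with pytest.raises(KeyError):
        classify_groups(karyos, {}, rec)


def brute_force_fisher(table):
    """Oracle: enumerate all tables with the observed margins."""
    t = np.asarray(table)
    row1 = t[0].sum()
    cols = t.sum(axis=0)

    def prob(xs):
        from math import comb
        num = 1
        for x, c in zip(xs, cols):
            num *= comb(int(c), int(x))
        return num / comb(int(t.sum()), int(row1))

    obs = prob(t[0])
    total = 0.0
    for xs in itertools.product(*[range(c + 1) for c in cols]):
        if sum(xs) != row1:
            continue
        p = prob(xs)
        if p <= obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def test_fisher_worked_value():
    assert fisher_exact_2xk([[4, 6], [0, 16]]) == pytest.approx(210 / 14950, rel=1e-9)
    assert fisher_exact_2xk([[5, 5], [5, 5]]) == 1.0


@given(st.lists(st.integers(min_value=0, max_value=12), min_size=4, max_size=4))
@settings(deadline=None, max_examples=80)
def test_fisher_2x2_matches_scipy_and_oracle(cells):
    table = [cells[:2], cells[2:]]
    if sum(cells) == 0 or sum(cells[:2]) == 0 or sum(cells[2:]) == 0:
        return
    got = fisher_exact_2xk(table)
    assert got == pytest.approx(brute_force_fisher(table), rel=1e-9)
    assert got == pytest.approx(scipy_fisher(table).pvalue, rel=1e-7)


@given(st.lists(st.integers(min_value=0, max_value=8), min_size=6, max_size=6))
@settings(deadline=None, max_examples=40)
def test_fisher_2x3_matches_enumeration_oracle(cells):
    table = [cells[:3], cells[3:]]
    if sum(cells) == 0 or sum(cells[:3]) == 0 or sum(cells[3:]) == 0:
        return
    assert fisher_exact_2xk(table) == pytest.approx(brute_force_fisher(table),
                                                    rel=1e-9)


def test_fisher_validates_input():
    with pytest.raises(ValueError):
        fisher_exact_2xk([[1, 2, 3, 4]])
    with pytest.raises(ValueError):
        fisher_exact_2xk([[1, -2], [3, 4]])


def test_associate_clinical_detects_group1_metastases(cohort39):
    karyos = truth_karyotypes(cohort39)
    men1 = {t.tumor_id: t.men1_somatic for t in cohort39.truths}
    groups = classify_groups(karyos, men1, mine_recurrent_loh(karyos))
    # construct clinical labels: 4/6 of group-1 metastasized, none elsewhere
    g1_ids = groups.loc[groups["group"] == 1, "tumor_id"].tolist()
    clinical = pd.DataFrame({
        "tumor_id": groups["tumor_id"],
        "grade": np.where(groups["group"] == 1, 2, 1),
        "metastasis": groups["tumor_id"].isin(g1_ids[:4]),
    })
    report = associate_clinical(groups, clinical)
    assert report["metastasis_p"] < 0.05
    assert report["grade_p"] < 0.05
    assert report["metastasis_table"].sum() == len(groups)


def test_associate_clinical_degenerate_single_group(cohort39):
    karyos = truth_karyotypes(cohort39)[:3]
    truths = cohort39.truths[:3]
    men1 = {t.tumor_id: True for t in truths}
    groups = classify_groups(karyos, men1, mine_recurrent_loh(karyos))
    clinical = pd.DataFrame({"tumor_id": groups["tumor_id"],
                             "grade": 1, "metastasis": False})
    if groups["group"].nunique() == 1:
        with pytest.warns(UserWarning):
            report = associate_clinical(groups, clinical)
        assert report["grade_p"] is None


def test_null_clinical_labels_give_uniform_p(cohort39):
    """Shuffled labels: p-values should not pile up below 0.05."""
    karyos = truth_karyotypes(cohort39)
    men1 = {t.tumor_id: t.men1_somatic for t in cohort39.truths}
    groups = classify_groups(karyos, men1, mine_recurrent_loh(karyos))
    rng = np.random.default_rng(9)
    ps = []
    for _ in range(40):
        met = rng.permutation([True] * 5 + [False] * (len(groups) - 5))
        clinical = pd.DataFrame({"tumor_id": groups["tumor_id"],
                                 "grade": 1 + rng.integers(0, 2, len(groups)),
                                 "metastasis": met})
        report = associate_clinical(groups, clinical)
        ps.append(report["metastasis_p"])
    # exact tests are conservative; well under 20% of nulls fall below 0.05
    assert np.mean(np.asarray(ps) < 0.05) < 0.2
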