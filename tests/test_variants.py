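"""Somatic filters, unopposed-germline detection, biallelic status, mutation rate."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pnetloh.io import read_bed, read_variant_vcf
from pnetloh.variants import (FilterConfig, biallelic_inactivation,
                              coding_mutation_rate, filter_somatic,
                              unopposed_germline)

DATA = Path(__file__).parent / "data"

# hand-derived expectations for the packaged 20-variant fixture
FIXTURE_EXPECT = {
    1000: "",
    2000: "tumor_alt",
    3000: "normal_alt",
    4000: "tumor_depth",
    5000: "normal_depth",
    50500: "blacklist",
    7000: "",
    8000: "tumor_depth,tumor_alt",
    9000: "normal_alt",
    10000: "",
    50001: "blacklist",
    53001: "",
    13000: "tumor_depth,normal_depth,tumor_alt,normal_alt",
    14000: "",
    15000: "tumor_alt",
    16000: "normal_alt",
    17000: "",
    18000: "tumor_depth",
    50000: "",
    53000: "blacklist",
}


@pytest.fixture()
def fixture_variants():
    return read_variant_vcf(DATA / "somatic_fixture.vcf")


@pytest.fixture()
def fixture_cfg():
    return FilterConfig(blacklist=read_bed(DATA / "blacklist_fixture.bed"))


def test_filter_fixture_exact_reasons(fixture_variants, fixture_cfg):
    out = filter_somatic(fixture_variants, fixture_cfg)
    assert len(out) == 20
    for _, row in out.iterrows():
        assert row["fail_reasons"] == FIXTURE_EXPECT[row["pos"]], row["pos"]
        assert row["passed"] == (FIXTURE_EXPECT[row["pos"]] == "")


def test_filter_idempotent_and_partition(fixture_variants, fixture_cfg):
    once = filter_somatic(fixture_variants, fixture_cfg)
    twice = filter_somatic(once, fixture_cfg)
    assert once["fail_reasons"].tolist() == twice["fail_reasons"].tolist()
    assert (once["passed"] | (once["fail_reasons"] != "")).all()
    shuffled = fixture_variants.sample(frac=1, random_state=0)
    out = filter_somatic(shuffled, fixture_cfg).sort_values("pos")
    assert out["fail_reasons"].tolist() == \
        once.sort_values("pos")["fail_reasons"].tolist()


def test_malformed_record_rejected_not_dropped():
    df = pd.DataFrame([{"chrom": "chr1", "pos": 10, "ref": "A", "alt": "T",
                        "gene": "g", "effect": "missense",
                        "t_ref": "oops", "t_alt": 20, "n_ref": 60, "n_alt": 0,
                        "origin": "somatic"}])
    out = filter_somatic(df, FilterConfig())
    assert len(out) == 1 and out["fail_reasons"].iloc[0] == "malformed"


@given(st.integers(min_value=0, max_value=200),
       st.integers(min_value=0, max_value=200),
       st.integers(min_value=0, max_value=200),
       st.integers(min_value=0, max_value=10))
@settings(deadline=None, max_examples=60)
def test_filter_pass_iff_all_thresholds(t_ref, t_alt, n_ref, n_alt):
    df = pd.DataFrame([{"chrom": "chr1", "pos": 5, "ref": "A", "alt": "T",
                        "gene": "g", "effect": "missense",
                        "t_ref": t_ref, "t_alt": t_alt,
                        "n_ref": n_ref, "n_alt": n_alt, "origin": "somatic"}])
    out = filter_somatic(df, FilterConfig())
    expect = (t_ref + t_alt >= 50 and n_ref + n_alt >= 50
              and t_alt >= 10 and n_alt <= 2)
    assert bool(out["passed"].iloc[0]) == expect


def loh_segments(chrom="chr11", cn=1, loh=True):
    seg = pd.DataFrame([{"chrom": chrom, "start": 0, "end": 300_000,
                         "mean_lr": -0.4, "cn": cn}])
    seg["loh"] = pd.array([loh], dtype="boolean")
    return seg


def germ(chrom, pos, t_ref, t_alt, n_ref, n_alt):
    return pd.DataFrame([{"chrom": chrom, "pos": pos, "ref": "A", "alt": "C",
                          "gene": "g", "effect": "missense",
                          "t_ref": t_ref, "t_alt": t_alt,
                          "n_ref": n_ref, "n_alt": n_alt,
                          "origin": "germline"}])


def test_unopposed_reported_with_consistency_flag():
    # germline ~1:1, tumor ratio 2.8 in an LoH segment -> reported
    out = unopposed_germline(germ("chr11", 1000, 25, 70, 52, 48),
                             loh_segments(), rho=0.5)
    assert len(out) == 1
    assert out["tumor_ratio"].iloc[0] == pytest.approx(2.8)
    # expected ratio for CN=1 ALT-retained at rho=0.5 is 1/(1-0.5) = 2.0
    assert out["expected_ratio"].iloc[0] == pytest.approx(2.0)
    assert bool(out["purity_consistent"].iloc[0])  # |2.8 - 2.0| <= 1.0


def test_unopposed_requires_loh_band_and_ratio():
    # diploid locus: never reported
    out = unopposed_germline(germ("chr11", 1000, 50, 50, 50, 50),
                             loh_segments(cn=2, loh=False), rho=0.5)
    assert out.empty
    # germline BAF outside ~1:1 band
    out = unopposed_germline(germ("chr11", 1000, 20, 60, 80, 20),
                             loh_segments(), rho=0.5)
    assert out.empty
    # tumor ratio below 1.5
    out = unopposed_germline(germ("chr11", 1000, 50, 55, 50, 50),
                             loh_segments(), rho=0.5)
    assert out.empty


def test_unopposed_simulated_ratio_recovery():
    # rho=0.5, CN=1, ALT retained: expected tumor ALT fraction 2/3
    rng = np.random.default_rng(1)
    depth = 150
    n = 200
    alts = rng.binomial(depth, 2 / 3, n)
    reported = 0
    for alt in alts:
        g = germ("chr11", 1000, depth - int(alt), int(alt), 75, 75)
        out = unopposed_germline(g, loh_segments(), rho=0.5)
        reported += len(out)
    assert reported >= 0.95 * n
    ratios = alts / (depth - alts)
    se = ratios.std(ddof=1) / np.sqrt(n)
    assert abs(ratios.mean() - 2.0) < 3 * se + 0.05


def test_biallelic_status_matrix(tiny_cohort):
    genes = tiny_cohort.genome.genes
    chrom_order = tiny_cohort.genome.chrom_names
    truth = tiny_cohort.truths[0]          # group 1: MEN1 hit + chr11 LoH
    karyo = truth.to_karyotype(chrom_order)
    men1_variant = pd.DataFrame([{"gene": "MEN1"}])
    assert biallelic_inactivation("MEN1", men1_variant, karyo, genes) == "biallelic"
    assert biallelic_inactivation("MEN1", pd.DataFrame({"gene": []}), karyo,
                                  genes) == "loh-only"
    diploid_gene = genes.loc[genes["chrom"] == "chr4", "gene_id"].iloc[0]
    var = pd.DataFrame([{"gene": diploid_gene}])
    assert biallelic_inactivation(diploid_gene, var, karyo, genes) == "monoallelic"
    assert biallelic_inactivation(diploid_gene, pd.DataFrame({"gene": []}),
                                  karyo, genes) == "wild-type"
    with pytest.raises(KeyError):
        biallelic_inactivation("NOPE", var, karyo, genes)


def test_coding_mutation_rate():
    assert coding_mutation_rate(2, 4_000_000) == pytest.approx(0.5)
    assert coding_mutation_rate(0, 1_000_000) == 0.0
    assert coding_mutation_rate(5, 2_500_000) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        coding_mutation_rate(1, 0)


def test_simulator_artifacts_fail_for_intended_reason(tiny_cohort):
    cfg = FilterConfig(blacklist=tiny_cohort.blacklist)
    reason_of = {"artifact_low_depth": "tumor_depth",
                 "artifact_low_tumor_alt": "tumor_alt",
                 "artifact_germline_support": "normal_alt",
                 "artifact_blacklist": "blacklist"}
    for tid in tiny_cohort.tumor_ids:
        som, _ = tiny_cohort.variants[tid]
        out = filter_somatic(som, cfg)
        for _, row in out.iterrows():
            cls = row["true_class"]
            if cls in reason_of:
                assert reason_of[cls] in row["fail_reasons"], (tid, cls)
            else:
                assert row["passed"], (tid, cls, row["fail_reasons"])
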