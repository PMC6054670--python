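"""End-to-end orchestration: counts -> hets -> CN -> karyotype -> groups -> dosage.

:func:`analyze_tumor` runs the single-tumor DNA stages; :func:`analyze_cohort`
adds the cohort stages (recurrent-LoH mining, group classification,
clinical association, dosage-expression analysis, unopposed-germline
detection) and, when ground truth is available, truth-vs-called confusion
summaries.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import allelic, copy_number, expression as expr_mod, groups as groups_mod
from .loh import (Karyotype, cohort_aneuploidy_summary, karyotype_from_segments,
                  karyotype_matrix, segment_loh)
from .simulate import SimulatedCohort
from .variants import FilterConfig, biallelic_inactivation, filter_somatic, \
    unopposed_germline

log = logging.getLogger("pnetloh")


@dataclass
class StageParams:
    """Tunable parameters of the analysis stages (defaults as documented
    per stage)."""

    het_baf_lo: float = 0.4
    het_baf_hi: float = 0.6
    het_alpha: float = 0.05
    min_depth: int = 50
    loess_frac: float = 0.3
    min_normal: int = 10
    smooth_window: int = 5
    smooth_z_cap: float = 3.0
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    cbs_min_width: int = 3
    cbs_merge_tol: float = 0.05
    cbs_undo_sd: float = 1.0
    max_cn: int = 8
    min_hets: int = 10
    default_purity: float = 0.5
    high_loh_min: int = 8
    member_freq: float = 0.8
    min_overlap: float = 0.8
    unopposed_ratio_min: float = 1.5
    seed: int = 0


@dataclass
class TumorResult:
    tumor_id: str
    purity: float
    segments: pd.DataFrame
    karyotype: Karyotype
    het_sites: pd.DataFrame
    somatic: pd.DataFrame = field(default_factory=pd.DataFrame)
    germline_unopposed: pd.DataFrame = field(default_factory=pd.DataFrame)
    men1_status: str = "wild-type"


def analyze_tumor(
    tumor_id: str,
    normal_tiles: pd.DataFrame,
    tumor_tiles: pd.DataFrame,
    normal_alleles: pd.DataFrame,
    tumor_alleles: pd.DataFrame,
    purity: float,
    params: StageParams | None = None,
    blacklist: pd.DataFrame | None = None,
    chrom_order: list[str] | None = None,
) -> TumorResult:
    """Run het calling, CN segmentation and LoH karyotyping for one tumor."""
    p = params or StageParams()
    hets = allelic.call_germline_hets(
        normal_alleles, baf_lo=p.het_baf_lo, baf_hi=p.het_baf_hi,
        alpha=p.het_alpha, min_depth=p.min_depth)
    hets = allelic.tumor_baf(hets, tumor_alleles, min_depth=p.min_depth)
    track = copy_number.tile_log_ratio(
        tumor_tiles, normal_tiles, loess_frac=p.loess_frac,
        min_normal=p.min_normal, blacklist=blacklist)
    track = copy_number.smooth_outliers(track, window=p.smooth_window,
                                        z_cap=p.smooth_z_cap)
    seed = int(np.random.SeedSequence(
        entropy=p.seed, spawn_key=(zlib.crc32(tumor_id.encode()),)
    ).generate_state(1)[0] % (2 ** 31))
    segs = copy_number.cbs_segment(
        track, alpha=p.cbs_alpha, n_perm=p.cbs_n_perm,
        min_width=p.cbs_min_width, merge_tol=p.cbs_merge_tol,
        undo_sd=p.cbs_undo_sd, seed=seed)
    segs = copy_number.assign_segment_cn(segs, purity, max_cn=p.max_cn)
    segs = segment_loh(segs, hets, purity, min_hets=p.min_hets)
    karyo = karyotype_from_segments(tumor_id, segs, chrom_order=chrom_order)
    return TumorResult(tumor_id=tumor_id, purity=purity, segments=segs,
                       karyotype=karyo, het_sites=hets)


@dataclass
class CohortReport:
    """Bundle of every cohort-level result table."""

    tumors: dict
    karyotype_matrix: pd.DataFrame
    aneuploidy: dict
    recurrent_set: groups_mod.RecurrentSet | None = None
    group_assignments: pd.DataFrame | None = None
    clinical_association: dict | None = None
    dosage_correlations: pd.Series | None = None
    chr11_comparison: dict | None = None
    confusion: dict | None = None


def analyze_cohort(
    cohort: SimulatedCohort,
    params: StageParams | None = None,
    purities: dict | None = None,
    use_truth_purity: bool = True,
) -> CohortReport:
    """Run the full pipeline on a (simulated or loaded) cohort.

    Purity per tumor comes from ``purities`` if given, else from the
    simulation truth when ``use_truth_purity`` (purity is a per-tumor
    input of the CN model, not an estimated quantity), else the default.
    """
    p = params or StageParams()
    genome = cohort.genome
    chrom_order = genome.chrom_names
    truth_by_id = {t.tumor_id: t for t in cohort.truths} if cohort.truths else {}
    results: dict[str, TumorResult] = {}
    men1_status: dict[str, bool] = {}
    for tid in cohort.tumor_ids:
        if purities and tid in purities:
            rho = purities[tid]
        elif use_truth_purity and tid in truth_by_id:
            rho = truth_by_id[tid].purity
        else:
            rho = p.default_purity
        nt, tt = cohort.tiles[tid]
        na, ta = cohort.alleles[tid]
        res = analyze_tumor(tid, nt, tt, na, ta, rho, params=p,
                            blacklist=cohort.blacklist, chrom_order=chrom_order)
        som, germ = cohort.variants[tid]
        fcfg = FilterConfig(min_depth=p.min_depth, blacklist=cohort.blacklist)
        som_f = filter_somatic(som, fcfg)
        res.somatic = som_f
        passing = som_f.loc[som_f["passed"]]
        res.men1_status = biallelic_inactivation("MEN1", passing, res.karyotype,
                                                 genome.genes)
        men1_status[tid] = bool((passing["gene"] == "MEN1").any())
        res.germline_unopposed = unopposed_germline(
            germ, res.segments, rho, ratio_min=p.unopposed_ratio_min)
        results[tid] = res
        log.info("tumor %s: %d segments, n_loh=%d, MEN1=%s", tid,
                 len(res.segments), res.karyotype.n_loh, res.men1_status)

    karyotypes = [results[tid].karyotype for tid in cohort.tumor_ids]
    report = CohortReport(
        tumors=results,
        karyotype_matrix=karyotype_matrix(karyotypes),
        aneuploidy=cohort_aneuploidy_summary(karyotypes),
    )
    recurrent = groups_mod.mine_recurrent_loh(
        karyotypes, high_loh_min=p.high_loh_min, member_freq=p.member_freq)
    report.recurrent_set = recurrent
    assignments = groups_mod.classify_groups(
        karyotypes, men1_status, recurrent, min_overlap=p.min_overlap)
    report.group_assignments = assignments
    if cohort.clinical is not None:
        report.clinical_association = groups_mod.associate_clinical(
            assignments, cohort.clinical)

    if cohort.expression is not None:
        try:
            matrix = expr_mod.batch_center(cohort.expression)
        except ValueError as e:
            warnings.warn(f"dosage stage skipped ({e})", stacklevel=2)
            matrix = None
        if matrix is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                chrom_means, _ = expr_mod.chromosome_mean_expression(matrix)
            report.dosage_correlations = expr_mod.cohort_cn_expression_correlations(
                karyotypes, chrom_means)
            try:
                report.chr11_comparison = expr_mod.compare_loss_vs_intact(
                    chrom_means, karyotypes, "chr11")
            except ValueError as e:
                warnings.warn(f"chr11 loss-vs-intact comparison skipped: {e}",
                              stacklevel=2)
    else:
        warnings.warn("no expression matrix; dosage stages skipped", stacklevel=2)

    if truth_by_id:
        report.confusion = truth_confusion(results, truth_by_id, assignments,
                                           chrom_order)
    return report


def truth_confusion(results: dict, truth_by_id: dict,
                    assignments: pd.DataFrame, chrom_order: list[str]) -> dict:
    """Truth-vs-called per-chromosome CN/LoH accuracy and group agreement."""
    cn_ok = cn_tot = 0
    tp = fp = fn = tn = 0
    for tid, res in results.items():
        truth = truth_by_id[tid]
        tcalls = truth.truth_calls(chrom_order).set_index("chrom")
        calls = res.karyotype.calls.set_index("chrom")
        for chrom in calls.index.intersection(tcalls.index):
            called_cn = int(calls.loc[chrom, "dominant_cn"])
            true_cn = int(tcalls.loc[chrom, "dominant_cn"])
            cn_tot += 1
            cn_ok += int(called_cn == true_cn)
            called_loh = calls.loc[chrom, "loh"]
            if pd.isna(called_loh):
                continue
            called_loh = bool(called_loh)
            true_loh = bool(tcalls.loc[chrom, "loh"])
            tp += called_loh and true_loh
            fp += called_loh and not true_loh
            fn += (not called_loh) and true_loh
            tn += (not called_loh) and not true_loh
    out = {
        "cn_accuracy": cn_ok / cn_tot if cn_tot else float("nan"),
        "loh_sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "loh_specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "n_chromosomes": cn_tot,
    }
    if assignments is not None:
        truth_groups = {tid: truth_by_id[tid].group_label for tid in truth_by_id}
        merged = assignments.assign(
            truth_group=assignments["tumor_id"].map(truth_groups))
        out["group_agreement"] = float(
            (merged["group"] == merged["truth_group"]).mean())
    return out
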