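"""Somatic variant filtering and germline/somatic interaction rules.

Variant tables are DataFrames with columns ``chrom, pos, ref, alt, gene,
effect, t_ref, t_alt, n_ref, n_alt, origin`` (tumor/normal allelic read
counts; positions 1-based).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allelic import expected_baf

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "effect",
                   "t_ref", "t_alt", "n_ref", "n_alt", "origin"]

EFFECT_CLASSES = ("nonsense", "frameshift", "missense", "splice", "other")


@dataclass
class FilterConfig:
    """Post-calling somatic filter thresholds.

    Defaults: tumor and normal depth >= 50, >= 10 tumor ALT reads,
    <= 2 ALT reads in the germline sample, and the site must not fall in
    the mappability blacklist (BED-style half-open intervals).
    """

    min_depth: int = 50
    min_tumor_alt: int = 10
    max_normal_alt: int = 2
    blacklist: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if min(self.min_depth, self.min_tumor_alt, self.max_normal_alt) < 0:
            raise ValueError("filter thresholds must be non-negative")


def _in_blacklist(chrom: np.ndarray, pos: np.ndarray, blacklist: pd.DataFrame) -> np.ndarray:
    """1-based positions falling inside half-open blacklist intervals."""
    hit = np.zeros(len(chrom), dtype=bool)
    if blacklist is None or not len(blacklist):
        return hit
    for c, sub in blacklist.groupby("chrom"):
        sel = chrom == c
        if not sel.any():
            continue
        order = np.argsort(sub["start"].to_numpy())
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order]
        p0 = pos[sel] - 1  # to 0-based
        idx = np.searchsorted(starts, p0, side="right") - 1
        ok = idx >= 0
        h = np.zeros(p0.size, dtype=bool)
        h[ok] = p0[ok] < ends[idx[ok]]
        hit[np.flatnonzero(sel)] = h
    return hit


def filter_somatic(variants: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Apply the post-calling somatic filters; nothing is silently dropped.

    Returns the input with ``passed`` (bool) and ``fail_reasons``
    (comma-joined subset of ``malformed, tumor_depth, normal_depth,
    tumor_alt, normal_alt, blacklist``) columns.  Idempotent and
    order-independent.
    """
    out = variants.copy()
    counts = out[["t_ref", "t_alt", "n_ref", "n_alt"]].apply(
        pd.to_numeric, errors="coerce")
    malformed = counts.isna().any(axis=1).to_numpy() | (counts < 0).any(axis=1).to_numpy()
    counts = counts.fillna(-1)
    t_depth = counts["t_ref"].to_numpy() + counts["t_alt"].to_numpy()
    n_depth = counts["n_ref"].to_numpy() + counts["n_alt"].to_numpy()
    reasons = []
    in_bl = _in_blacklist(out["chrom"].to_numpy(), out["pos"].to_numpy(),
                          cfg.blacklist)
    for i in range(len(out)):
        r = []
        if malformed[i]:
            r.append("malformed")
        else:
            if t_depth[i] < cfg.min_depth:
                r.append("tumor_depth")
            if n_depth[i] < cfg.min_depth:
                r.append("normal_depth")
            if counts["t_alt"].iloc[i] < cfg.min_tumor_alt:
                r.append("tumor_alt")
            if counts["n_alt"].iloc[i] > cfg.max_normal_alt:
                r.append("normal_alt")
            if in_bl[i]:
                r.append("blacklist")
        reasons.append(",".join(r))
    out["fail_reasons"] = reasons
    out["passed"] = [r == "" for r in reasons]
    return out


def unopposed_germline(
    germline: pd.DataFrame,
    segments: pd.DataFrame,
    rho: float,
    ratio_min: float = 1.5,
    germline_band: tuple[float, float] = (0.4, 0.6),
    ratio_tol: float = 1.0,
) -> pd.DataFrame:
    """Detect germline het variants rendered unopposed by somatic LoH.

    A germline variant is reported iff its germline BAF lies in
    ``germline_band`` (~1:1 ALT:REF), its locus falls inside an LoH
    segment, and the tumor ALT:REF ratio is >= ``ratio_min``.  For each
    reported variant a ``purity_consistent`` flag records whether the
    observed tumor ratio is within ``ratio_tol`` of the value expected
    from the segment's copy number with the ALT allele retained
    (``b / (1 - b)`` with ``b = expected_baf(rho, c, c)``; e.g.
    ``1 / (1 - rho)`` for CN = 1); the flag is advisory, not a filter.
    """
    lo, hi = germline_band
    rows = []
    for _, v in germline.iterrows():
        t_depth = v["t_ref"] + v["t_alt"]
        if t_depth == 0:
            warnings.warn(f"no tumor coverage at {v['chrom']}:{v['pos']}; skipped",
                          stacklevel=2)
            continue
        n_depth = v["n_ref"] + v["n_alt"]
        if n_depth == 0:
            continue
        g_baf = v["n_alt"] / n_depth
        if not (lo < g_baf < hi):
            continue
        seg = segments.loc[
            (segments["chrom"] == v["chrom"])
            & (segments["start"] < v["pos"]) & (v["pos"] <= segments["end"])]
        if seg.empty:
            continue
        seg = seg.iloc[0]
        if pd.isna(seg["loh"]) or not bool(seg["loh"]):
            continue
        ratio = v["t_alt"] / v["t_ref"] if v["t_ref"] > 0 else np.inf
        if ratio < ratio_min:
            continue
        c = int(seg["cn"])
        if c > 0 or rho < 1.0:
            b = expected_baf(rho, c, c)
            exp_ratio = b / (1.0 - b) if b < 1.0 else np.inf
        else:
            exp_ratio = np.nan
        consistent = bool(np.isfinite(ratio) and np.isfinite(exp_ratio)
                          and abs(ratio - exp_ratio) <= ratio_tol)
        rows.append({**{k: v[k] for k in ["chrom", "pos", "ref", "alt", "gene"]},
                     "germline_ratio": (v["n_alt"] / v["n_ref"]
                                        if v["n_ref"] > 0 else np.inf),
                     "tumor_ratio": ratio,
                     "segment_cn": c,
                     "expected_ratio": exp_ratio,
                     "purity_consistent": consistent})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene",
                                       "germline_ratio", "tumor_ratio",
                                       "segment_cn", "expected_ratio",
                                       "purity_consistent"])


def biallelic_inactivation(
    gene: str,
    somatic_passing: pd.DataFrame,
    karyotype,
    genes: pd.DataFrame,
) -> str:
    """Classify a gene's inactivation status in one tumor.

    * ``biallelic``  — passing somatic variant in the gene AND the gene's
      chromosome carries LoH (the remaining wild-type allele is lost);
    * ``monoallelic`` — variant without LoH;
    * ``loh-only``    — LoH without variant;
    * ``wild-type``   — neither.
    """
    row = genes.loc[genes["gene_id"] == gene]
    if row.empty:
        raise KeyError(f"gene {gene!r} not in annotation")
    chrom = row["chrom"].iloc[0]
    call = karyotype.calls.loc[karyotype.calls["chrom"] == chrom]
    loh = bool(call["loh"].iloc[0]) if len(call) and pd.notna(call["loh"].iloc[0]) else False
    has_variant = bool((somatic_passing["gene"] == gene).any()) if len(somatic_passing) else False
    if has_variant and loh:
        return "biallelic"
    if has_variant:
        return "monoallelic"
    if loh:
        return "loh-only"
    return "wild-type"


def coding_mutation_rate(n_mutations: int, callable_bp: int) -> float:
    """Coding mutations per Mb of genome callable at >= 50x coverage."""
    if callable_bp <= 0:
        raise ValueError("callable_bp must be positive")
    return n_mutations / (callable_bp / 1e6)
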