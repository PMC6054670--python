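"""Per-segment and per-autosome LoH calls, dominant CN, cohort summaries.

LoH evidence is the mirrored B-allele-frequency deviation ``d = |b_T - 0.5|``
averaged over the germline het sites within a segment; it is agnostic to
which parental allele was retained, so copy-loss and copy-neutral LoH are
detected by the same statistic.  The decision threshold ``theta(rho)`` is
half the one-copy-loss deviation at the tumor's purity
(:func:`pnetloh.allelic.loh_deviation_threshold`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allelic import loh_deviation_threshold, loh_threshold_for_cn


def segment_loh(
    segments: pd.DataFrame,
    het_sites: pd.DataFrame,
    rho: float,
    min_hets: int = 10,
    theta: float | None = None,
) -> pd.DataFrame:
    """Flag LoH per segment from mirrored BAF deviation.

    A segment with at least ``min_hets`` mapped het sites is LoH iff its
    mean deviation ``d_bar`` reaches the decision threshold: the base
    threshold ``theta(rho)`` (half the one-copy-loss deviation) for
    segments at CN <= 2, raised for higher assigned CN so that the allelic
    imbalance intrinsic to unbalanced gains (e.g. 2:1 in a trisomy) is not
    mistaken for LoH (:func:`pnetloh.allelic.loh_threshold_for_cn`).
    Segments with fewer hets inherit the chromosome-level call (deviation
    pooled over the whole chromosome, against the same segment threshold);
    if the chromosome itself lacks ``min_hets`` hets the flag is unknown
    (NA) and propagates.

    Adds columns ``n_hets, baf_dev, loh`` to the segment table.
    """
    out = segments.copy()
    out["n_hets"] = 0
    out["baf_dev"] = np.nan
    loh_flags: list[object] = [pd.NA] * len(out)

    def seg_theta(seg) -> float:
        if theta is not None:
            return theta
        if "cn" in seg.index and pd.notna(seg["cn"]):
            return loh_threshold_for_cn(rho, int(seg["cn"]))
        return loh_deviation_threshold(rho)

    for chrom, sub in out.groupby("chrom", sort=False):
        hs = het_sites.loc[het_sites["chrom"] == chrom]
        dev = hs["baf_dev"].to_numpy(dtype=float)
        pos = hs["pos"].to_numpy()
        chrom_n = dev.size
        chrom_dev = float(np.mean(dev)) if chrom_n else np.nan
        for idx, seg in sub.iterrows():
            # segment bp range is half-open [start, end); positions 1-based
            inside = (pos > seg["start"]) & (pos <= seg["end"])
            n = int(inside.sum())
            out.at[idx, "n_hets"] = n
            if n:
                out.at[idx, "baf_dev"] = float(np.mean(dev[inside]))
            th = seg_theta(seg)
            if n >= min_hets:
                flag: object = bool(out.at[idx, "baf_dev"] >= th)
            elif chrom_n >= min_hets:
                flag = bool(chrom_dev >= th)
            else:
                flag = pd.NA
            loh_flags[out.index.get_loc(idx)] = flag
    out["loh"] = pd.array(loh_flags, dtype="boolean")
    return out


@dataclass
class Karyotype:
    """Per-autosome dominant CN and LoH calls for one tumor."""

    tumor_id: str
    calls: pd.DataFrame  # chrom, dominant_cn, loh, support_fraction, heterogeneous

    @property
    def n_monosomic(self) -> int:
        c = self.calls
        return int(((c["loh"] == True) & (c["dominant_cn"] == 1)).sum())  # noqa: E712

    @property
    def n_loh(self) -> int:
        return int((self.calls["loh"] == True).sum())  # noqa: E712

    def loh_chromosomes(self) -> set[str]:
        return set(self.calls.loc[self.calls["loh"] == True, "chrom"])  # noqa: E712


def chromosome_call(
    segments: pd.DataFrame,
    whole_chrom_loh_frac: float = 0.8,
    het_state_frac: float = 0.2,
) -> dict:
    """Roll one chromosome's segments up to a single call.

    * ``dominant_cn``: bp-length-weighted mode of segment CN.
    * ``loh``: True iff >= ``whole_chrom_loh_frac`` of the covered bp lies
      in LoH segments (whole-chromosome LoH); segments with unknown LoH are
      excluded from both numerator and denominator, and the call is NA when
      every segment is unknown.
    * ``heterogeneous``: True when more than one CN state each covers
      >= ``het_state_frac`` of the chromosome (segmental intra-chromosomal
      CN variation, e.g. mixed loss/amplification chromosomes).
    """
    if segments.empty:
        raise ValueError("chromosome_call needs at least one segment")
    seg = segments.copy()
    seg["bp"] = seg["end"] - seg["start"]
    total = seg["bp"].sum()
    by_cn = seg.groupby("cn")["bp"].sum().sort_values(ascending=False)
    dominant = int(by_cn.index[0])
    support = float(by_cn.iloc[0] / total)
    heterogeneous = bool((by_cn / total >= het_state_frac).sum() > 1)
    known = seg.loc[seg["loh"].notna()]
    if known.empty:
        loh: object = pd.NA
    else:
        loh_bp = known.loc[known["loh"].astype(bool), "bp"].sum()
        loh = bool(loh_bp / known["bp"].sum() >= whole_chrom_loh_frac)
    return {
        "chrom": seg["chrom"].iloc[0],
        "dominant_cn": dominant,
        "loh": loh,
        "support_fraction": support,
        "heterogeneous": heterogeneous,
    }


def karyotype_from_segments(
    tumor_id: str,
    segments: pd.DataFrame,
    chrom_order: list[str] | None = None,
    **call_kwargs,
) -> Karyotype:
    """Build a per-autosome karyotype from a CN+LoH-annotated segment table."""
    rows = []
    order = chrom_order or list(dict.fromkeys(segments["chrom"]))
    for chrom in order:
        sub = segments.loc[segments["chrom"] == chrom]
        if sub.empty:
            continue
        rows.append(chromosome_call(sub, **call_kwargs))
    calls = pd.DataFrame(rows)
    calls["loh"] = pd.array(calls["loh"], dtype="boolean")
    return Karyotype(tumor_id=tumor_id, calls=calls)


def cohort_aneuploidy_summary(karyotypes: list[Karyotype]) -> dict:
    """Per-tumor monosomy/LoH counts and the cohort-level fractions.

    Returns ``{"per_tumor": DataFrame, "fractions": dict}`` where the
    fractions report the share of tumors with >= 1 monosomic chromosome,
    >= 1 LoH chromosome, and >= 8 LoH chromosomes.
    """
    if not karyotypes:
        raise ValueError("empty cohort")
    per = pd.DataFrame({
        "tumor_id": [k.tumor_id for k in karyotypes],
        "n_monosomic": [k.n_monosomic for k in karyotypes],
        "n_loh": [k.n_loh for k in karyotypes],
    })
    n = len(per)
    fractions = {
        "ge1_monosomy": float((per["n_monosomic"] >= 1).sum() / n),
        "ge1_loh": float((per["n_loh"] >= 1).sum() / n),
        "ge8_loh": float((per["n_loh"] >= 8).sum() / n),
    }
    return {"per_tumor": per, "fractions": fractions}


def karyotype_matrix(karyotypes: list[Karyotype]) -> pd.DataFrame:
    """Tumor x chromosome matrix of ``"<cn>"`` / ``"<cn>*"`` strings (* = LoH)."""
    rows = {}
    for k in karyotypes:
        vals = {}
        for _, c in k.calls.iterrows():
            star = "*" if (pd.notna(c["loh"]) and bool(c["loh"])) else ""
            vals[c["chrom"]] = f"{int(c['dominant_cn'])}{star}"
        rows[k.tumor_id] = vals
    return pd.DataFrame.from_dict(rows, orient="index")
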