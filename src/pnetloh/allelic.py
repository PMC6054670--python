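"""Germline heterozygote detection and B-allele-frequency evidence.

Allele-count tables are pandas DataFrames with columns
``chrom, pos, ref, alt, ref_count, alt_count`` (positions 1-based, unique
per chromosome within a sample).

The purity mixture model used throughout the package lives here as
:func:`expected_baf`: a tumor sample is a mixture of a fraction ``rho`` of
tumor cells (carrying ``a`` ALT copies out of ``c`` total at a germline het
site) and ``1 - rho`` of diploid stromal cells (carrying 1 ALT of 2), so

    b = (rho * a + (1 - rho)) / (rho * c + 2 * (1 - rho)).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import binom

ALLELE_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


def binomial_equal_allele_p(n_alt, n):
    """Two-sided exact binomial p-value against a balanced (p=0.5) null.

    The p-value is the total probability of outcomes whose point mass does
    not exceed that of the observation; for the symmetric p=0.5 null this
    equals ``min(1, 2 * P(X <= min(k, n-k)))``.  Symmetric in
    ``k <-> n - k``.  Vectorized over array inputs.
    """
    n_alt = np.asarray(n_alt)
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("depth n must be >= 1")
    if np.any((n_alt < 0) | (n_alt > n)):
        raise ValueError("alt count must satisfy 0 <= n_alt <= n")
    m = np.minimum(n_alt, n - n_alt)
    p = np.minimum(1.0, 2.0 * binom.cdf(m, n, 0.5))
    return p if p.ndim else float(p)


def expected_baf(rho: float, c, a):
    """Expected tumor BAF at a germline het site under the purity mixture.

    Parameters
    ----------
    rho
        Tumor purity in (0, 1].
    c
        Total copy number of the locus in tumor cells (>= 0).
    a
        ALT copies in tumor cells, 0 <= a <= c.

    Symmetric: ``expected_baf(rho, c, a) + expected_baf(rho, c, c - a) == 1``.
    """
    c = np.asarray(c, dtype=float)
    a = np.asarray(a, dtype=float)
    if not (0.0 < rho <= 1.0):
        raise ValueError("purity must be in (0, 1]")
    if np.any(c < 0) or np.any((a < 0) | (a > c)):
        raise ValueError("need c >= 0 and 0 <= a <= c")
    denom = rho * c + 2.0 * (1.0 - rho)
    if np.any(denom <= 0):
        raise ValueError("no DNA at locus (rho=1 with c=0)")
    b = (rho * a + (1.0 - rho)) / denom
    return b if b.ndim else float(b)


def loh_deviation_threshold(rho: float) -> float:
    """Mirrored-BAF threshold for LoH evidence: half the one-copy-loss shift.

    The one-copy-loss deviation at purity ``rho`` is
    ``expected_baf(rho, 1, 1) - 0.5 = rho / (2 * (2 - rho))``; the threshold
    sits at half that, which keeps copy-neutral LoH (deviation ``rho/2``)
    comfortably above it while balanced segments stay below.
    """
    return 0.5 * (expected_baf(rho, 1, 1) - 0.5)


def loh_threshold_for_cn(rho: float, c: int) -> float:
    """LoH deviation threshold adapted to a segment's assigned copy number.

    Unbalanced gains also shift BAF — a trisomic segment carries its
    germline hets at 2:1, a deviation that can exceed the plain threshold
    without any allele having been lost.  For ``c >= 3`` the threshold
    therefore moves to the midpoint between the most-balanced allele
    configuration (``a = ceil(c/2)``) and the fully unopposed one
    (``a = c``); for ``c <= 2`` it reduces to
    :func:`loh_deviation_threshold`.
    """
    base = loh_deviation_threshold(rho)
    if c <= 2:
        return base
    d_bal = expected_baf(rho, c, -(-c // 2)) - 0.5
    d_full = expected_baf(rho, c, c) - 0.5
    return max(base, 0.5 * (d_bal + d_full))


def call_germline_hets(
    germline: pd.DataFrame,
    baf_lo: float = 0.4,
    baf_hi: float = 0.6,
    alpha: float = 0.05,
    min_depth: int = 50,
    criterion: str = "not_rejected",
) -> pd.DataFrame:
    """Identify germline heterozygous positions.

    A site is called het iff its germline BAF lies strictly inside
    ``(baf_lo, baf_hi)``, its depth is at least ``min_depth`` and the
    balanced-allele hypothesis is compatible with the read counts.

    ``criterion="not_rejected"`` (default) requires the two-sided exact
    binomial p-value to be ``>= alpha`` (balance not rejected at the
    ``1 - alpha`` confidence level).  ``criterion="literal"`` instead
    requires ``p >= 1 - alpha`` — a far stricter reading that rejects
    most true hets at high depth; it is exposed for comparison only.

    Returns a DataFrame sorted by (chrom, pos) with columns
    ``chrom, pos, ref, alt, ref_count, alt_count, baf, p_het``.
    """
    if germline.empty:
        raise ValueError("empty allele-count table")
    df = germline.copy()
    depth = df["ref_count"].to_numpy() + df["alt_count"].to_numpy()
    keep = depth >= max(min_depth, 1)
    df = df.loc[keep].copy()
    depth = depth[keep]
    if df.empty:
        return df.assign(baf=pd.Series(dtype=float), p_het=pd.Series(dtype=float))
    baf = df["alt_count"].to_numpy() / depth
    p = binomial_equal_allele_p(df["alt_count"].to_numpy(), depth)
    if criterion == "not_rejected":
        compatible = p >= alpha
    elif criterion == "literal":
        compatible = p >= 1.0 - alpha
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    het = (baf > baf_lo) & (baf < baf_hi) & compatible
    out = df.loc[het, ALLELE_COLUMNS].copy()
    out["baf"] = baf[het]
    out["p_het"] = np.asarray(p)[het]
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def tumor_baf(hets: pd.DataFrame, tumor: pd.DataFrame, min_depth: int = 50) -> pd.DataFrame:
    """Attach tumor BAF evidence to germline het sites.

    Sites absent from the tumor table, or with tumor depth below
    ``min_depth``, are dropped.  Adds columns ``tumor_baf`` (``b_T``) and
    ``baf_dev`` (mirrored deviation ``|b_T - 0.5|``).
    """
    t = tumor[["chrom", "pos", "ref_count", "alt_count"]].rename(
        columns={"ref_count": "t_ref", "alt_count": "t_alt"})
    merged = hets.merge(t, on=["chrom", "pos"], how="inner")
    depth = merged["t_ref"] + merged["t_alt"]
    merged = merged.loc[depth >= max(min_depth, 1)].copy()
    if merged.empty:
        warnings.warn("no het sites covered in tumor sample", stacklevel=2)
        merged["tumor_baf"] = pd.Series(dtype=float)
        merged["baf_dev"] = pd.Series(dtype=float)
        return merged
    b = merged["t_alt"] / (merged["t_ref"] + merged["t_alt"])
    merged["tumor_baf"] = b
    merged["baf_dev"] = (b - 0.5).abs()
    return merged.reset_index(drop=True)
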