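"""Recurrent-LoH mining, three-group tumor classification, clinical association.

The cohort splits on two axes: somatic MEN1 status and the LoH karyotype.
Group 1 tumors are MEN1-mutant with the recurrent multi-chromosome LoH
pattern; Group 2 tumors are MEN1-mutant with chromosome 11 LoH but without
the recurrent pattern; Group 3 tumors lack a somatic MEN1 mutation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genome import MEN1_CHROM
from .loh import Karyotype


@dataclass(frozen=True)
class RecurrentSet:
    """Chromosome set recurrently lost in the high-LoH tumors."""

    chromosomes: tuple[str, ...]
    support: int                    # number of high-LoH tumors backing the set
    member_freqs: dict              # chrom -> frequency among high-LoH tumors


def mine_recurrent_loh(
    karyotypes: list[Karyotype],
    high_loh_min: int = 8,
    member_freq: float = 0.8,
) -> RecurrentSet:
    """Mine the chromosome set shared by high-LoH tumors.

    High-LoH tumors carry LoH of >= ``high_loh_min`` chromosomes; the
    recurrent set contains every chromosome with LoH in at least
    ``member_freq`` of them.  With no high-LoH tumors the set is empty.
    """
    if len(karyotypes) < 2:
        raise ValueError("need >= 2 karyotypes to mine a recurrent pattern")
    high = [k for k in karyotypes if k.n_loh >= high_loh_min]
    if not high:
        return RecurrentSet(chromosomes=(), support=0, member_freqs={})
    counts: dict[str, int] = {}
    for k in high:
        for chrom in k.loh_chromosomes():
            counts[chrom] = counts.get(chrom, 0) + 1
    freqs = {c: n / len(high) for c, n in counts.items()}
    members = tuple(sorted((c for c, f in freqs.items() if f >= member_freq),
                           key=_chrom_key))
    support = sum(1 for k in high
                  if set(members) <= k.loh_chromosomes()) if members else 0
    return RecurrentSet(chromosomes=members, support=support, member_freqs=freqs)


def _chrom_key(name: str):
    digits = "".join(ch for ch in name if ch.isdigit())
    return (int(digits) if digits else 10 ** 9, name)


def classify_groups(
    karyotypes: list[Karyotype],
    men1_status: dict,
    recurrent_set: RecurrentSet,
    min_overlap: float = 0.8,
    chr11: str = MEN1_CHROM,
) -> pd.DataFrame:
    """Assign every tumor to exactly one of the three CN groups.

    * Group 3: no somatic MEN1 mutation.
    * Among MEN1-mutant tumors: Group 1 iff chr11 LoH and the tumor's LoH
      chromosomes cover >= ``min_overlap`` of the recurrent set's members;
      Group 2 otherwise.  MEN1-mutant tumors lacking chr11 LoH are still
      Group 2 but flagged as anomalies.

    ``men1_status`` maps tumor_id -> bool (passing somatic MEN1 variant).
    """
    rows = []
    members = set(recurrent_set.chromosomes)
    for k in karyotypes:
        if k.tumor_id not in men1_status:
            raise KeyError(f"missing MEN1 status for {k.tumor_id}")
        men1 = bool(men1_status[k.tumor_id])
        loh = k.loh_chromosomes()
        chr11_loh = chr11 in loh
        overlap = (len(loh & members) / len(members)) if members else 0.0
        if not men1:
            group = 3
        elif chr11_loh and members and overlap >= min_overlap:
            group = 1
        else:
            group = 2
        rows.append({
            "tumor_id": k.tumor_id,
            "group": group,
            "men1_somatic": men1,
            "chr11_loh": chr11_loh,
            "n_loh": k.n_loh,
            "recurrent_overlap": overlap,
            "anomaly": bool(men1 and not chr11_loh),
        })
    return pd.DataFrame(rows)


def fisher_exact_2xk(table) -> float:
    """Two-sided Fisher exact p-value for a 2 x k table (k = 2 or 3).

    Conditions on both margins and sums the multivariate hypergeometric
    probabilities of every table whose probability does not exceed the
    observed table's (standard probability-mass two-sided convention).
    Computed by full enumeration of the first row.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] not in (2, 3):
        raise ValueError("table must be 2x2 or 2x3")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row1 = int(t[0].sum())
    cols = t.sum(axis=0)
    if t.sum() == 0 or row1 + int(t[1].sum()) == 0:
        raise ValueError("margins must be positive")

    def log_prob(xs):
        lp = -_log_comb(int(t.sum()), row1)
        for x, c in zip(xs, cols):
            lp += _log_comb(int(c), int(x))
        return lp

    obs = log_prob(t[0])
    total = 0.0
    k = t.shape[1]
    ranges = [range(0, int(c) + 1) for c in cols[:-1]]
    for xs in itertools.product(*ranges):
        last = row1 - sum(xs)
        if last < 0 or last > cols[-1]:
            continue
        lp = log_prob((*xs, last))
        if lp <= obs + 1e-9:
            total += np.exp(lp)
    return float(min(1.0, total))


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -np.inf
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def associate_clinical(groups: pd.DataFrame, clinical: pd.DataFrame) -> dict:
    """Test association of CN group with tumor grade and metastasis.

    Builds group x grade and group x metastasis contingency tables and
    applies :func:`fisher_exact_2xk` (grade classes are collapsed to
    low = grade 1 vs high = grade 2-3 so the table stays 2 x k).  Tumors
    missing clinical fields are excluded with a warning.  Returns a report
    dict containing both tables and p-values.
    """
    merged = groups.merge(clinical, on="tumor_id", how="left")
    missing = merged["grade"].isna() | merged["metastasis"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} tumors missing clinical fields; excluded",
                      stacklevel=2)
        merged = merged.loc[~missing]
    present = sorted(merged["group"].unique())
    report: dict = {"groups_present": present}
    if len(present) < 2:
        warnings.warn("fewer than two groups present; association skipped",
                      stacklevel=2)
        report["grade_p"] = report["metastasis_p"] = None
        return report
    grade_tab = np.array([
        [int(((merged["group"] == g) & (merged["grade"] <= 1)).sum()) for g in present],
        [int(((merged["group"] == g) & (merged["grade"] >= 2)).sum()) for g in present],
    ])
    met_tab = np.array([
        [int(((merged["group"] == g) & merged["metastasis"].astype(bool)).sum())
         for g in present],
        [int(((merged["group"] == g) & ~merged["metastasis"].astype(bool)).sum())
         for g in present],
    ])
    report["grade_table"] = grade_tab
    report["metastasis_table"] = met_tab
    report["grade_p"] = fisher_exact_2xk(grade_tab)
    report["metastasis_p"] = fisher_exact_2xk(met_tab)
    return report
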