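"""Synthetic tumor/normal cohort generator with known ground truth.

The generator emulates the observable summaries of a deep tumor/normal
sequencing study of pancreatic neuroendocrine tumors: per-tile read
counts under integer chromosome/segment copy number diluted by diploid
stroma, SNP allele counts at germline het/hom sites, somatic and germline
variant tables (including deliberate below-threshold artifacts that
downstream filters must reject), a log2 expression matrix with a
whole-chromosome dosage effect and a two-batch offset, and a clinical
table whose grade/metastasis probabilities differ by karyotype group.

Noise model: tile counts are negative-binomial (Poisson recovered as the
dispersion size -> infinity), allele counts beta-binomial (binomial as the
precision -> infinity).  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .allelic import expected_baf
from .genome import (ConfigError, GenomeModel, MEN1_CHROM,
                     RECURRENT_LOH_CHROMS, build_genome)
from .expression import ExpressionMatrix

GROUP_LABELS = (1, 2, 3)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Cohort composition and sequencing parameters default to a 39-tumor
    cohort (10 / 16 / 13 tumors in Groups 1 / 2 / 3), ~150x tile and SNP
    depth, purity uniform on [0.4, 0.8], mild count overdispersion, and a
    dosage slope of 0.5 log2 units per copy.
    """

    n_group1: int = 10
    n_group2: int = 16
    n_group3: int = 13
    tile_depth: float = 150.0          # mean reads per 3 kb tile
    snp_depth: float = 150.0           # mean reads per SNP site
    nb_size: float = 30.0              # negative-binomial dispersion (size)
    bb_precision: float = 500.0        # beta-binomial precision (alpha + beta)
    purity_range: tuple[float, float] = (0.4, 0.8)
    p_het: float = 0.5                 # fraction of candidate SNP sites that are het
    hom_error: float = 0.002           # sequencing-error ALT fraction at hom-ref sites
    cn_loh_frac: float = 0.2           # Group-1 LoH chromosomes that are copy-neutral
    group3_max_aneuploidy: float = 0.35  # per-chromosome aberration rate upper bound
    dosage_beta: float = 0.5           # log2 expression units per copy
    expr_sigma: float = 0.5            # per-gene expression noise SD
    batch_offset: float = 1.0          # additive offset between the two batches
    expr_baseline_mean: float = 7.0
    expr_baseline_sd: float = 1.0
    n_passenger: int = 2               # somatic passenger variants per tumor
    n_unopposed: int = 2               # germline hets placed on LoH chromosomes
    n_opposed: int = 2                 # germline hets on diploid chromosomes
    n_artifacts: int = 4               # below-threshold somatic artifacts per tumor
    seed: int = 0
    # genome scaffold
    n_chromosomes: int = 22
    chrom_length: int = 3_000_000
    tile_size: int = 3000
    snps_per_chrom: int = 200
    genes_per_chrom: int = 50

    def validate(self) -> None:
        if min(self.n_group1, self.n_group2, self.n_group3) < 0:
            raise ConfigError("group sizes must be non-negative")
        if min(self.tile_depth, self.snp_depth, self.nb_size, self.bb_precision) <= 0:
            raise ConfigError("depths and dispersion parameters must be positive")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError("purity range must lie within (0, 1]")
        if not (0.0 <= self.p_het <= 1.0 and 0.0 <= self.cn_loh_frac <= 1.0):
            raise ConfigError("fractions must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["purity_range"] = list(self.purity_range)
        return d


@dataclass
class KaryotypeTruth:
    """Ground-truth karyotype for one simulated tumor."""

    tumor_id: str
    chrom_states: dict                 # chrom -> (total_cn, loh)
    purity: float
    men1_somatic: bool
    group_label: int
    segments: dict = field(default_factory=dict)  # chrom -> [(start, end, cn, loh)]

    def state_at(self, chrom: str, pos_bp: float) -> tuple[int, bool]:
        """(cn, loh) at a 0-based bp offset, honouring segmental overrides."""
        cn, loh = self.chrom_states[chrom]
        for start, end, seg_cn, seg_loh in self.segments.get(chrom, []):
            if start <= pos_bp < end:
                return int(seg_cn), bool(seg_loh)
        return int(cn), bool(loh)

    def truth_calls(self, chrom_order: list[str]) -> pd.DataFrame:
        """Whole-chromosome truth as a calls table (dominant state by bp)."""
        rows = [{"chrom": c,
                 "dominant_cn": int(self.chrom_states[c][0]),
                 "loh": bool(self.chrom_states[c][1])}
                for c in chrom_order if c in self.chrom_states]
        return pd.DataFrame(rows)

    def to_karyotype(self, chrom_order: list[str]):
        """Noiseless ground-truth karyotype (for round-trip classification
        and truth-anchored dosage analysis)."""
        from .loh import Karyotype

        calls = self.truth_calls(chrom_order)
        calls["support_fraction"] = 1.0
        calls["heterogeneous"] = False
        calls["loh"] = pd.array(calls["loh"], dtype="boolean")
        return Karyotype(tumor_id=self.tumor_id, calls=calls)


def _nb_counts(rng, mean, size):
    """Negative-binomial draws parameterized by mean and dispersion size."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def _bb_counts(rng, n, b, precision):
    """Beta-binomial ALT counts with mean fraction b and given precision."""
    n = np.asarray(n)
    b = np.clip(np.asarray(b, dtype=float), 0.0, 1.0)
    out = np.zeros(n.shape, dtype=np.int64)
    mid = (b > 0.0) & (b < 1.0) & (n > 0)
    if mid.any():
        p = rng.beta(b[mid] * precision, (1.0 - b[mid]) * precision)
        out[mid] = rng.binomial(n[mid], p)
    fixed1 = (b >= 1.0) & (n > 0)
    out[fixed1] = n[fixed1]
    return out


def simulate_karyotype(group: int, config: SimConfig, rng: np.random.Generator,
                       tumor_id: str = "T") -> KaryotypeTruth:
    """Draw a ground-truth karyotype for one tumor of the given group.

    Group 1: LoH of the canonical recurrent chromosome set (CN = 1, or
    copy-neutral with probability ``cn_loh_frac``) plus a somatic MEN1 hit.
    Group 2: chromosome 11 LoH (CN = 1) only, plus a somatic MEN1 hit.
    Group 3: no MEN1 hit; a per-tumor aberration rate drawn uniformly on
    [0, ``group3_max_aneuploidy``] makes each chromosome monosomic (p 0.5),
    trisomic (p 0.4) or copy-neutral LoH (p 0.1), spanning euploid to
    extensively aneuploid genomes.
    """
    if group not in GROUP_LABELS:
        raise ConfigError(f"unknown group {group}")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    states = {c: (2, False) for c in chroms}
    purity = float(rng.uniform(*config.purity_range))
    if group == 1:
        for c in RECURRENT_LOH_CHROMS:
            if c not in states:
                continue
            if rng.random() < config.cn_loh_frac:
                states[c] = (2, True)      # copy-neutral LoH
            else:
                states[c] = (1, True)
        men1 = True
    elif group == 2:
        if MEN1_CHROM in states:
            states[MEN1_CHROM] = (1, True)
        men1 = True
    else:
        rate = float(rng.uniform(0.0, config.group3_max_aneuploidy))
        for c in chroms:
            if rng.random() < rate:
                u = rng.random()
                if u < 0.5:
                    states[c] = (1, True)
                elif u < 0.9:
                    states[c] = (3, False)
                else:
                    states[c] = (2, True)
        men1 = False
    return KaryotypeTruth(tumor_id=tumor_id, chrom_states=states, purity=purity,
                          men1_somatic=men1, group_label=group)


def _tile_cn(genome: GenomeModel, truth: KaryotypeTruth, chrom: str):
    starts, ends = genome.tile_bounds(chrom)
    mids = (starts + ends) / 2.0
    cn = np.empty(mids.size, dtype=np.int64)
    loh = np.empty(mids.size, dtype=bool)
    base_cn, base_loh = truth.chrom_states[chrom]
    cn[:] = base_cn
    loh[:] = base_loh
    for s, e, seg_cn, seg_loh in truth.segments.get(chrom, []):
        sel = (mids >= s) & (mids < e)
        cn[sel] = seg_cn
        loh[sel] = seg_loh
    return cn, loh


def simulate_counts(
    genome: GenomeModel, truth: KaryotypeTruth, config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (normal tiles, tumor tiles, normal alleles, tumor alleles).

    Tumor tile means scale the configured depth by the stromal mixture
    factor ``(rho * c + 2 (1 - rho)) / 2``; tumor ALT counts at het sites
    follow the purity mixture BAF with per-site random retained/gained
    haplotype.  Allele tables carry ``true_het`` / ``true_baf`` ground
    truth columns, which downstream callers ignore.
    """
    bad = set(truth.chrom_states) - set(genome.chrom_names)
    if bad:
        raise ConfigError(f"truth chromosomes absent from genome: {sorted(bad)}")
    rho = truth.purity
    tile_rows_n, tile_rows_t = [], []
    for chrom in genome.chrom_names:
        starts, ends = genome.tile_bounds(chrom)
        widths = (ends - starts) / genome.tile_size
        cn, _ = _tile_cn(genome, truth, chrom)
        mean_n = config.tile_depth * widths
        factor = (rho * cn + 2.0 * (1.0 - rho)) / 2.0
        mean_t = mean_n * factor
        tile_rows_n.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "count": _nb_counts(rng, mean_n, config.nb_size)}))
        tile_rows_t.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "count": _nb_counts(rng, mean_t, config.nb_size)}))
    normal_tiles = pd.concat(tile_rows_n, ignore_index=True)
    tumor_tiles = pd.concat(tile_rows_t, ignore_index=True)

    al_n, al_t = [], []
    for chrom in genome.chrom_names:
        pos = genome.snp_positions.get(chrom, np.empty(0, dtype=int))
        if pos.size == 0:
            continue
        m = pos.size
        is_het = rng.random(m) < config.p_het
        hom_alt = ~is_het & (rng.random(m) < 0.5)
        g_frac = np.where(is_het, 0.5,
                          np.where(hom_alt, 1.0 - config.hom_error, config.hom_error))
        n_depth = rng.poisson(config.snp_depth, m)
        n_alt = _bb_counts(rng, n_depth, g_frac, config.bb_precision)

        cn = np.empty(m, dtype=np.int64)
        loh = np.empty(m, dtype=bool)
        for i, p in enumerate(pos):
            cn[i], loh[i] = truth.state_at(chrom, p - 1)
        alt_copies = np.where(loh, np.where(rng.random(m) < 0.5, cn, 0),
                              np.where(cn == 2, 1,
                                       np.where(cn > 2,
                                                1 + (rng.random(m) < 0.5), 1)))
        alt_copies = np.minimum(alt_copies, np.maximum(cn, 0))
        denom = rho * cn + 2.0 * (1.0 - rho)
        t_frac = np.where(is_het,
                          np.where(denom > 0,
                                   (rho * alt_copies + (1.0 - rho)) / np.maximum(denom, 1e-12),
                                   0.5),
                          g_frac)
        depth_factor = denom / 2.0
        t_depth = rng.poisson(config.snp_depth * depth_factor, m)
        t_alt = _bb_counts(rng, t_depth, t_frac, config.bb_precision)

        base = pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "ref": "A", "alt": "G",
            "true_het": is_het, "true_baf": t_frac, "true_cn": cn, "true_loh": loh,
        })
        al_n.append(base.assign(ref_count=n_depth - n_alt, alt_count=n_alt))
        al_t.append(base.assign(ref_count=t_depth - t_alt, alt_count=t_alt))
    cols = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count",
            "true_het", "true_baf", "true_cn", "true_loh"]
    normal_alleles = pd.concat(al_n, ignore_index=True)[cols]
    tumor_alleles = pd.concat(al_t, ignore_index=True)[cols]
    return normal_tiles, tumor_tiles, normal_alleles, tumor_alleles


def make_blacklist(genome: GenomeModel, rng: np.random.Generator,
                   per_chrom: int = 1, width_tiles: int = 3) -> pd.DataFrame:
    """Low-mappability exclusion intervals (BED half-open), a few per chromosome."""
    rows = []
    for chrom, length in genome.chromosomes:
        n_tiles = genome.n_tiles(chrom)
        for _ in range(per_chrom):
            first = int(rng.integers(0, max(1, n_tiles - width_tiles)))
            start = first * genome.tile_size
            end = min((first + width_tiles) * genome.tile_size, length)
            rows.append({"chrom": chrom, "start": start, "end": end})
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def _variant_counts(rng, depth_mean, frac, precision):
    depth = max(int(rng.poisson(depth_mean)), 1)
    alt = int(_bb_counts(rng, np.array([depth]), np.array([frac]), precision)[0])
    return depth - alt, alt


def simulate_variants(
    genome: GenomeModel, truth: KaryotypeTruth, config: SimConfig,
    rng: np.random.Generator, blacklist: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate (somatic, germline) variant tables for one tumor.

    Somatic: a MEN1 variant on chr11 when ``truth.men1_somatic`` (tumor
    VAF consistent with mutation of the retained allele under the chr11
    state), passenger variants on diploid chromosomes (VAF rho/2), and
    below-threshold artifacts cycling through low depth, < 10 tumor ALT
    reads, > 2 germline ALT reads and a blacklisted position.

    Germline: het variants on LoH chromosomes (ALT on the retained
    haplotype -> unopposed in the tumor) and on diploid chromosomes
    (opposed).  A ``true_class`` column records the intent of each record.
    """
    rho = truth.purity
    genes = genome.gene_midpoints()
    somatic_rows, germline_rows = [], []

    def gene_site(chrom=None, exclude=()):
        pool = genes if chrom is None else genes[genes["chrom"] == chrom]
        pool = pool[~pool["gene_id"].isin(exclude)]
        row = pool.iloc[int(rng.integers(0, len(pool)))]
        return row["gene_id"], row["chrom"], int(row["midpoint"])

    used: list[str] = []
    if truth.men1_somatic:
        if MEN1_CHROM not in genome.chrom_names:
            raise ConfigError("MEN1 chromosome absent from genome")
        men1 = genes[genes["gene_id"] == "MEN1"].iloc[0]
        c11, _ = truth.state_at(MEN1_CHROM, men1["midpoint"])
        denom = rho * c11 + 2.0 * (1.0 - rho)
        vaf = rho * 1.0 / denom if denom > 0 else 0.0
        t_ref, t_alt = _variant_counts(rng, config.snp_depth * denom / 2.0,
                                       vaf, config.bb_precision)
        somatic_rows.append({
            "chrom": MEN1_CHROM, "pos": int(men1["midpoint"]), "ref": "C", "alt": "T",
            "gene": "MEN1",
            "effect": str(rng.choice(["nonsense", "frameshift", "missense"])),
            "t_ref": t_ref, "t_alt": t_alt,
            "n_ref": int(rng.poisson(config.snp_depth)), "n_alt": 0,
            "origin": "somatic", "true_class": "men1",
        })
        used.append("MEN1")

    diploid = [c for c, (cn, loh) in truth.chrom_states.items()
               if cn == 2 and not loh]
    for _ in range(config.n_passenger):
        chrom = diploid[int(rng.integers(0, len(diploid)))] if diploid else None
        gid, chrom, pos = gene_site(chrom, exclude=used)
        used.append(gid)
        t_ref, t_alt = _variant_counts(rng, config.snp_depth, rho / 2.0,
                                       config.bb_precision)
        somatic_rows.append({
            "chrom": chrom, "pos": pos, "ref": "G", "alt": "A", "gene": gid,
            "effect": str(rng.choice(list(EFFECTS))),
            "t_ref": t_ref, "t_alt": t_alt,
            "n_ref": int(rng.poisson(config.snp_depth)), "n_alt": 0,
            "origin": "somatic", "true_class": "passenger",
        })

    artifact_kinds = ["low_depth", "low_tumor_alt", "germline_support", "blacklist"]
    for i in range(config.n_artifacts):
        kind = artifact_kinds[i % len(artifact_kinds)]
        gid, chrom, pos = gene_site(exclude=used)
        used.append(gid)
        t_ref, t_alt = _variant_counts(rng, config.snp_depth, rho / 2.0,
                                       config.bb_precision)
        n_ref, n_alt = int(rng.poisson(config.snp_depth)), 0
        if kind == "low_depth":
            t_ref, t_alt = 20, 10
        elif kind == "low_tumor_alt":
            t_alt = int(rng.integers(3, 10))
            t_ref = int(config.snp_depth) - t_alt
        elif kind == "germline_support":
            n_alt = int(rng.integers(3, 8))
        elif kind == "blacklist" and blacklist is not None and len(blacklist):
            bl = blacklist.iloc[int(rng.integers(0, len(blacklist)))]
            chrom, pos = bl["chrom"], int((bl["start"] + bl["end"]) // 2) + 1
            gid = "blacklisted_site"
        somatic_rows.append({
            "chrom": chrom, "pos": pos, "ref": "T", "alt": "C", "gene": gid,
            "effect": "missense", "t_ref": t_ref, "t_alt": t_alt,
            "n_ref": n_ref, "n_alt": n_alt,
            "origin": "somatic", "true_class": f"artifact_{kind}",
        })

    loh_chroms = [c for c, (cn, loh) in truth.chrom_states.items() if loh]
    for _ in range(config.n_unopposed if loh_chroms else 0):
        chrom = loh_chroms[int(rng.integers(0, len(loh_chroms)))]
        gid, chrom, pos = gene_site(chrom, exclude=used)
        used.append(gid)
        cn, _ = truth.state_at(chrom, pos)
        b = expected_baf(rho, cn, cn)   # ALT on the retained haplotype
        n_depth = int(rng.poisson(config.snp_depth))
        n_alt = int(rng.binomial(n_depth, 0.5))
        t_ref, t_alt = _variant_counts(
            rng, config.snp_depth * (rho * cn + 2 * (1 - rho)) / 2.0,
            b, config.bb_precision)
        germline_rows.append({
            "chrom": chrom, "pos": pos, "ref": "A", "alt": "C", "gene": gid,
            "effect": "missense", "t_ref": t_ref, "t_alt": t_alt,
            "n_ref": n_depth - n_alt, "n_alt": n_alt,
            "origin": "germline", "true_class": "unopposed",
        })
    for _ in range(config.n_opposed):
        chrom = diploid[int(rng.integers(0, len(diploid)))] if diploid else None
        gid, chrom, pos = gene_site(chrom, exclude=used)
        used.append(gid)
        n_depth = int(rng.poisson(config.snp_depth))
        n_alt = int(rng.binomial(n_depth, 0.5))
        t_ref, t_alt = _variant_counts(rng, config.snp_depth, 0.5,
                                       config.bb_precision)
        germline_rows.append({
            "chrom": chrom, "pos": pos, "ref": "A", "alt": "C", "gene": gid,
            "effect": "missense", "t_ref": t_ref, "t_alt": t_alt,
            "n_ref": n_depth - n_alt, "n_alt": n_alt,
            "origin": "germline", "true_class": "opposed",
        })
    cols = VARIANT_OUT_COLUMNS
    return (pd.DataFrame(somatic_rows, columns=cols),
            pd.DataFrame(germline_rows, columns=cols))


EFFECTS = ("nonsense", "frameshift", "missense", "splice", "other")
VARIANT_OUT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "effect",
                       "t_ref", "t_alt", "n_ref", "n_alt", "origin", "true_class"]


def simulate_expression(
    genome: GenomeModel, truths: list[KaryotypeTruth], config: SimConfig,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Log2 expression with a linear whole-chromosome dosage effect.

    Gene g in tumor t: ``baseline_g + beta * (c_{t, chrom(g)} - 2) +
    batch_offset + Normal(0, sigma)``.  Tumors alternate between two
    batches ("frozen", "FFPE"); the second batch gets the additive offset.
    """
    if len(truths) < 2:
        raise ConfigError("expression simulation needs >= 2 tumors")
    genes = genome.gene_midpoints()
    baseline = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd,
                          len(genes))
    samples = [t.tumor_id for t in truths]
    batches = pd.Series(["frozen" if i % 2 == 0 else "FFPE"
                         for i in range(len(samples))], index=samples)
    values = np.empty((len(genes), len(samples)))
    for j, truth in enumerate(truths):
        cn = np.array([truth.state_at(ch, mid)[0]
                       for ch, mid in zip(genes["chrom"], genes["midpoint"])])
        offset = config.batch_offset if batches.iloc[j] == "FFPE" else 0.0
        values[:, j] = (baseline + config.dosage_beta * (cn - 2.0) + offset
                        + rng.normal(0.0, config.expr_sigma, len(genes)))
    vals = pd.DataFrame(values, index=genes["gene_id"].to_numpy(), columns=samples)
    info = genome.genes.set_index("gene_id")[["chrom", "start", "end"]]
    return ExpressionMatrix(values=vals, gene_info=info, batches=batches)


def simulate_clinical(truths: list[KaryotypeTruth], rng: np.random.Generator) -> pd.DataFrame:
    """Grade (1-3) and metastasis flags with group-dependent probabilities.

    Group 1 tumors are mostly grade 2-3 with a 40% metastasis rate;
    Group 2 are almost all grade 1 and never metastasize; Group 3 is mixed.
    """
    grade_p = {1: (0.1, 0.6, 0.3), 2: (0.94, 0.06, 0.0), 3: (0.5, 0.4, 0.1)}
    met_p = {1: 0.4, 2: 0.0, 3: 0.15}
    rows = []
    for t in truths:
        g = int(rng.choice([1, 2, 3], p=grade_p[t.group_label]))
        rows.append({"tumor_id": t.tumor_id, "grade": g,
                     "metastasis": bool(rng.random() < met_p[t.group_label])})
    return pd.DataFrame(rows)


@dataclass
class SimulatedCohort:
    """Everything one simulated study produces, with its ground truth."""

    config: SimConfig
    genome: GenomeModel
    truths: list[KaryotypeTruth]
    blacklist: pd.DataFrame
    tiles: dict          # tumor_id -> (normal_tiles, tumor_tiles)
    alleles: dict        # tumor_id -> (normal_alleles, tumor_alleles)
    variants: dict       # tumor_id -> (somatic, germline)
    expression: ExpressionMatrix
    clinical: pd.DataFrame

    @property
    def tumor_ids(self) -> list[str]:
        return [t.tumor_id for t in self.truths]


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Simulate the full cohort described by ``config`` (deterministic in seed)."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = build_genome(config.n_chromosomes, config.chrom_length,
                          config.tile_size, config.snps_per_chrom,
                          config.genes_per_chrom, seed=config.seed)
    blacklist = make_blacklist(genome, rng)
    truths: list[KaryotypeTruth] = []
    labels = [1] * config.n_group1 + [2] * config.n_group2 + [3] * config.n_group3
    for i, group in enumerate(labels):
        truths.append(simulate_karyotype(group, config, rng,
                                         tumor_id=f"T{i + 1:03d}"))
    tiles, alleles, variants = {}, {}, {}
    for truth in truths:
        nt, tt, na, ta = simulate_counts(genome, truth, config, rng)
        tiles[truth.tumor_id] = (nt, tt)
        alleles[truth.tumor_id] = (na, ta)
        variants[truth.tumor_id] = simulate_variants(genome, truth, config, rng,
                                                     blacklist)
    expression = simulate_expression(genome, truths, config, rng)
    clinical = simulate_clinical(truths, rng)
    return SimulatedCohort(config=config, genome=genome, truths=truths,
                           blacklist=blacklist, tiles=tiles, alleles=alleles,
                           variants=variants, expression=expression,
                           clinical=clinical)
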