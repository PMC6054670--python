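"""Readers/writers for the package's plain-text interchange formats.

Tile tracks are BED-like TSV (``chrom, start, end, count``; 0-based
half-open).  Allele counts travel as 6-column TSV
(``chrom, pos, ref, alt, ref_count, alt_count``; 1-based) or as minimal
VCF with per-sample ``AD`` allelic depths.  Variant tables, expression
matrices, karyotypes and clinical tables are TSV; truth and reports are
JSON; configs are YAML.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allelic import ALLELE_COLUMNS
from .expression import ExpressionMatrix
from .simulate import KaryotypeTruth, SimConfig, SimulatedCohort


# ---------------------------------------------------------------- TSV / BED

def read_tile_track(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = ["chrom", "start", "end", "count"]
    if not set(need) <= set(df.columns):
        raise ValueError(f"tile track {path} must have columns {need}")
    return df[need]


def write_tile_track(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], usecols=[0, 1, 2])
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def read_allele_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not set(ALLELE_COLUMNS) <= set(df.columns):
        raise ValueError(f"allele table {path} must have columns {ALLELE_COLUMNS}")
    return df


def write_allele_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------- VCF

def write_minimal_vcf(df: pd.DataFrame, path, sample: str = "SAMPLE",
                      contigs: list[tuple[str, int]] | None = None) -> None:
    """Write an allele-count table as a minimal VCF with an AD FORMAT field."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs or []:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref, alt)">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    for _, r in df.iterrows():
        lines.append(f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}"
                     f"\t.\t.\t.\tAD\t{int(r['ref_count'])},{int(r['alt_count'])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_minimal_vcf(path) -> pd.DataFrame:
    """Read a single-sample VCF with AD depths into an allele-count table.

    Multi-allelic records keep the first ALT only (with a warning).
    """
    from cyvcf2 import VCF

    rows = []
    multi = 0
    vcf = VCF(str(path))
    for v in vcf:
        if len(v.ALT) > 1:
            multi += 1
        ad = v.format("AD")[0]
        rows.append({"chrom": v.CHROM, "pos": v.POS, "ref": v.REF,
                     "alt": v.ALT[0] if v.ALT else ".",
                     "ref_count": int(ad[0]), "alt_count": int(ad[1])})
    vcf.close()
    if multi:
        warnings.warn(f"{multi} multi-allelic records; kept first ALT only",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=ALLELE_COLUMNS)


def write_variant_vcf(df: pd.DataFrame, path,
                      contigs: list[tuple[str, int]] | None = None) -> None:
    """Write a variant table as a two-sample (TUMOR, NORMAL) VCF with AD depths."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs or []:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">')
    lines.append('##INFO=<ID=EFFECT,Number=1,Type=String,'
                 'Description="Coding effect class">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref, alt)">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL")
    for _, r in df.iterrows():
        info = f"GENE={r.get('gene', '.')};EFFECT={r.get('effect', '.')}"
        lines.append(
            f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\t.\t{info}"
            f"\tAD\t{int(r['t_ref'])},{int(r['t_alt'])}"
            f"\t{int(r['n_ref'])},{int(r['n_alt'])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_variant_vcf(path) -> pd.DataFrame:
    """Read a two-sample (TUMOR, NORMAL) VCF with AD depths into a variant table."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ti = samples.index("TUMOR") if "TUMOR" in samples else 0
    ni = samples.index("NORMAL") if "NORMAL" in samples else len(samples) - 1
    rows = []
    for v in vcf:
        ad = v.format("AD")
        gene = v.INFO.get("GENE") or "."
        effect = v.INFO.get("EFFECT") or "."
        rows.append({
            "chrom": v.CHROM, "pos": v.POS, "ref": v.REF,
            "alt": v.ALT[0] if v.ALT else ".",
            "gene": gene, "effect": effect,
            "t_ref": int(ad[ti][0]), "t_alt": int(ad[ti][1]),
            "n_ref": int(ad[ni][0]), "n_alt": int(ad[ni][1]),
            "origin": "somatic",
        })
    vcf.close()
    return pd.DataFrame(rows)


# --------------------------------------------------------------- expression

def write_expression(matrix: ExpressionMatrix, path) -> None:
    info = matrix.gene_info.loc[matrix.values.index]
    out = pd.concat([info.reset_index().rename(columns={"index": "gene_id"}),
                     matrix.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)
    Path(str(path) + ".batches").write_text(
        "\n".join(f"{s}\t{b}" for s, b in matrix.batches.items()) + "\n")


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    info = df[["gene_id", "chrom", "start", "end"]].set_index("gene_id")
    values = df.drop(columns=["chrom", "start", "end"]).set_index("gene_id")
    batch_path = Path(str(path) + ".batches")
    pairs = [ln.split("\t") for ln in batch_path.read_text().splitlines() if ln]
    batches = pd.Series({s: b for s, b in pairs})
    return ExpressionMatrix(values=values, gene_info=info, batches=batches)


# ------------------------------------------------------------ truth / config

def _truth_to_dict(t: KaryotypeTruth) -> dict:
    return {
        "tumor_id": t.tumor_id,
        "chrom_states": {c: [int(cn), bool(loh)]
                         for c, (cn, loh) in t.chrom_states.items()},
        "segments": {c: [[int(s), int(e), int(cn), bool(loh)]
                         for s, e, cn, loh in segs]
                     for c, segs in t.segments.items()},
        "purity": float(t.purity),
        "men1_somatic": bool(t.men1_somatic),
        "group_label": int(t.group_label),
    }


def write_truth(truths: list[KaryotypeTruth], path) -> None:
    Path(path).write_text(json.dumps([_truth_to_dict(t) for t in truths], indent=1))


def read_truth(path) -> list[KaryotypeTruth]:
    raw = json.loads(Path(path).read_text())
    out = []
    for d in raw:
        out.append(KaryotypeTruth(
            tumor_id=d["tumor_id"],
            chrom_states={c: (int(cn), bool(loh))
                          for c, (cn, loh) in d["chrom_states"].items()},
            segments={c: [tuple(seg) for seg in segs]
                      for c, segs in d.get("segments", {}).items()},
            purity=float(d["purity"]),
            men1_somatic=bool(d["men1_somatic"]),
            group_label=int(d["group_label"]),
        ))
    return out


def write_sim_config(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def read_sim_config(path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "purity_range" in raw:
        raw["purity_range"] = tuple(raw["purity_range"])
    return SimConfig(**raw)


# ------------------------------------------------------------- cohort on disk

def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write a simulated cohort to a directory of plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_sim_config(cohort.config, out / "config.yaml")
    write_truth(cohort.truths, out / "truth.json")
    write_bed(cohort.blacklist, out / "blacklist.bed")
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    write_expression(cohort.expression, out / "expression.tsv")
    contigs = list(cohort.genome.chromosomes)
    for tid in cohort.tumor_ids:
        nt, tt = cohort.tiles[tid]
        write_tile_track(nt, out / f"{tid}.normal.tiles.tsv")
        write_tile_track(tt, out / f"{tid}.tumor.tiles.tsv")
        na, ta = cohort.alleles[tid]
        write_allele_table(na[ALLELE_COLUMNS], out / f"{tid}.normal.alleles.tsv")
        write_allele_table(ta[ALLELE_COLUMNS], out / f"{tid}.tumor.alleles.tsv")
        som, germ = cohort.variants[tid]
        som.to_csv(out / f"{tid}.somatic.tsv", sep="\t", index=False)
        germ.to_csv(out / f"{tid}.germline.tsv", sep="\t", index=False)
        write_minimal_vcf(na, out / f"{tid}.normal.vcf", sample=f"{tid}N",
                          contigs=contigs)


def read_cohort_inputs(indir) -> dict:
    """Load the per-tumor analysis inputs written by :func:`write_cohort`."""
    ind = Path(indir)
    config = read_sim_config(ind / "config.yaml")
    truths = read_truth(ind / "truth.json") if (ind / "truth.json").exists() else None
    blacklist = read_bed(ind / "blacklist.bed") if (ind / "blacklist.bed").exists() else None
    clinical = (pd.read_csv(ind / "clinical.tsv", sep="\t")
                if (ind / "clinical.tsv").exists() else None)
    expression = (read_expression(ind / "expression.tsv")
                  if (ind / "expression.tsv").exists() else None)
    tumor_ids = sorted({p.name.split(".")[0] for p in ind.glob("*.tumor.tiles.tsv")})
    data = {}
    for tid in tumor_ids:
        data[tid] = {
            "normal_tiles": read_tile_track(ind / f"{tid}.normal.tiles.tsv"),
            "tumor_tiles": read_tile_track(ind / f"{tid}.tumor.tiles.tsv"),
            "normal_alleles": read_allele_table(ind / f"{tid}.normal.alleles.tsv"),
            "tumor_alleles": read_allele_table(ind / f"{tid}.tumor.alleles.tsv"),
            "somatic": pd.read_csv(ind / f"{tid}.somatic.tsv", sep="\t"),
            "germline": pd.read_csv(ind / f"{tid}.germline.tsv", sep="\t"),
        }
    return {"config": config, "truths": truths, "blacklist": blacklist,
            "clinical": clinical, "expression": expression, "tumors": data}


def load_cohort(indir) -> SimulatedCohort:
    """Reassemble a :class:`SimulatedCohort` from a directory on disk.

    The genome scaffold is rebuilt deterministically from the stored
    config, so coordinates match the original simulation exactly.
    """
    from .genome import build_genome

    inputs = read_cohort_inputs(indir)
    cfg = inputs["config"]
    genome = build_genome(cfg.n_chromosomes, cfg.chrom_length, cfg.tile_size,
                          cfg.snps_per_chrom, cfg.genes_per_chrom, seed=cfg.seed)
    tiles = {tid: (d["normal_tiles"], d["tumor_tiles"])
             for tid, d in inputs["tumors"].items()}
    alleles = {tid: (d["normal_alleles"], d["tumor_alleles"])
               for tid, d in inputs["tumors"].items()}
    variants = {tid: (d["somatic"], d["germline"])
                for tid, d in inputs["tumors"].items()}
    return SimulatedCohort(config=cfg, genome=genome,
                           truths=inputs["truths"] or [],
                           blacklist=inputs["blacklist"],
                           tiles=tiles, alleles=alleles, variants=variants,
                           expression=inputs["expression"],
                           clinical=inputs["clinical"])


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return str(o)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, cls=_ReportEncoder))
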