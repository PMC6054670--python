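"""Coordinate scaffold shared by every analysis stage.

A :class:`GenomeModel` fixes the chromosome set, the tiling used for read
counting, the SNP positions interrogated for allelic analysis, and the gene
annotation used for expression aggregation.  All downstream coordinates are
relative to this model, so real genome tracks (e.g. hg19 tiles) load the
same way as the desk-scale synthetic genome built by :func:`build_genome`.

Conventions: tiles are 0-based half-open (BED); SNP and variant positions
are 1-based (VCF); gene intervals are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Invalid configuration or model parameters."""


#: The ten chromosomes recurrently affected by LoH in the high-LoH tumor group.
RECURRENT_LOH_CHROMS: tuple[str, ...] = (
    "chr1", "chr2", "chr3", "chr6", "chr8",
    "chr10", "chr11", "chr16", "chr21", "chr22",
)

MEN1_CHROM = "chr11"


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome/tile/SNP/gene coordinate frame.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs; names must be unique.
    tile_size
        Width in bp of the read-counting tiles (last tile of a chromosome
        may be shorter).
    snp_positions
        Per-chromosome sorted 1-based positions of candidate SNP sites.
    genes
        DataFrame with columns ``gene_id, chrom, start, end`` (1-based
        inclusive); every gene lies on exactly one chromosome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    tile_size: int = 3000
    snp_positions: Mapping[str, np.ndarray] = field(default_factory=dict)
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end"]))

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigError("chromosome names must be unique")
        if self.tile_size <= 0:
            raise ConfigError("tile_size must be positive")
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigError(f"chromosome {name} has non-positive length")
        for chrom, pos in self.snp_positions.items():
            if chrom not in lengths:
                raise ConfigError(f"SNP positions on unknown chromosome {chrom}")
            pos = np.asarray(pos)
            if pos.size and (pos.min() < 1 or pos.max() > lengths[chrom]):
                raise ConfigError(f"SNP position outside chromosome {chrom}")
            if np.any(np.diff(pos) <= 0):
                raise ConfigError(f"SNP positions on {chrom} not strictly sorted")
        if len(self.genes):
            bad = ~self.genes["chrom"].isin(lengths)
            if bad.any():
                raise ConfigError("gene on unknown chromosome")
            if not self.genes["gene_id"].is_unique:
                raise ConfigError("gene ids must be unique")

    @property
    def chrom_names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def n_tiles(self, chrom: str) -> int:
        length = self.lengths[chrom]
        return -(-length // self.tile_size)  # ceil division

    def tile_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """0-based half-open (starts, ends) arrays for one chromosome."""
        length = self.lengths[chrom]
        starts = np.arange(0, length, self.tile_size, dtype=np.int64)
        ends = np.minimum(starts + self.tile_size, length)
        return starts, ends

    def tile_frame(self) -> pd.DataFrame:
        """All tiles as a ``chrom, start, end`` DataFrame in model order."""
        parts = []
        for chrom in self.chrom_names:
            starts, ends = self.tile_bounds(chrom)
            parts.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(parts, ignore_index=True)

    def gene_midpoints(self) -> pd.DataFrame:
        """Genes with their midpoint position, used for tile/segment assignment."""
        g = self.genes.copy()
        g["midpoint"] = (g["start"] + g["end"]) // 2
        return g


def build_genome(
    n_chromosomes: int = 22,
    chrom_length: int = 3_000_000,
    tile_size: int = 3000,
    snps_per_chrom: int = 200,
    genes_per_chrom: int = 50,
    seed: int = 0,
) -> GenomeModel:
    """Build a deterministic desk-scale genome model.

    Defaults give 22 autosomes of 3 Mb (1000 tiles of 3 kb each), 200
    candidate SNP positions and 50 genes per chromosome.  SNP positions are
    drawn uniformly (without replacement) from a seeded generator; genes are
    placed deterministically on an even grid.  One gene on chr11 is named
    ``MEN1`` so simulated tumor-suppressor hits have a stable anchor.
    """
    if min(n_chromosomes, chrom_length, tile_size, snps_per_chrom, genes_per_chrom) <= 0:
        raise ConfigError("all genome sizes must be positive")
    rng = np.random.default_rng(seed)
    chroms = tuple((f"chr{i + 1}", int(chrom_length)) for i in range(n_chromosomes))
    snp_positions = {}
    for name, length in chroms:
        pos = rng.choice(np.arange(1, length + 1), size=min(snps_per_chrom, length),
                         replace=False)
        snp_positions[name] = np.sort(pos)
    rows = []
    for name, length in chroms:
        pitch = length // genes_per_chrom
        for i in range(genes_per_chrom):
            start = i * pitch + pitch // 5 + 1
            end = min((i + 1) * pitch - pitch // 5, length)
            gene_id = f"{name}_g{i:03d}"
            rows.append((gene_id, name, start, end))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    if MEN1_CHROM in dict(chroms) and genes_per_chrom > 24:
        idx = genes.index[(genes["chrom"] == MEN1_CHROM)][24]
        genes.loc[idx, "gene_id"] = "MEN1"
    return GenomeModel(chromosomes=chroms, tile_size=tile_size,
                       snp_positions=snp_positions, genes=genes)
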