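"""Synthetic genome model: chromosomes, probe maps, arm boundaries and gene loci.

The coordinate system is deliberately fabricated (round chromosome lengths,
fixed fractional gene positions) so that no real genomic coordinate is baked
into the package.  Real annotation (hg19 BED files) can be substituted at any
entry point that accepts gene or CNV intervals.

Conventions: probe positions are 1-based; all stored intervals are 0-based
half-open (BED-compatible); reports render 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a simulation or calling configuration is invalid."""


#: Synthetic chromosome lengths in bp (round numbers, decreasing magnitude).
DEFAULT_CHROMOSOMES: dict[str, int] = {
    "chr1": 240_000_000, "chr2": 235_000_000, "chr3": 195_000_000,
    "chr4": 190_000_000, "chr5": 180_000_000, "chr6": 170_000_000,
    "chr7": 160_000_000, "chr8": 145_000_000, "chr9": 140_000_000,
    "chr10": 135_000_000, "chr11": 134_000_000, "chr12": 132_000_000,
    "chr13": 115_000_000, "chr14": 107_000_000, "chr15": 100_000_000,
    "chr16": 90_000_000, "chr17": 83_000_000, "chr18": 80_000_000,
    "chr19": 60_000_000, "chr20": 64_000_000, "chr21": 48_000_000,
    "chr22": 50_000_000, "chrX": 155_000_000, "chrY": 57_000_000,
}

#: Acrocentric chromosomes get a short p arm; everything else a 0.4 centromere.
_ACROCENTRIC = {"chr13", "chr14", "chr15", "chr21", "chr22"}
_CENTROMERE_FRACTION = 0.4
_ACRO_CENTROMERE_FRACTION = 0.15

#: Gene loci as (chromosome, fractional midpoint).  The panel genes recurrently
#: mutated in MDS/CMML sit on their canonical chromosome arms; the chr13 set
#: covers the region recurrently shattered by chromothripsis.
GENE_LOCI: dict[str, tuple[str, float]] = {
    "DNMT3A": ("chr2", 0.10),   # 2p
    "TET2": ("chr4", 0.55),     # 4q
    "SF3B1": ("chr2", 0.85),
    "TP53": ("chr17", 0.10),    # 17p
    "RUNX1": ("chr21", 0.75),   # 21q
    "BCOR": ("chrX", 0.25),     # Xp
    "XPO4": ("chr13", 0.25),
    "FLT3": ("chr13", 0.30),
    "FLT1": ("chr13", 0.35),
    "BRCA2": ("chr13", 0.45),
    "RB1": ("chr13", 0.60),
    "EZH2": ("chr7", 0.90),
    "CUX1": ("chr7", 0.65),
    "SPARC": ("chr5", 0.80),
    "U2AF1": ("chr21", 0.92),
}

GENE_SIZE_BP = 200_000

#: Genes screened by the targeted sequencing panel (deletion follow-up).
PANEL_GENES = ("DNMT3A", "TET2", "RUNX1", "TP53", "BCOR")


@dataclass(frozen=True)
class GeneInterval:
    name: str
    chromosome: str
    start: int  # 0-based half-open
    end: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GenomeModel:
    """Ordered chromosomes with probe maps, arm boundaries and gene annotation."""

    chromosomes: list[str]
    lengths: dict[str, int]
    probes: dict[str, np.ndarray]  # 1-based positions, strictly increasing
    genes: list[GeneInterval] = field(default_factory=list)
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            if self.lengths[chrom] <= 0:
                raise ConfigurationError(f"zero-length chromosome {chrom!r}")
            pos = self.probes.get(chrom)
            if pos is not None and len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ConfigurationError(
                    f"probe positions not strictly increasing on {chrom}")
        for gene in self.genes:
            if not (0 <= gene.start < gene.end <= self.lengths[gene.chromosome]):
                raise ConfigurationError(
                    f"gene {gene.name} outside chromosome bounds")

    def arm_interval(self, chromosome: str, arm: str) -> tuple[int, int]:
        """0-based half-open interval of a chromosome arm ('p' or 'q')."""
        length = self.lengths[chromosome]
        cen = self.centromeres.get(chromosome, int(length * _CENTROMERE_FRACTION))
        if arm == "p":
            return (0, cen)
        if arm == "q":
            return (cen, length)
        raise ValueError(f"unknown arm {arm!r}")

    def genes_on(self, chromosome: str) -> list[GeneInterval]:
        return [g for g in self.genes if g.chromosome == chromosome]

    def gene(self, name: str) -> GeneInterval:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"unknown gene {name!r}")

    def probes_in(self, chromosome: str, start: int, end: int) -> np.ndarray:
        """Indices of probes whose 1-based position falls in [start, end) (0-based)."""
        pos = self.probes[chromosome]
        return np.flatnonzero((pos - 1 >= start) & (pos - 1 < end))

    def to_dict(self) -> dict:
        return {
            "chromosomes": self.chromosomes,
            "lengths": self.lengths,
            "probes": {c: self.probes[c].tolist() for c in self.chromosomes},
            "centromeres": self.centromeres,
            "genes": [
                {"name": g.name, "chromosome": g.chromosome,
                 "start": g.start, "end": g.end}
                for g in self.genes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeModel":
        return cls(
            chromosomes=list(d["chromosomes"]),
            lengths={k: int(v) for k, v in d["lengths"].items()},
            probes={k: np.asarray(v, dtype=np.int64) for k, v in d["probes"].items()},
            genes=[GeneInterval(**g) for g in d.get("genes", [])],
            centromeres={k: int(v) for k, v in d.get("centromeres", {}).items()},
        )


def allocate_probes(lengths: Mapping[str, int], probe_count: int) -> dict[str, int]:
    """Distribute `probe_count` probes proportionally to chromosome length.

    Largest-remainder apportionment: counts are exact (sum to `probe_count`)
    and deterministic.
    """
    chroms = list(lengths)
    total = sum(lengths.values())
    if total <= 0:
        raise ConfigurationError("total genome length must be positive")
    quotas = np.array([lengths[c] * probe_count / total for c in chroms])
    counts = np.floor(quotas).astype(int)
    remainder = probe_count - counts.sum()
    # ties broken by chromosome order for determinism
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return dict(zip(chroms, counts.tolist()))


def build_genome_model(
    config=None,
    *,
    probe_count: int | None = None,
    chromosomes: Mapping[str, int] | None = None,
    with_genes: bool = True,
) -> GenomeModel:
    """Fabricate a genome model with evenly spaced probes.

    Accepts either a :class:`~karyoshatter.simulate.SimulationConfig` (its
    ``probe_count`` is used) or an explicit ``probe_count``.  Probe positions
    are deterministic: the i-th probe on a chromosome of length L with n
    probes sits at round((i + 0.5) * L / n), 1-based.
    """
    if probe_count is None:
        if config is None:
            raise ConfigurationError("need a config or an explicit probe_count")
        probe_count = config.probe_count
    lengths = dict(chromosomes) if chromosomes is not None else dict(DEFAULT_CHROMOSOMES)
    for name, length in lengths.items():
        if length <= 0:
            raise ConfigurationError(f"zero-length chromosome {name!r}")
    if probe_count < 2 * len(lengths):
        raise ConfigurationError(
            f"probe_count {probe_count} < 2 per chromosome ({len(lengths)} chromosomes)")
    counts = allocate_probes(lengths, probe_count)
    probes: dict[str, np.ndarray] = {}
    for name, length in lengths.items():
        n = counts[name]
        pos = np.rint((np.arange(n) + 0.5) * length / n).astype(np.int64)
        pos = np.maximum(pos, 1)
        # enforce strict monotonicity for pathological densities
        if n > 1:
            fix = np.where(np.diff(pos) <= 0)[0]
            for i in fix:
                pos[i + 1] = pos[i] + 1
        probes[name] = pos

    genes: list[GeneInterval] = []
    if with_genes:
        for gname, (chrom, frac) in GENE_LOCI.items():
            if chrom not in lengths:
                continue
            mid = int(lengths[chrom] * frac)
            start = max(0, mid - GENE_SIZE_BP // 2)
            genes.append(GeneInterval(gname, chrom, start,
                                      min(start + GENE_SIZE_BP, lengths[chrom])))

    centromeres = {
        name: int(length * (_ACRO_CENTROMERE_FRACTION if name in _ACROCENTRIC
                            else _CENTROMERE_FRACTION))
        for name, length in lengths.items()
    }
    return GenomeModel(
        chromosomes=list(lengths),
        lengths=lengths,
        probes=probes,
        genes=genes,
        centromeres=centromeres,
    )


def overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap in bp between two 0-based half-open intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
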