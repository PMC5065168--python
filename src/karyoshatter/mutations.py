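"""Targeted-sequencing variant tables: scoring filters, zygosity, biallelic status.

Variant tables carry one row per mutation with sample, gene, cDNA change,
protein change, mutation type, variant allele frequency (VAF, percent of
reads) and an optional COSMIC identifier.  VAF separates heterozygous
mutations (~50%) from homozygous-or-hemizygous ones (near 100%); VAF alone
cannot distinguish true homozygosity from a hemizygous mutation on the
single allele remaining after deletion, so those are one class and the
distinction is surfaced through :func:`biallelic_status` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import CNACall, LOSS
from .genome import GeneInterval, overlap_bp

MUTATION_TYPES = frozenset(
    {"missense", "nonsense", "frameshift", "synonymous", "intronic", "SNP"})

HETEROZYGOUS = "heterozygous"
HOMOZYGOUS_OR_HEMIZYGOUS = "homozygous_or_hemizygous"

#: canonical column order of the on-disk variant table
COLUMNS = ("sample", "gene", "cdna_change", "protein_change",
           "mutation_type", "vaf", "cosmic_id")

#: accepted header aliases (publication-style tables)
_ALIASES = {
    "sample id": "sample",
    "nucleotide change": "cdna_change",
    "mutation type": "mutation_type",
    "aa change": "protein_change",
    "vaf (%)": "vaf",
    "cosmic id": "cosmic_id",
}


@dataclass(frozen=True)
class MutationRecord:
    sample: str
    gene: str
    cdna_change: str
    protein_change: str
    mutation_type: str
    vaf: float  # percent
    cosmic_id: str | None = None

    def __post_init__(self) -> None:
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.mutation_type!r}")
        if not (0.0 <= self.vaf <= 100.0):
            raise ValueError(f"VAF {self.vaf} outside [0, 100]")


@dataclass(frozen=True)
class ZygosityCall:
    record: MutationRecord
    zygosity: str  # HETEROZYGOUS | HOMOZYGOUS_OR_HEMIZYGOUS


@dataclass(frozen=True)
class BiallelicStatus:
    patient: str
    gene: str
    category: str  # deletion_plus_mutation | deletion_only | mutation_only | wild_type


@dataclass(frozen=True)
class MinimalDeletedRegion:
    """Genomic intersection of overlapping deletions across patients."""

    label: str
    chromosome: str
    start: int
    end: int
    n_supporting_patients: int

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    @property
    def size_kb(self) -> float:
        return self.size_bp / 1e3


def load_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a tab-delimited variant table into records, validating each row."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [_ALIASES.get(c.strip().lower(), c.strip().lower())
                  for c in df.columns]
    missing = [c for c in COLUMNS if c not in df.columns and c != "cosmic_id"]
    if missing:
        raise ValueError(f"mutation table {path} missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            vaf = float(getattr(row, "vaf"))
            records.append(MutationRecord(
                sample=getattr(row, "sample"),
                gene=getattr(row, "gene"),
                cdna_change=getattr(row, "cdna_change"),
                protein_change=getattr(row, "protein_change"),
                mutation_type=getattr(row, "mutation_type"),
                vaf=vaf,
                cosmic_id=(getattr(row, "cosmic_id", "") or None),
            ))
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return records


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.sample, r.gene, r.cdna_change, r.protein_change,
          r.mutation_type, r.vaf, r.cosmic_id or "") for r in records],
        columns=list(COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def filter_scored_variants(
    records: Iterable[MutationRecord],
    known_snp_ids: Iterable[str] = (),
) -> list[MutationRecord]:
    """Drop variants that are not scored: intronic changes and known SNPs.

    A record is a known SNP when its COSMIC/identifier field, its cDNA
    change, or its explicit ``SNP`` type matches the exclusion list.
    Idempotent.
    """
    snp_ids = set(known_snp_ids)
    return [
        r for r in records
        if r.mutation_type not in ("intronic", "SNP")
        and (r.cosmic_id or "") not in snp_ids
        and r.cdna_change not in snp_ids
    ]


def classify_zygosity(record: MutationRecord, hom_vaf_threshold: float = 80.0
                      ) -> ZygosityCall:
    """Classify by VAF: >= threshold (inclusive) is homozygous-or-hemizygous.

    The default of 80% sits between the observed heterozygous (40–55%) and
    homozygous/hemizygous (>89%) VAF clusters in targeted myeloid panels.
    """
    zyg = (HOMOZYGOUS_OR_HEMIZYGOUS if record.vaf >= hom_vaf_threshold
           else HETEROZYGOUS)
    return ZygosityCall(record=record, zygosity=zyg)


def biallelic_status(
    patient: str,
    gene: str,
    loss_calls: Sequence[CNACall],
    zygosity_calls: Sequence[ZygosityCall],
    gene_intervals: Mapping[str, GeneInterval],
) -> BiallelicStatus:
    """Combine deletion calls and retained mutations into biallelic status.

    ``deletion_plus_mutation`` means one allele is lost and the other carries
    a mutation — biallelic inactivation of the gene.
    """
    if gene not in gene_intervals:
        raise KeyError(f"unknown gene {gene!r}")
    gi = gene_intervals[gene]
    deleted = any(
        c.direction == LOSS and c.chromosome == gi.chromosome
        and overlap_bp(c.interval, gi.interval) > 0
        for c in loss_calls)
    mutated = any(z.record.gene == gene and z.record.sample == patient
                  for z in zygosity_calls)
    if deleted and mutated:
        category = "deletion_plus_mutation"
    elif deleted:
        category = "deletion_only"
    elif mutated:
        category = "mutation_only"
    else:
        category = "wild_type"
    return BiallelicStatus(patient=patient, gene=gene, category=category)


def minimal_deleted_region(
    label: str,
    deletions: Sequence[tuple[str, tuple[int, int]]],
) -> MinimalDeletedRegion | None:
    """Intersect deletions at one locus across patients.

    ``deletions`` is a list of (chromosome, (start, end)) intervals, 0-based
    half-open, all on one chromosome.  Returns ``None`` when the common
    intersection is empty (never a zero-length interval).
    """
    if not deletions:
        raise ValueError("need at least one deletion")
    chroms = {c for c, _ in deletions}
    if len(chroms) != 1:
        raise ValueError(f"deletions span multiple chromosomes: {sorted(chroms)}")
    start = max(iv[0] for _, iv in deletions)
    end = min(iv[1] for _, iv in deletions)
    if end <= start:
        return None
    return MinimalDeletedRegion(
        label=label,
        chromosome=next(iter(chroms)),
        start=start,
        end=end,
        n_supporting_patients=len(deletions),
    )
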