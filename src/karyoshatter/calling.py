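"""Copy-number aberration calling from segmented profiles.

Segments are thresholded on their mean log2 ratio into losses (copy state 1)
and gains (copy state 3); the diploid state 2 is never emitted as a call.
Calls are then annotated: germline-CNV overlap (reciprocal-overlap rule
against a catalogue of polymorphic regions, e.g. the Database of Genomic
Variants), the cryptic size class (small enough to escape banded metaphase
cytogenetics), and the sequencing-follow-up flag for sizeable deletions
hitting a panel gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .genome import GeneInterval, overlap_bp
from .segmentation import Segment

LOSS, GAIN = "loss", "gain"


@dataclass(frozen=True)
class CallingConfig:
    """Thresholds and rules for turning segments into CNA calls.

    The loss/gain thresholds sit midway between the diploid level (log2 = 0)
    and the single-copy levels (−1 and +0.585); both are inclusive.
    """

    loss_threshold: float = -0.25
    gain_threshold: float = 0.25
    min_probes: int = 5
    segmentation_penalty: float = 0.5
    cnv_overlap_fraction: float = 0.5
    cryptic_max: int = 5_000_000   # <= 5 Mb escapes conventional cytogenetics
    followup_min: int = 100_000    # deletions > 100 kb at panel genes get sequenced

    def __post_init__(self) -> None:
        if not (self.loss_threshold < 0 < self.gain_threshold):
            raise ValueError("need loss_threshold < 0 < gain_threshold")
        if not (0 < self.cnv_overlap_fraction <= 1):
            raise ValueError("cnv_overlap_fraction must be in (0, 1]")
        if self.min_probes < 1 or self.segmentation_penalty <= 0:
            raise ValueError("min_probes >= 1 and positive penalty required")
        if self.cryptic_max <= 0 or self.followup_min <= 0:
            raise ValueError("size bounds must be positive")


@dataclass(frozen=True)
class CNACall:
    """A called gain or loss with its copy state and annotation flags."""

    chromosome: str
    start: int   # 0-based half-open
    end: int
    mean_log2: float
    n_probes: int
    direction: str          # "loss" | "gain"
    copy_state: int         # 1 | 3
    cryptic: bool = False
    germline_cnv: bool = False
    followup: bool = False

    def __post_init__(self) -> None:
        if self.direction not in (LOSS, GAIN):
            raise ValueError(f"bad direction {self.direction!r}")
        if (self.direction == LOSS) != (self.copy_state == 1):
            raise ValueError("loss <=> copy_state 1; gain <=> copy_state 3")

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def segment_state(mean_log2: float, config: CallingConfig) -> int:
    """Map a segment mean to a copy state by the calling thresholds."""
    if mean_log2 <= config.loss_threshold:
        return 1
    if mean_log2 >= config.gain_threshold:
        return 3
    return 2


def call_cnas(segments: Sequence[Segment], config: CallingConfig) -> list[CNACall]:
    """Threshold segments into CNA calls, merging adjacent same-direction runs.

    Adjacent aberrant segments on the same chromosome merge into one call
    when no diploid segment lies between them; the merged mean is the
    probe-weighted mean of the members.
    """
    calls: list[CNACall] = []
    run: list[Segment] = []
    run_state = 2
    run_chrom = None

    def flush() -> None:
        nonlocal run
        if not run:
            return
        n = sum(s.n_probes for s in run)
        mean = sum(s.mean_log2 * s.n_probes for s in run) / n
        calls.append(CNACall(
            chromosome=run[0].chromosome,
            start=run[0].start,
            end=run[-1].end,
            mean_log2=mean,
            n_probes=n,
            direction=LOSS if run_state == 1 else GAIN,
            copy_state=run_state,
        ))
        run = []

    for seg in segments:
        state = segment_state(seg.mean_log2, config)
        if seg.chromosome != run_chrom or state != run_state:
            flush()
            run_chrom, run_state = seg.chromosome, state
        if state != 2:
            run.append(seg)
    flush()
    return [classify_cryptic(c, config) for c in calls]


def classify_cryptic(call: CNACall, config: CallingConfig) -> CNACall:
    """Flag calls small enough to be invisible to metaphase cytogenetics.

    The bound is inclusive: a call of exactly ``cryptic_max`` bp is cryptic.
    """
    return replace(call, cryptic=call.size_bp <= config.cryptic_max)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def filter_germline_cnv(
    calls: Iterable[CNACall],
    cnv_regions: dict[str, list[tuple[int, int]]],
    config: CallingConfig,
) -> list[CNACall]:
    """Flag calls matching catalogued germline copy-number variants.

    A call is germline when its reciprocal overlap with any CNV region on
    the same chromosome is at least ``cnv_overlap_fraction`` (the overlap
    must cover that fraction of *both* intervals).  Flagged calls stay in
    the returned list but are excluded from downstream somatic counts by
    :func:`retained`.  Idempotent.
    """
    out = []
    for call in calls:
        regions = cnv_regions.get(call.chromosome, [])
        hit = any(_reciprocal_overlap(call.interval, r) >= config.cnv_overlap_fraction
                  for r in regions)
        out.append(replace(call, germline_cnv=hit))
    return out


def retained(calls: Iterable[CNACall]) -> list[CNACall]:
    """Somatic calls: those not flagged as germline CNVs."""
    return [c for c in calls if not c.germline_cnv]


def select_for_sequencing(
    calls: Iterable[CNACall],
    panel_genes: Sequence[GeneInterval],
    config: CallingConfig,
) -> list[CNACall]:
    """Flag deletions warranting targeted sequencing of the remaining allele.

    A call is flagged when it is a loss, strictly larger than
    ``followup_min`` bp, and overlaps (>= 1 bp) a panel gene.
    """
    out = []
    for call in calls:
        hit = (
            call.direction == LOSS
            and call.size_bp > config.followup_min
            and any(g.chromosome == call.chromosome
                    and overlap_bp(call.interval, g.interval) > 0
                    for g in panel_genes)
        )
        out.append(replace(call, followup=hit))
    return out
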