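"""Chromothripsis detection from oscillating segmental copy-number states.

A chromosome is called chromothriptic when its segmented profile shows at
least ``min_switches`` changes of segmental copy number (run-length encoded
transitions between adjacent differing states), oscillating among at most
``max_states`` distinct states (1 = deletion, 2 = normal, 3 = gain), on that
single chromosome.  Shattering confined to one chromosome with rapid 1/2/3
oscillation is the copy-number signature of a one-step catastrophic
rearrangement, as opposed to the stepwise accumulation of independent CNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .calling import CallingConfig, segment_state
from .genome import GeneInterval, overlap_bp
from .segmentation import Segment


@dataclass(frozen=True)
class ChromothripsisConfig:
    min_switches: int = 10
    max_states: int = 3

    def __post_init__(self) -> None:
        if self.min_switches < 1:
            raise ValueError("min_switches must be >= 1")
        if self.max_states not in (2, 3):
            raise ValueError("max_states must be 2 or 3")


@dataclass(frozen=True)
class ChromothripsisCall:
    patient: str
    chromosome: str
    n_state_switches: int
    n_distinct_states: int
    positive: bool
    states: tuple[int, ...]


def assign_states(segments: Sequence[Segment], config: CallingConfig) -> list[int]:
    """Map ordered segments of one chromosome to copy states 1/2/3."""
    return [segment_state(s.mean_log2, config) for s in segments]


def run_length_encode(states: Sequence[int]) -> list[int]:
    out: list[int] = []
    for s in states:
        if not out or out[-1] != s:
            out.append(s)
    return out


def count_state_switches(states: Sequence[int]) -> int:
    """Number of changes of segmental copy number along a chromosome.

    Equals the run-length-encoded length minus one; 0 for empty or constant
    sequences.
    """
    rle = run_length_encode(states)
    return max(0, len(rle) - 1)


def evaluate_states(states: Sequence[int], config: ChromothripsisConfig
                    ) -> tuple[int, int, bool]:
    """Apply the oscillation criterion to an arbitrary copy-state sequence.

    Returns (n_switches, n_distinct_states, positive): positive requires at
    least ``min_switches`` transitions AND at most ``max_states`` distinct
    states — a profile wandering through more states reflects stepwise
    aberration accumulation rather than a single shattering event.
    """
    switches = count_state_switches(states)
    distinct = len(set(states))
    positive = switches >= config.min_switches and distinct <= config.max_states
    return switches, distinct, positive


def detect_chromothripsis(
    patient: str,
    segments_by_chromosome: Mapping[str, Sequence[Segment]],
    config: ChromothripsisConfig,
    calling_config: CallingConfig,
) -> list[ChromothripsisCall]:
    """Evaluate the oscillation criterion independently on each chromosome."""
    calls = []
    for chrom, segs in segments_by_chromosome.items():
        states = tuple(assign_states(segs, calling_config))
        switches, distinct, positive = evaluate_states(states, config)
        calls.append(ChromothripsisCall(
            patient=patient,
            chromosome=chrom,
            n_state_switches=switches,
            n_distinct_states=distinct,
            positive=positive,
            states=states,
        ))
    return calls


def affected_genes(
    segments: Sequence[Segment],
    genes: Sequence[GeneInterval],
    calling_config: CallingConfig,
) -> dict[str, set[int]]:
    """Per gene, the set of non-normal states of segments it overlaps."""
    out: dict[str, set[int]] = {}
    for gene in genes:
        states = {
            segment_state(s.mean_log2, calling_config)
            for s in segments
            if s.chromosome == gene.chromosome
            and overlap_bp((s.start, s.end), gene.interval) > 0
        }
        states.discard(2)
        if states:
            out[gene.name] = states
    return out


def shared_affected_genes(
    per_patient_segments: Mapping[str, Sequence[Segment]],
    genes: Sequence[GeneInterval],
    calling_config: CallingConfig,
) -> dict[str, str]:
    """Genes hit by a non-normal segment in *every* positive patient.

    Returns gene -> direction: "amplified" when every overlap in every
    patient is a gain, "deleted" when every overlap is a loss, else "mixed".
    """
    if not per_patient_segments:
        raise ValueError("need at least one positive patient")
    if not genes:
        raise ValueError("no gene annotation for the called chromosome")
    per_patient = [affected_genes(segs, genes, calling_config)
                   for segs in per_patient_segments.values()]
    common = set(per_patient[0])
    for hits in per_patient[1:]:
        common &= set(hits)
    result = {}
    for name in sorted(common):
        states = set().union(*(hits[name] for hits in per_patient))
        if states == {3}:
            result[name] = "amplified"
        elif states == {1}:
            result[name] = "deleted"
        else:
            result[name] = "mixed"
    return result
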