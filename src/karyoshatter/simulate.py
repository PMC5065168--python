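"""Synthetic aCGH cohorts with implanted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a whole-genome tiling probe map (~135k probes by default,
down-scalable), patients carrying large recurrent aberrations at
frequencies mirroring an MDS/CMML cohort, cryptic (few-Mb) deletions at
panel-gene loci, chromothripsis chromosomes with a controlled number of
copy-state switches, germline CNV regions, ISCN karyotype strings that
encode only the events large enough for banded metaphases to see, and
variant tables with binomially sampled allele frequencies.  Every implanted
event is recorded in a :class:`TruthRecord`, so recovery can be scored
exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .genome import (PANEL_GENES, ConfigurationError, GenomeModel,
                     build_genome_model)

MALE, FEMALE = "male", "female"

CRYPTIC_CLASS = "cryptic-at-gene"

#: default per-cohort implant fractions for the large recurrent aberration
#: classes (fractions of all patients, large classes scaled from their
#: observed share among aCGH-abnormal MDS/CMML patients)
DEFAULT_EVENT_FREQUENCIES: dict[str, float] = {
    "del(5q)": 0.083,
    "del(20q)": 0.043,
    "-Y": 0.033,
    "+8": 0.033,
    "del(7q)": 0.030,
    "+1q": 0.017,
    "del(17p)": 0.013,
    "del(11q)": 0.013,
    CRYPTIC_CLASS: 0.126,
}

#: class name -> (chromosome, scope, copy state); scope is "whole", "p" or "q"
EVENT_CLASS_DEFS: dict[str, tuple[str, str, int]] = {
    "del(5q)": ("chr5", "q", 1),
    "del(7q)": ("chr7", "q", 1),
    "del(20q)": ("chr20", "q", 1),
    "del(11q)": ("chr11", "q", 1),
    "del(17p)": ("chr17", "p", 1),
    "del(4q)": ("chr4", "q", 1),
    "del(12q)": ("chr12", "q", 1),
    "+8": ("chr8", "whole", 3),
    "-Y": ("chrY", "whole", 1),
    "+1q": ("chr1", "q", 3),
}

#: ISCN tokens for the named classes (pseudo-band text; parsed by arm letter)
_CLASS_TOKENS: dict[str, str] = {
    "del(5q)": "del(5)(q13q33)",
    "del(7q)": "del(7)(q22q36)",
    "del(20q)": "del(20)(q11q13)",
    "del(11q)": "del(11)(q14q23)",
    "del(17p)": "del(17)(p11p13)",
    "del(4q)": "del(4)(q24q31)",
    "del(12q)": "del(12)(q13q21)",
    "+8": "+8",
    "-Y": "-Y",
    "+1q": "dup(1)(q21q32)",
}

#: synthetic germline CNV catalogue: (chromosome, fractional start, size frac)
_CNV_CATALOGUE_LOCI = [
    ("chr3", 0.30, 0.015),
    ("chr6", 0.70, 0.015),
    ("chr9", 0.50, 0.015),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic cohort; the seed fully determines output."""

    n_patients: int = 301
    probe_count: int = 135_000
    noise_sd: float = 0.10
    chromothripsis_prevalence: float = 0.01
    event_frequency_table: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_FREQUENCIES))
    read_depth: int = 500
    seed: int = 0
    male_fraction: float = 0.635
    non_informative_fraction: float = 0.133
    germline_cnv_rate: float = 0.20
    other_allele_mutation_rate: float = 0.35
    karyotype_min_size: int = 10_000_000
    cryptic_event_size: int = 3_000_000
    chromothripsis_chromosome: str = "chr13"
    chromothripsis_switch_range: tuple[int, int] = (11, 18)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        fractions = {
            "chromothripsis_prevalence": self.chromothripsis_prevalence,
            "male_fraction": self.male_fraction,
            "non_informative_fraction": self.non_informative_fraction,
            "germline_cnv_rate": self.germline_cnv_rate,
            "other_allele_mutation_rate": self.other_allele_mutation_rate,
            **{f"frequency[{k}]": v for k, v in self.event_frequency_table.items()},
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} = {value} outside [0, 1]")
        if self.read_depth < 1:
            raise ConfigurationError("read_depth must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        # classes sharing a chromosome are mutually exclusive within a patient
        by_chrom: dict[str, float] = {}
        for name, frac in self.event_frequency_table.items():
            if name == CRYPTIC_CLASS:
                continue
            if name not in EVENT_CLASS_DEFS:
                raise ConfigurationError(f"unknown aberration class {name!r}")
            chrom = EVENT_CLASS_DEFS[name][0]
            by_chrom[chrom] = by_chrom.get(chrom, 0.0) + frac
        for chrom, total in by_chrom.items():
            if total > 1.0:
                raise ConfigurationError(
                    f"exclusive class fractions on {chrom} sum to {total} > 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["event_frequency_table"] = dict(self.event_frequency_table)
        d["chromothripsis_switch_range"] = list(self.chromothripsis_switch_range)
        return d


@dataclass(frozen=True)
class Event:
    """An implanted copy-number event (requested coordinates)."""

    chromosome: str
    start: int       # 0-based half-open
    end: int
    copy_state: int  # 1 | 2 | 3
    name: str = ""
    germline: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end <= start")
        if self.copy_state not in (1, 2, 3):
            raise ValueError(f"copy state {self.copy_state} not in {{1,2,3}}")


@dataclass(frozen=True)
class RealizedEvent:
    """An implanted event with the bp span of the probes it actually covers."""

    event: Event
    realized_start: int
    realized_end: int
    n_probes: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.realized_start, self.realized_end)


@dataclass
class TrueVariant:
    sample: str
    gene: str
    cdna_change: str
    protein_change: str
    mutation_type: str
    true_vaf: float
    zygosity: str
    cosmic_id: str = ""


@dataclass
class TruthRecord:
    patient: str
    sex: str
    events: list[RealizedEvent]
    switch_counts: dict[str, int]
    variants: list[TrueVariant]
    karyotype_status: str           # normal | abnormal | non_informative
    chromothripsis: bool = False
    chromothripsis_chromosome: str | None = None
    chromothripsis_switches: int = 0

    def somatic_events(self) -> list[RealizedEvent]:
        return [e for e in self.events
                if not e.event.germline and e.event.copy_state != 2]

    def to_dict(self) -> dict:
        return {
            "patient": self.patient,
            "sex": self.sex,
            "events": [
                {"chromosome": e.event.chromosome, "start": e.event.start,
                 "end": e.event.end, "copy_state": e.event.copy_state,
                 "name": e.event.name, "germline": e.event.germline,
                 "realized_start": e.realized_start,
                 "realized_end": e.realized_end, "n_probes": e.n_probes}
                for e in self.events
            ],
            "switch_counts": self.switch_counts,
            "variants": [dataclasses.asdict(v) for v in self.variants],
            "karyotype_status": self.karyotype_status,
            "chromothripsis": self.chromothripsis,
            "chromothripsis_chromosome": self.chromothripsis_chromosome,
            "chromothripsis_switches": self.chromothripsis_switches,
        }


def _run_length_switches(states: np.ndarray) -> int:
    if len(states) == 0:
        return 0
    return int(np.sum(states[1:] != states[:-1]))


def simulate_patient_profile(
    model: GenomeModel,
    events: Sequence[Event],
    noise_sd: float,
    seed: int | np.random.Generator,
    sex: str = MALE,
) -> tuple[pd.DataFrame, list[RealizedEvent], dict[str, int]]:
    """Render implanted events into a noisy probe-level log2-ratio table.

    Probe value = log2(state / 2) + N(0, noise_sd).  Returns the probe table,
    the probe-aligned realized events, and per-chromosome state-switch counts
    (run-length encoded over the probe state sequence).  Female patients emit
    no chrY probes (sex-matched reference).  Overlapping events on one
    chromosome are an error; every event must cover at least one probe.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_chrom: dict[str, list[Event]] = {}
    for ev in events:
        if ev.chromosome not in model.lengths:
            raise ConfigurationError(f"event on unknown chromosome {ev.chromosome!r}")
        by_chrom.setdefault(ev.chromosome, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs.sort(key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping events on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})")

    chroms = [c for c in model.chromosomes if not (sex == FEMALE and c == "chrY")]
    frames = []
    realized: list[RealizedEvent] = []
    switch_counts: dict[str, int] = {}
    for chrom in chroms:
        pos = model.probes[chrom]
        states = np.full(len(pos), 2, dtype=np.int8)
        for ev in by_chrom.get(chrom, []):
            idx = model.probes_in(chrom, ev.start, ev.end)
            if len(idx) == 0:
                raise ConfigurationError(
                    f"event {ev.name or ev.chromosome} [{ev.start},{ev.end}) "
                    "covers no probe")
            states[idx] = ev.copy_state
            realized.append(RealizedEvent(
                event=ev,
                realized_start=int(pos[idx[0]]) - 1,
                realized_end=int(pos[idx[-1]]),
                n_probes=len(idx),
            ))
        values = np.log2(states / 2.0)
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=len(pos))
        switch_counts[chrom] = _run_length_switches(states)
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos, "log2ratio": values}))
    table = pd.concat(frames, ignore_index=True)
    return table, realized, switch_counts


def simulate_chromothripsis_chromosome(
    model: GenomeModel,
    chromosome: str,
    n_switches: int,
    allowed_states: Sequence[int],
    seed: int | np.random.Generator,
    min_probes_per_segment: int = 20,
) -> list[Event]:
    """Shatter one chromosome into ``n_switches + 1`` oscillating segments.

    Adjacent segments always differ in state; states are drawn only from
    ``allowed_states``.  Returns one :class:`Event` per segment (including
    normal, state-2 segments) so the full oscillation pattern is explicit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_switches < 1:
        raise ValueError("n_switches must be >= 1")
    allowed = sorted(set(int(s) for s in allowed_states))
    if not set(allowed) <= {1, 2, 3} or len(allowed) < 2:
        raise ValueError("allowed_states must be >= 2 states from {1,2,3}")
    pos = model.probes[chromosome]
    k = n_switches + 1
    if k * min_probes_per_segment > len(pos):
        raise ConfigurationError(
            f"{k} segments x {min_probes_per_segment} probes exceed the "
            f"{len(pos)} probes on {chromosome}")
    extra = len(pos) - k * min_probes_per_segment
    lengths = np.full(k, min_probes_per_segment)
    lengths += rng.multinomial(extra, np.full(k, 1.0 / k))
    bounds = np.concatenate(([0], np.cumsum(lengths)))

    states = [int(rng.choice(allowed))]
    for _ in range(k - 1):
        choices = [s for s in allowed if s != states[-1]]
        states.append(int(rng.choice(choices)))

    events = []
    for i in range(k):
        lo, hi = bounds[i], bounds[i + 1]
        events.append(Event(
            chromosome=chromosome,
            start=int(pos[lo]) - 1,
            end=int(pos[hi - 1]),
            copy_state=states[i],
            name=f"chromothripsis_seg{i}",
        ))
    return events


def simulate_variant_table(
    variants: Sequence[TrueVariant],
    read_depth: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Binomially resample true VAFs at the given read depth.

    Observed VAF = 100 * Binomial(depth, true_vaf / 100) / depth, rounded to
    one decimal (reporting precision of clinical amplicon panels).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if read_depth < 1:
        raise ValueError("read_depth must be >= 1")
    rows = []
    for v in variants:
        alt = rng.binomial(read_depth, v.true_vaf / 100.0)
        vaf = round(100.0 * alt / read_depth, 1)
        rows.append((v.sample, v.gene, v.cdna_change, v.protein_change,
                     v.mutation_type, vaf, v.cosmic_id))
    return pd.DataFrame(rows, columns=[
        "sample", "gene", "cdna_change", "protein_change",
        "mutation_type", "vaf", "cosmic_id"])


def _stratified_pick(rng: np.random.Generator, candidates: np.ndarray,
                     fraction: float) -> np.ndarray:
    """Pick round(fraction * n) members without replacement (exact counts)."""
    n_pick = int(round(fraction * len(candidates)))
    if n_pick == 0:
        return np.array([], dtype=candidates.dtype)
    return rng.choice(candidates, size=min(n_pick, len(candidates)), replace=False)


def _class_event(name: str, model: GenomeModel) -> Event:
    chrom, scope, state = EVENT_CLASS_DEFS[name]
    if scope == "whole":
        start, end = 0, model.lengths[chrom]
    else:
        start, end = model.arm_interval(chrom, scope)
    return Event(chrom, start, end, state, name=name)


def _cryptic_event(gene_name: str, model: GenomeModel, size: int) -> Event:
    gene = model.gene(gene_name)
    mid = (gene.start + gene.end) // 2
    start = max(0, mid - size // 2)
    end = min(start + size, model.lengths[gene.chromosome])
    return Event(gene.chromosome, start, end, 1,
                 name=f"{CRYPTIC_CLASS}:{gene_name}")


def _overlaps_any(ev: Event, others: Sequence[Event]) -> bool:
    return any(o.chromosome == ev.chromosome
               and ev.start < o.end and o.start < ev.end for o in others)


_AA = ("Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
       "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val")


def _random_variant(rng: np.random.Generator, sample: str, gene: str,
                    true_vaf: float, zygosity: str) -> TrueVariant:
    bases = "ACGT"
    pos = int(rng.integers(100, 5000))
    ref, alt = rng.choice(list(bases), size=2, replace=False)
    mtype = str(rng.choice(["missense", "nonsense", "frameshift"],
                           p=[0.6, 0.25, 0.15]))
    aa = int(pos // 3) + 1
    if mtype == "missense":
        protein = f"p.{rng.choice(_AA)}{aa}{rng.choice(_AA)}"
    elif mtype == "nonsense":
        protein = f"p.{rng.choice(_AA)}{aa}*"
    else:
        protein = f"p.{rng.choice(_AA)}{aa}fs*{int(rng.integers(2, 40))}"
    cosmic = f"COSM{int(rng.integers(10_000, 999_999))}"
    return TrueVariant(sample, gene, f"c.{pos}{ref}>{alt}", protein, mtype,
                       true_vaf, zygosity, cosmic)


@dataclass
class Cohort:
    config: SimulationConfig
    model: GenomeModel
    truth: list[TruthRecord]
    probe_tables: dict[str, pd.DataFrame]
    karyotypes: list[tuple[str, str, int]]   # patient, iscn, n_metaphases
    mutation_table: pd.DataFrame
    cnv_regions: dict[str, list[tuple[int, int]]]
    snp_ids: list[str]

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        (out / "probes").mkdir(parents=True, exist_ok=True)
        io.write_json(self.config.to_dict(), out / "config.json")
        io.write_json(self.model.to_dict(), out / "genome.json")
        io.write_bed(
            ((g.chromosome, g.start, g.end, g.name) for g in self.model.genes),
            out / "genes.bed")
        io.write_bed(
            ((chrom, s, e, f"CNV_{chrom}_{i}")
             for chrom, ivs in sorted(self.cnv_regions.items())
             for i, (s, e) in enumerate(ivs)),
            out / "cnv_regions.bed")
        for pid, table in self.probe_tables.items():
            io.write_probe_table(table, out / "probes" / f"{pid}.tsv")
        io.write_karyotype_table(self.karyotypes, out / "karyotypes.tsv")
        self.mutation_table.to_csv(out / "mutations.tsv", sep="\t", index=False)
        (out / "snp_ids.txt").write_text(
            "".join(f"{s}\n" for s in self.snp_ids))
        io.write_json([t.to_dict() for t in self.truth], out / "truth.json")
        return out


def _iscn_token(ev: RealizedEvent, model: GenomeModel) -> str:
    """Render an implanted event as a simplified ISCN abnormality token."""
    name = ev.event.name
    if name in _CLASS_TOKENS:
        return _CLASS_TOKENS[name]
    chrom = ev.event.chromosome
    num = chrom.removeprefix("chr")
    length = model.lengths[chrom]
    if ev.event.end - ev.event.start >= 0.95 * length:
        if ev.event.copy_state == 3:
            return f"+{num}"
        return f"-{num}"
    cen = model.centromeres.get(chrom, length // 2)
    arm = "q" if ev.event.start >= cen else "p"
    band = f"{arm}11{arm}21"
    if ev.event.copy_state == 3:
        return f"dup({num})({band})"
    return f"del({num})({band})"


def _render_karyotype(
    truth: TruthRecord,
    model: GenomeModel,
    min_visible: int,
) -> str:
    """ISCN string encoding only the CC-visible (>= min_visible bp) events."""
    visible = [e for e in truth.somatic_events()
               if e.event.end - e.event.start >= min_visible]
    sex_chroms = "XY" if truth.sex == MALE else "XX"
    if not visible:
        return f"46,{sex_chroms}[20]"
    tokens, modal = [], 46
    for ev in visible:
        tok = _iscn_token(ev, model)
        if tok.startswith("+") and "(" not in tok:
            modal += 1
        elif tok.startswith("-"):
            modal -= 1
        if tok == "-Y":
            sex_chroms = "X"
        tokens.append(tok)
    abnormal_clone = ",".join([str(modal), sex_chroms, *tokens]) + "[15]"
    normal_sex = "XY" if truth.sex == MALE else "XX"
    return f"{abnormal_clone}/46,{normal_sex}[5]"


def simulate_cohort(config: SimulationConfig, out_dir: str | Path | None = None
                    ) -> Cohort:
    """Generate a full synthetic cohort; optionally write it to disk.

    Implant counts per aberration class are exact: round(fraction x n)
    patients per class, drawn without replacement, so class prevalences are
    reproducible and within binomial error of any i.i.d. scheme.
    """
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_patients + 2)
    rng = np.random.default_rng(child_seeds[0])
    model = build_genome_model(config)

    n = config.n_patients
    ids = np.array([f"P{i:04d}" for i in range(1, n + 1)])
    n_male = int(round(config.male_fraction * n))
    sexes = {pid: (MALE if i < n_male else FEMALE)
             for i, pid in enumerate(rng.permutation(ids))}

    # stratified class implantation (exact counts per class)
    assignments: dict[str, list[str]] = {pid: [] for pid in ids}
    for cls, frac in config.event_frequency_table.items():
        pool = ids if cls != "-Y" else np.array(
            [p for p in ids if sexes[p] == MALE])
        for pid in sorted(_stratified_pick(rng, pool, frac).tolist()):
            assignments[pid].append(cls)
    ct_patients = set(sorted(
        _stratified_pick(rng, ids, config.chromothripsis_prevalence).tolist()))
    germline_patients = set(sorted(
        _stratified_pick(rng, ids, config.germline_cnv_rate).tolist()))
    non_informative = set(sorted(
        _stratified_pick(rng, ids, config.non_informative_fraction).tolist()))

    # germline CNV catalogue (synthetic loci)
    cnv_regions: dict[str, list[tuple[int, int]]] = {}
    for chrom, frac, size_frac in _CNV_CATALOGUE_LOCI:
        length = model.lengths[chrom]
        start = int(length * frac)
        cnv_regions.setdefault(chrom, []).append(
            (start, start + int(length * size_frac)))
    cnv_list = [(c, iv) for c, ivs in cnv_regions.items() for iv in ivs]

    truth_records: list[TruthRecord] = []
    probe_tables: dict[str, pd.DataFrame] = {}
    karyotypes: list[tuple[str, str, int]] = []
    all_variants: list[TrueVariant] = []
    snp_ids = ["rs0000001", "rs0000002"]

    sw_lo, sw_hi = config.chromothripsis_switch_range
    for i, pid in enumerate(ids):
        pid = str(pid)
        prng = np.random.default_rng(child_seeds[i + 1])
        sex = sexes[pid]
        events: list[Event] = []
        for cls in assignments[pid]:
            if cls == CRYPTIC_CLASS:
                candidates = [g for g in PANEL_GENES
                              if not _overlaps_any(
                                  _cryptic_event(g, model,
                                                 config.cryptic_event_size),
                                  events)
                              and not (sex == FEMALE
                                       and model.gene(g).chromosome == "chrY")]
                if not candidates:
                    continue
                gene = str(prng.choice(candidates))
                events.append(_cryptic_event(gene, model,
                                             config.cryptic_event_size))
            else:
                ev = _class_event(cls, model)
                if not _overlaps_any(ev, events):
                    events.append(ev)
        ct_switches = 0
        if pid in ct_patients:
            ct_switches = int(prng.integers(sw_lo, sw_hi + 1))
            events = [e for e in events
                      if e.chromosome != config.chromothripsis_chromosome]
            events.extend(simulate_chromothripsis_chromosome(
                model, config.chromothripsis_chromosome, ct_switches,
                (1, 2, 3), prng))
        if pid in germline_patients:
            chrom, iv = cnv_list[int(prng.integers(len(cnv_list)))]
            ev = Event(chrom, iv[0], iv[1], 1, name="germline_cnv",
                       germline=True)
            if not _overlaps_any(ev, events):
                events.append(ev)

        table, realized, switches = simulate_patient_profile(
            model, events, config.noise_sd, prng, sex=sex)
        probe_tables[pid] = table

        # variants: chromothripsis cases carry TP53 mutations; a fraction of
        # cryptic-deletion carriers are mutated on the remaining allele
        variants: list[TrueVariant] = []
        if pid in ct_patients:
            if prng.random() < 1 / 3:
                variants.append(_random_variant(prng, pid, "TP53", 46.5,
                                                "heterozygous"))
                variants.append(_random_variant(prng, pid, "TP53", 43.5,
                                                "heterozygous"))
            else:
                variants.append(_random_variant(
                    prng, pid, "TP53", 93.5, "homozygous_or_hemizygous"))
        for ev in events:
            if ev.name.startswith(CRYPTIC_CLASS):
                gene = ev.name.split(":", 1)[1]
                if prng.random() < config.other_allele_mutation_rate:
                    if prng.random() < 0.5:
                        tv, zyg = 90.0, "homozygous_or_hemizygous"
                    else:
                        tv, zyg = 50.0, "heterozygous"
                    variants.append(_random_variant(prng, pid, gene, tv, zyg))
        if variants and prng.random() < 0.2:
            v = _random_variant(prng, pid, variants[0].gene, 49.0,
                                "heterozygous")
            v.mutation_type = "intronic"
            variants.append(v)
        if variants and prng.random() < 0.1:
            v = _random_variant(prng, pid, variants[0].gene, 51.0,
                                "heterozygous")
            v.cosmic_id = snp_ids[0]
            variants.append(v)
        all_variants.extend(variants)

        record = TruthRecord(
            patient=pid,
            sex=sex,
            events=realized,
            switch_counts=switches,
            variants=variants,
            karyotype_status="",
            chromothripsis=pid in ct_patients,
            chromothripsis_chromosome=(config.chromothripsis_chromosome
                                       if pid in ct_patients else None),
            chromothripsis_switches=ct_switches,
        )
        if pid in non_informative:
            record.karyotype_status = "non_informative"
            iscn, metaphases = "", 0
        else:
            iscn = _render_karyotype(record, model, config.karyotype_min_size)
            metaphases = 20
            record.karyotype_status = (
                "abnormal" if "/" in iscn else "normal")
        truth_records.append(record)
        karyotypes.append((pid, iscn, metaphases))

    mut_rng = np.random.default_rng(child_seeds[-1])
    mutation_table = simulate_variant_table(all_variants, config.read_depth,
                                            mut_rng)
    return_cohort = Cohort(
        config=config,
        model=model,
        truth=truth_records,
        probe_tables=probe_tables,
        karyotypes=karyotypes,
        mutation_table=mutation_table,
        cnv_regions=cnv_regions,
        snp_ids=snp_ids,
    )
    if out_dir is not None:
        return_cohort.write(out_dir)
    return return_cohort
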