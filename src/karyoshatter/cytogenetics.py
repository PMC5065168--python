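"""Conventional-cytogenetics karyotypes: ISCN parsing, adequacy, concordance.

A deliberately small subset of ISCN nomenclature is supported — enough for
the abnormality classes recurrent in MDS/CMML: interstitial deletions
(``del(5)(q13q33)``), whole-chromosome losses and gains (``-7``, ``+8``),
Y loss (``-Y``), duplications and balanced translocations, in clones
separated by ``/`` with cell counts in ``[n]``.  Anything else parses to
kind ``other`` with a warning rather than failing the pipeline.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .calling import CNACall, GAIN, LOSS
from .genome import GenomeModel, overlap_bp

NORMAL, ABNORMAL, NON_INFORMATIVE = "normal", "abnormal", "non_informative"

KIND_DEL = "del"
KIND_MONOSOMY = "monosomy"
KIND_TRISOMY = "trisomy"
KIND_GAIN = "gain"
KIND_LOSS_Y = "loss_Y"
KIND_TRANSLOCATION = "translocation"
KIND_OTHER = "other"

DETECTED, MISSED, EXPECTED_UNDETECTABLE = (
    "detected", "missed", "expected_undetectable")

#: an abnormality must be seen in at least this many metaphases of a clone
MIN_CLONE_METAPHASES = 2


class ISCNError(ValueError):
    """Raised for karyotype strings outside the supported grammar."""


@dataclass(frozen=True)
class Abnormality:
    kind: str
    chromosome: str | None      # "chr5" style, None when unmappable
    arm: str | None             # "p" | "q" | None
    token: str                  # original ISCN token
    band_text: str = ""
    clone_size: int = 0         # metaphases carrying it


@dataclass
class Clone:
    modal_number: int
    sex_designation: str
    tokens: list[str]
    n_cells: int

    def render(self) -> str:
        parts = [str(self.modal_number), self.sex_designation, *self.tokens]
        return ",".join(parts) + f"[{self.n_cells}]"


@dataclass
class KaryotypeRecord:
    patient: str
    iscn: str
    n_metaphases: int
    status: str
    abnormalities: list[Abnormality] = field(default_factory=list)
    clones: list[Clone] = field(default_factory=list)

    def render(self) -> str:
        """Reconstruct the ISCN string from the parsed clone structure."""
        return "/".join(c.render() for c in self.clones)


_TOKEN_DEL = re.compile(r"^del\((\w+)\)(?:\(([pq][\w.]*)\))?$")
_TOKEN_DUP = re.compile(r"^dup\((\w+)\)(?:\(([pq][\w.]*)\))?$")
_TOKEN_NUM = re.compile(r"^([+-])(\w+)$")
_TOKEN_TRANS = re.compile(r"^t\([\w;]+\)(?:\([\w.;]+\))?$")
_TOKEN_CHROM_IN_PARENS = re.compile(r"\((\w+)[;)]")
_SEX_FIELD = re.compile(r"^[XY]{1,4}$")


def _norm_chrom(name: str) -> str:
    return name if name.startswith("chr") else f"chr{name}"


def _classify_token(token: str) -> Abnormality:
    m = _TOKEN_DEL.match(token)
    if m:
        band = m.group(2) or ""
        return Abnormality(KIND_DEL, _norm_chrom(m.group(1)),
                           band[0] if band else None, token, band)
    m = _TOKEN_DUP.match(token)
    if m:
        band = m.group(2) or ""
        return Abnormality(KIND_GAIN, _norm_chrom(m.group(1)),
                           band[0] if band else None, token, band)
    m = _TOKEN_NUM.match(token)
    if m:
        sign, name = m.groups()
        if sign == "-" and name == "Y":
            return Abnormality(KIND_LOSS_Y, "chrY", None, token)
        if name.isdigit() or name in ("X", "Y"):
            kind = KIND_TRISOMY if sign == "+" else KIND_MONOSOMY
            return Abnormality(kind, _norm_chrom(name), None, token)
        warnings.warn(f"unsupported ISCN token {token!r}; kind=other", stacklevel=3)
        return Abnormality(KIND_OTHER, None, None, token)
    if _TOKEN_TRANS.match(token):
        m2 = _TOKEN_CHROM_IN_PARENS.search(token)
        chrom = _norm_chrom(m2.group(1)) if m2 else None
        return Abnormality(KIND_TRANSLOCATION, chrom, None, token)
    warnings.warn(f"unsupported ISCN token {token!r}; kind=other", stacklevel=3)
    return Abnormality(KIND_OTHER, None, None, token)


def _parse_clone(text: str) -> Clone:
    m = re.match(r"^(.*)\[(\d+)\]$", text.strip())
    if not m:
        raise ISCNError(f"clone {text!r} lacks a cell count '[n]'")
    body, n_cells = m.group(1), int(m.group(2))
    fields = [f.strip() for f in body.split(",") if f.strip()]
    if len(fields) < 2:
        raise ISCNError(f"clone {text!r} needs modal number and sex designation")
    if not fields[0].isdigit():
        raise ISCNError(f"bad modal chromosome number {fields[0]!r} in {text!r}")
    if not _SEX_FIELD.match(fields[1]):
        raise ISCNError(f"bad sex designation {fields[1]!r} in {text!r}")
    return Clone(int(fields[0]), fields[1], fields[2:], n_cells)


def parse_iscn(iscn: str, patient: str = "", n_metaphases: int | None = None
               ) -> KaryotypeRecord:
    """Parse a simplified ISCN karyotype into a :class:`KaryotypeRecord`.

    Metaphases are summed across clones unless ``n_metaphases`` overrides.
    An empty string is a failed culture (non-informative, 0 metaphases).
    Identical abnormality tokens recurring in several clones are merged,
    their clone sizes summed.
    """
    iscn = iscn.strip()
    if not iscn:
        return KaryotypeRecord(patient, "", 0, NON_INFORMATIVE)
    clones = [_parse_clone(part) for part in iscn.split("/")]
    total = sum(c.n_cells for c in clones)
    if n_metaphases is None:
        n_metaphases = total
    merged: dict[str, Abnormality] = {}
    for clone in clones:
        for token in clone.tokens:
            ab = _classify_token(token)
            if token in merged:
                prev = merged[token]
                merged[token] = Abnormality(
                    prev.kind, prev.chromosome, prev.arm, prev.token,
                    prev.band_text, prev.clone_size + clone.n_cells)
            else:
                merged[token] = Abnormality(
                    ab.kind, ab.chromosome, ab.arm, ab.token,
                    ab.band_text, clone.n_cells)
    abnormalities = list(merged.values())
    if n_metaphases == 0:
        status = NON_INFORMATIVE
    elif abnormalities:
        status = ABNORMAL
    else:
        status = NORMAL
    return KaryotypeRecord(patient, iscn, n_metaphases, status,
                           abnormalities, clones)


GE20, M11_19, LE10 = "ge20", "m11_19", "le10"


def adequacy_category(n_metaphases: int) -> str:
    """Band the number of good-quality metaphases analyzed.

    >=20 is an adequate study; 0 means absence of mitosis (non-informative).
    """
    if n_metaphases < 0:
        raise ValueError("metaphase count cannot be negative")
    if n_metaphases == 0:
        return NON_INFORMATIVE
    if n_metaphases >= 20:
        return GE20
    if n_metaphases >= 11:
        return M11_19
    return LE10


def clonal_abnormalities(record: KaryotypeRecord) -> list[Abnormality]:
    """Abnormalities supported by at least MIN_CLONE_METAPHASES metaphases."""
    return [a for a in record.abnormalities
            if a.clone_size >= MIN_CLONE_METAPHASES]


def classify_complex_cc(record: KaryotypeRecord) -> bool | None:
    """Complex karyotype by cytogenetics: >= 3 clonal abnormalities.

    Returns ``None`` (not evaluable) for non-informative karyotypes.
    """
    if record.status == NON_INFORMATIVE:
        return None
    return len(clonal_abnormalities(record)) >= 3


def classify_complex_acgh(n_cnas: int) -> bool:
    """Complex karyotype by array: at least five copy-number changes."""
    if n_cnas < 0:
        raise ValueError("CNA count cannot be negative")
    return n_cnas >= 5


@dataclass
class ConcordanceResult:
    per_abnormality: list[tuple[Abnormality, str]]

    @property
    def counts(self) -> Counter:
        return Counter(status for _, status in self.per_abnormality)

    @property
    def n_detected(self) -> int:
        return self.counts[DETECTED]

    @property
    def n_missed(self) -> int:
        return self.counts[MISSED]

    @property
    def n_expected_undetectable(self) -> int:
        return self.counts[EXPECTED_UNDETECTABLE]

    @property
    def total(self) -> int:
        return len(self.per_abnormality)


def _abnormality_region(ab: Abnormality, genome: GenomeModel
                        ) -> tuple[tuple[int, int] | None, str | None]:
    """Genomic interval and expected CNA direction for a CC abnormality."""
    if ab.chromosome is not None and ab.chromosome not in genome.lengths:
        raise KeyError(f"chromosome {ab.chromosome!r} absent from genome model")
    if ab.kind in (KIND_DEL, KIND_MONOSOMY, KIND_LOSS_Y):
        direction = LOSS
    elif ab.kind in (KIND_TRISOMY, KIND_GAIN):
        direction = GAIN
    else:
        direction = None
    if ab.chromosome is None:
        return None, direction
    if ab.arm in ("p", "q") and ab.kind in (KIND_DEL, KIND_GAIN):
        return genome.arm_interval(ab.chromosome, ab.arm), direction
    return (0, genome.lengths[ab.chromosome]), direction


def match_cc_to_acgh(
    record: KaryotypeRecord,
    calls: Sequence[CNACall],
    genome: GenomeModel,
    min_reciprocal_overlap: float = 0.0,
) -> ConcordanceResult:
    """Match clonal CC abnormalities against array CNA calls.

    An unbalanced abnormality is ``detected`` when a same-direction call
    overlaps its arm- or chromosome-level interval (any overlap by default —
    banded-metaphase breakpoints are too coarse for a reciprocal rule, but a
    minimum reciprocal overlap can be imposed).  Balanced translocations are
    copy-neutral and ``expected_undetectable``.
    """
    results: list[tuple[Abnormality, str]] = []
    for ab in clonal_abnormalities(record):
        if ab.kind == KIND_TRANSLOCATION:
            results.append((ab, EXPECTED_UNDETECTABLE))
            continue
        region, direction = _abnormality_region(ab, genome)
        if region is None:
            results.append((ab, MISSED))
            continue
        span = region[1] - region[0]
        matched = False
        for call in calls:
            if call.chromosome != ab.chromosome:
                continue
            if direction is not None and call.direction != direction:
                continue
            ov = overlap_bp(call.interval, region)
            if ov <= 0:
                continue
            if min_reciprocal_overlap > 0:
                if min(ov / call.size_bp, ov / span) < min_reciprocal_overlap:
                    continue
            matched = True
            break
        results.append((ab, DETECTED if matched else MISSED))
    return ConcordanceResult(results)


#: Large recurrent aberration classes: name -> (chromosome, arm or None, direction)
ABERRATION_CLASSES: dict[str, tuple[str, str | None, str]] = {
    "del(5q)": ("chr5", "q", LOSS),
    "del(7q)": ("chr7", "q", LOSS),
    "del(20q)": ("chr20", "q", LOSS),
    "del(11q)": ("chr11", "q", LOSS),
    "del(17p)": ("chr17", "p", LOSS),
    "del(4q)": ("chr4", "q", LOSS),
    "del(12q)": ("chr12", "q", LOSS),
    "+8": ("chr8", None, GAIN),
    "-Y": ("chrY", None, LOSS),
    "+1q": ("chr1", "q", GAIN),
}


def classify_call_class(call: CNACall, genome: GenomeModel) -> str | None:
    """Assign a large (non-cryptic) call to a named recurrent class by arm overlap."""
    if call.cryptic:
        return None
    for name, (chrom, arm, direction) in ABERRATION_CLASSES.items():
        if call.chromosome != chrom or call.direction != direction:
            continue
        region = (genome.arm_interval(chrom, arm) if arm
                  else (0, genome.lengths[chrom]))
        if overlap_bp(call.interval, region) > 0:
            return name
    return None


@dataclass
class CohortSummary:
    n_patients: int
    n_with_cna: int
    subgroup_sizes: dict[str, int]
    subgroup_with_cna: dict[str, int]
    n_calls: int
    n_losses: int
    n_gains: int
    class_counts: dict[str, int]
    n_complex_cc: int
    n_complex_acgh: int

    @property
    def fraction_with_cna(self) -> float:
        return self.n_with_cna / self.n_patients

    def subgroup_fraction(self, group: str) -> float:
        size = self.subgroup_sizes.get(group, 0)
        return self.subgroup_with_cna.get(group, 0) / size if size else float("nan")

    @property
    def loss_fraction(self) -> float:
        return self.n_losses / self.n_calls if self.n_calls else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_with_cna": self.n_with_cna,
            "fraction_with_cna": self.fraction_with_cna,
            "subgroup_sizes": self.subgroup_sizes,
            "subgroup_with_cna": self.subgroup_with_cna,
            "n_calls": self.n_calls,
            "n_losses": self.n_losses,
            "n_gains": self.n_gains,
            "loss_fraction": self.loss_fraction,
            "class_counts": self.class_counts,
            "n_complex_cc": self.n_complex_cc,
            "n_complex_acgh": self.n_complex_acgh,
        }


def summarize_cohort(
    patients: Sequence[tuple[KaryotypeRecord, Sequence[CNACall]]],
    genome: GenomeModel,
) -> CohortSummary:
    """Cohort-level counts: CNA burden per cytogenetic subgroup, loss/gain
    split, recurrent-class frequencies and complex-karyotype counts."""
    if not patients:
        raise ValueError("empty cohort")
    subgroup_sizes: Counter = Counter()
    subgroup_with_cna: Counter = Counter()
    class_counts: Counter = Counter()
    n_with = n_calls = n_loss = n_gain = n_cc = n_acgh = 0
    for record, calls in patients:
        calls = [c for c in calls if not c.germline_cnv]
        subgroup_sizes[record.status] += 1
        if calls:
            n_with += 1
            subgroup_with_cna[record.status] += 1
        n_calls += len(calls)
        n_loss += sum(c.direction == LOSS for c in calls)
        n_gain += sum(c.direction == GAIN for c in calls)
        for call in calls:
            cls = classify_call_class(call, genome)
            if cls:
                class_counts[cls] += 1
        if classify_complex_cc(record):
            n_cc += 1
        if classify_complex_acgh(len(calls)):
            n_acgh += 1
    return CohortSummary(
        n_patients=len(patients),
        n_with_cna=n_with,
        subgroup_sizes=dict(subgroup_sizes),
        subgroup_with_cna=dict(subgroup_with_cna),
        n_calls=n_calls,
        n_losses=n_loss,
        n_gains=n_gain,
        class_counts=dict(class_counts),
        n_complex_cc=n_cc,
        n_complex_acgh=n_acgh,
    )


class DegenerateTableError(ValueError):
    """Raised when a contingency table has an empty row or column."""


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float


def categorical_association(table: np.ndarray | Sequence[Sequence[int]]
                            ) -> TestResult:
    """Exact test of association for a 2x2 contingency table (two-sided).

    Larger tables fall back to the chi-squared test of independence.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need a contingency table with >= 2 rows and columns")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has an empty margin")
    if t.shape == (2, 2):
        res = stats.fisher_exact(t, alternative="two-sided")
        return TestResult("fisher_exact", float(res.statistic), float(res.pvalue))
    chi2 = stats.chi2_contingency(t)
    return TestResult("chi2_contingency", float(chi2.statistic), float(chi2.pvalue))


def continuous_association(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum comparison of a continuous variable."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.ranksums(a, b)
    return TestResult("wilcoxon_rank_sum", float(res.statistic), float(res.pvalue))


def association_tests(groups: Mapping[str, Sequence]) -> TestResult:
    """Dispatch on the value type: numeric -> rank-sum, labels -> exact test."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    values = list(groups.values())
    numeric = all(
        len(v) > 0 and all(isinstance(x, (int, float, np.number)) for x in v)
        for v in values)
    if numeric:
        if len(groups) != 2:
            raise ValueError("rank-sum comparison needs exactly two groups")
        return continuous_association(values[0], values[1])
    labels = sorted({x for v in values for x in v})
    table = [[list(v).count(lab) for lab in labels] for v in values]
    return categorical_association(table)
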