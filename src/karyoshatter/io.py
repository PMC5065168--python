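"""Readers and writers for the plain-text formats the pipeline exchanges.

Probe tables are tab-delimited ``chrom  pos  log2ratio`` with 1-based
positions.  Segments travel as SEG tables (``sample  chrom  start  end
n_probes  seg_mean``) with 1-based inclusive coordinates; BED files are
0-based half-open.  All writers are bit-stable for fixed input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .calling import CNACall
from .segmentation import Segment

PROBE_COLUMNS = ("chrom", "pos", "log2ratio")
SEG_COLUMNS = ("sample", "chrom", "start", "end", "n_probes", "seg_mean")
CALL_COLUMNS = ("sample", "chrom", "start", "end", "n_probes", "mean_log2",
                "direction", "copy_state", "size_bp", "cryptic",
                "germline_cnv", "followup")


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table {path} missing columns {sorted(missing)}")
    return df


def write_probe_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_seg(segments_by_sample: dict[str, Sequence[Segment]], path: str | Path) -> None:
    """Write segments with 1-based inclusive coordinates (SEG convention)."""
    rows = [
        (sample, s.chromosome, s.start + 1, s.end, s.n_probes, round(s.mean_log2, 6))
        for sample, segs in segments_by_sample.items()
        for s in segs
    ]
    pd.DataFrame(rows, columns=list(SEG_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> dict[str, list[Segment]]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SEG file {path} missing columns {sorted(missing)}")
    out: dict[str, list[Segment]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample), []).append(Segment(
            chromosome=str(row.chrom),
            start=int(row.start) - 1,
            end=int(row.end),
            mean_log2=float(row.seg_mean),
            n_probes=int(row.n_probes),
        ))
    return out


def write_calls(calls_by_sample: dict[str, Sequence[CNACall]], path: str | Path) -> None:
    rows = [
        (sample, c.chromosome, c.start + 1, c.end, c.n_probes,
         round(c.mean_log2, 6), c.direction, c.copy_state, c.size_bp,
         int(c.cryptic), int(c.germline_cnv), int(c.followup))
        for sample, calls in calls_by_sample.items()
        for c in calls
    ]
    pd.DataFrame(rows, columns=list(CALL_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> dict[str, list[CNACall]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[CNACall]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample), []).append(CNACall(
            chromosome=str(row.chrom),
            start=int(row.start) - 1,
            end=int(row.end),
            mean_log2=float(row.mean_log2),
            n_probes=int(row.n_probes),
            direction=str(row.direction),
            copy_state=int(row.copy_state),
            cryptic=bool(row.cryptic),
            germline_cnv=bool(row.germline_cnv),
            followup=bool(row.followup),
        ))
    return out


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file into chrom -> list of 0-based half-open intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path} line {lineno}: need >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path} line {lineno}: end <= start")
            out.setdefault(parts[0], []).append((start, end))
    return out


def read_bed_named(path: str | Path) -> list[tuple[str, str, int, int]]:
    """BED with a name column: list of (name, chrom, start, end)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path} line {lineno}: need 4 BED columns (with name)")
            rows.append((parts[3], parts[0], int(parts[1]), int(parts[2])))
    return rows


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (chrom, start, end, name) rows as BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_karyotype_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient": str, "iscn": str},
                     keep_default_na=False)
    missing = {"patient", "iscn", "n_metaphases"} - set(df.columns)
    if missing:
        raise ValueError(f"karyotype table {path} missing columns {sorted(missing)}")
    return df


def write_karyotype_table(rows: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["patient", "iscn", "n_metaphases"]).to_csv(
        path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
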