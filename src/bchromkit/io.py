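"""File-format adapters: FASTA/FASTQ, SAM/BAM, BED, primer TSV, Ct CSV, JSON.

All genomic coordinates are 0-based half-open internally; SAM/BAM 1-based
POS values are converted on read.  Round-trips are lossless for the text
formats; malformed records raise with file and reason rather than being
skipped silently.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import Region
from .simulate import FastqRead

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_alignments",
    "read_bed",
    "write_bed",
    "read_primer_tsv",
    "write_primer_tsv",
    "primer_role",
    "read_ct_csv",
    "write_ct_csv",
    "write_report_json",
    "load_table1_primers",
    "load_table3_primers",
    "load_table2_regions",
]

CT_COLUMNS = ["sample_id", "genotype", "assay", "replicate", "ct"]


def read_fasta(path: str | Path) -> dict[str, str]:
    path = Path(path)
    records: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
    except (ValueError, FileNotFoundError):
        raise
    except Exception as exc:  # malformed input surfaces with context
        raise ValueError(f"{path}: malformed FASTA ({exc})") from exc
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, *, width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")
    del width  # Bio.SeqIO wraps at 60; kept for interface stability


def read_fastq(path: str | Path) -> list[FastqRead]:
    path = Path(path)
    reads: list[FastqRead] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: malformed FASTQ ({exc})") from exc
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.name}\n{read.sequence}\n+\n{read.quality}\n")


def read_alignments(path: str | Path, *, min_mapq: int = 0):
    """Yield (reference_name, 0-based leftmost position) per counted read.

    Accepts SAM or BAM.  Primary mapped non-duplicate records only; MAPQ
    below ``min_mapq`` is skipped.  SAM POS is 1-based on disk; pysam
    exposes it 0-based, which is what we emit.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            yield rec.reference_name, rec.reference_start


def read_bed(path: str | Path) -> list[Region]:
    regions: list[Region] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 else 0.0
            regions.append(Region(fields[0], start, end, name, score))
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in regions:
            handle.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\n")


def primer_role(primer_id: str) -> str:
    """Role of a primer from its ID under the marker naming convention.

    ``B`` marks a B-specific forward primer (e.g. 49B1-F), ``C`` a control
    forward (49C+-F), ``R`` a shared reverse (49-R, Scaffold_3-R), and
    ``F`` a plain forward as used by the qPCR pairs (Scaffold_3-F).
    """
    head, _, orient = primer_id.rpartition("-")
    if orient == "R":
        return "R"
    if "B" in head.removeprefix("Scaffold"):
        return "B"
    if "C" in head:
        return "C"
    return "F"


def read_primer_tsv(path: str | Path) -> pd.DataFrame:
    """Primer table with columns id, sequence[, role, template].

    A missing role column is derived from the ID naming convention.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "sequence"):
        if col not in df.columns:
            raise ValueError(f"{path}: primer TSV must have an {col!r} column")
    df["sequence"] = df["sequence"].str.upper().str.replace(" ", "", regex=False)
    if "role" not in df.columns:
        df["role"] = df["id"].map(primer_role)
    return df


def write_primer_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "assay", "ct") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: Ct table lacks column(s) {', '.join(missing)}")
    if (df["ct"] <= 0).any():
        bad = df.index[df["ct"] <= 0][0]
        raise ValueError(f"{path}: non-positive Ct value at row {bad}")
    return df


def write_ct_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_report_json(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")


def _data_path(name: str):
    return resources.files("bchromkit").joinpath("data", name)


def load_table1_primers() -> pd.DataFrame:
    """Shipped qualitative (presence/absence) multiplex primer table."""
    with resources.as_file(_data_path("qualitative_primers.tsv")) as p:
        return read_primer_tsv(p)


def load_table3_primers() -> pd.DataFrame:
    """Shipped qPCR primer pairs for the six candidate regions."""
    with resources.as_file(_data_path("qpcr_primers.tsv")) as p:
        return read_primer_tsv(p)


def load_table2_regions() -> list[Region]:
    """Shipped BED of the six high-coverage candidate regions."""
    with resources.as_file(_data_path("qpcr_regions.bed")) as p:
        return read_bed(p)
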