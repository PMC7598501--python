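"""On-disk formats.

FASTA/FASTQ go through Bio.SeqIO (Phred+33 qualities), interval annotations
are BED (0-based, half-open, family/subfamily in the name column), tables and
intensity profiles are TSV with a header row. Every writer has a reader that
round-trips its records losslessly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reads import Read, ReadSet


# ---------------------------------------------------------------- FASTA

def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------- FASTQ

def write_fastq(path, rs: ReadSet) -> None:
    records = []
    for r in rs:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path, interleaved_pairs: bool = False) -> ReadSet:
    """Read a FASTQ file; with ``interleaved_pairs`` consecutive records are
    linked as mates (record 2i with record 2i+1)."""
    reads: list[Read] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = tuple(rec.letter_annotations["phred_quality"])
        reads.append(Read(rec.id, str(rec.seq).upper(), quals))
    if interleaved_pairs:
        if len(reads) % 2:
            raise ValueError("interleaved FASTQ must contain an even number of records")
        linked = []
        for i in range(0, len(reads), 2):
            a, b = reads[i], reads[i + 1]
            linked.append(Read(a.id, a.bases, a.qualities, mate_id=b.id))
            linked.append(Read(b.id, b.bases, b.qualities, mate_id=a.id))
        reads = linked
    return ReadSet(reads)


# ---------------------------------------------------------------- BED

def write_bed(path, intervals: Iterable[tuple[str, int, int, str]]) -> None:
    """Write (chrom, start, end, name) intervals, 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


# ---------------------------------------------------------------- TSV

def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_profile_tsv(path, positions, channels: dict[str, "pd.Series | list"]) -> None:
    df = pd.DataFrame({"position": positions, **channels})
    write_tsv(path, df)


def read_profile_tsv(path) -> pd.DataFrame:
    df = read_tsv(path)
    if "position" not in df.columns:
        raise ValueError(f"{path}: profile TSV must have a 'position' column")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
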