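"""Read quality control: sliding-window quality trimming and length filtering.

Shotgun reads are trimmed from the 3' end before screening.  The trimmer scans
windows of ``window`` bases from the 5' end; at the first window whose mean
Phred quality drops below ``min_mean_q`` the read is cut at the first
below-threshold base inside that window.  Leading and trailing runs of N are
then removed, and reads shorter than ``min_len`` are rejected.  Reads without
qualities (FASTA input) skip the quality step but still undergo N-trimming and
the length filter.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )


@dataclass(frozen=True)
class QCParams:
    window: int = 4
    min_mean_q: float = 20.0
    min_len: int = 50

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_mean_q <= 0 or self.min_len < 1:
            raise ValueError("QC parameters must be strictly positive")


def _quality_cut(quals: tuple[int, ...], window: int, min_mean_q: float) -> int:
    """Return the 3'-truncation point under the sliding-window rule."""
    n = len(quals)
    if n < window:
        return n
    running = sum(quals[:window])
    threshold = min_mean_q * window
    for i in range(n - window + 1):
        if i > 0:
            running += quals[i + window - 1] - quals[i - 1]
        if running < threshold:
            for j in range(i, i + window):
                if quals[j] < min_mean_q:
                    return j
            return i
    return n


def trim_read(read: Read, params: QCParams = QCParams()) -> Read | None:
    """Trim one read; returns None when the trimmed read fails the length filter."""
    seq = read.sequence.upper()
    quals = read.qualities
    if quals is not None:
        cut = _quality_cut(quals, params.window, params.min_mean_q)
        seq = seq[:cut]
        quals = quals[:cut]
    # strip leading/trailing N runs
    start = 0
    end = len(seq)
    while start < end and seq[start] == "N":
        start += 1
    while end > start and seq[end - 1] == "N":
        end -= 1
    seq = seq[start:end]
    if quals is not None:
        quals = quals[start:end]
    if len(seq) < params.min_len:
        return None
    return Read(read_id=read.read_id, sequence=seq, qualities=quals, sample_id=read.sample_id)


def trim_reads(reads: Iterable[Read], params: QCParams = QCParams()) -> tuple[list[Read], dict]:
    """Trim a batch of reads; returns (kept reads, QC log entry)."""
    kept: list[Read] = []
    n_in = 0
    for r in reads:
        n_in += 1
        t = trim_read(r, params)
        if t is not None:
            kept.append(t)
    log = {
        "reads_in": n_in,
        "reads_kept": len(kept),
        "bases_kept": sum(len(r.sequence) for r in kept),
    }
    return kept, log


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastx(path: str | Path, sample_id: str | None = None) -> Iterator[Read]:
    """Iterate reads from a FASTQ (Phred+33) or FASTA file, optionally gzipped.

    The sample id defaults to the file stem, per the one-file-per-sample
    convention ``<sample_id>.fastq[.gz]``.
    """
    path = Path(path)
    stem = path.name
    for suffix in (".gz", ".fastq", ".fq", ".fasta", ".fa", ".fna"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    sid = sample_id if sample_id is not None else stem
    name = path.name.lower()
    is_fastq = name.endswith((".fastq", ".fq", ".fastq.gz", ".fq.gz"))
    fmt = "fastq" if is_fastq else "fasta"
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            quals = None
            if is_fastq:
                quals = tuple(rec.letter_annotations["phred_quality"])
            yield Read(read_id=rec.id, sequence=str(rec.seq).upper(), qualities=quals,
                       sample_id=sid)


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else (30,) * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n")
            fh.write("".join(chr(33 + q) for q in quals) + "\n")


def write_qc_log(entries: dict[str, dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\treads_in\treads_kept\tbases_kept\n")
        for sid in sorted(entries):
            e = entries[sid]
            fh.write(f"{sid}\t{e['reads_in']}\t{e['reads_kept']}\t{e['bases_kept']}\n")
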