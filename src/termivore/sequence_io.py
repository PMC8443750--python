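"""Sequence file I/O and contig utilities.

FASTA and FASTQ reading/writing (plain or gzip, detected by magic bytes),
contig length filtering, and the rotation used to rewrite contigs so that a
predicted terminus becomes position 1.
"""
from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

IUPAC_NUC = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ContigRecord:
    """An assembled contig: the unit of analysis.

    ``id`` is the FASTA header token up to the first whitespace;
    ``description`` keeps the full header for reports.
    """

    id: str
    seq: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read, optionally with its mate (paired-end)."""

    id: str
    seq: str
    mate_seq: str | None = None


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    # gzip detected by the two magic bytes, never by file extension
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[ContigRecord]:
    """Parse a (multi-)FASTA file into :class:`ContigRecord` objects.

    Sequences are uppercased; ids are header tokens before the first
    whitespace and must be unique. Raises ``ValueError`` on an empty file,
    duplicate ids, or non-IUPAC characters (reported with position).
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if rec.id in seen:
                raise ValueError(f"duplicate contig id: {rec.id!r}")
            seen.add(rec.id)
            bad = set(seq) - IUPAC_NUC
            if bad:
                i = min(seq.index(b) for b in bad)
                raise ValueError(
                    f"non-IUPAC character {seq[i]!r} at position {i + 1} "
                    f"of contig {rec.id!r}"
                )
            if not seq:
                raise ValueError(f"contig {rec.id!r} has empty sequence")
            records.append(
                ContigRecord(id=rec.id, seq=seq, description=rec.description)
            )
    if not records:
        raise ValueError(f"no contigs found in {path}")
    return records


def write_fasta(records: Iterable[ContigRecord], path: str | Path,
                width: int = 70) -> None:
    """Write contigs as wrapped FASTA."""
    with open(path, "w") as out:
        for rec in records:
            header = rec.description if rec.description else rec.id
            out.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i:i + width] + "\n")


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str]]:
    with _open_maybe_gzip(path) as handle:
        n = 0
        try:
            for title, seq, _qual in FastqGeneralIterator(handle):
                n += 1
                yield title.split(None, 1)[0], seq.upper()
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record {n + 1} in {path}: {exc}")


def stream_reads(path_r1: str | Path,
                 path_r2: str | Path | None = None) -> Iterator[ReadRecord]:
    """Stream reads lazily from FASTQ (optionally paired, optionally gzipped).

    Paired mode yields both mates in one :class:`ReadRecord`; files must be
    mate-synchronized and of equal length. Qualities are parsed and ignored.
    """
    it1 = _fastq_records(path_r1)
    if path_r2 is None:
        for rid, seq in it1:
            yield ReadRecord(id=rid, seq=seq)
        return
    it2 = _fastq_records(path_r2)
    n = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise ValueError(
                f"paired FASTQ files desynchronized after {n} records: "
                f"{'R1' if r1 is None else 'R2'} exhausted first"
            )
        n += 1
        yield ReadRecord(id=r1[0], seq=r1[1], mate_seq=r2[1])


def write_fastq_pair(r1: Sequence[tuple[str, str]],
                     r2: Sequence[tuple[str, str]],
                     path_r1: str | Path, path_r2: str | Path,
                     quality_char: str = "I") -> None:
    """Write paired (id, seq) lists as two FASTQ files with constant quality."""
    for reads, path, suffix in ((r1, path_r1, "/1"), (r2, path_r2, "/2")):
        with open(path, "w") as out:
            for rid, seq in reads:
                out.write(f"@{rid}{suffix}\n{seq}\n+\n{quality_char * len(seq)}\n")


def filter_contigs(contigs: Sequence[ContigRecord],
                   min_len: int) -> list[ContigRecord]:
    """Keep contigs with length >= ``min_len`` (inclusive), preserving order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [c for c in contigs if c.length >= min_len]
    removed = len(contigs) - len(kept)
    if removed:
        logger.info("filtered out %d contig(s) shorter than %d bp",
                    removed, min_len)
    if not kept:
        logger.warning("no contigs remain after length filter (%d bp)", min_len)
    return kept


def rotate_to_start(seq: str, new_start: int) -> str:
    """Rotate a sequence so that 0-based ``new_start`` becomes the first base."""
    if not 0 <= new_start < len(seq):
        raise ValueError(
            f"new_start {new_start} out of range for sequence of "
            f"length {len(seq)}"
        )
    return seq[new_start:] + seq[:new_start]
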