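"""Exact k-mer seed read mapping and per-strand coverage accumulation.

The terminus signal lives in the first base of each read, so mapping is by
perfect match of a short seed (the read's first k bases, default 20) against
an index of every contig k-mer. For each read placed uniquely within a
contig we record two things per strand:

* SPC (starting position coverage): the count of reads whose 5' base maps at
  each contig position, and
* whole coverage: the count of reads overlapping each position, obtained by
  extending the read length from its start coordinate.

A reverse-strand hit of the seed's reverse complement at index position q
places the read's first base at contig coordinate q + k - 1. Reads with more
than one candidate start within a contig are skipped for that contig
(within-contig repeats must not fabricate peaks); reads may still count on
several different contigs, which are treated as independent candidate
genomes. Coordinates are 0-based half-open throughout this module.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .sequence_io import ContigRecord, ReadRecord, reverse_complement


@dataclass
class SeedIndex:
    """Exact-match index of every k-mer on the forward strand of each contig."""

    k: int
    table: dict[str, list[tuple[str, int]]]
    contig_lengths: dict[str, int]

    def lookup(self, kmer: str) -> Sequence[tuple[str, int]]:
        return self.table.get(kmer, ())


@dataclass
class CoverageProfiles:
    """Per-contig SPC and coverage arrays, one pair per strand."""

    contig_id: str
    spc_fwd: np.ndarray
    spc_rev: np.ndarray
    cov_fwd: np.ndarray
    cov_rev: np.ndarray
    n_reads_used: int = 0
    n_ambiguous_skipped: int = 0
    mean_read_len: float = 0.0
    _len_sum: int = field(default=0, repr=False)

    @property
    def length(self) -> int:
        return self.spc_fwd.shape[0]

    @property
    def total_coverage(self) -> np.ndarray:
        return self.cov_fwd + self.cov_rev

    @property
    def mean_coverage(self) -> float:
        return float(self.total_coverage.mean()) if self.length else 0.0


def _empty_profiles(contig_id: str, length: int) -> CoverageProfiles:
    zeros = lambda: np.zeros(length, dtype=np.int64)  # noqa: E731
    return CoverageProfiles(contig_id, zeros(), zeros(), zeros(), zeros())


def build_seed_index(contigs: Sequence[ContigRecord], k: int = 20) -> SeedIndex:
    """Index every forward-strand k-mer of every contig.

    k-mers containing N are excluded so that ambiguous bases can never
    create spurious start positions. Contigs shorter than k get zero
    entries (a warning is logged upstream by the pipeline).
    """
    if k < 8:
        raise ValueError(f"seed length k must be >= 8, got {k}")
    if not contigs:
        raise ValueError("cannot build a seed index from zero contigs")
    table: dict[str, list[tuple[str, int]]] = {}
    lengths: dict[str, int] = {}
    for contig in contigs:
        seq = contig.seq
        lengths[contig.id] = len(seq)
        # positions of N bases, to skip windows overlapping them cheaply
        next_n = _next_n_positions(seq)
        for pos in range(len(seq) - k + 1):
            if next_n[pos] < pos + k:
                continue
            kmer = seq[pos:pos + k]
            table.setdefault(kmer, []).append((contig.id, pos))
    return SeedIndex(k=k, table=table, contig_lengths=lengths)


def _next_n_positions(seq: str) -> np.ndarray:
    """next_n[i] = smallest j >= i with seq[j] == 'N' (len(seq) if none)."""
    L = len(seq)
    out = np.full(L + 1, L, dtype=np.int64)
    nxt = L
    for i in range(L - 1, -1, -1):
        if seq[i] == "N":
            nxt = i
        out[i] = nxt
    return out


def _read_units(reads: Iterable[ReadRecord]) -> Iterator[str]:
    """Yield each mate as an independent read sequence."""
    for read in reads:
        yield read.seq
        if read.mate_seq is not None:
            yield read.mate_seq


def accumulate_profiles(index: SeedIndex,
                        reads: Iterable[ReadRecord]) -> dict[str, CoverageProfiles]:
    """Map reads through the seed index and accumulate SPC + coverage.

    Each mate of a pair is treated as an independent read. Per contig, a
    read is used only when it has exactly one candidate start (forward seed
    hits plus reverse-complement seed hits combined); ambiguous reads are
    counted in ``n_ambiguous_skipped``. The conservation invariant
    ``spc_fwd.sum() + spc_rev.sum() == n_reads_used`` holds per contig.
    """
    if not index.table and not index.contig_lengths:
        raise ValueError("empty seed index")
    k = index.k
    profiles = {cid: _empty_profiles(cid, L)
                for cid, L in index.contig_lengths.items()}
    n_usable = 0
    n_total = 0
    for seq in _read_units(reads):
        n_total += 1
        if len(seq) < k:
            continue
        n_usable += 1
        seed = seq[:k]
        fwd_hits = index.lookup(seed)
        rev_hits = index.lookup(reverse_complement(seed))
        if not fwd_hits and not rev_hits:
            continue
        read_len = len(seq)
        # group candidate starts by contig: (contig, strand, start)
        per_contig: dict[str, list[tuple[bool, int]]] = {}
        for cid, p in fwd_hits:
            per_contig.setdefault(cid, []).append((True, p))
        for cid, q in rev_hits:
            per_contig.setdefault(cid, []).append((False, q + k - 1))
        for cid, candidates in per_contig.items():
            prof = profiles[cid]
            if len(candidates) > 1:
                prof.n_ambiguous_skipped += 1
                continue
            is_fwd, start = candidates[0]
            L = prof.length
            if is_fwd:
                prof.spc_fwd[start] += 1
                prof.cov_fwd[start:min(start + read_len, L)] += 1
            else:
                prof.spc_rev[start] += 1
                prof.cov_rev[max(0, start - read_len + 1):start + 1] += 1
            prof.n_reads_used += 1
            prof._len_sum += read_len
    if n_total and not n_usable:
        raise ValueError(
            f"no usable reads: all {n_total} reads shorter than seed "
            f"length {k}"
        )
    if n_total == 0:
        raise ValueError("no reads provided")
    for prof in profiles.values():
        if prof.n_reads_used:
            prof.mean_read_len = prof._len_sum / prof.n_reads_used
    return profiles


def brute_force_profiles(contigs: Sequence[ContigRecord],
                         reads: Iterable[ReadRecord],
                         k: int = 20) -> dict[str, CoverageProfiles]:
    """Reference mapper: scan every read against every contig position.

    Semantics identical to :func:`accumulate_profiles` (seed = first k
    bases, exact match, per-contig ambiguity rule) but implemented by
    exhaustive substring search. Quadratic; for validation on small inputs
    only.
    """
    profiles = {c.id: _empty_profiles(c.id, c.length) for c in contigs}
    seqs = {c.id: c.seq for c in contigs}
    n_usable = n_total = 0
    for seq in _read_units(reads):
        n_total += 1
        if len(seq) < k:
            continue
        n_usable += 1
        seed = seq[:k]
        if "N" in seed:
            continue
        rc_seed = reverse_complement(seed)
        read_len = len(seq)
        for cid, cseq in seqs.items():
            candidates: list[tuple[bool, int]] = []
            for p in _find_all(cseq, seed):
                candidates.append((True, p))
            for q in _find_all(cseq, rc_seed):
                candidates.append((False, q + k - 1))
            if not candidates:
                continue
            prof = profiles[cid]
            if len(candidates) > 1:
                prof.n_ambiguous_skipped += 1
                continue
            is_fwd, start = candidates[0]
            L = prof.length
            if is_fwd:
                prof.spc_fwd[start] += 1
                prof.cov_fwd[start:min(start + read_len, L)] += 1
            else:
                prof.spc_rev[start] += 1
                prof.cov_rev[max(0, start - read_len + 1):start + 1] += 1
            prof.n_reads_used += 1
            prof._len_sum += read_len
    if n_total and not n_usable:
        raise ValueError("no usable reads")
    for prof in profiles.values():
        if prof.n_reads_used:
            prof.mean_read_len = prof._len_sum / prof.n_reads_used
    return profiles


def _find_all(haystack: str, needle: str) -> Iterator[int]:
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1
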