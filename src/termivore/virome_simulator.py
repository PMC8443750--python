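"""Virion read simulator: the ground-truth generator for the whole pipeline.

Simulates the DNA molecules that terminase packaging mechanisms actually
produce, shears them the way a sonication library prep does, and emits
paired-end FASTQ plus the reference contigs and a truth table. The key
physical facts being emulated:

* every packaged molecule END becomes a ligatable fragment end, so read
  starts pile up exactly at termini at a rate of roughly one fragment per
  mean-fragment-length of molecule;
* cos molecules are clonal (all cut at the same concatemer site), DTR
  molecules carry the terminal repeat twice while the assembled contig
  carries it once, pac series initiate exactly at pac but accumulate
  headful-size noise downstream, and T4-like random headfuls share no end
  at all.

Molecule ends are encoded so that mapped peak coordinates land exactly on
the truth coordinates the packaging classifier's Delta convention expects:
the forward-peak coordinate is the first molecule base, the reverse-peak
coordinate the last.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .packaging_classifier import Mechanism
from .sequence_io import ContigRecord, reverse_complement, write_fasta, \
    write_fastq_pair

#: per-molecule headful-size noise (sd as fraction of genome length); only
#: series-initiating molecules share an exact end, as for real pac phages
HEADFUL_JITTER_SD = 0.01

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class VirionSpec:
    """Parameters of one simulated phage."""

    name: str
    genome_len: int
    mechanism: Mechanism | None    # None = T4-like random headful (no termini)
    gc: float = 0.5
    cut_pos: int = 0              # cos/pac/DTR top-strand coordinate (0-based)
    overhang_len: int = 0         # cos only, 1..20 bp
    repeat_len: int = 0           # DTR only, >= 30 bp
    headful_factor: float = 1.03  # headful length / genome length
    series_len: int = 4           # headfuls per packaging series
    n_read_pairs: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cut_pos < self.genome_len:
            raise ValueError("cut_pos out of genome range")
        if self.mechanism in (Mechanism.COS_5P, Mechanism.COS_3P):
            if not 1 <= self.overhang_len <= 20:
                raise ValueError("cos overhang_len must be in [1, 20]")
        if self.mechanism is Mechanism.DTR and self.repeat_len < 30:
            raise ValueError("DTR repeat_len must be >= 30")
        if self.headful_factor <= 1:
            raise ValueError("headful_factor must exceed 1")


@dataclass
class TruthRecord:
    """Ground-truth termini implied by a VirionSpec, on the emitted contig."""

    name: str
    mechanism: Mechanism | None   # None encodes random headful (no signal)
    term_fwd: int | None = None   # 1-based
    term_rev: int | None = None   # 1-based
    overhang_len: int | None = None
    repeat_len: int | None = None

    @property
    def expected_call(self) -> Mechanism:
        """Mechanism the detector should report for this phage."""
        return self.mechanism if self.mechanism else Mechanism.NO_SIGNAL


def simulate_genome(length: int, gc: float, seed: int) -> str:
    """Random i.i.d. genome with the given GC content; seeded."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def _circular_slice(genome: str, start: int, length: int) -> str:
    """Substring of the circularized genome, wrapping as needed."""
    L = len(genome)
    start %= L
    reps = (start + length) // L + 1
    return (genome * reps)[start:start + length]


def make_virion_molecules(genome: str, spec: VirionSpec, n_molecules: int,
                          seed: int) -> tuple[list[str], TruthRecord]:
    """Generate the linear DNA molecules a packaging mechanism produces.

    The reference contig for every mechanism is the plain genome string
    (for DTR this is the repeat-collapsed form assemblers emit). Molecule
    boundaries encode the truth peaks: first base at the forward terminus
    coordinate, last base at the reverse terminus coordinate.
    """
    L = len(genome)
    if spec.genome_len != L:
        raise ValueError("genome length does not match spec")
    rng = np.random.default_rng(seed)
    c, o, r = spec.cut_pos, spec.overhang_len, spec.repeat_len
    mech = spec.mechanism

    if mech is Mechanism.COS_5P:
        # fwd peak at c, rev peak at c + o: both terminus coordinates are
        # present at each end of the blunted molecule
        mol = _circular_slice(genome, c, L + o + 1)
        truth = TruthRecord(spec.name, mech, term_fwd=c + 1,
                            term_rev=c + o + 1 if c + o < L else (c + o) % L + 1,
                            overhang_len=o)
        return [mol] * n_molecules, truth
    if mech is Mechanism.COS_3P:
        mol = _circular_slice(genome, c, L - o + 1)
        truth = TruthRecord(spec.name, mech, term_fwd=c + 1,
                            term_rev=(c - o) % L + 1, overhang_len=o)
        return [mol] * n_molecules, truth
    if mech is Mechanism.DTR:
        mol = _circular_slice(genome, c, L + r)
        truth = TruthRecord(spec.name, mech, term_fwd=c + 1,
                            term_rev=(c + r - 1) % L + 1, repeat_len=r)
        return [mol] * n_molecules, truth
    if mech is Mechanism.HEADFUL_PAC:
        mols: list[str] = []
        pos = c
        jitter_sd = HEADFUL_JITTER_SD * L
        for j in range(n_molecules):
            if j % spec.series_len == 0:
                pos = c  # new series initiates exactly at pac
            headful = int(round(rng.normal(spec.headful_factor * L,
                                           jitter_sd)))
            headful = max(L // 2, headful)
            mols.append(_circular_slice(genome, pos, headful))
            pos = (pos + headful) % L
        truth = TruthRecord(spec.name, mech, term_fwd=c + 1)
        return mols, truth
    # T4-like random headful: uniform start, no shared ends
    jitter_sd = HEADFUL_JITTER_SD * L
    starts = rng.integers(0, L, size=n_molecules)
    mols = []
    for s in starts:
        headful = int(round(rng.normal(spec.headful_factor * L, jitter_sd)))
        mols.append(_circular_slice(genome, int(s), max(L // 2, headful)))
    truth = TruthRecord(spec.name, None)
    return mols, truth


def shear_and_sequence(molecules: Sequence[str], n_read_pairs: int,
                       frag_mu: float = 400.0, frag_sd: float = 100.0,
                       read_len: int = 75, error_rate: float = 0.0,
                       seed: int = 0,
                       name_prefix: str = "frag",
                       ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Shear molecules and emit paired (id, sequence) read lists.

    Fragment length ~ Normal(frag_mu, frag_sd) truncated to
    [read_len, molecule length]. The fragment window start is uniform over
    [-(f - read_len), L - read_len] and the window is clipped at the
    molecule bounds, so a fragment begins (or ends) exactly at a molecule
    end with probability ~ f/L per draw — one end-anchored fragment per
    expected fragment count, which is what random mechanical shearing of
    each whole molecule yields and what creates the terminus signal. R1 is
    the first read_len bases of the fragment, R2 the reverse complement of
    the last read_len bases.
    """
    if not molecules:
        raise ValueError("no molecules to shear")
    if read_len > frag_mu:
        raise ValueError("read_len must not exceed mean fragment length")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(m) for m in molecules], dtype=np.int64)
    weights = lengths / lengths.sum()
    mol_idx = rng.choice(len(molecules), size=n_read_pairs, p=weights)
    mol_lens = lengths[mol_idx]
    frags = np.rint(rng.normal(frag_mu, frag_sd, size=n_read_pairs)).astype(np.int64)
    # redraw out-of-range fragment lengths (truncated normal)
    bad = (frags < read_len) | (frags > mol_lens)
    while bad.any():
        frags[bad] = np.rint(
            rng.normal(frag_mu, frag_sd, size=int(bad.sum()))
        ).astype(np.int64)
        bad = (frags < read_len) | (frags > mol_lens)
    lo = -(frags - read_len)
    hi = mol_lens - read_len          # inclusive
    starts = lo + np.floor(
        rng.random(n_read_pairs) * (hi - lo + 1)
    ).astype(np.int64)
    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    for i in range(n_read_pairs):
        mol = molecules[mol_idx[i]]
        s = int(starts[i])
        a, b = max(0, s), min(len(mol), s + int(frags[i]))
        frag = mol[a:b]
        seq1 = frag[:read_len]
        seq2 = reverse_complement(frag[-read_len:])
        rid = f"{name_prefix}_{i}"
        r1.append((rid, seq1))
        r2.append((rid, seq2))
    if error_rate > 0:
        r1 = _add_errors(r1, error_rate, rng)
        r2 = _add_errors(r2, error_rate, rng)
    return r1, r2


def _add_errors(reads: list[tuple[str, str]], rate: float,
                rng: np.random.Generator) -> list[tuple[str, str]]:
    out = []
    for rid, seq in reads:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hit = np.nonzero(rng.random(arr.size) < rate)[0]
        for j in hit:
            choices = _BASES[_BASES != arr[j]]
            arr[j] = rng.choice(choices)
        out.append((rid, arr.tobytes().decode()))
    return out


def default_mock_specs(n_read_pairs: int = 20_000, genome_len: int = 40_000,
                       seed: int = 0) -> list[VirionSpec]:
    """The five-phage reference panel: one spec per packaging mechanism.

    Lambda-like 5' cos (12 nt overhang), HK97-like 3' cos (10 nt), T7-like
    DTR (160 bp repeat), P1-like headful with pac (series of 4, 3% terminal
    redundancy), and a T4-like random headful that must yield no signal.
    """
    mid = genome_len // 2
    common = dict(genome_len=genome_len, n_read_pairs=n_read_pairs)
    return [
        VirionSpec(name="cos5_lambda_like", mechanism=Mechanism.COS_5P,
                   cut_pos=mid, overhang_len=12, seed=seed * 10 + 1, **common),
        VirionSpec(name="cos3_hk97_like", mechanism=Mechanism.COS_3P,
                   cut_pos=mid, overhang_len=10, seed=seed * 10 + 2, **common),
        VirionSpec(name="dtr_t7_like", mechanism=Mechanism.DTR,
                   cut_pos=mid, repeat_len=160, seed=seed * 10 + 3, **common),
        VirionSpec(name="pac_p1_like", mechanism=Mechanism.HEADFUL_PAC,
                   cut_pos=mid, headful_factor=1.03, series_len=4,
                   seed=seed * 10 + 4, **common),
        VirionSpec(name="headful_random_t4_like", mechanism=None,
                   cut_pos=0, seed=seed * 10 + 5, **common),
    ]


def build_mock_virome(specs: Sequence[VirionSpec], out_prefix: str | Path,
                      seed: int = 0, n_molecules: int = 2000,
                      frag_mu: float = 400.0, frag_sd: float = 100.0,
                      read_len: int = 75, error_rate: float = 0.0,
                      ) -> dict[str, Path]:
    """Simulate a pooled mock virome: FASTQ pair, reference FASTA, truth TSV.

    Reads from all phages are pooled and shuffled with the run seed; output
    is byte-reproducible for fixed seeds. ``n_molecules`` sets the library
    complexity per phage: it should stay well above the per-molecule-end
    sampling depth (n_read_pairs * frag_mu / genome_len / n_molecules << 1)
    or the same physical molecule end is drawn repeatedly, a
    duplicate-read artifact absent from real libraries of virion DNA.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate spec names")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    contigs: list[ContigRecord] = []
    truths: list[TruthRecord] = []
    pooled_r1: list[tuple[str, str]] = []
    pooled_r2: list[tuple[str, str]] = []
    for s in specs:
        genome = simulate_genome(s.genome_len, s.gc, s.seed)
        mols, truth = make_virion_molecules(genome, s, n_molecules,
                                            seed=s.seed + 1)
        r1, r2 = shear_and_sequence(
            mols, s.n_read_pairs, frag_mu=frag_mu, frag_sd=frag_sd,
            read_len=read_len, error_rate=error_rate, seed=s.seed + 2,
            name_prefix=s.name,
        )
        contigs.append(ContigRecord(id=s.name, seq=genome))
        truths.append(truth)
        pooled_r1.extend(r1)
        pooled_r2.extend(r2)
    order = np.random.default_rng(seed).permutation(len(pooled_r1))
    pooled_r1 = [pooled_r1[i] for i in order]
    pooled_r2 = [pooled_r2[i] for i in order]

    paths = {
        "r1": Path(f"{out_prefix}.R1.fastq"),
        "r2": Path(f"{out_prefix}.R2.fastq"),
        "fasta": Path(f"{out_prefix}.contigs.fasta"),
        "truth": Path(f"{out_prefix}.truth.tsv"),
    }
    write_fastq_pair(pooled_r1, pooled_r2, paths["r1"], paths["r2"])
    write_fasta(contigs, paths["fasta"])
    with open(paths["truth"], "w") as out:
        out.write("name\tmechanism\tterm_fwd\tterm_rev\toverhang_len\trepeat_len\n")
        for t in truths:
            fmt = lambda v: "-" if v is None else str(v)  # noqa: E731
            mech = t.mechanism.value if t.mechanism else "HEADFUL_RANDOM"
            out.write(f"{t.name}\t{mech}\t{fmt(t.term_fwd)}\t{fmt(t.term_rev)}"
                      f"\t{fmt(t.overhang_len)}\t{fmt(t.repeat_len)}\n")
    return paths
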