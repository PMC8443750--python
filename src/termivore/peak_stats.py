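"""Start-position enrichment statistics and peak calling.

Under random fragmentation, a read that covers a position is equally likely
to start at any of the ~mean_read_len positions of its span, so the null
for the start count X at a position with coverage c is

    X ~ Binomial(c, 1 / mean_read_len)

and the enrichment p-value is the upper tail P(X >= spc). This conditions
on local coverage, which is what makes the statistic usable where coverage
is uneven (contig edges, terminal repeats) and across contigs of wildly
different abundance in one virome.

Per contig, p-values for all positions with coverage >= min_cov on either
strand are pooled and corrected with Benjamini-Hochberg; candidates must
also pass the effect-size gate tau = spc/cov >= tau_min. Nearby candidates
on one strand are merged and each cluster is represented by its maximal-SPC
position; the best representative per strand is the primary peak, all other
representatives are reported as secondary peaks (candidate secondary
terminase cutting sites).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .mapping import CoverageProfiles

DEFAULT_ALPHA = 0.01
DEFAULT_TAU_MIN = 0.1
DEFAULT_MIN_COV = 10
DEFAULT_MERGE_WINDOW = 20


@dataclass(frozen=True)
class PeakCall:
    """A significantly start-enriched position on one strand."""

    strand: str           # "fwd" | "rev"
    pos: int              # 0-based
    spc: int
    cov: int
    tau: float            # spc / cov
    pval: float
    qval: float
    at_edge: bool = False


@dataclass
class PeakSet:
    """Primary and secondary peak calls for one contig."""

    contig_id: str
    primary_fwd: PeakCall | None = None
    primary_rev: PeakCall | None = None
    secondary: list[PeakCall] = field(default_factory=list)
    mean_cov: float = 0.0
    low_coverage: bool = False

    @property
    def all_peaks(self) -> list[PeakCall]:
        out = [p for p in (self.primary_fwd, self.primary_rev) if p]
        return out + list(self.secondary)


def start_enrichment_pvalue(spc: int, cov: int, mean_read_len: float) -> float:
    """Upper-tail binomial probability P(X >= spc), X ~ Bin(cov, 1/mean_read_len).

    Returns 1.0 for an uncovered position. ``spc > cov`` is an invariant
    breach upstream and raises.
    """
    if spc > cov:
        raise ValueError(f"spc ({spc}) exceeds coverage ({cov})")
    if spc < 0 or cov < 0:
        raise ValueError("spc and cov must be non-negative")
    if mean_read_len <= 1:
        raise ValueError("mean_read_len must exceed 1")
    if cov == 0 or spc == 0:
        return 1.0
    return float(binom.sf(spc - 1, cov, 1.0 / mean_read_len))


def _cluster_candidates(strand_positions: np.ndarray, spc: np.ndarray,
                        merge_window: int) -> list[int]:
    """Merge sorted candidate positions within merge_window into clusters;
    return the representative index (max spc, ties -> smaller pos) of each."""
    reps: list[int] = []
    if strand_positions.size == 0:
        return reps
    cluster_start = 0
    for i in range(1, strand_positions.size + 1):
        if (i == strand_positions.size
                or strand_positions[i] - strand_positions[i - 1] > merge_window):
            block = slice(cluster_start, i)
            local_spc = spc[block]
            best = cluster_start + int(np.argmax(local_spc))
            reps.append(best)
            cluster_start = i
    return reps


def call_peaks(profiles: CoverageProfiles,
               alpha: float = DEFAULT_ALPHA,
               tau_min: float = DEFAULT_TAU_MIN,
               min_cov: int = DEFAULT_MIN_COV,
               merge_window: int = DEFAULT_MERGE_WINDOW,
               edge_margin: int = 20) -> PeakSet:
    """Call primary and secondary start-enrichment peaks for one contig.

    Positions with strand coverage below ``min_cov`` are untested (they do
    not enter the BH correction). A candidate needs q <= alpha and
    tau >= tau_min.
    """
    L = profiles.length
    mean_cov = profiles.mean_coverage
    peakset = PeakSet(contig_id=profiles.contig_id, mean_cov=mean_cov,
                      low_coverage=mean_cov < min_cov)
    mrl = profiles.mean_read_len
    if mrl <= 1 or profiles.n_reads_used == 0:
        return peakset

    p_start = 1.0 / mrl
    tested: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    pvals: list[np.ndarray] = []
    for strand, spc, cov in (("fwd", profiles.spc_fwd, profiles.cov_fwd),
                             ("rev", profiles.spc_rev, profiles.cov_rev)):
        mask = cov >= min_cov
        pos = np.nonzero(mask)[0]
        s, c = spc[pos], cov[pos]
        # sf(s-1) with s=0 -> 1.0 exactly; compute vectorized
        p = binom.sf(s - 1, c, p_start)
        p = np.where(s == 0, 1.0, p)
        tested.append((strand, pos, s, c))
        pvals.append(p)
    all_p = np.concatenate(pvals) if pvals else np.empty(0)
    if all_p.size == 0:
        return peakset
    _, qvals, _, _ = multipletests(all_p, method="fdr_bh")

    offset = 0
    per_strand_reps: dict[str, list[PeakCall]] = {"fwd": [], "rev": []}
    for (strand, pos, s, c), p in zip(tested, pvals):
        q = qvals[offset:offset + pos.size]
        offset += pos.size
        cand = (q <= alpha) & (s / np.maximum(c, 1) >= tau_min)
        idx = np.nonzero(cand)[0]
        if idx.size == 0:
            continue
        reps = _cluster_candidates(pos[idx], s[idx], merge_window)
        for r in reps:
            j = idx[r]
            position = int(pos[j])
            per_strand_reps[strand].append(PeakCall(
                strand=strand, pos=position, spc=int(s[j]), cov=int(c[j]),
                tau=float(s[j] / c[j]), pval=float(p[j]), qval=float(q[j]),
                at_edge=position < edge_margin or position >= L - edge_margin,
            ))

    secondary: list[PeakCall] = []
    for strand, reps in per_strand_reps.items():
        if not reps:
            continue
        # primary: smallest q, then larger spc, then smaller position
        reps_sorted = sorted(reps, key=lambda pk: (pk.qval, -pk.spc, pk.pos))
        primary = reps_sorted[0]
        if strand == "fwd":
            peakset.primary_fwd = primary
        else:
            peakset.primary_rev = primary
        secondary.extend(reps_sorted[1:])
    peakset.secondary = sorted(secondary, key=lambda pk: (pk.strand, pk.pos))
    return peakset
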