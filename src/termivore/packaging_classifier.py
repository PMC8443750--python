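"""Packaging-mechanism classification from peak geometry and coverage.

The physical end structure of packaged phage DNA leaves a geometric
signature in the pair of start-enrichment peaks:

* cos phages: terminase cuts a concatemer with staggered nicks at a fixed
  site; the forward peak marks the top-strand cut, the reverse peak the
  bottom-strand cut. With Delta = pos_rev - pos_fwd, a small positive Delta
  means protruding 5' ends (lambda-like), a small negative Delta protruding
  3' ends (HK97-like); the overhang length is |Delta|.
* DTR phages (T7-like): the packaged genome carries the same short repeat
  at both ends; assemblers collapse it, so mapped coverage doubles over the
  repeat and the two peaks sit repeat-length apart. Confirmed by the
  coverage elevation ratio between the peaks.
* headful/pac phages (P1-like): packaging series initiate precisely at pac
  but subsequent headful cuts drift, so exactly one strand carries a peak.
* headful without pac (T4-like): random packaging start, no signal at all.

Contigs from circularly permuted assemblies may place the two termini on
opposite sides of the arbitrary contig origin; a circular fallback
re-evaluates the complementary arc before giving up.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .mapping import CoverageProfiles
from .peak_stats import DEFAULT_MERGE_WINDOW, PeakSet

DEFAULT_MAX_OVERHANG = 20
DEFAULT_MAX_DTR = 10_000
DEFAULT_DTR_RATIO_MIN = 1.4


class Mechanism(str, Enum):
    """Packaging mechanism classes, with the field's display vocabulary."""

    COS_5P = "COS_5P"
    COS_3P = "COS_3P"
    DTR = "DTR"
    HEADFUL_PAC = "HEADFUL_PAC"
    NO_SIGNAL = "NO_SIGNAL"
    AMBIGUOUS = "AMBIGUOUS"
    LOW_COVERAGE = "LOW_COVERAGE"

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    Mechanism.COS_5P: "5' cos",
    Mechanism.COS_3P: "3' cos",
    Mechanism.DTR: "DTR (short)",
    Mechanism.HEADFUL_PAC: "headful (pac)",
    Mechanism.NO_SIGNAL: "-",
    Mechanism.AMBIGUOUS: "ambiguous",
    Mechanism.LOW_COVERAGE: "low coverage",
}

#: classes for which termini are considered resolved (contig gets rotated)
RESOLVED = frozenset({Mechanism.COS_5P, Mechanism.COS_3P, Mechanism.DTR,
                      Mechanism.HEADFUL_PAC})


@dataclass
class TerminiPrediction:
    """Mechanism call plus termini coordinates for one contig.

    ``term_fwd`` / ``term_rev`` are 1-based inclusive positions on the
    contig (None when absent).
    """

    contig_id: str
    mechanism: Mechanism
    term_fwd: int | None = None
    term_rev: int | None = None
    overhang_len: int | None = None
    repeat_len: int | None = None
    elevation_ratio: float | None = None
    pac_strand: str | None = None
    warnings: list[str] = field(default_factory=list)


def coverage_elevation_ratio(profiles: CoverageProfiles, a: int, b: int,
                             guard: int = DEFAULT_MERGE_WINDOW) -> float:
    """Mean total coverage over [a, b] relative to the rest of the contig.

    The flank excludes a guard band of ``guard`` bp around a and b.
    Returns ``inf`` when the flank is uncovered.
    """
    if a >= b:
        raise ValueError(f"require a < b, got a={a}, b={b}")
    L = profiles.length
    if a < 0 or b >= L:
        raise ValueError("interval out of contig bounds")
    total = profiles.total_coverage
    inner = float(total[a:b + 1].mean())
    flank_mask = np.ones(L, dtype=bool)
    flank_mask[max(0, a - guard):min(L, b + guard + 1)] = False
    if not flank_mask.any():
        return math.inf
    flank = float(total[flank_mask].mean())
    if flank == 0.0:
        return math.inf
    return inner / flank


def _circular_elevation(profiles: CoverageProfiles, a: int, b: int,
                        guard: int = DEFAULT_MERGE_WINDOW) -> float:
    """Elevation ratio for the wrapped interval [a..L) + [0..b]."""
    L = profiles.length
    total = profiles.total_coverage
    idx = np.r_[a:L, 0:b + 1]
    inner = float(total[idx].mean())
    flank_mask = np.ones(L, dtype=bool)
    flank_mask[max(0, a - guard):L] = False
    flank_mask[0:min(L, b + guard + 1)] = False
    if not flank_mask.any():
        return math.inf
    flank = float(total[flank_mask].mean())
    return math.inf if flank == 0.0 else inner / flank


def classify_packaging(peaks: PeakSet, profiles: CoverageProfiles,
                       max_overhang: int = DEFAULT_MAX_OVERHANG,
                       max_dtr: int = DEFAULT_MAX_DTR,
                       dtr_ratio_min: float = DEFAULT_DTR_RATIO_MIN,
                       ) -> TerminiPrediction:
    """Total decision function: every peak set yields exactly one prediction."""
    cid = peaks.contig_id
    pred = TerminiPrediction(contig_id=cid, mechanism=Mechanism.NO_SIGNAL)
    fwd, rev = peaks.primary_fwd, peaks.primary_rev

    if peaks.low_coverage and fwd is None and rev is None:
        pred.mechanism = Mechanism.LOW_COVERAGE
        pred.warnings.append(
            f"very low mean coverage ({peaks.mean_cov:.1f}x); "
            "inspect coverage plots manually"
        )
        return pred

    if fwd is None and rev is None:
        pred.mechanism = Mechanism.NO_SIGNAL
        return pred

    if fwd is None or rev is None:
        peak = fwd if fwd is not None else rev
        pred.mechanism = Mechanism.HEADFUL_PAC
        pred.pac_strand = peak.strand
        if peak.strand == "fwd":
            pred.term_fwd = peak.pos + 1
        else:
            pred.term_rev = peak.pos + 1
        if peaks.low_coverage:
            pred.warnings.append("pac call at low coverage")
        return pred

    # peaks on both strands
    delta = rev.pos - fwd.pos
    if -max_overhang <= delta <= max_dtr:
        return _classify_two_peaks(pred, profiles, fwd.pos, rev.pos, delta,
                                   max_overhang, max_dtr, dtr_ratio_min,
                                   circular=False)

    # Delta out of range on the linear contig: evaluate the complementary
    # arc under a circular interpretation (circularly permuted assembly)
    L = profiles.length
    delta_c = delta - L if delta > 0 else delta + L
    if -max_overhang <= delta_c <= max_dtr:
        circ = _classify_two_peaks(pred, profiles, fwd.pos, rev.pos, delta_c,
                                   max_overhang, max_dtr, dtr_ratio_min,
                                   circular=True)
        if circ.mechanism is not Mechanism.AMBIGUOUS:
            circ.warnings.append(
                "termini resolved under circular interpretation"
            )
        return circ

    pred.mechanism = Mechanism.AMBIGUOUS
    pred.term_fwd = fwd.pos + 1
    pred.term_rev = rev.pos + 1
    pred.warnings.append(
        f"two peaks {abs(delta)} bp apart: no linear or circular "
        "terminus geometry fits"
    )
    return pred


def _classify_two_peaks(pred: TerminiPrediction, profiles: CoverageProfiles,
                        pos_fwd: int, pos_rev: int, delta: int,
                        max_overhang: int, max_dtr: int,
                        dtr_ratio_min: float,
                        circular: bool) -> TerminiPrediction:
    """Apply the two-peak rules for a Delta already known to be in range."""
    pred.term_fwd = pos_fwd + 1
    pred.term_rev = pos_rev + 1
    if 0 < delta <= max_overhang:
        pred.mechanism = Mechanism.COS_5P
        pred.overhang_len = delta
        return pred
    if -max_overhang <= delta < 0:
        pred.mechanism = Mechanism.COS_3P
        pred.overhang_len = -delta
        return pred
    if delta == 0:
        pred.mechanism = Mechanism.AMBIGUOUS
        pred.warnings.append("blunt or unresolved cos polarity")
        return pred
    # max_overhang < delta <= max_dtr: terminal-repeat hypothesis
    if circular:
        ratio = _circular_elevation(profiles, pos_fwd, pos_rev)
    else:
        ratio = coverage_elevation_ratio(profiles, pos_fwd, pos_rev)
    pred.elevation_ratio = ratio
    if ratio >= dtr_ratio_min:
        pred.mechanism = Mechanism.DTR
        pred.repeat_len = delta
        return pred
    pred.mechanism = Mechanism.AMBIGUOUS
    pred.warnings.append(
        f"peaks {abs(delta)} bp apart but coverage elevation "
        f"{ratio:.2f} below DTR threshold"
    )
    return pred
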