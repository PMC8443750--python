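# Methods

## Model and procedure

The pipeline treats each assembled contig as an independent candidate viral
genome and asks, per position and strand, whether the count of read 5′ ends
mapping exactly there (the starting position coverage, SPC) exceeds what
random fragmentation of DNA would produce.

**Mapping.** Reads are placed by perfect match of a seed — the first *k*
bases of the read, default *k* = 20 — against a hash index of every
forward-strand k-mer of every contig. A reverse-strand hit of the seed's
reverse complement at index position *q* puts the read's 5′ base at contig
coordinate *q* + *k* − 1. Seeds are matched exactly because the terminus
signal lives in the read's first base; a mismatch-tolerant aligner would
blur exactly the coordinate being tested. The k-mer index makes total work
linear in reads + contigs, which is what allows simultaneous analysis of
hundreds of contigs against one pooled read set. Rules, in order, per read
and contig: k-mers containing N are never indexed (ambiguity must not
create start positions); a read with more than one candidate start within a
contig is discarded *for that contig* (within-contig repeats would
otherwise fabricate peaks; this keeps the conservation invariant
Σ SPC = reads-used testable); a read may count on several different contigs
(assembly variants must each be analyzable on their own). Mates of a pair
are mapped as independent reads; fragment-span coverage is deliberately not
assumed, since virome insert-size distributions are heterogeneous. Coverage
is accumulated by extending the read length from the start coordinate,
clipped at contig bounds. Contigs are linear: seeds never wrap the origin,
so edge positions have depressed coverage; the statistic below conditions
on local coverage, which keeps interior and edge peaks on the same scale.

**Enrichment test.** For a position with strand coverage *c*, start count
*s*, and mean used-read length ℓ, the null is s ~ Binomial(c, 1/ℓ): a read
that covers the position is equally likely to have started at any of the ~ℓ
positions of its span. The p-value is the exact upper tail (scipy's
binomial survival function). Conditioning on coverage — rather than
comparing SPC to a genome-wide rate — is what normalizes the statistic
against the whole-sequence coverage, so contigs of very different abundance
in one virome are tested on equal footing, as are doubly covered DTR
intervals.

Positions with *c* < min_cov (default 10) are *untested* rather than
tested-and-failed: below ~10× a call is untrustworthy anyway, and leaving
those positions out keeps them from diluting the multiple-testing
correction. Benjamini–Hochberg runs across all tested positions of one
contig, both strands pooled — each contig is one genome hypothesis, and
pooling across contigs would couple unrelated phages. Candidates need
q ≤ α (default 0.01) *and* τ = s/c ≥ τ_min (default 0.1): at extreme
coverage, vanishing effects become significant, and the τ gate imposes a
minimal effect size; 0.1 is low enough to keep pac peaks, which carry only
the series-initiating fraction (~1/series length) of molecule ends, well
above the gate at realistic series lengths. Candidates within merge_window
(default 20 bp, the seed length) on one strand merge into a cluster
represented by the maximal-SPC position (ties: smaller coordinate —
determinism). The per-strand primary peak is the representative with the
smallest q (ties: larger SPC, then smaller coordinate); all other
representatives are reported as secondary peaks.

**Classification.** With a forward-strand peak at *a* and a reverse-strand
peak at *b* (0-based), Δ = b − a. Staggered terminase nicks with the top
strand cut left of the bottom strand leave protruding 5′ ends, so
0 < Δ ≤ max_overhang (default 20 bp, the biological ceiling for cohesive
ends) is 5′ cos with overhang Δ; the mirror case is 3′ cos; Δ = 0 is
ambiguous (blunt or unresolved polarity). For max_overhang < Δ ≤ max_dtr
(default 10 kb) the terminal-repeat hypothesis is tested by the coverage
elevation ratio: mean total coverage over [a, b] divided by the mean over
the rest of the contig excluding a merge_window guard band. A collapsed DTR
is covered by both molecule ends, giving ~2× over the repeat; the threshold
is 1.4, below the ideal 2.0, tolerating coverage noise and partial repeat
collapse. Note the *measured* ratio on simulated DTR phages is typically
3–4, not 2: the terminus start pileups themselves sit inside [a, b] and add
~spc × read-length/repeat-length to the interval mean. The 1.4 threshold is
a lower bound for accepting the repeat hypothesis, not an estimate of the
expected value. A peak on exactly one strand is a headful/pac call (the
other genome end varies molecule-to-molecule); no peaks at adequate
coverage is "no signal" (T4-like random packaging); no peaks at mean
coverage below min_cov yields a low-coverage warning instead of a claim.
When Δ is out of range on the linear contig, the complementary arc is
evaluated under a circular interpretation (Δ ± L), handling circularly
permuted contigs whose arbitrary origin falls between the termini;
coordinates are reported unchanged with a warning.

All user-facing coordinates are 1-based inclusive; internals are 0-based
half-open.

## The simulator

`virome_simulator` generates what each mechanism physically packages.
Genomes are i.i.d. with adjustable GC. Molecules:

* **cos (5′/3′):** clonal rotations of the circular genome cut at
  `cut_pos`. Overhangs are modeled at coordinate level, not as literal
  single-stranded ends (short-read preps blunt them anyway): molecule
  boundaries are chosen so that the mapped forward peak lands at `cut_pos`
  and the reverse peak at `cut_pos` ± overhang — the same Δ convention the
  classifier decodes. This is the one shared contract between generator and
  detector; it encodes the staggered-nick geometry, not a tautology, since
  mapping, statistics and clustering all sit between the two.
* **DTR:** molecules of length L + repeat carrying the repeat at both ends;
  the emitted reference contig is the collapsed form (repeat once), which
  is what assemblers produce and what the detector must handle.
* **headful/pac:** packaging series restart exactly at the pac site every
  `series_len` molecules (default 4, putting ~25 % of left ends at pac — a
  deliberately weak-peak regime); successive headfuls measure
  `headful_factor` × L (default 1.03, ~3 % terminal redundancy) plus
  per-molecule Gaussian noise with sd 1 % of L. The noise is essential
  biology: real headful measurement is imprecise, so only series-initiating
  molecules share an exact end — a deterministic headful would wrongly give
  every j-th molecule in every series the same ends and put exact peaks on
  both strands.
* **random headful:** uniform start, headful length — the no-signal
  control.

**Shearing.** Fragment lengths are Normal(400, 100) truncated to
[read length, molecule length]. The fragment window start is uniform over
[−(f − r), L − r] (r = read length) and clipped at molecule bounds, so a
fragment starts exactly at a molecule end with probability ≈ f/L per draw —
one end-anchored fragment per expected fragment count, the rate whole-
molecule mechanical shearing produces, and precisely the enrichment the
detector exists to find. R1 is the first r bases of the fragment, R2 the
reverse complement of the last r; substitution errors are i.i.d. at
`error_rate` (default 0). Everything is seeded; changing only the run seed
changes reads but never truth.

**Library complexity.** `build_mock_virome` simulates `n_molecules`
physical molecules per phage (default 2000). This must stay well above the
per-end sampling depth (read pairs × f/L per molecule end), otherwise the
same physical end is drawn repeatedly — a duplicate-read artifact absent
from real virion libraries (≫10⁶ particles) that manifests as spurious SPC
pileups on signal-free contigs.

**What the simulator does not model:** indels, quality-score error
profiles, GC-coverage bias, chimeric reads, host or prophage contamination,
tagmentation start bias (explicitly incompatible with the method), Mu-like
host-DNA ends. Passing the simulation suite therefore demonstrates the
statistical and geometric machinery under clean library chemistry; on real
data, library-prep violations and contamination can add failure modes the
suite does not probe.

## Problem sizes and defaults

The reference mock study uses five 40 kb phages at 2×10⁴ read pairs each
(~75× coverage; a 1:100 scale model of a 2×10⁶-pairs-per-phage pooled mock
run, keeping per-position coverage in the regime where exact recovery is
expected). The false-positive experiment uses 100 signal-free 3 kb contigs
at ~30×, the coverage the method's guidance calls adequate for unequivocal
calls; mapper cross-validation uses 20 random contigs ≤ 2 kb × 500 reads
against a quadratic brute-force scan. These sizes keep the full suite and
the acceptance script in the minutes range on one core while preserving
each experiment's operating regime.

Defaults: k = 20, min contig length 500 bp (inclusive ≥, the comparator
being an implementation choice), α = 0.01, τ_min = 0.1, min_cov = 10,
merge_window = 20 bp, max_overhang = 20 bp, max_dtr = 10 kb,
dtr_ratio_min = 1.4. An optional mean-coverage pre-filter (e.g. reject
contigs ≤ 10×) exists but is off by default — it is a recommendation to the
user, not part of the method.

## Numerical and degenerate-input choices

* The binomial tail is computed exactly (no normal approximation); verified
  against integer-combinatorics summation to 1e−12.
* cov = 0 or spc = 0 gives p = 1; spc > cov is an invariant breach and an
  error; mean read length ≤ 1 is rejected.
* Zero-coverage contigs yield an empty peak set flagged low-coverage, never
  an exception; classification is total — every peak set maps to exactly
  one mechanism label.
* Coverage elevation returns infinity when flanks are uncovered (a contig
  that is all repeat cannot be distinguished from uniform coverage; the
  infinite ratio accepts the repeat hypothesis and the q-values carry the
  evidence).
* Parallel execution (`--core`) maps contigs over a process pool in
  submission order; results and report bytes are identical for any worker
  count. The multi-machine analogue is contract-compatible (contigs are
  independent) but not implemented.
* Edge positions (within k of a contig end) are flagged `at_edge` on peak
  calls: coverage conditioning keeps them testable, but the uniform-start
  null is mildly optimistic there because a read covering position *i* < ℓ
  can only have started at one of *i* + 1 positions. With min_cov = 10 this
  inflation is contained; callers interpreting edge peaks should weigh the
  flag.

## Known limitations

* Exact-seed mapping loses reads with an error in the first k bases; at
  realistic short-read error rates this costs sensitivity roughly
  proportional to k × error rate but does not bias peak position.
* The within-contig ambiguity rule discards reads from repeats longer than
  k; a terminus inside such a repeat is invisible.
* Headful phages whose pac-proximal end is imprecise, or whose series are
  very long, fall below the τ gate and return no signal — indistinguishable
  from random packaging by design.
* Mechanisms leaving no over-represented start (random headful, circular
  ssDNA genomes) are out of reach of the statistic itself, not just this
  implementation.
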