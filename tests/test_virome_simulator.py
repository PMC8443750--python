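"""Virion simulator: genome composition, molecule geometry per packaging
mechanism, shearing statistics, and pooled mock-virome output."""
import math
from collections import Counter

import numpy as np
import pytest

from termivore.sequence_io import read_fasta, reverse_complement, stream_reads
from termivore.virome_simulator import (
    Mechanism, VirionSpec, build_mock_virome, default_mock_specs,
    make_virion_molecules, shear_and_sequence, simulate_genome,
)


class TestSimulateGenome:
    def test_deterministic_for_fixed_seed(self):
        assert simulate_genome(1000, 0.5, 7) == simulate_genome(1000, 0.5, 7)

    def test_gc_content_concentrates(self):
        g = simulate_genome(100_000, 0.5, 3)
        gc = (g.count("G") + g.count("C")) / len(g)
        assert abs(gc - 0.5) < 0.01

    def test_low_gc_limit_is_at_rich(self):
        g = simulate_genome(5000, 0.01, 3)
        assert (g.count("A") + g.count("T")) / len(g) > 0.95

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(10, 0.5, 0)


def spec_for(mech, genome_len=4000, **kw):
    base = dict(name="x", genome_len=genome_len, mechanism=mech,
                cut_pos=genome_len // 2, seed=9)
    base.update(kw)
    return VirionSpec(**base)


class TestMakeVirionMolecules:
    def test_cos_molecules_are_clonal(self):
        g = simulate_genome(4000, 0.5, 1)
        spec = spec_for(Mechanism.COS_5P, overhang_len=12)
        mols, _ = make_virion_molecules(g, spec, 3, 0)
        assert len(mols) == 3
        assert mols[0] == mols[1] == mols[2]

    def test_molecule_end_coordinates_encode_truth_peaks(self):
        g = simulate_genome(4000, 0.5, 1)
        for mech, kw, d_rev in (
            (Mechanism.COS_5P, dict(overhang_len=12), 12),
            (Mechanism.COS_3P, dict(overhang_len=10), -10),
            (Mechanism.DTR, dict(repeat_len=160), 159),
        ):
            spec = spec_for(mech, **kw)
            mols, truth = make_virion_molecules(g, spec, 1, 0)
            c = spec.cut_pos
            assert truth.term_fwd == c + 1
            assert truth.term_rev == c + d_rev + 1
            # first molecule base sits at the forward-terminus coordinate,
            # last base at the reverse-terminus coordinate
            assert mols[0][:25] == g[c:c + 25]
            assert mols[0][-1] == g[c + d_rev]

    def test_dtr_molecule_duplicates_repeat_reference_is_collapsed(self):
        g = simulate_genome(4000, 0.5, 1)
        spec = spec_for(Mechanism.DTR, repeat_len=160)
        mols, _ = make_virion_molecules(g, spec, 1, 0)
        assert len(mols[0]) == 4000 + 160
        c = spec.cut_pos
        assert mols[0][:160] == mols[0][4000:]  # terminal repeat twice
        assert g.count(g[c:c + 160]) == 1       # but once on the contig

    def test_pac_series_initiate_exactly_at_cut(self):
        g = simulate_genome(4000, 0.5, 1)
        spec = spec_for(Mechanism.HEADFUL_PAC, series_len=4)
        mols, truth = make_virion_molecules(g, spec, 40, 0)
        c = spec.cut_pos
        n_at_pac = sum(m[:30] == g[c:c + 30] for m in mols)
        assert n_at_pac == 10  # exactly 1 in series_len
        assert truth.term_fwd == c + 1 and truth.term_rev is None

    def test_random_headful_shares_no_end(self):
        g = simulate_genome(4000, 0.5, 1)
        spec = spec_for(None)
        mols, truth = make_virion_molecules(g, spec, 50, 0)
        starts = Counter(m[:20] for m in mols)
        assert max(starts.values()) <= 2  # no common exact start
        assert truth.expected_call is Mechanism.NO_SIGNAL

    def test_genome_spec_mismatch_rejected(self):
        g = simulate_genome(4000, 0.5, 1)
        with pytest.raises(ValueError):
            make_virion_molecules(g, spec_for(None, genome_len=5000,
                                              cut_pos=0), 5, 0)


class TestShearAndSequence:
    def test_requested_pair_count_is_emitted(self):
        mols = [simulate_genome(2000, 0.5, 2)]
        r1, r2 = shear_and_sequence(mols, 500, seed=4)
        assert len(r1) == len(r2) == 500

    def test_error_free_reads_are_substrings_of_molecules(self):
        mols = [simulate_genome(2000, 0.5, 2), simulate_genome(3000, 0.5, 3)]
        r1, r2 = shear_and_sequence(mols, 300, seed=4)
        joined = "|".join(mols)
        for (_, s1), (_, s2) in zip(r1, r2):
            assert s1 in joined
            assert reverse_complement(s2) in joined

    def test_end_pinned_fraction_matches_analytic_count(self):
        """P(fragment starts at the molecule's first base) under the
        clipped-uniform window equals E_f[(f-r+1)/(L+f-2r+1)] over the
        truncated fragment-length distribution; verified by enumeration."""
        L, read_len, mu, sd = 2000, 75, 400.0, 100.0
        mols = [simulate_genome(L, 0.5, 2)]
        n = 60_000
        r1, _ = shear_and_sequence(mols, n, frag_mu=mu, frag_sd=sd,
                                   read_len=read_len, seed=11)
        left = mols[0][:read_len]
        hits = sum(s == left for _, s in r1)
        # analytic oracle: enumerate the discretized truncated normal
        fs = np.arange(read_len, L + 1)
        w = np.exp(-0.5 * ((fs - mu) / sd) ** 2)
        w /= w.sum()
        p_left = float(np.sum(w * (fs - read_len + 1)
                              / (L + fs - 2 * read_len + 1)))
        sigma = math.sqrt(n * p_left * (1 - p_left))
        assert abs(hits - n * p_left) < 5 * sigma
        # and the scale is ~ one end-anchored fragment per expected
        # fragment count, the physical shearing rate
        assert 0.5 / (L / mu) < hits / n < 2.0 / (L / mu)

    def test_substitution_errors_change_bases_at_requested_rate(self):
        mols = [simulate_genome(2000, 0.5, 2)]
        clean_r1, _ = shear_and_sequence(mols, 400, seed=6, error_rate=0.0)
        noisy_r1, _ = shear_and_sequence(mols, 400, seed=6, error_rate=0.05)
        diffs = sum(a != b for (_, s1), (_, s2) in zip(clean_r1, noisy_r1)
                    for a, b in zip(s1, s2))
        total = sum(len(s) for _, s in clean_r1)
        assert 0.03 < diffs / total < 0.07

    def test_read_longer_than_fragment_mean_rejected(self):
        with pytest.raises(ValueError):
            shear_and_sequence([simulate_genome(2000, 0.5, 2)], 10,
                               frag_mu=50.0, read_len=75)


class TestBuildMockVirome:
    def test_pooled_counts_truth_rows_and_reproducibility(self, tmp_path):
        specs = default_mock_specs(n_read_pairs=200, genome_len=3000, seed=2)
        paths = build_mock_virome(specs, tmp_path / "m", seed=2,
                                  n_molecules=40)
        reads = list(stream_reads(paths["r1"], paths["r2"]))
        assert len(reads) == 5 * 200
        contigs = read_fasta(paths["fasta"])
        assert [c.id for c in contigs] == [s.name for s in specs]
        truth_lines = paths["truth"].read_text().strip().splitlines()
        assert len(truth_lines) == 1 + len(specs)
        # byte-for-byte reproducible at fixed seed
        paths2 = build_mock_virome(specs, tmp_path / "m2", seed=2,
                                   n_molecules=40)
        assert paths["r1"].read_bytes() == paths2["r1"].read_bytes()
        assert paths["r2"].read_bytes() == paths2["r2"].read_bytes()

    def test_changing_seed_changes_reads_not_truth(self, tmp_path):
        specs = default_mock_specs(n_read_pairs=100, genome_len=3000, seed=2)
        a = build_mock_virome(specs, tmp_path / "a", seed=1, n_molecules=20)
        b = build_mock_virome(specs, tmp_path / "b", seed=9, n_molecules=20)
        assert a["r1"].read_bytes() != b["r1"].read_bytes()
        assert a["truth"].read_text() == b["truth"].read_text()

    def test_duplicate_names_rejected(self, tmp_path):
        spec = spec_for(None, genome_len=3000, cut_pos=0)
        with pytest.raises(ValueError, match="duplicate"):
            build_mock_virome([spec, spec], tmp_path / "d")
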