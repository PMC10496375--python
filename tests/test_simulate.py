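"""Synthetic-data generator: determinism, planted structure, coverage
model and mixture draws."""

import numpy as np
import pytest

from virago.genome import revcomp
from virago.panhandle import panhandle_align
from virago.segments import rpkm
from virago.simulate import (
    LBV4_SPEC,
    OSTRAVIRUS_SPEC,
    QINVIRUS_SPEC,
    TLV_SPEC,
    IsolateSimSpec,
    ReassortmentSpec,
    VirusSpec,
    gen_clone_screen,
    gen_isolate_reads,
    gen_strains,
    gen_virus,
)


class TestGenVirus:
    def test_deterministic_byte_identical(self):
        a = gen_virus(LBV4_SPEC, 7)
        b = gen_virus(LBV4_SPEC, 7)
        assert [s.sequence for s in a.segments] == [s.sequence for s in b.segments]
        c = gen_virus(LBV4_SPEC, 8)
        assert [s.sequence for s in a.segments] != [s.sequence for s in c.segments]

    def test_perfect_panhandle_without_bulges(self):
        spec = VirusSpec(name="V", n_segments=1, segment_lengths=(1200,),
                         panhandle_len=20, n_bulges=0)
        g = gen_virus(spec, 3)
        d = panhandle_align(g.segments[0].sequence, window=20)
        assert d.n_pairs == 20
        assert d.n_mismatches == 0
        assert d.bulges == []

    def test_three_prime_terminus_is_revcomp_of_five_prime(self):
        spec = VirusSpec(name="V", n_segments=1, segment_lengths=(1200,),
                         panhandle_len=25, n_bulges=0)
        seq = gen_virus(spec, 5).segments[0].sequence
        assert seq[-25:] == revcomp(seq[:25])

    def test_canonical_octamer_planted(self):
        g = gen_virus(LBV4_SPEC, 11)
        for seg in g.segments:
            d = panhandle_align(seg.sequence, window=26)
            assert d.canonical_octamer_match
            assert d.octamer_distance == 0

    def test_seven_segment_genome_conserves_lengths(self):
        g = gen_virus(OSTRAVIRUS_SPEC, 1)
        assert len(g.segments) == 7
        assert g.total_length == sum(OSTRAVIRUS_SPEC.segment_lengths)
        for seg, L in zip(g.segments, OSTRAVIRUS_SPEC.segment_lengths):
            assert len(seg) == L
            assert seg.sequence.startswith("AAAGAAAAAAC")

    def test_every_segment_carries_long_orf(self):
        from virago.segments import find_orfs

        for spec in (TLV_SPEC, LBV4_SPEC, QINVIRUS_SPEC):
            g = gen_virus(spec, 2)
            for seg in g.segments:
                assert any(o.aa_len >= 100 for o in find_orfs(seg.sequence))

    def test_segment_too_short_rejected_with_sizing_diagnostic(self):
        with pytest.raises(ValueError, match="nt"):
            VirusSpec(name="V", n_segments=1, segment_lengths=(50,),
                      panhandle_len=25)


class TestGenStrains:
    def test_zero_rate_identity(self):
        genome = gen_virus(TLV_SPEC, 1)
        rspec = ReassortmentSpec(
            n_strains=3,
            per_segment_topologies={"seg1": "T", "seg2": "T"},
            mutation_rate=0.0,
        )
        strains, _ = gen_strains(genome, rspec, seed=1)
        for g in strains.values():
            assert [s.sequence for s in g.segments] == [
                s.sequence for s in genome.segments
            ]

    def test_true_trees_returned_per_segment(self):
        genome = gen_virus(TLV_SPEC, 1)
        rspec = ReassortmentSpec(
            n_strains=4,
            per_segment_topologies={"seg1": "A", "seg2": "B"},
        )
        strains, trees = gen_strains(genome, rspec, seed=2)
        assert set(trees) == {"seg1", "seg2"}
        assert len(strains) == 4
        assert set(trees["seg1"].taxa) == set(strains)

    def test_saturating_rate_rejected(self):
        genome = gen_virus(TLV_SPEC, 1)
        rspec = ReassortmentSpec(
            n_strains=4,
            per_segment_topologies={"seg1": "T", "seg2": "T"},
            internal_branch_scale=2.0, mutation_rate=2.0,
        )
        with pytest.raises(ValueError, match="saturated"):
            gen_strains(genome, rspec, seed=3)

    def test_divergence_scales_with_rate(self):
        genome = gen_virus(TLV_SPEC, 1)
        def mean_div(rate):
            rspec = ReassortmentSpec(
                n_strains=2, per_segment_topologies={"seg1": "T", "seg2": "T"},
                internal_branch_scale=0.0001, mutation_rate=rate)
            strains, _ = gen_strains(genome, rspec, seed=4)
            a, b = [g.segments[0].sequence for g in strains.values()]
            return sum(x != y for x, y in zip(a, b)) / len(a)
        assert mean_div(0.01) < mean_div(0.1) < mean_div(0.5)


class TestGenIsolateReads:
    def test_read_conservation(self):
        genomes = [gen_virus(TLV_SPEC, 1), gen_virus(QINVIRUS_SPEC, 1)]
        sim = IsolateSimSpec(viruses_present=frozenset({"TLV", "QIN"}),
                             abundance={"TLV": 2.0, "QIN": 1.0},
                             total_reads=100_000)
        cs = gen_isolate_reads(genomes, sim, seed=5)
        assert sum(c.mapped_reads for c in cs) == 100_000

    def test_rpkm_tracks_abundance_ratio(self):
        genomes = [gen_virus(TLV_SPEC, 1), gen_virus(QINVIRUS_SPEC, 1)]
        for seed in range(20):
            sim = IsolateSimSpec(viruses_present=frozenset({"TLV", "QIN"}),
                                 abundance={"TLV": 100.0, "QIN": 1.0},
                                 total_reads=50_000)
            cs = gen_isolate_reads(genomes, sim, seed=seed)
            tlv = np.mean([rpkm(c.mapped_reads, len(c), cs.total_mapped_reads)
                           for c in cs if c.id.startswith("TLV")])
            qin = np.mean([rpkm(c.mapped_reads, len(c), cs.total_mapped_reads)
                           for c in cs if c.id.startswith("QIN")])
            assert 50 <= tlv / qin <= 200

    def test_zero_reads_zero_coverage(self):
        genomes = [gen_virus(TLV_SPEC, 1)]
        sim = IsolateSimSpec(viruses_present=frozenset({"TLV"}), total_reads=0)
        cs = gen_isolate_reads(genomes, sim, seed=1)
        assert all(c.mapped_reads == 0 for c in cs)
        assert all(c.depth.sum() == 0 for c in cs)

    def test_satellite_without_helper_omitted_with_warning(self):
        genomes = [gen_virus(OSTRAVIRUS_SPEC, 1)]
        sim = IsolateSimSpec(viruses_present=frozenset({"OV"}),
                             total_reads=1000)
        with pytest.warns(UserWarning, match="satellite"):
            cs = gen_isolate_reads(genomes, sim, seed=1)
        assert len(cs) == 0

    def test_satellite_with_helper_emitted(self):
        genomes = [gen_virus(OSTRAVIRUS_SPEC, 1), gen_virus(TLV_SPEC, 1)]
        sim = IsolateSimSpec(viruses_present=frozenset({"OV", "TLV"}),
                             total_reads=1000)
        cs = gen_isolate_reads(genomes, sim, seed=1)
        assert any(c.id.startswith("OV") for c in cs)

    def test_empty_genome_set_rejected(self):
        sim = IsolateSimSpec(viruses_present=frozenset({"TLV"}))
        with pytest.raises(ValueError, match="no genomes"):
            gen_isolate_reads([], sim, seed=1)

    def test_coverage_depth_matches_expectation(self):
        genomes = [gen_virus(TLV_SPEC, 1)]
        sim = IsolateSimSpec(viruses_present=frozenset({"TLV"}),
                             total_reads=10_000)
        cs = gen_isolate_reads(genomes, sim, read_len=150, seed=6)
        for c in cs:
            expected = c.mapped_reads * 150 / len(c)
            assert c.mean_depth == pytest.approx(expected, rel=0.05)


class TestGenCloneScreen:
    def test_all_both_pattern(self):
        sim = IsolateSimSpec(
            viruses_present=frozenset({"A", "B"}),
            cell_mixture={("A", "B"): 1.0},
        )
        screen = gen_clone_screen(sim, n_clones=8, seed=1)
        assert screen.presence.all()

    def test_mixture_coverage_probability(self):
        """With a uniform 4-pattern mixture and 8 clones the chance that a
        screen shows all four patterns is 1 - 4(3/4)^8 + 6(1/2)^8 - 4(1/4)^8
        (inclusion-exclusion); the empirical rate over 1000 seeded screens
        must match, and every pattern must appear somewhere."""
        sim = IsolateSimSpec(
            viruses_present=frozenset({"A", "B"}),
            cell_mixture={(): 0.25, ("A",): 0.25, ("B",): 0.25,
                          ("A", "B"): 0.25},
        )
        expect = 1 - 4 * 0.75**8 + 6 * 0.5**8 - 4 * 0.25**8
        from virago.clones import classify_clones

        full = 0
        seen = set()
        for seed in range(1000):
            screen = gen_clone_screen(sim, n_clones=8, seed=seed)
            cls = classify_clones(screen)
            seen |= set(cls.census)
            if len(cls.census) == 4:
                full += 1
        assert len(seen) == 4
        assert full / 1000 == pytest.approx(expect, abs=0.05)

    def test_nonpositive_clone_count_rejected(self):
        sim = IsolateSimSpec(viruses_present=frozenset({"A"}),
                             cell_mixture={("A",): 1.0})
        with pytest.raises(ValueError, match="positive"):
            gen_clone_screen(sim, n_clones=0, seed=1)

    def test_detection_threshold_hides_low_abundance_virus(self):
        sim = IsolateSimSpec(
            viruses_present=frozenset({"A", "B"}),
            cell_mixture={("A", "B"): 1.0},
        )
        screen = gen_clone_screen(sim, n_clones=200, seed=2,
                                  detect_prob={"A": 0.2})
        frac_a = screen.presence[:, screen.viruses.index("A")].mean()
        frac_b = screen.presence[:, screen.viruses.index("B")].mean()
        assert frac_b == 1.0
        assert frac_a == pytest.approx(0.2, abs=0.1)


class TestSpecValidation:
    def test_abundance_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            IsolateSimSpec(viruses_present=frozenset({"A"}),
                           abundance={"A": 0.0})

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            IsolateSimSpec(viruses_present=frozenset({"A"}),
                           cell_mixture={("A",): 0.7})

    def test_octamer_must_be_8nt(self):
        with pytest.raises(ValueError, match="8 nt"):
            VirusSpec(name="V", n_segments=1, segment_lengths=(1000,),
                      terminal_octamer="ACACA")

    def test_stream_isolation_between_operations(self):
        """Interleaving extra generator calls does not perturb others."""
        a1 = gen_virus(TLV_SPEC, 9)
        gen_virus(LBV4_SPEC, 9)  # unrelated extra call
        a2 = gen_virus(TLV_SPEC, 9)
        assert a1.segments[0].sequence == a2.segments[0].sequence
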