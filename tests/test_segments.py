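"""Segment identification: RPKM, terminal motifs, band matching, ORFs,
alignment column statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virago.genome import revcomp
from virago.segments import (
    Contig,
    ContigSet,
    call_segments,
    find_orfs,
    find_terminal_motif,
    match_bands,
    pairwise_identity,
    rpkm,
    variable_sites,
)
from ._oracles import naive_motif_hits

MOTIF = "AAAGAAAAAAC"


def _cs(seqs, reads=None, total=1_000_000):
    contigs = [
        Contig(id=f"c{i}", sequence=s,
               mapped_reads=0 if reads is None else reads[i])
        for i, s in enumerate(seqs)
    ]
    return ContigSet(contigs=contigs, total_mapped_reads=total)


class TestRPKM:
    @pytest.mark.parametrize(
        "reads,length,total,expected",
        [(1000, 1000, 10**6, 1000.0), (0, 500, 10**6, 0.0),
         (500, 2000, 10**7, 25.0)],
    )
    def test_formula(self, reads, length, total, expected):
        assert rpkm(reads, length, total) == expected

    def test_scale_invariance(self):
        """Doubling mapped and total reads everywhere leaves RPKM fixed."""
        assert rpkm(300, 1500, 10**6) == rpkm(600, 1500, 2 * 10**6)

    def test_zero_length_or_total_rejected(self):
        with pytest.raises(ValueError):
            rpkm(10, 0, 10**6)
        with pytest.raises(ValueError):
            rpkm(10, 100, 0)


class TestTerminalMotif:
    def test_five_prime_forward_hit(self):
        cs = _cs([MOTIF + "G" * 200])
        hits = find_terminal_motif(cs, MOTIF)
        assert any(h.end == "5p" and h.orientation == "fwd" and h.offset == 0
                   for h in hits)

    def test_three_prime_revcomp_hit(self):
        cs = _cs(["G" * 200 + revcomp(MOTIF)])
        hits = find_terminal_motif(cs, MOTIF)
        assert any(h.end == "3p" and h.orientation == "rc" for h in hits)

    def test_absent_motif_empty(self):
        cs = _cs(["G" * 200])
        assert find_terminal_motif(cs, MOTIF) == []

    def test_interior_motif_not_reported(self):
        cs = _cs(["G" * 50 + MOTIF + "G" * 50])
        assert find_terminal_motif(cs, MOTIF, max_offset=3) == []

    def test_short_motif_rejected(self):
        with pytest.raises(ValueError, match="6 nt"):
            find_terminal_motif(_cs(["ACGT" * 30]), "ACGT")

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=12, max_size=200),
        offset=st.integers(min_value=0, max_value=5),
    )
    def test_matches_naive_scan_oracle(self, seq, offset):
        cs = _cs([seq])
        mine = {(h.end, h.orientation, h.offset)
                for h in find_terminal_motif(cs, MOTIF, max_offset=offset)}
        assert mine == naive_motif_hits(seq, MOTIF, offset)


class TestMatchBands:
    def test_contig_matches_nearest_band(self):
        cs = _cs(["A" * 3470])
        res = match_bands(cs, [3.5, 2.2])
        assert res.assignments["c0"] == 3.5

    def test_out_of_tolerance_unmatched(self):
        cs = _cs(["A" * 5000])
        res = match_bands(cs, [3.5, 2.2])
        assert res.assignments["c0"] is None

    def test_tie_breaks_toward_larger_band(self):
        cs = _cs(["A" * 3000])  # 3.0 kb, equidistant rel to none; construct tie
        res = match_bands(cs, [3.0, 3.0])
        assert res.assignments["c0"] == 3.0

    def test_perfect_rank_agreement_gives_rho_one(self):
        seqs = ["A" * 3000, "C" * 2000, "G" * 1000]
        cs = _cs(seqs, reads=[9000, 4000, 1000])
        ranks = {3.0: 1, 2.0: 2, 1.0: 3}  # brightest = highest coverage
        res = match_bands(cs, [3.0, 2.0, 1.0], brightness_ranks=ranks)
        assert res.spearman_rho == pytest.approx(1.0)
        assert all("coverage" in res.criteria[c.id] for c in cs)

    def test_negative_band_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            match_bands(_cs(["A" * 100]), [-1.0])


class TestFindORFs:
    def test_planted_single_long_orf(self):
        from virago.simulate import QINVIRUS_SPEC, gen_virus

        g = gen_virus(QINVIRUS_SPEC, 1)
        lens = [o.aa_len for o in find_orfs(g.segments[0].sequence)]
        assert 1679 in lens

    def test_two_orfs_in_one_frame_separated_by_stop(self):
        from virago.simulate import QINVIRUS_SPEC, gen_virus

        g = gen_virus(QINVIRUS_SPEC, 1)
        lens = [o.aa_len for o in find_orfs(g.segments[1].sequence)]
        assert 375 in lens and 231 in lens

    def test_all_n_sequence_empty(self):
        assert find_orfs("N" * 600) == []

    def test_minus_strand_orf_found_with_forward_coordinates(self):
        rng = np.random.default_rng(0)
        from virago.simulate import _codon_string

        orf = "ATG" + _codon_string(149, rng) + "TAA"
        seq = "TTTTT" + revcomp(orf) + "TTTTT"
        hits = [o for o in find_orfs(seq) if o.strand == "-"]
        assert hits and hits[0].aa_len == 150
        o = hits[0]
        assert revcomp(seq[o.start:o.end]).startswith("ATG")

    def test_sorted_by_length_descending(self):
        from virago.simulate import QINVIRUS_SPEC, gen_virus

        g = gen_virus(QINVIRUS_SPEC, 1)
        lens = [o.aa_len for o in find_orfs(g.segments[1].sequence)]
        assert lens == sorted(lens, reverse=True)


class TestVariableSites:
    def test_identical_sequences_zero(self):
        assert variable_sites(["ACGT" * 5, "ACGT" * 5]) == 0.0

    def test_single_difference_percent(self):
        assert variable_sites(["AAAAAAAAAA", "AAAAAAAAAC"]) == 10.0

    def test_matches_columnwise_oracle_on_random_alignments(self, rng):
        for _ in range(25):
            n, L = 4, 50
            mat = rng.choice(list("ACGT-"), size=(n, L), p=[0.23]*4 + [0.08])
            seqs = ["".join(row) for row in mat]
            # independent column scan
            var = tot = 0
            for j in range(L):
                col = [s[j] for s in seqs if s[j] != "-"]
                if not col:
                    continue
                tot += 1
                if len(set(col)) > 1:
                    var += 1
            expected = 100.0 * var / tot if tot else 0.0
            assert variable_sites(seqs) == pytest.approx(expected)

    def test_amino_acid_level_translates_first(self):
        a = "ATGGCTGCT"   # M A A
        b = "ATGGCAGCT"   # M A A (synonymous change)
        assert variable_sites([a, b], level="nt") > 0
        assert variable_sites([a, b], level="aa") == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            variable_sites(["ACGT", "ACG"])


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGT", "ACGT") == 100.0

    def test_nine_of_ten(self):
        assert pairwise_identity("AAAAAAAAAA", "AAAAAAAAAC") == 90.0

    def test_gap_columns_excluded_from_denominator(self):
        assert pairwise_identity("AC-GT-ACGT", "ACCGTAACGT") == 100.0

    def test_unaligned_unequal_directs_to_aligner(self):
        with pytest.raises(ValueError, match="align"):
            pairwise_identity("ACGT", "ACGTA", aligned=False)


class TestCallSegments:
    def test_all_three_criteria_on_planted_segments(self):
        from virago.simulate import (
            OSTRAVIRUS_SPEC, TLV_SPEC, IsolateSimSpec, gen_isolate_reads,
            gen_virus,
        )

        genomes = [gen_virus(OSTRAVIRUS_SPEC, 1), gen_virus(TLV_SPEC, 1)]
        sim = IsolateSimSpec(viruses_present=frozenset({"OV", "TLV"}),
                             abundance={"TLV": 100.0, "OV": 1.0},
                             total_reads=200_000)
        cs = gen_isolate_reads(genomes, sim, seed=3)
        bands = [3.5, 2.2, 5.0, 4.2, 4.0, 3.0, 2.4, 1.6, 1.3]
        # the abundant helper virus's bands are bright (rank 1), the rare
        # satellite's bands dim (rank 2, tied within the virus): coverage
        # should rank the same way
        ranks = {3.5: 1, 2.2: 1, 5.0: 2, 4.2: 2, 4.0: 2, 3.0: 2, 2.4: 2,
                 1.6: 2, 1.3: 2}
        calls = call_segments(cs, bands_kb=bands, motif=MOTIF,
                              brightness_ranks=ranks)
        ov = [c for c in calls if c.contig_id.startswith("OV")]
        assert len(ov) == 7
        for call in ov:
            assert call.criteria_passed == {"length", "coverage", "terminus"}
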