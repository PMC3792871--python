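"""Degenerate primer design: consensus/degeneracy, nearest-neighbor Tm
against the Biopython oracle, hairpin/dimer screens, intron mapping, and
pair enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from markermine.primers import (
    PrimerConstraints,
    conservation_profile,
    consensus_primer,
    degeneracy,
    design_pairs,
    dimer_screen,
    encode_pcr_program,
    expansions,
    hairpin_screen,
    map_introns,
    parse_pcr_program,
    project_introns,
    tm_nn,
)
from markermine.seqcore import IUPAC_SETS, MultipleAlignment, Sequence, revcomp_str

PRIMER = st.text(alphabet="ACGTRYSWKM", min_size=1, max_size=12)


def _aln(*rows):
    return MultipleAlignment(
        rows=[Sequence(f"r{i}", r) for i, r in enumerate(rows)]
    )


class TestConservation:
    def test_invariant_column_scores_one(self):
        assert conservation_profile(_aln("A", "A", "A"))[0] == 1.0

    def test_gap_forces_zero(self):
        assert conservation_profile(_aln("A", "-", "A"))[0] == 0.0

    def test_two_state_column_is_fully_conserved(self):
        assert conservation_profile(_aln("A", "G", "A", "G"))[0] == 1.0

    def test_three_state_column_scores_below_one(self):
        p = conservation_profile(_aln("A", "C", "G"))[0]
        assert p == pytest.approx(2 / 3)


class TestConsensus:
    def test_identical_rows(self):
        assert consensus_primer(_aln("ACGT", "ACGT"), (0, 4)) == "ACGT"

    def test_two_state_column_becomes_code(self):
        assert consensus_primer(_aln("GGACC", "GGGCC"), (0, 5)) == "GGRCC"

    def test_gapped_window_refused(self):
        with pytest.raises(ValueError, match="gap"):
            consensus_primer(_aln("AC-T", "ACGT"), (0, 4))

    def test_minimal_cover_property(self):
        aln = _aln("ACGT", "ATGT", "GCGA")
        cons = consensus_primer(aln, (0, 4))
        for j in range(4):
            observed = {r.residues[j] for r in aln.rows}
            covered = IUPAC_SETS[cons[j]]
            union = set().union(*(IUPAC_SETS[o] for o in observed))
            assert union == covered  # minimal: exactly the observed set


class TestDegeneracy:
    def test_published_primer_has_eight_expansions(self):
        # S, Y, R each double the count
        assert degeneracy("GGACCTGGSCTYGCTGARGAGTG") == 8

    @pytest.mark.parametrize("p, d", [("ACGT", 1), ("NN", 16), ("RYSW", 16)])
    def test_examples(self, p, d):
        assert degeneracy(p) == d
        assert len(expansions(p)) == d

    def test_gap_is_an_error(self):
        with pytest.raises(ValueError):
            degeneracy("AC-T")

    @given(PRIMER, PRIMER)
    @settings(max_examples=40, deadline=None)
    def test_multiplicative_over_concatenation(self, x, y):
        assert degeneracy(x + y) == degeneracy(x) * degeneracy(y)

    def test_cap_is_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            expansions("N" * 6, cap=1024)


class TestMeltingTemperature:
    def _oracle(self, seq, na_mM=50.0, primer_nM=500.0):
        # independent implementation path: Biopython with the same
        # published table (SantaLucia & Hicks 2004) and salt correction
        from Bio.SeqUtils import MeltingTemp as mt

        half = primer_nM / 2.0
        return mt.Tm_NN(seq, nn_table=mt.DNA_NN4, Na=na_mM,
                        dnac1=half, dnac2=half, saltcorr=5)

    @pytest.mark.parametrize(
        "seq",
        ["AGCGTACCGTTAGCCATGCA", "ACGTACGTACGTACGTAA", "GGCCGGCCAATTGGCCAT"],
    )
    def test_matches_independent_oracle(self, seq):
        assert tm_nn(seq).mean == pytest.approx(self._oracle(seq), abs=0.1)

    def test_oracle_agreement_on_random_primers(self, rng):
        for _ in range(25):
            seq = random_dna(int(rng.integers(16, 30)), rng)
            assert tm_nn(seq).mean == pytest.approx(
                self._oracle(seq), abs=0.1
            )

    def test_gc_rich_melts_higher_than_at_only(self):
        at = tm_nn("A" * 18)
        gc = tm_nn("GC" * 9)
        assert at.max < gc.min

    def test_summary_ordering_and_degenerate_extremes(self):
        s = tm_nn("ACGTRYACGTACGTACGTAC")
        assert s.min <= s.mean <= s.max
        assert s.n_expansions == 4
        # mean equals the average over explicit expansions
        tms = [tm_nn(e).mean for e in expansions("ACGTRYACGTACGTACGTAC")]
        assert s.mean == pytest.approx(np.mean(tms), abs=1e-9)

    def test_single_sequence_summary_is_degenerate(self):
        s = tm_nn("ACGTACGTACGTACGTACGT")
        assert s.min == s.mean == s.max


class TestHairpinAndDimers:
    def test_stem_of_four_with_loop_flags(self):
        flagged, stem = hairpin_screen("GGGGAAATTTCCCC")
        assert flagged and stem >= 4

    @pytest.mark.parametrize("seq", ["ATATAT", "AAAAAAAAAAAA"])
    def test_short_or_unstructured_not_flagged(self, seq):
        assert hairpin_screen(seq)[0] is False

    def test_revcomp_dimer_is_maximal(self):
        s = "ACGGTCAGTT"
        score = dimer_screen(s, revcomp_str(s))
        assert score == len(s) + 1  # full pairing + one long-run bonus

    def test_unpairable_sequences_score_zero(self):
        assert dimer_screen("AAAAAA", "CCCCCC") == 0.0

    def test_self_dimer_matches_offset_oracle(self):
        seq = "ACGTACGT"

        def oracle(a, b):
            br = b[::-1]
            best = 0.0
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            for off in range(-(len(br) - 1), len(a)):
                lo, hi = max(0, off), min(len(a), off + len(br))
                paired = [comp[a[i]] == br[i - off] for i in range(lo, hi)]
                sc = float(sum(paired))
                run = 0
                for p in paired + [False]:
                    if p:
                        run += 1
                    else:
                        if run >= 4:
                            sc += 1
                        run = 0
                best = max(best, sc)
            return best

        assert dimer_screen(seq, seq) == oracle(seq, seq)

    def test_anchored_variant_requires_terminal_pairing(self):
        # 3' end of seq_a is A; b offers no T anywhere
        assert dimer_screen("GGGA", "GGGG", anchored_3prime=True) == 0.0
        assert dimer_screen("GGGA", "TCCC", anchored_3prime=True) > 0.0


class TestIntronMapping:
    def test_planted_intron_recovered_exactly(self, rng):
        exon1, exon2 = random_dna(200, rng), random_dna(180, rng)
        intron = "GTAAG" + random_dna(110, rng) + "TTCAG"
        cdna = exon1 + exon2
        genomic = exon1 + intron + exon2
        (i,) = map_introns(genomic, cdna)
        assert (i.genomic_start, i.genomic_end) == (200, 200 + 120)
        assert i.canonical and i.cdna_pos == 200

    def test_identical_sequences_give_empty_map(self, rng):
        s = random_dna(300, rng)
        assert len(map_introns(s, s)) == 0

    def test_shiftable_boundary_lands_on_gt_ag(self, rng):
        # micro-homology: intron starts with the same bases that follow
        # it in the exon, so the aligner's gap placement is ambiguous
        exon1 = random_dna(150, rng) + "CAG"
        exon2 = "CAGTT" + random_dna(150, rng)
        intron = "GT" + random_dna(80, rng) + "AG"
        genomic = exon1 + intron + exon2
        cdna = exon1 + exon2
        (i,) = map_introns(genomic, cdna)
        assert genomic[i.genomic_start:i.genomic_start + 2] == "GT"
        assert genomic[i.genomic_end - 2:i.genomic_end] == "AG"
        assert cdna == genomic[:i.genomic_start] + genomic[i.genomic_end:]

    def test_divergent_inputs_error(self, rng):
        with pytest.raises(ValueError, match="divergent"):
            map_introns(random_dna(200, rng), random_dna(200, rng))

    def test_two_introns(self, rng):
        e1, e2, e3 = (random_dna(150, rng) for _ in range(3))
        i1 = "GTAAG" + random_dna(60, rng) + "TTCAG"
        i2 = "GTAAG" + random_dna(90, rng) + "TTCAG"
        genomic = e1 + i1 + e2 + i2 + e3
        imap = map_introns(genomic, e1 + e2 + e3)
        assert [(i.genomic_start, i.genomic_end) for i in imap] == [
            (150, 220), (370, 470)
        ]


class TestProjection:
    def test_identity_mapping_without_gaps(self, rng):
        from markermine.primers import Intron, IntronMap

        imap = IntronMap(introns=[Intron(10, 100, 5, "GT", "AG")])
        assert project_introns(imap, "ACGTACGTAC") == [5]

    def test_alignment_gap_shifts_position(self):
        from markermine.primers import Intron, IntronMap

        imap = IntronMap(introns=[Intron(10, 100, 3, "GT", "AG")])
        # three residues, then a 10-column gap, then more residues
        row = "ACG" + "-" * 10 + "TACGT"
        assert project_introns(imap, row) == [13]


class TestDesignPairs:
    def _conserved_alignment(self, rng, n_rows=8, ncols=260, n_var=12):
        base = random_dna(ncols, rng)
        var_cols = rng.choice(ncols, size=n_var, replace=False)
        rows = []
        for i in range(n_rows):
            chars = list(base)
            for j in var_cols:
                if rng.random() < 0.5:
                    chars[j] = {"A": "G", "G": "A", "C": "T",
                                "T": "C"}[chars[j]]
            rows.append(Sequence(f"sp{i}", "".join(chars)))
        return MultipleAlignment(rows=rows)

    def test_conserved_flanks_yield_bracketing_pair(self, rng):
        aln = self._conserved_alignment(rng)
        res = design_pairs(aln, [130], PrimerConstraints(product_min=50))
        assert res.pairs
        p = res.pairs[0]
        assert p.fwd_window[1] <= 130 <= p.rev_window[0]

    def test_all_variable_alignment_rejects_everything(self, rng):
        rows = [Sequence(f"r{i}", random_dna(120, rng)) for i in range(6)]
        res = design_pairs(MultipleAlignment(rows=rows), [60])
        assert res.pairs == [] and sum(res.rejections.values()) > 0

    def test_raising_degeneracy_cap_never_removes_pairs(self, rng):
        aln = self._conserved_alignment(rng)
        lo = design_pairs(aln, [130], PrimerConstraints(product_min=50,
                                                        max_degeneracy=4))
        hi = design_pairs(aln, [130], PrimerConstraints(product_min=50,
                                                        max_degeneracy=96))
        assert len(hi.pairs) >= len(lo.pairs)

    def test_emitted_pairs_pass_independent_rescreen(self, rng):
        aln = self._conserved_alignment(rng)
        cons = PrimerConstraints(product_min=50)
        res = design_pairs(aln, [130], cons)
        for p in res.pairs[:5]:
            for primer, rep in ((p.forward, p.thermo_fwd),
                                (p.reverse, p.thermo_rev)):
                assert cons.min_len <= len(primer) <= cons.max_len
                assert degeneracy(primer) <= cons.max_degeneracy
                assert cons.tm_min <= tm_nn(primer).mean <= cons.tm_max
                assert not hairpin_screen(primer)[0]
                assert dimer_screen(primer, primer) <= cons.max_self_dimer
            assert abs(p.thermo_fwd.tm.mean - p.thermo_rev.tm.mean) <= \
                cons.max_pair_tm_diff
            assert dimer_screen(p.forward, p.reverse) <= \
                cons.max_hetero_dimer


class TestPcrProgram:
    def test_published_code_parses(self):
        assert parse_pcr_program("6512035") == (65, 120, 35)

    def test_round_trip(self):
        assert parse_pcr_program(encode_pcr_program(55, 60, 40)) == (55, 60, 40)

    def test_bad_code_rejected(self):
        with pytest.raises(ValueError):
            parse_pcr_program("12ab")
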