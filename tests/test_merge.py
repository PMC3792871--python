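"""Tree-guided fragment merging, chimera flagging, duplication reports,
and supermatrix concatenation."""

import numpy as np
import pytest

from markermine.merge import (
    ConflictError,
    DuplicationReport,
    FragmentSet,
    candidate_groups,
    concat_loci,
    conflicts,
    extract_copy_alignment,
    flag_duplications,
    iterate_merge,
    merge_group,
)
from markermine.seqcore import MultipleAlignment, Sequence
from markermine.trees import mp_search, parse_newick


def _fs(*rows):
    """rows = (id, accession, residues)"""
    return FragmentSet(
        MultipleAlignment(
            rows=[Sequence(i, r, accession=a) for i, a, r in rows]
        )
    )


class TestConflicts:
    def test_disjoint_coverage_has_none(self):
        fs = _fs(("a", "x", "ACGT????"), ("b", "x", "????ACGT"))
        assert conflicts(fs.alignment, "a", "b") == 0

    def test_ambiguity_is_compatible(self):
        fs = _fs(("a", "x", "ACGR"), ("b", "x", "ACGA"))
        assert conflicts(fs.alignment, "a", "b") == 0

    def test_two_mismatches_count(self):
        fs = _fs(("a", "x", "AAGT"), ("b", "x", "CAGA"))
        assert conflicts(fs.alignment, "a", "b") == 2

    def test_symmetry(self):
        fs = _fs(("a", "x", "AAGT"), ("b", "x", "CAGA"))
        assert conflicts(fs.alignment, "a", "b") == conflicts(
            fs.alignment, "b", "a"
        )

    def test_identical_rows_disallowed(self):
        fs = _fs(("a", "x", "ACGT"))
        with pytest.raises(ValueError):
            conflicts(fs.alignment, "a", "a")


class TestCandidateGroups:
    def test_sister_fragments_group(self):
        fs = _fs(
            ("x1", "x", "ACGT????"),
            ("x2", "x", "????ACGT"),
            ("y1", "y", "ACGAACGA"),
            ("z1", "z", "AGGTAGGA"),
        )
        tree = parse_newick("((x1,x2),(y1,z1));")
        groups, arb = candidate_groups(tree, fs, "x")
        assert groups == [("x1", "x2")] and not arb

    def test_split_foreign_accession_blocks_grouping(self):
        # y keeps two separated rows inside the clade spanned by x's rows:
        # the duplication signature, so x must not merge across it
        fs = _fs(
            ("x1", "x", "ACGT????"),
            ("x2", "x", "????ACGT"),
            ("y1", "y", "ACGA????"),
            ("y2", "y", "????ACGA"),
            ("z1", "z", "AGGTAGGA"),
        )
        tree = parse_newick("(((x1,y1),(x2,y2)),z1);")
        groups, arb = candidate_groups(tree, fs, "x")
        assert groups == [("x1",), ("x2",)]

    def test_three_mutually_compatible_tips_form_one_group(self):
        fs = _fs(
            ("x1", "x", "ACGT????????"),
            ("x2", "x", "??GTAC??????"),
            ("x3", "x", "????ACGT????"),
            ("y1", "y", "ACGAACGAACGA"),
        )
        tree = parse_newick("((x1,x2),(x3,y1));")
        groups, _ = candidate_groups(tree, fs, "x")
        assert groups == [("x1", "x2", "x3")]

    def test_conflicting_pair_stays_apart(self):
        fs = _fs(
            ("x1", "x", "AAAA????"),
            ("x2", "x", "??CCCC??"),
            ("y1", "y", "AAAACC??"),
            ("z1", "z", "AAAACCAA"),
        )
        tree = parse_newick("((x1,x2),(y1,z1));")
        groups, _ = candidate_groups(tree, fs, "x")
        assert groups == [("x1",), ("x2",)]


class TestMergeGroup:
    def test_compatible_fragments_span_union(self):
        fs = _fs(
            ("a", "x", "ACGTAC????"),
            ("b", "x", "????ACGTAC"),
        )
        row = merge_group(fs, ("a", "b"))
        assert row.residues == "ACGTACGTAC"
        assert row.accession == "x"

    def test_ambiguity_resolves_to_intersection(self):
        fs = _fs(("a", "x", "AR"), ("b", "x", "AA"))
        assert merge_group(fs, ("a", "b")).residues == "AA"

    def test_conflict_names_the_column(self):
        fs = _fs(("a", "x", "AAAA"), ("b", "x", "AACA"))
        with pytest.raises(ConflictError, match=r"\[2\]"):
            merge_group(fs, ("a", "b"))

    def test_order_independence(self):
        fs = _fs(
            ("a", "x", "ACGT????"),
            ("b", "x", "??GTAC??"),
            ("c", "x", "????ACGT"),
        )
        import itertools

        outputs = {
            merge_group(fs, perm).residues
            for perm in itertools.permutations(("a", "b", "c"))
        }
        assert len(outputs) == 1

    def test_gap_only_where_all_rows_gapped(self):
        fs = _fs(("a", "x", "AC-?"), ("b", "x", "AC-A"))
        assert merge_group(fs, ("a", "b")).residues == "AC-A"


class TestIterateMerge:
    def test_already_merged_input_is_fixpoint(self):
        fs = _fs(
            ("a", "w", "ACGTAAAA"),
            ("b", "x", "ACGAAAAT"),
            ("c", "y", "AGGTAATA"),
            ("d", "z", "ATGTATAA"),
        )
        out, log = iterate_merge(
            fs, lambda f: mp_search(f.alignment, seed=1)[0]
        )
        assert [r.id for r in out.rows] == ["a", "b", "c", "d"]
        assert log.records == []

    def test_fig5_style_ambiguity_yields_two_chimeras(self):
        # two conflicting 5' fragments, two conflicting 3' fragments,
        # no overlap between the ends: pairing is arbitrary
        fs = _fs(
            ("f1", "x", "AAAAAAAA????????"),
            ("f2", "x", "AAAACCCC????????"),
            ("g1", "x", "????????GGGGGGGG"),
            ("g2", "x", "????????GGGGTTTT"),
            ("o1", "y", "AAAAAAAAGGGGGGGG"),
            ("o2", "z", "AAAACCCCGGGGTTTT"),
        )

        def tree_fn(f):
            have = {r.id for r in f.rows}
            if {"f1", "f2", "g1", "g2"} <= have:
                return parse_newick("(((f1,g1),(f2,g2)),(o1,o2));")
            return mp_search(f.alignment, seed=1)[0]

        out, log = iterate_merge(fs, tree_fn)
        x_rows = out.rows_of("x")
        assert len(x_rows) == 2
        assert all(log.chimera_flags.get(r) for r in x_rows)

    def test_single_copy_closure_on_synthetic_family(self, small_sim):
        from markermine.search import harvest, hits_to_alignment

        cfg, pools, truth = small_sim
        fam = truth.families["fam001"]
        ref = sorted(fam.transcripts)[0]
        query = Sequence("q", fam.transcripts[ref])
        hits = harvest([query], list(pools.values()), rounds=1)["q"]
        aln = hits_to_alignment(query, hits, list(pools.values()))
        fs = FragmentSet(aln)

        def tree_fn(f):
            return mp_search(f.alignment, n_starts=1, seed=42, ratchet=2)[0]

        out, log = iterate_merge(fs, tree_fn)
        assert all(len(out.rows_of(a)) == 1 for a in out.accessions())
        assert sum(log.chimera_flags.values()) == 0
        assert len(out.rows) < len(fs.rows)
        # merged residues equal the true transcript over covered spans
        for r in out.rows:
            tip = next(t for t in fam.transcripts
                       if t.startswith(r.accession))
            truth_seq = fam.transcripts[tip]
            for j, c in enumerate(r.residues):
                if c not in "-?":
                    assert c == truth_seq[j]

    def test_row_count_never_increases(self, small_sim):
        from markermine.search import harvest, hits_to_alignment

        cfg, pools, truth = small_sim
        fam = truth.families["fam002"]
        ref = sorted(fam.transcripts)[0]
        query = Sequence("q", fam.transcripts[ref])
        hits = harvest([query], list(pools.values()), rounds=1)["q"]
        fs = FragmentSet(hits_to_alignment(query, hits, list(pools.values())))
        counts = [len(fs.rows)]
        cur = fs
        for _ in range(5):
            cur, log = iterate_merge(
                cur, lambda f: mp_search(f.alignment, seed=42, ratchet=1)[0],
                max_rounds=1,
            )
            counts.append(len(cur.rows))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDuplications:
    def test_single_row_accessions_are_clean(self):
        fs = _fs(("a", "x", "ACGT"), ("b", "y", "ACGA"),
                 ("c", "z", "AGGT"), ("d", "w", "ATGT"))
        tree = parse_newick("((a,b),(c,d));")
        rep = flag_duplications(tree, fs)
        assert rep.flagged() == []

    def test_distant_rows_with_split_neighbors_are_flagged(self):
        fs = _fs(
            ("x1", "x", "AAAAAAAA"),
            ("x2", "x", "CCCCCCCC"),
            ("y1", "y", "AAAAAAAT"),
            ("y2", "y", "CCCCCCCT"),
            ("z1", "z", "AAAATTTT"),
        )
        tree = parse_newick("(((x1,y1),z1),(x2,y2));")
        rep = flag_duplications(tree, fs)
        assert set(rep.flagged()) == {"x", "y"}
        assert rep.entries["x"]["tip_count"] == 2

    def test_planted_root_duplication_flags_all_carriers(self):
        from markermine.simdata import SimConfig, make_pools

        cfg = SimConfig(n_taxa=6, n_families=1, dropout=0.0, loss_prob=0.0,
                        seed=7)
        pools, truth = make_pools(cfg, force_root_duplication_in="fam001")
        fam = truth.families["fam001"]
        carriers = {t.split("|")[0] for t in fam.transcripts
                    if not t.endswith("c0")}
        rows = []
        for cid, (tip, a, b, strand) in fam.fragments.items():
            seg = fam.transcripts[tip][a:b]
            rows.append(
                Sequence(cid, "?" * a + seg
                         + "?" * (cfg.transcript_length - b),
                         accession=tip.split("|")[0])
            )
        fs = FragmentSet(MultipleAlignment(rows=rows))

        def tree_fn(f):
            return mp_search(f.alignment, n_starts=1, seed=42, ratchet=2)[0]

        out, log = iterate_merge(fs, tree_fn)
        tree = tree_fn(out)
        rep = flag_duplications(tree, out)
        assert carriers <= set(rep.flagged())


class TestExtractAndConcat:
    def test_full_subset_is_column_equal(self):
        fs = _fs(("a", "x", "ACGT"), ("b", "y", "AC-T"))
        aln, prov = extract_copy_alignment(fs, ["a", "b"])
        assert aln.ncols == 4 and prov == [0, 1, 2, 3]

    def test_all_gap_columns_drop_with_provenance(self):
        fs = _fs(("a", "x", "AC-T"), ("b", "y", "AC?T"))
        aln, prov = extract_copy_alignment(fs, ["a", "b"])
        assert aln.ncols == 3 and prov == [0, 1, 3]
        # provenance round-trips residues
        for r in aln.rows:
            parent = fs.alignment.row(r.id).residues
            assert all(
                r.residues[j] == parent[prov[j]] for j in range(aln.ncols)
            )

    def test_unknown_tip_is_an_error(self):
        fs = _fs(("a", "x", "ACGT"))
        with pytest.raises(KeyError):
            extract_copy_alignment(fs, ["nope"])

    def test_concat_shapes_charsets_and_filler(self):
        l1 = MultipleAlignment(
            rows=[Sequence("r1", "ACG", accession="x"),
                  Sequence("r2", "AGG", accession="y")]
        )
        l2 = MultipleAlignment(
            rows=[Sequence("r3", "TTTTT", accession="x")]
        )
        out = concat_loci({"locus1": l1, "locus2": l2}, ["x", "y"])
        assert out.ncols == 8
        assert out.charsets == {"locus1": (0, 3), "locus2": (3, 8)}
        assert out.row("y").residues == "AGG" + "?" * 5

    def test_concat_total_length_is_sum(self):
        l1 = MultipleAlignment(rows=[Sequence("a", "A" * 300,
                                              accession="x")])
        l2 = MultipleAlignment(rows=[Sequence("b", "C" * 700,
                                              accession="x")])
        out = concat_loci({"A": l1, "B": l2}, ["x"])
        assert out.ncols == 1000

    def test_duplicate_accession_within_locus_rejected(self):
        l1 = MultipleAlignment(
            rows=[Sequence("a", "ACG", accession="x"),
                  Sequence("b", "ACC", accession="x")]
        )
        with pytest.raises(ValueError, match="duplicate"):
            concat_loci({"locus1": l1}, ["x"])
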