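"""Phylogeny engine: newick, NJ, parsimony (vs exhaustive oracle),
likelihood closed forms, branch optimization, bootstrap, simulation."""

import math

import numpy as np
import pytest

from conftest import fitch_oracle, random_alignment, random_tree
from markermine.seqcore import MultipleAlignment, Sequence
from markermine.trees import (
    NewickParseError,
    SubstModel,
    bootstrap,
    discrete_gamma_rates,
    fitch_score,
    mp_search,
    nj_tree,
    optimize_branch_lengths,
    parse_newick,
    prune_loglik,
    simulate_evolution,
    smallest_spanning_clade,
    write_newick,
)


def _aln(**rows):
    return MultipleAlignment(
        rows=[Sequence(k, v) for k, v in rows.items()]
    )


class TestNewick:
    def test_parse_four_tip_tree(self):
        t = parse_newick("((A,B),(C,D));")
        assert sorted(t.tip_labels()) == ["A", "B", "C", "D"]
        assert len(t.bipartitions()) == 1

    def test_round_trip_topology_and_lengths(self):
        text = "((A:0.100000,B:0.200000):0.050000,(C:0.300000,D:0.400000):0.010000);"
        t = parse_newick(text)
        t2 = parse_newick(write_newick(t))
        assert t2.bipartitions().keys() == t.bipartitions().keys()
        lengths = sorted(
            round(n.length, 6) for n in t2.postorder() if n.length is not None
        )
        assert lengths == [0.01, 0.05, 0.1, 0.2, 0.3, 0.4]

    def test_unbalanced_parentheses_raise(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A,B),(C,D);")

    def test_spanning_clade_requires_known_labels(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(KeyError):
            smallest_spanning_clade(t, {"A", "Z"})

    def test_spanning_clade_of_sisters_is_the_cherry(self):
        t = parse_newick("((A,B),(C,(D,E)));")
        assert smallest_spanning_clade(t, {"D", "E"}) == {"D", "E"}
        assert smallest_spanning_clade(t, {"C", "D"}) == {"C", "D", "E"}


class TestNeighborJoining:
    def test_additive_matrix_recovers_tree_exactly(self):
        # tree ((A:2,B:3):1,C:4,D:5) with internal edge 1
        labels = ["A", "B", "C", "D"]
        dm = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        t = nj_tree(dm, labels)
        assert frozenset({"A", "B"}) in t.bipartitions() or frozenset(
            {"C", "D"}
        ) in t.bipartitions()
        total = sum(n.length for n in t.postorder() if n.length)
        assert total == pytest.approx(2 + 3 + 4 + 5 + 1)

    def test_three_taxa_closed_form(self):
        dm = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        t = nj_tree(dm, ["A", "B", "C"])
        lens = {n.label: n.length for n in t.tips()}
        assert lens == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_asymmetric_matrix_rejected(self):
        dm = np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(dm, ["A", "B", "C"])


class TestFitch:
    def test_invariant_column_costs_nothing(self):
        t = parse_newick("((A,B),(C,D));")
        assert fitch_score(t, _aln(A="A", B="A", C="A", D="A")) == 0

    def test_aabb_pattern_costs_one(self):
        t = parse_newick("((A,B),(C,D));")
        assert fitch_score(t, _aln(A="A", B="A", C="T", D="T")) == 1

    def test_ambiguity_and_missing_are_state_sets(self):
        t = parse_newick("((A,B),(C,D));")
        # B fixes A, C fixes G: one change somewhere; R and ? are free
        assert fitch_score(t, _aln(A="R", B="A", C="G", D="?")) == 1
        assert fitch_score(t, _aln(A="R", B="A", C="R", D="?")) == 0

    def test_label_mismatch_lists_offenders(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="E"):
            fitch_score(t, _aln(A="A", B="A", C="A", E="A"))

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(20):
            k = int(rng.integers(4, 7))
            labels = [f"t{i}" for i in range(k)]
            tree = random_tree(labels, rng)
            aln = random_alignment(labels, 8, rng, p_other=0.2)
            assert fitch_score(tree, aln) == fitch_oracle(tree, aln)


class TestMpSearch:
    def test_four_tips_equals_exhaustive_best(self, rng):
        labels = ["A", "B", "C", "D"]
        aln = random_alignment(labels, 40, rng)
        _, score = mp_search(aln, n_starts=2, seed=1)
        topologies = ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]
        best = min(fitch_score(parse_newick(t), aln) for t in topologies)
        assert score == best

    def test_recovers_simulated_topology(self):
        t = parse_newick(
            "(((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05):0.05,"
            "(E:0.05,F:0.05):0.05);"
        )
        aln = simulate_evolution(t, SubstModel.jc(), 2000, seed=3)
        found, _ = mp_search(aln, n_starts=2, seed=5)
        assert found.bipartitions().keys() == t.bipartitions().keys()

    def test_same_seed_same_result(self, rng):
        aln = random_alignment([f"t{i}" for i in range(7)], 60, rng)
        t1, s1 = mp_search(aln, n_starts=2, seed=9)
        t2, s2 = mp_search(aln, n_starts=2, seed=9)
        assert s1 == s2 and write_newick(t1) == write_newick(t2)

    def test_needs_four_tips(self, rng):
        with pytest.raises(ValueError):
            mp_search(random_alignment(["a", "b", "c"], 10, rng))


class TestLikelihood:
    def test_two_taxon_jc_closed_form(self):
        d = 0.37
        t = parse_newick(f"(A:{d / 2},B:{d / 2});")
        lm = math.log((1 / 16) * (1 + 3 * math.exp(-4 * d / 3)))
        lx = math.log((1 / 16) * (1 - math.exp(-4 * d / 3)))
        aln = _aln(A="AACGT", B="AACGA")  # 4 matches, 1 mismatch
        expect = 4 * lm + lx
        assert prune_loglik(t, aln, SubstModel.jc()) == pytest.approx(
            expect, abs=1e-10
        )

    def test_zero_distance_identical_sequences(self):
        t = parse_newick("(A:0.0,B:0.0);")
        aln = _aln(A="ACGTACGT", B="ACGTACGT")
        assert prune_loglik(t, aln, SubstModel.jc()) == pytest.approx(
            8 * math.log(0.25), abs=1e-10
        )

    def test_gtr_with_equal_rates_and_freqs_nests_jc(self, rng):
        t = parse_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.08):0.03);")
        aln = random_alignment(["A", "B", "C", "D"], 50, rng)
        gtr = SubstModel.gtr(rates=(1.0,) * 6, freqs=(0.25,) * 4)
        assert prune_loglik(t, aln, gtr) == pytest.approx(
            prune_loglik(t, aln, SubstModel.jc()), abs=1e-9
        )

    def test_likelihood_invariant_to_rerooting(self, rng):
        aln = random_alignment(["A", "B", "C", "D"], 60, rng)
        m = SubstModel.hky(kappa=3.0, freqs=(0.3, 0.2, 0.2, 0.3),
                           plus_G=True, alpha=0.7)
        t1 = parse_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.08):0.02);")
        # same unrooted tree re-rooted at each internal node
        t2 = parse_newick("(A:0.1,B:0.2,(C:0.15,D:0.08):0.07);")
        t3 = parse_newick("(C:0.15,D:0.08,(A:0.1,B:0.2):0.07);")
        l1 = prune_loglik(t1, aln, m)
        assert prune_loglik(t2, aln, m) == pytest.approx(l1, abs=1e-8)
        assert prune_loglik(t3, aln, m) == pytest.approx(l1, abs=1e-8)

    def test_negative_branch_rejected(self):
        t = parse_newick("(A:-0.1,B:0.1);")
        with pytest.raises(ValueError, match="negative"):
            prune_loglik(t, _aln(A="A", B="A"), SubstModel.jc())

    def test_gamma_rates_have_mean_one(self):
        for alpha in (0.2, 0.7, 1.0, 5.0, 50.0):
            r = discrete_gamma_rates(alpha, 4)
            assert r.mean() == pytest.approx(1.0)
            assert np.all(np.diff(r) > 0)
        assert np.allclose(discrete_gamma_rates(1e4, 4), 1.0, atol=0.05)


class TestBranchOptimization:
    def test_two_taxon_jc_matches_analytic_distance(self, rng):
        t = parse_newick("(A:0.05,B:0.05);")
        aln = simulate_evolution(
            parse_newick("(A:0.08,B:0.08);"), SubstModel.jc(), 4000, seed=4
        )
        p = sum(
            a != b
            for a, b in zip(aln.rows[0].residues, aln.rows[1].residues)
        ) / aln.ncols
        analytic = -0.75 * math.log(1 - 4 * p / 3)
        opt, _ = optimize_branch_lengths(t, aln, SubstModel.jc(), tol=1e-8)
        total = sum(n.length for n in opt.postorder() if n.length is not None)
        assert total == pytest.approx(analytic, abs=1e-6)

    def test_lnl_never_decreases(self, rng):
        aln = random_alignment(["A", "B", "C", "D"], 80, rng)
        t = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        m = SubstModel.jc()
        before = prune_loglik(t, aln, m)
        _, after = optimize_branch_lengths(t, aln, m)
        assert after >= before - 1e-9

    def test_start_at_optimum_is_stable(self, rng):
        aln = random_alignment(["A", "B", "C", "D"], 80, rng)
        t = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        m = SubstModel.jc()
        t1, l1 = optimize_branch_lengths(t, aln, m, tol=1e-6)
        t2, l2 = optimize_branch_lengths(t1, aln, m, tol=1e-6)
        assert l2 == pytest.approx(l1, abs=1e-3)


class TestBootstrap:
    def _infer(self, a):
        return mp_search(a, n_starts=1, seed=0)[0]

    def test_single_replicate_supports_are_binary(self, rng):
        aln = random_alignment(["A", "B", "C", "D", "E"], 40, rng)
        res = bootstrap(aln, 1, self._infer, seed=3)
        assert set(res.support.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self, rng):
        aln = random_alignment(["A", "B", "C", "D", "E"], 40, rng)
        r1 = bootstrap(aln, 10, self._infer, seed=3)
        r2 = bootstrap(aln, 10, self._infer, seed=3)
        assert r1.support == r2.support

    def test_strong_branch_gets_high_support(self):
        t = parse_newick(
            "(((A:0.05,B:0.05):0.1,(C:0.05,D:0.05):0.1):0.05,"
            "(E:0.05,F:0.05):0.1);"
        )
        aln = simulate_evolution(t, SubstModel.jc(), 1500, seed=8)
        res = bootstrap(aln, 100, self._infer, seed=8)
        ab = frozenset({"C", "D"})  # canonical side excludes tip A
        assert res.support.get(ab, 0.0) >= 95.0


class TestSimulation:
    def test_zero_length_tree_gives_identical_rows(self):
        t = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        aln = simulate_evolution(t, SubstModel.jc(), 100, seed=1)
        assert len({r.residues for r in aln.rows}) == 1

    def test_base_frequencies_match_model(self):
        freqs = (0.4, 0.1, 0.2, 0.3)
        t = parse_newick("(A:0.05,B:0.05);")
        aln = simulate_evolution(
            t, SubstModel.hky(2.0, freqs), 20000, seed=2
        )
        counts = np.array(
            [aln.rows[0].residues.count(b) for b in "ACGT"], dtype=float
        )
        assert np.allclose(counts / counts.sum(), freqs, atol=0.02)

    def test_divergence_matches_jc_expectation(self):
        d = 0.2
        t = parse_newick(f"(A:{d / 2},B:{d / 2});")
        n = 100_000
        aln = simulate_evolution(t, SubstModel.jc(), n, seed=6)
        p = sum(
            a != b
            for a, b in zip(aln.rows[0].residues, aln.rows[1].residues)
        ) / n
        expect = 0.75 * (1 - math.exp(-4 * d / 3))
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(p - expect) < 3 * se

    def test_gtr_parameter_recovery(self):
        # exchangeabilities and alpha recovered within 10% at 1e5 sites
        from markermine.partition import fit_subset_model

        true_rates = (1.5, 4.0, 0.8, 1.2, 5.0, 1.0)
        freqs = (0.3, 0.2, 0.2, 0.3)
        m = SubstModel.gtr(true_rates, freqs, plus_G=True, alpha=0.6)
        t = parse_newick(
            "(((A:0.1,B:0.1):0.05,C:0.12):0.04,(D:0.1,E:0.1):0.06);"
        )
        aln = simulate_evolution(t, m, 100_000, seed=12)
        fit = fit_subset_model(
            tuple(range(aln.ncols)), aln, t, "GTR+G"
        )["model"]
        assert fit.alpha == pytest.approx(0.6, rel=0.10)
        for got, want in zip(fit.rates[:5], true_rates[:5]):
            assert got == pytest.approx(want, rel=0.10)
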