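from itertools import product

import numpy as np
import pytest

from rootedml.likelihood import compute_loglik, optimize_branch_lengths
from rootedml.models import build_gtr, jukes_cantor
from rootedml.search import (SearchConfig, SearchError,
                             corrected_distance_matrix, fitch_score,
                             hill_climb_nni, mp_starting_tree, nj_tree,
                             nni_neighbors, respects_constraint, run_search)
from rootedml.simgen import SimSpec, random_tree, simulate_alignment
from rootedml.treeio import Alignment, DNA, Tree, compress_patterns, parse_newick

from conftest import toy_alignment


def brute_force_fitch(tree, aln):
    """Minimum changes over all internal labelings (exhaustive)."""
    alph = aln.alphabet
    internals = [n for n in tree.postorder() if not n.is_leaf]
    total = 0
    for site in range(aln.n_sites):
        best = np.inf
        leaf_state = {}
        ok = True
        for leaf in tree.leaves():
            c = aln.sequence(leaf.name)[site]
            allowed = np.flatnonzero(alph.partial(c))
            leaf_state[leaf.name] = allowed
        for assign in product(range(alph.n_states), repeat=len(internals)):
            states = {id(n): s for n, s in zip(internals, assign)}
            cost = 0
            for n in tree.postorder():
                if n is tree.root:
                    continue
                ps = states[id(n.parent)]
                if n.is_leaf:
                    cost += int(ps not in leaf_state[n.name])
                else:
                    cost += int(states[id(n)] != ps)
            best = min(best, cost)
        total += best
    return total


class TestFitch:
    def test_identical_sequences_zero(self):
        aln = toy_alignment({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        tree = parse_newick("(a,b,c);")
        assert fitch_score(tree, compress_patterns(aln)) == 0

    def test_single_change_forced(self):
        aln = toy_alignment({"A1": "A", "A2": "A", "B1": "C", "B2": "C"})
        tree = parse_newick("((A1,A2),(B1,B2));")
        assert fitch_score(tree, compress_patterns(aln)) == 1

    def test_against_exhaustive_oracle(self, rng):
        tree = random_tree(6, "yule", 0.2, seed=13)
        aln = simulate_alignment(SimSpec(tree=tree, model=jukes_cantor(),
                                         n_sites=5, seed=14))
        score = fitch_score(tree, compress_patterns(aln))
        assert score == brute_force_fitch(tree, aln)

    def test_weighted_patterns(self):
        aln = toy_alignment({"a": "AAAC", "b": "AAAC", "c": "CCCA"})
        tree = parse_newick("(a,b,c);")
        assert fitch_score(tree, compress_patterns(aln)) == 4


class TestStartingTrees:
    def test_three_taxa_unique_topology(self):
        aln = toy_alignment({"a": "AC", "b": "AG", "c": "AT"})
        t = mp_starting_tree(compress_patterns(aln), seed=0)
        assert sorted(t.leaf_names()) == ["a", "b", "c"]

    def test_recovers_strong_caterpillar(self):
        tree = random_tree(6, "caterpillar", 0.05, seed=40)
        for n in tree.postorder():
            if n is not tree.root and not n.is_leaf:
                n.length = 0.4  # long internal branches: clean signal
        aln = simulate_alignment(SimSpec(tree=tree, model=jukes_cantor(),
                                         n_sites=2000, seed=41))
        mp = mp_starting_tree(compress_patterns(aln), seed=0)
        assert mp.canonical_topology(rooted=False) \
            == tree.canonical_topology(rooted=False)

    def test_deterministic_per_seed(self, small_patterns):
        t1 = mp_starting_tree(small_patterns, seed=7)
        t2 = mp_starting_tree(small_patterns, seed=7)
        assert t1.newick() == t2.newick()


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # ((A:1,B:2):1,(C:3,D:4)) as an additive distance matrix
        labels = ["A", "B", "C", "D"]
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        t = nj_tree(D, labels)
        assert t.canonical_topology(rooted=False) \
            == parse_newick("((A,B),(C,D));").canonical_topology(rooted=False)
        lv, M = t.leaf_distances()
        assert np.allclose(M, D)

    def test_three_point_formulas(self):
        labels = ["A", "B", "C"]
        D = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float)
        t = nj_tree(D, labels)
        d = {l.name: l.length for l in t.leaves()}
        assert abs(d["A"] - (5 + 9 - 8) / 2) < 1e-12
        assert abs(d["B"] - (5 + 8 - 9) / 2) < 1e-12
        assert abs(d["C"] - (9 + 8 - 5) / 2) < 1e-12

    def test_ultrametric_path_lengths(self):
        labels = ["A", "B", "C", "D"]
        D = np.array([[0, 2, 6, 6], [2, 0, 6, 6],
                      [6, 6, 0, 4], [6, 6, 4, 0]], float)
        t = nj_tree(D, labels)
        lv, M = t.leaf_distances()
        assert np.allclose(M, D)  # additive, hence exact recovery

    def test_asymmetric_rejected(self):
        with pytest.raises(SearchError):
            nj_tree(np.array([[0, 1], [2, 0]], float), ["A", "B"])

    def test_saturated_distances_capped(self):
        aln = toy_alignment({"a": "ACGT" * 5, "b": "CATG" * 5, "c": "ACGT" * 5})
        D = corrected_distance_matrix(aln)
        assert D[0, 1] == 10.0
        assert D[0, 2] == 0.0


class TestNNI:
    def test_four_taxon_completes_topology_set(self):
        tree = parse_newick("(A:1,B:1,(C:1,D:1):1);")
        edge = next(n for n in tree.internal_edges())
        alts = nni_neighbors(tree, edge)
        canon = {t.canonical_topology(rooted=False) for t in alts}
        canon.add(tree.canonical_topology(rooted=False))
        assert len(canon) == 3

    def test_involution(self):
        tree = parse_newick("(A:1,B:1,(C:1,(D:1,E:1):1):1);")
        edge = next(n for n in tree.internal_edges())
        alt = nni_neighbors(tree, edge)[0]
        edge_alt = next(
            n for n in alt.internal_edges()
            if {l.name for l in _leaves(n)} != {"D", "E"}
        )
        back = {t.canonical_topology(rooted=False)
                for t in nni_neighbors(alt, edge_alt)}
        assert tree.canonical_topology(rooted=False) in back

    def test_rooted_neighbors_stay_rooted(self):
        tree = parse_newick("((A:1,(B:1,C:1):1):1,(D:1,E:1):1);")
        edge = next(n for n in tree.internal_edges()
                    if n.parent is not tree.root)
        for alt in nni_neighbors(tree, edge):
            assert alt.is_rooted
            assert len(alt.root.children) == 2

    def test_leaf_branch_rejected(self):
        tree = parse_newick("(A:1,B:1,(C:1,D:1):1);")
        leaf = next(n for n in tree.postorder() if n.name == "A")
        with pytest.raises(SearchError):
            nni_neighbors(tree, leaf)


class TestConstraint:
    def test_star_constraint_always_true(self):
        tree = parse_newick("((A,B),(C,D));")
        star = parse_newick("(A,B,C,D);")
        assert respects_constraint(tree, star)

    def test_self_constraint(self):
        tree = parse_newick("((A,B),(C,D));")
        assert respects_constraint(tree, tree)

    def test_conflicting_split(self):
        tree = parse_newick("((A,C),(B,D));")
        cons = parse_newick("((A,B),C,D);")
        assert not respects_constraint(tree, cons)

    def test_missing_taxon_error(self):
        tree = parse_newick("((A,B),(C,D));")
        cons = parse_newick("((A,B),(C,E));")
        with pytest.raises(SearchError):
            respects_constraint(tree, cons)


class TestHillClimb:
    def _four_taxon_instance(self, seed):
        tree = random_tree(4, "yule", 0.25, seed=seed)
        aln = simulate_alignment(SimSpec(tree=tree, model=jukes_cantor(),
                                         n_sites=400, seed=seed + 1))
        return tree, aln

    def _exhaustive_best(self, aln):
        pat = compress_patterns(aln)
        a, b, c, d = sorted(aln.taxa)
        best = None
        for nwk in (f"(({a},{b}),{c},{d});", f"(({a},{c}),{b},{d});",
                    f"(({a},{d}),{b},{c});"):
            t = parse_newick(nwk)
            for n in t.edges():
                n.length = 0.1
            t, _ = optimize_branch_lengths(t, jukes_cantor(), None, pat)
            lnl = compute_loglik(t, jukes_cantor(), None, pat).total_lnl
            if best is None or lnl > best[0]:
                best = (lnl, t)
        return best

    @pytest.mark.parametrize("seed", range(0, 40, 8))
    def test_matches_exhaustive_on_four_taxa(self, seed):
        tree, aln = self._four_taxon_instance(seed + 60)
        pat = compress_patterns(aln)
        start = mp_starting_tree(pat, seed=seed)
        result, trace = hill_climb_nni(start, jukes_cantor(), None, pat)
        lnl_best, t_best = self._exhaustive_best(aln)
        lnl = compute_loglik(result, jukes_cantor(), None, pat).total_lnl
        assert lnl >= lnl_best - 1e-6
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_start_at_optimum_unchanged(self):
        tree, aln = self._four_taxon_instance(90)
        pat = compress_patterns(aln)
        _, t_best = self._exhaustive_best(aln)
        result, _ = hill_climb_nni(t_best, jukes_cantor(), None, pat)
        assert result.canonical_topology(rooted=False) \
            == t_best.canonical_topology(rooted=False)


class TestRunSearch:
    def test_multiple_runs_ranked(self, small_alignment):
        res = run_search(small_alignment, jukes_cantor(), None,
                         SearchConfig(mode="fast", n_runs=3, seed=5))
        assert len(res.runs) == 3
        lnls = [r.lnl for r in res.runs]
        assert lnls == sorted(lnls, reverse=True)
        assert res.best_lnl == lnls[0]

    def test_recovers_strong_signal_topology(self):
        tree = random_tree(8, "yule", 0.08, seed=70)
        for n in tree.postorder():
            if n is not tree.root and not n.is_leaf:
                n.length = 0.3
        model = build_gtr([1, 2, 1, 1, 2, 1], [0.3, 0.2, 0.25, 0.25])
        aln = simulate_alignment(SimSpec(tree=tree, model=model,
                                         n_sites=5000, seed=71))
        res = run_search(aln, model, None, SearchConfig(mode="fast", seed=2))
        assert res.best_tree.canonical_topology(rooted=False) \
            == tree.canonical_topology(rooted=False)

    def test_constrained_search_respects_constraint(self, small_alignment):
        cons = parse_newick("((t1,t2),t3,t4,t5,t6);")
        res = run_search(small_alignment, jukes_cantor(), None,
                         SearchConfig(mode="fast", seed=3, constraint=cons))
        assert respects_constraint(res.best_tree, cons)

    def test_three_taxa_unique(self):
        aln = toy_alignment({"a": "ACGTACGT", "b": "ACGTACGA", "c": "ACCTACGA"})
        res = run_search(aln, jukes_cantor(), None,
                         SearchConfig(mode="fast", seed=1))
        assert sorted(res.best_tree.leaf_names()) == ["a", "b", "c"]

    def test_too_few_taxa(self):
        aln = toy_alignment({"a": "AC", "b": "AG"})
        with pytest.raises(SearchError):
            run_search(aln, jukes_cantor(), None, SearchConfig(seed=0))


def _leaves(node):
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out
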