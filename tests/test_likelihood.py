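from itertools import product

import numpy as np
import pytest

from rootedml.likelihood import (BRANCH_MIN, LikelihoodResult, ModelFit,
                                 RootingRequiredError, compute_loglik,
                                 optimize_branch_lengths,
                                 optimize_model_params, root_search,
                                 site_rates_empirical_bayes, site_rates_ml,
                                 _subtree_leaves)
from rootedml.models import (RateModel, build_gtr, build_unrest,
                             discretize_rates, jukes_cantor)
from rootedml.simgen import SimSpec, random_tree, simulate_alignment
from rootedml.transprob import transition_matrix
from rootedml.treeio import Alignment, DNA, compress_patterns, parse_newick


def brute_force_lnl(tree, model, rate_model, aln, root_freqs=None):
    """Exhaustive sum over all internal-state assignments, per site."""
    rate_model = rate_model or RateModel.uniform()
    pi = model.stationary_freqs if root_freqs is None else root_freqs
    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = {n.name: n for n in tree.postorder() if n.is_leaf}
    alph = aln.alphabet
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for c in range(rate_model.n_categories):
            r = rate_model.category_rates[c]
            P = {id(n): transition_matrix(model.Q, (n.length or 0.0) * r)
                 for n in tree.postorder() if n is not tree.root}
            lik = 0.0
            for assign in product(range(model.n_states), repeat=len(internals)):
                states = {id(n): s for n, s in zip(internals, assign)}
                p = pi[states[id(tree.root)]]
                for n in tree.postorder():
                    if n is tree.root:
                        continue
                    ps = states[id(n.parent)]
                    if n.is_leaf:
                        row = alph.partial(aln.sequence(n.name)[site])
                        p *= float(P[id(n)][ps] @ row)
                    else:
                        p *= P[id(n)][ps, states[id(n)]]
                lik += p
            site_lik += rate_model.category_weights[c] * lik
        total += np.log(site_lik)
    return total


class TestComputeLoglik:
    def test_two_leaf_jc_closed_form(self):
        t1, t2 = 0.05, 0.25
        tree = parse_newick(f"(A:{t1},B:{t2});")
        aln = Alignment(["A", "B"], ["A", "A"], DNA)
        res = compute_loglik(tree, jukes_cantor(), None, compress_patterns(aln))
        expect = np.log(0.25 * (0.25 + 0.75 * np.exp(-4 * (t1 + t2) / 3)))
        assert abs(res.total_lnl - expect) < 1e-12

    @pytest.mark.parametrize("model_maker", [
        lambda rng: jukes_cantor(),
        lambda rng: build_gtr(rng.uniform(0.3, 3, 6), rng.dirichlet(np.ones(4) * 4)),
        lambda rng: build_unrest(rng.uniform(0.3, 3, 12)),
    ])
    def test_against_exhaustive_oracle(self, rng, model_maker):
        tree = random_tree(4, "yule", 0.2, seed=17)
        model = model_maker(rng)
        rm = discretize_rates(0.7, 0.0, 2)
        aln = simulate_alignment(SimSpec(tree=tree, model=model,
                                         rate_model=rm, n_sites=10, seed=5))
        res = compute_loglik(tree, model, rm, compress_patterns(aln))
        oracle = brute_force_lnl(tree, model, rm, aln)
        assert abs(res.total_lnl - oracle) < 1e-8

    def test_reversible_rerooting_invariance(self, gtr_model, small_tree):
        aln = simulate_alignment(SimSpec(tree=small_tree, model=gtr_model,
                                         n_sites=200, seed=2))
        pat = compress_patterns(aln)
        ref = compute_loglik(small_tree, gtr_model, None, pat).total_lnl
        unrooted = small_tree.unroot()
        for node in list(unrooted.postorder()):
            if node is unrooted.root:
                continue
            rerooted = unrooted.reroot_at_edge(node, 0.4)
            lnl = compute_loglik(rerooted, gtr_model, None, pat).total_lnl
            assert abs(lnl - ref) < 1e-8

    def test_nonreversible_rooting_matters(self, rng):
        tree = random_tree(6, "yule", 0.2, seed=8)
        m = build_unrest(np.array([4, 1, .5, .5, 4, 1, 1, .5, 4, 4, .5, 1]))
        aln = simulate_alignment(SimSpec(tree=tree, model=m, n_sites=4000, seed=9))
        pat = compress_patterns(aln)
        l0 = compute_loglik(tree, m, None, pat).total_lnl
        other = tree.unroot().reroot_at_edge("t1", 0.5)
        l1 = compute_loglik(other, m, None, pat).total_lnl
        assert abs(l0 - l1) > 1e-3

    def test_nonreversible_requires_rooted(self, rng):
        m = build_unrest(rng.uniform(0.5, 2, 12))
        tree = parse_newick("(A:0.1,B:0.1,C:0.1);")
        aln = Alignment(["A", "B", "C"], ["A", "C", "G"], DNA)
        with pytest.raises(RootingRequiredError):
            compute_loglik(tree, m, None, compress_patterns(aln))

    def test_pattern_compression_equivalence(self, small_alignment, gtr_model,
                                             small_tree):
        pat = compress_patterns(small_alignment)
        res = compute_loglik(small_tree, gtr_model, None, pat)
        per_site = 0.0
        for j in range(small_alignment.n_sites):
            single = small_alignment.subset_sites([j])
            r = compute_loglik(small_tree, gtr_model, None,
                               compress_patterns(single))
            per_site += r.total_lnl
            assert abs(r.total_lnl - res.per_site_lnl[j]) < 1e-10
        assert abs(per_site - res.total_lnl) < 1e-8

    def test_total_is_weighted_pattern_sum(self, small_patterns, small_tree):
        res = compute_loglik(small_tree, jukes_cantor(), None, small_patterns)
        assert abs(res.total_lnl
                   - small_patterns.weights @ res.per_pattern_lnl) < 1e-8


class TestScaling:
    def test_scaling_neutral_on_small_data(self, small_tree, small_patterns,
                                           gtr_model):
        on = compute_loglik(small_tree, gtr_model, None, small_patterns,
                            use_scaling=True).total_lnl
        off = compute_loglik(small_tree, gtr_model, None, small_patterns,
                             use_scaling=False).total_lnl
        assert abs(on - off) < 1e-8

    def test_deep_tree_underflow_rescued(self):
        n = 2000
        tree = random_tree(n, "caterpillar", 0.0, seed=1)
        for node in tree.postorder():
            if node is not tree.root:
                node.length = 0.4
        taxa = tree.leaf_names()
        aln = Alignment(taxa, ["A" if i % 2 else "C" for i in range(n)], DNA)
        pat = compress_patterns(aln)
        unscaled = compute_loglik(tree, jukes_cantor(), None, pat,
                                  use_scaling=False)
        scaled = compute_loglik(tree, jukes_cantor(), None, pat,
                                use_scaling=True)
        assert not np.isfinite(unscaled.total_lnl)
        assert np.isfinite(scaled.total_lnl)
        assert scaled.scaling_events > 0

    def test_safe_mode_threshold_agrees(self, small_tree, small_patterns,
                                        gtr_model):
        normal = compute_loglik(small_tree, gtr_model, None, small_patterns)
        safe = compute_loglik(small_tree, gtr_model, None, small_patterns,
                              scale_threshold=1.0)
        assert abs(normal.total_lnl - safe.total_lnl) < 1e-6
        assert safe.scaling_events >= normal.scaling_events


class TestBranchOptimization:
    def test_identical_sequences_hit_lower_bound(self):
        aln = Alignment(["A", "B"], ["ACGT" * 50] * 2, DNA)
        pat = compress_patterns(aln)
        tree = parse_newick("(A:0.3,B:0.3);")
        opt, _ = optimize_branch_lengths(tree, jukes_cantor(), None, pat)
        assert sum(n.length for n in opt.edges()) < 10 * BRANCH_MIN

    def test_jc_distance_mle(self):
        p = 0.15
        n = 2000
        k = int(n * p)
        aln = Alignment(["X", "Y"], ["A" * n, "C" * k + "A" * (n - k)], DNA)
        pat = compress_patterns(aln)
        tree = parse_newick("(X:0.1,Y:0.1);")
        opt, trace = optimize_branch_lengths(tree, jukes_cantor(), None, pat)
        total = sum(nd.length for nd in opt.edges())
        assert abs(total - (-0.75 * np.log(1 - 4 * p / 3))) < 1e-4
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_trace_monotone_on_random_data(self, small_alignment, small_tree):
        pat = compress_patterns(small_alignment)
        start = small_tree.copy()
        for nd in start.edges():
            nd.length = 0.5
        _, trace = optimize_branch_lengths(start, jukes_cantor(), None, pat)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))


class TestModelOptimization:
    def test_stationary_at_truth(self):
        tree = random_tree(5, "yule", 0.15, seed=21)
        model = build_gtr([1, 2, 1, 1, 3, 1], [0.3, 0.2, 0.3, 0.2])
        aln = simulate_alignment(SimSpec(tree=tree, model=model,
                                         n_sites=5000, seed=22))
        pat = compress_patterns(aln)
        tree_opt, _ = optimize_branch_lengths(tree, model, None, pat)
        lnl0 = compute_loglik(tree_opt, model, None, pat).total_lnl
        fit = optimize_model_params(tree_opt, model, None, pat, max_rounds=1)
        assert fit.lnl >= lnl0 - 1e-6
        assert fit.lnl - lnl0 < 2.0  # near-stationary at the truth

    def test_small_scale_gtr_recovery(self):
        tree = random_tree(6, "yule", 0.12, seed=31)
        exch = np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0])
        freqs = np.array([0.3, 0.2, 0.25, 0.25])
        model = build_gtr(exch, freqs)
        aln = simulate_alignment(SimSpec(tree=tree, model=model,
                                         n_sites=8000, seed=32))
        pat = compress_patterns(aln)
        start = build_gtr(np.ones(6), freqs)
        fit = optimize_model_params(tree.copy(), start, None, pat,
                                    max_rounds=3)
        est = fit.model.free_params["exchangeabilities"]
        est = est / est[-1]
        assert np.max(np.abs(est - exch) / exch) < 0.2


class TestSiteRates:
    def _fit(self, tree, model, rm, pat):
        return ModelFit(tree=tree, model=model, rate_model=rm,
                        lnl=0.0, trace=[])

    def test_single_category_rates_are_one(self, small_tree, small_patterns):
        fit = self._fit(small_tree, jukes_cantor(), RateModel.uniform(),
                        small_patterns)
        sr = site_rates_empirical_bayes(fit, small_patterns)
        assert np.allclose(sr.rates, 1.0)

    def test_eb_rates_bounded_by_categories(self, small_tree, small_patterns):
        rm = discretize_rates(0.6, 0.0, 4)
        fit = self._fit(small_tree, jukes_cantor(), rm, small_patterns)
        sr = site_rates_empirical_bayes(fit, small_patterns)
        assert sr.rates.min() >= rm.category_rates.min() - 1e-12
        assert sr.rates.max() <= rm.category_rates.max() + 1e-12

    def test_conserved_site_slower_than_variable(self):
        taxa = ["a", "b", "c", "d"]
        aln = Alignment(taxa, ["AC", "AG", "AT", "AA"], DNA)
        pat = compress_patterns(aln)
        tree = parse_newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);")
        rm = discretize_rates(0.6, 0.0, 4)
        fit = self._fit(tree, jukes_cantor(), rm, pat)
        sr = site_rates_empirical_bayes(fit, pat)
        assert sr.rates[0] < sr.rates[1]

    def test_ml_constant_site_hits_floor(self):
        taxa = ["a", "b", "c", "d"]
        aln = Alignment(taxa, ["AC", "AG", "AT", "AA"], DNA)
        pat = compress_patterns(aln)
        tree = parse_newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);")
        fit = self._fit(tree, jukes_cantor(), RateModel.uniform(), pat)
        sr = site_rates_ml(fit, pat)
        assert sr.rates[0] <= 1e-3
        assert sr.rates[1] > sr.rates[0]

    def test_ml_rates_permutation_invariant(self, small_tree):
        aln = simulate_alignment(SimSpec(tree=small_tree,
                                         model=jukes_cantor(),
                                         n_sites=40, seed=3))
        perm = np.random.default_rng(0).permutation(aln.n_sites)
        shuffled = aln.subset_sites(list(perm))
        fit = ModelFit(tree=small_tree, model=jukes_cantor(),
                       rate_model=RateModel.uniform(), lnl=0.0, trace=[])
        r1 = site_rates_ml(fit, compress_patterns(aln)).rates
        r2 = site_rates_ml(fit, compress_patterns(shuffled)).rates
        assert np.allclose(r1[perm], r2, atol=1e-9)


class TestRootSearch:
    def test_radius_zero_returns_input(self, small_tree, small_patterns):
        best, report = root_search(small_tree, jukes_cantor(), None,
                                   small_patterns, radius=0)
        assert best.canonical_topology() == small_tree.canonical_topology()

    def test_reversible_candidates_all_equal(self, small_tree, gtr_model):
        aln = simulate_alignment(SimSpec(tree=small_tree, model=gtr_model,
                                         n_sites=300, seed=6))
        pat = compress_patterns(aln)
        # converge branch lengths tightly first: the pulley invariance of the
        # candidate lnLs holds at the joint optimum
        tree, _ = optimize_branch_lengths(small_tree, gtr_model, None, pat,
                                          tol=1e-8, max_sweeps=50)
        _, report = root_search(tree, gtr_model, None, pat, radius=None)
        vals = [v for k, v in report.items() if k != "best"]
        assert max(vals) - min(vals) < 1e-6

    def test_unrooted_start_rejected(self, small_tree, small_patterns):
        with pytest.raises(RootingRequiredError):
            root_search(small_tree.unroot(), jukes_cantor(), None,
                        small_patterns)

    def test_unrest_recovers_true_root(self):
        m = build_unrest(np.array([4, 1, .5, .5, 4, 1, 1, .5, 4, 4, .5, 1]))
        hits = 0
        for seed in range(5):
            tree = random_tree(6, "yule", 0.15, seed=200 + seed)
            aln = simulate_alignment(SimSpec(tree=tree, model=m,
                                             n_sites=10_000, seed=seed))
            pat = compress_patterns(aln)
            start = tree.unroot().reroot_at_edge(min(tree.leaf_names()))
            best, _ = root_search(start, m, None, pat, radius=None)
            hits += _root_split(best) == _root_split(tree)
        assert hits >= 4


def _root_split(tree):
    c = tree.root.children[0]
    side = frozenset(l.name for l in _subtree_leaves(c))
    return frozenset([side, frozenset(set(tree.leaf_names()) - side)])
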