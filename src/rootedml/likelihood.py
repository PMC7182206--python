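"""Pruning-algorithm likelihoods, optimization, site rates and root search.

Partial likelihoods are arrays of shape (patterns, rate categories, states)
propagated post-order; per-pattern log scaling factors guard against
underflow. On rooted trees the recursion runs in the direction of time, so
nonreversible models are supported; unrooted (basal-trifurcation) trees are
valid for reversible models only, where the pulley principle makes the
likelihood independent of root placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .models import RateModel, SubstitutionModel, ModelError
from .transprob import spectral_decompose, transition_matrix
from .treeio import Node, PatternTable, Tree

SCALE_THRESHOLD = 1e-80
BRANCH_MIN = 1e-6
BRANCH_MAX = 10.0
BRENT_TOL = 1e-6       # lnL units for one-dimensional searches
SWEEP_TOL = 1e-4       # lnL units for full optimization loops


class RootingRequiredError(ValueError):
    """Nonreversible likelihoods are defined on rooted trees only."""


@dataclass
class LikelihoodResult:
    total_lnl: float
    per_site_lnl: np.ndarray
    per_pattern_lnl: np.ndarray
    scaling_events: int
    per_category_lik: np.ndarray | None = None  # (patterns, categories), unscaled
    scale_log: np.ndarray | None = None         # per-pattern log scaling


@dataclass
class SiteRates:
    rates: np.ndarray
    method: str               # "empirical-bayes" | "ml"
    categories: np.ndarray | None = None  # most-probable category (EB)


def _tip_partials(patterns: PatternTable) -> dict[str, np.ndarray]:
    cache = getattr(patterns, "_tip_cache", None)
    if cache is None:
        cache = patterns.tip_partials()
        patterns._tip_cache = cache
    return cache


def _edge_pmats(tree: Tree, model: SubstitutionModel, rates: np.ndarray,
                cache=None) -> dict[int, np.ndarray]:
    """id(node) -> (categories, states, states) transition matrices."""
    if cache is None:
        cache = spectral_decompose(model.Q)
    out = {}
    for node in tree.postorder():
        if node is tree.root:
            continue
        t = node.length or 0.0
        out[id(node)] = np.stack([transition_matrix(cache, t * r) for r in rates])
    return out


def _check_rooting(tree: Tree, model: SubstitutionModel) -> None:
    if not model.reversible and not tree.is_rooted:
        raise RootingRequiredError(
            "nonreversible models require a rooted tree (root of out-degree 2)"
        )


def _postorder_partials(tree, patterns, pmats, n_cat, use_scaling=True,
                        scale_threshold=SCALE_THRESHOLD):
    """Returns (partials, scales, scaling_events).

    partials: id(node) -> (P, C, S); scales: id(node) -> per-pattern log
    factors accumulated within that node's subtree.
    """
    tips = _tip_partials(patterns)
    P = patterns.n_patterns
    events = 0
    partials: dict[int, np.ndarray] = {}
    scales: dict[int, np.ndarray] = {}
    zero = np.zeros(P)
    for node in tree.postorder():
        if node.is_leaf:
            tp = tips[node.name]
            partials[id(node)] = np.broadcast_to(tp[:, None, :], (P, n_cat, tp.shape[1]))
            scales[id(node)] = zero
            continue
        D = None
        sc = np.zeros(P)
        for child in node.children:
            contrib = np.einsum("pcs,cjs->pcj", partials[id(child)], pmats[id(child)])
            D = contrib if D is None else D * contrib
            sc = sc + scales[id(child)]
        if use_scaling:
            m = D.max(axis=(1, 2))
            small = (m < scale_threshold) & (m > 0)
            if np.any(small):
                factor = np.where(small, m, 1.0)
                D = D / factor[:, None, None]
                sc = sc + np.log(factor)
                events += int(small.sum())
        partials[id(node)] = D
        scales[id(node)] = sc
    return partials, scales, events


def compute_loglik(tree: Tree, model: SubstitutionModel,
                   rate_model: RateModel | None, patterns: PatternTable,
                   root_freqs: np.ndarray | None = None,
                   use_scaling: bool = True,
                   spectral_cache=None,
                   scale_threshold: float = SCALE_THRESHOLD) -> LikelihoodResult:
    """Felsenstein pruning over compressed site patterns.

    `root_freqs` defaults to the model's stationary distribution.
    """
    _check_rooting(tree, model)
    rate_model = rate_model or RateModel.uniform()
    missing = set(tree.leaf_names()) - set(patterns.taxa)
    if missing:
        raise ModelError(f"tree leaves not in alignment: {sorted(missing)}")
    pi = model.stationary_freqs if root_freqs is None else np.asarray(root_freqs)
    pmats = _edge_pmats(tree, model, rate_model.category_rates, spectral_cache)
    partials, scales, events = _postorder_partials(
        tree, patterns, pmats, rate_model.n_categories, use_scaling,
        scale_threshold,
    )
    scale_log = scales[id(tree.root)]
    D = partials[id(tree.root)]
    cat_lik = np.einsum("pcs,s->pc", D, pi)
    site_lik = cat_lik @ rate_model.category_weights
    with np.errstate(divide="ignore"):
        per_pattern = np.log(site_lik) + scale_log
    total = float(patterns.weights @ per_pattern)
    return LikelihoodResult(
        total_lnl=total,
        per_site_lnl=patterns.expand(per_pattern),
        per_pattern_lnl=per_pattern,
        scaling_events=events,
        per_category_lik=cat_lik,
        scale_log=scale_log,
    )


# ---------------------------------------------------------------------------
# outside (above-edge) conditionals: cheap per-edge 1-D optimization

def _outside_arrays(tree, patterns, pmats, partials, subtree_scales,
                    root_freqs, n_cat):
    """id(node) -> conditional of all data outside the node's subtree given
    the state at its parent (root prior included, the node's own edge
    excluded), plus the matching per-pattern log scale."""
    P = patterns.n_patterns
    F: dict[int, np.ndarray] = {}
    fscale: dict[int, np.ndarray] = {}
    contribs = {
        id(n): np.einsum("pcs,cjs->pcj", partials[id(n)], pmats[id(n)])
        for n in tree.postorder() if n is not tree.root
    }
    for node in tree.preorder():
        if node is tree.root:
            base = np.broadcast_to(root_freqs[None, None, :],
                                   (P, n_cat, len(root_freqs))).copy()
            base_scale = np.zeros(P)
        else:
            base = np.einsum("pci,cij->pcj", F[id(node)], pmats[id(node)])
            base_scale = fscale[id(node)]
        for child in node.children:
            out = base.copy()
            sc = base_scale.copy()
            for sib in node.children:
                if sib is not child:
                    out = out * contribs[id(sib)]
                    sc = sc + subtree_scales[id(sib)]
            m = out.max(axis=(1, 2))
            small = (m < SCALE_THRESHOLD) & (m > 0)
            if np.any(small):
                factor = np.where(small, m, 1.0)
                out = out / factor[:, None, None]
                sc = sc + np.log(factor)
            F[id(child)] = out
            fscale[id(child)] = sc
    return F, fscale


class _EdgeObjective:
    """lnL as a function of one branch length, everything else fixed."""

    def __init__(self, tree, model, rate_model, patterns, root_freqs, cache):
        self.tree = tree
        self.model = model
        self.rate_model = rate_model
        self.patterns = patterns
        self.root_freqs = root_freqs
        self.cache = cache
        self.refresh()

    def refresh(self):
        rates = self.rate_model.category_rates
        self.pmats = _edge_pmats(self.tree, self.model, rates, self.cache)
        self.partials, self.scales, _ = _postorder_partials(
            self.tree, self.patterns, self.pmats, self.rate_model.n_categories
        )
        self.F, self.fscale = _outside_arrays(
            self.tree, self.patterns, self.pmats, self.partials, self.scales,
            self.root_freqs, self.rate_model.n_categories,
        )

    def lnl_for_edge(self, node, t: float) -> float:
        rates = self.rate_model.category_rates
        Pm = np.stack([transition_matrix(self.cache, t * r) for r in rates])
        D = self.partials[id(node)]
        F = self.F[id(node)]
        lik = np.einsum("pci,cij,pcj->pc", F, Pm, D)
        site = lik @ self.rate_model.category_weights
        with np.errstate(divide="ignore"):
            lnl = np.log(site) + self.scales[id(node)] + self.fscale[id(node)]
        return float(self.patterns.weights @ lnl)


_EDGE_GRID = np.geomspace(BRANCH_MIN, BRANCH_MAX, 13)


def _optimize_edge_length(obj: "_EdgeObjective", node) -> tuple[float, float]:
    """Coarse log-grid scan (the branch-length surface can be multimodal,
    with a saturation plateau at long lengths) followed by a bracketed
    refinement around the best grid point."""
    t0 = node.length or BRANCH_MIN
    grid = np.unique(np.concatenate([_EDGE_GRID, [t0]]))
    vals = np.array([obj.lnl_for_edge(node, t) for t in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi <= lo:
        return float(grid[i]), float(vals[i])
    res = minimize_scalar(
        lambda t: -obj.lnl_for_edge(node, t),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-8},
    )
    if -res.fun > vals[i]:
        return float(res.x), float(-res.fun)
    return float(grid[i]), float(vals[i])


def optimize_branch_lengths(tree: Tree, model: SubstitutionModel,
                            rate_model: RateModel | None,
                            patterns: PatternTable,
                            root_freqs: np.ndarray | None = None,
                            tol: float = SWEEP_TOL, max_sweeps: int = 20,
                            edges=None) -> tuple[Tree, list[float]]:
    """Bracketed one-dimensional optimization per branch, sweeping until the
    improvement falls below `tol`. Returns (tree copy, lnL trace); the trace
    is non-decreasing. Lengths are bounded to [1e-6, 10]."""
    _check_rooting(tree, model)
    rate_model = rate_model or RateModel.uniform()
    tree = tree.copy()
    pi = model.stationary_freqs if root_freqs is None else np.asarray(root_freqs)
    cache = spectral_decompose(model.Q)
    obj = _EdgeObjective(tree, model, rate_model, patterns, pi, cache)
    # `edges`: restrict to edges whose child-side leaf set is listed
    edge_filter = None if edges is None else {frozenset(e) for e in edges}
    trace = [compute_loglik(tree, model, rate_model, patterns, pi,
                            spectral_cache=cache).total_lnl]
    for _ in range(max_sweeps):
        for node in tree.edges():
            if edge_filter is not None:
                side = frozenset(l.name for l in _subtree_leaves(node))
                if side not in edge_filter:
                    continue
            obj.refresh()
            t_new, lnl_new = _optimize_edge_length(obj, node)
            current = obj.lnl_for_edge(node, node.length or BRANCH_MIN)
            if lnl_new > current:
                node.length = t_new
        lnl = compute_loglik(tree, model, rate_model, patterns, pi,
                             spectral_cache=cache).total_lnl
        gain = lnl - trace[-1]
        trace.append(max(lnl, trace[-1]))
        if gain < tol:
            break
    return tree, trace


# ---------------------------------------------------------------------------
# model-parameter optimization

@dataclass
class ModelFit:
    tree: Tree
    model: SubstitutionModel
    rate_model: RateModel
    lnl: float
    trace: list


def _neg_lnl_for_model(theta, template, tree, rate_model, patterns):
    try:
        model = template.updated(np.asarray(theta))
        res = compute_loglik(tree, model, rate_model, patterns)
    except (ModelError, FloatingPointError, np.linalg.LinAlgError):
        return 1e10
    if not np.isfinite(res.total_lnl):
        return 1e10
    return -res.total_lnl


def _optimize_q_params(tree, model, rate_model, patterns):
    try:
        theta0 = model.param_vector()
    except ModelError:
        return model
    if theta0.size == 0:
        return model
    res = minimize(
        _neg_lnl_for_model, theta0,
        args=(model, tree, rate_model, patterns),
        method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-8},
    )
    lnl0 = compute_loglik(tree, model, rate_model, patterns).total_lnl
    if -res.fun <= lnl0:
        return model  # no improvement: keep incumbent
    return model.updated(res.x)


def _optimize_rate_model(tree, model, rate_model, patterns):
    from .models import discretize_rates

    if rate_model.mode not in ("gamma", "gamma+inv"):
        return rate_model
    k = rate_model.n_categories if rate_model.mode == "gamma" \
        else rate_model.n_categories - 1

    def neg(log_alpha, p_inv):
        try:
            rm = discretize_rates(float(np.exp(log_alpha)), p_inv, k)
        except ModelError:
            return 1e10
        r = compute_loglik(tree, model, rm, patterns).total_lnl
        return -r if np.isfinite(r) else 1e10

    p_inv = rate_model.p_invariant
    res = minimize_scalar(lambda la: neg(la, p_inv),
                          bounds=(np.log(0.02), np.log(100.0)),
                          method="bounded", options={"xatol": 1e-4})
    alpha = float(np.exp(res.x))
    if rate_model.mode == "gamma+inv":
        res2 = minimize_scalar(
            lambda p: neg(np.log(alpha), p),
            bounds=(0.0, 0.95), method="bounded", options={"xatol": 1e-4},
        )
        p_inv = float(res2.x)
    return discretize_rates(alpha, p_inv, k)


def optimize_model_params(tree: Tree, model: SubstitutionModel,
                          rate_model: RateModel | None,
                          patterns: PatternTable,
                          tol: float = SWEEP_TOL,
                          max_rounds: int = 10) -> ModelFit:
    """Coordinate ascent over branch lengths, Q parameters and rate
    heterogeneity until the round-over-round lnL gain drops below `tol`."""
    rate_model = rate_model or RateModel.uniform()
    trace = []
    lnl = compute_loglik(tree, model, rate_model, patterns).total_lnl
    for _ in range(max_rounds):
        tree, _ = optimize_branch_lengths(tree, model, rate_model, patterns)
        model = _optimize_q_params(tree, model, rate_model, patterns)
        rate_model = _optimize_rate_model(tree, model, rate_model, patterns)
        new = compute_loglik(tree, model, rate_model, patterns).total_lnl
        trace.append(new)
        if new - lnl < tol:
            lnl = max(new, lnl)
            break
        lnl = new
    return ModelFit(tree=tree, model=model, rate_model=rate_model,
                    lnl=lnl, trace=trace)


# ---------------------------------------------------------------------------
# site-specific rates

def site_rates_empirical_bayes(fit: ModelFit, patterns: PatternTable) -> SiteRates:
    """Posterior-mean rate per site: sum_c r_c P(c | site)."""
    res = compute_loglik(fit.tree, fit.model, fit.rate_model, patterns)
    w = fit.rate_model.category_weights
    post = res.per_category_lik * w[None, :]
    denom = post.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    post = post / denom
    rates = post @ fit.rate_model.category_rates
    cats = np.argmax(post, axis=1)
    return SiteRates(rates=patterns.expand(rates), method="empirical-bayes",
                     categories=patterns.expand(cats))


ML_RATE_MIN = 1e-4
ML_RATE_MAX = 100.0
ML_RATE_GRID = 64


def site_rates_ml(fit: ModelFit, patterns: PatternTable) -> SiteRates:
    """Per-site ML rate: a log-spaced grid scan refined by bracketed search.

    The site rate scales every branch length for that site alone; the fitted
    mixture is replaced by a single per-site multiplier.
    """
    uniform = RateModel.uniform()
    grid = np.concatenate([[ML_RATE_MIN],
                           np.geomspace(ML_RATE_MIN, ML_RATE_MAX, ML_RATE_GRID)[1:]])
    cache = spectral_decompose(fit.model.Q)

    def pattern_lnl(rate: float) -> np.ndarray:
        scaled = fit.tree.copy()
        for n in scaled.edges():
            n.length = (n.length or 0.0) * rate
        res = compute_loglik(scaled, fit.model, uniform, patterns,
                             spectral_cache=cache)
        return res.per_pattern_lnl

    table = np.stack([pattern_lnl(r) for r in grid])   # (grid, patterns)
    best_idx = np.argmax(table, axis=0)
    rates = np.empty(patterns.n_patterns)
    for p in range(patterns.n_patterns):
        i = int(best_idx[p])
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if lo == hi:
            rates[p] = grid[i]
            continue
        res = minimize_scalar(
            lambda r, p=p: -pattern_lnl(r)[p],
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-6},
        )
        rates[p] = res.x if -res.fun >= table[i, p] else grid[i]
    # snap near-boundary refinements onto the declared bounds
    rates = np.clip(rates, ML_RATE_MIN, ML_RATE_MAX)
    return SiteRates(rates=patterns.expand(rates), method="ml")


# ---------------------------------------------------------------------------
# root search

def _unrooted_edge_keys(tree: Tree) -> dict[frozenset, Node]:
    """Map each edge of the unrooted form to a representative child node,
    keyed by the leaf-set split it induces."""
    out = {}
    names = set(tree.leaf_names())
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = frozenset(l.name for l in _subtree_leaves(node))
        key = frozenset([side, frozenset(names - side)])
        out.setdefault(key, node)
    return out


def _subtree_leaves(node: Node):
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


def root_search(tree: Tree, model: SubstitutionModel,
                rate_model: RateModel | None, patterns: PatternTable,
                radius: int | None = 2) -> tuple[Tree, dict[str, float]]:
    """Evaluate root placements on branches within `radius` edges of the
    current root branch (None = all branches). Each candidate is rerooted,
    the two root-adjacent branch lengths re-optimized, and the best candidate
    gets a final full branch-length sweep. Ties keep the incumbent."""
    if not tree.is_rooted:
        raise RootingRequiredError("root_search needs a rooted starting tree")
    rate_model = rate_model or RateModel.uniform()
    if radius == 0:
        lnl = compute_loglik(tree, model, rate_model, patterns).total_lnl
        return tree.copy(), {"current": lnl}

    unrooted = tree.unroot()
    # adjacency over edges of the unrooted tree
    edges = [n for n in unrooted.postorder() if n is not unrooted.root]
    def edge_split(n):
        side = frozenset(l.name for l in _subtree_leaves(n))
        return frozenset([side, frozenset(set(unrooted.leaf_names()) - side)])

    # the current root branch corresponds to the split of either root child
    root_child = tree.root.children[0]
    current_key = frozenset([
        frozenset(l.name for l in _subtree_leaves(root_child)),
        frozenset(set(tree.leaf_names())
                  - {l.name for l in _subtree_leaves(root_child)}),
    ])
    # BFS over edge adjacency (edges sharing a node)
    dist = {id(e): None for e in edges}
    keys = {id(e): edge_split(e) for e in edges}
    start = [e for e in edges if keys[id(e)] == current_key]
    from collections import deque
    dq = deque()
    for e in start:
        dist[id(e)] = 0
        dq.append(e)
    incident: dict[int, list[Node]] = {}
    for e in edges:
        for endpoint in (e, e.parent):
            incident.setdefault(id(endpoint), []).append(e)
    while dq:
        e = dq.popleft()
        for endpoint in (e, e.parent):
            for other in incident.get(id(endpoint), []):
                if dist[id(other)] is None:
                    dist[id(other)] = dist[id(e)] + 1
                    dq.append(other)
    candidates = [e for e in edges
                  if radius is None or (dist[id(e)] is not None and dist[id(e)] <= radius)]

    incumbent_lnl = compute_loglik(tree, model, rate_model, patterns).total_lnl
    best_tree, best_lnl, best_is_incumbent = tree.copy(), incumbent_lnl, True
    report: dict[str, float] = {}
    for e in candidates:
        cand = unrooted.reroot_at_edge(e, fraction=0.5)
        root_sides = [frozenset(l.name for l in _subtree_leaves(c))
                      for c in cand.root.children]
        cand_opt, _ = optimize_branch_lengths(
            cand, model, rate_model, patterns, edges=root_sides,
            tol=1e-9, max_sweeps=6,
        )
        if not model.reversible:
            # rerooting reverses edge directions tree-wide, so fixed lengths
            # handicap candidates unevenly under nonreversible models: give
            # each candidate a short full sweep before comparing
            cand_opt, _ = optimize_branch_lengths(
                cand_opt, model, rate_model, patterns, max_sweeps=2,
            )
        lnl = compute_loglik(cand_opt, model, rate_model, patterns).total_lnl
        label = "|".join(sorted(",".join(sorted(s)) for s in keys[id(e)]))
        report[label] = lnl
        if lnl > best_lnl + 1e-9:
            best_tree, best_lnl, best_is_incumbent = cand_opt, lnl, False
    if not best_is_incumbent:
        best_tree, _ = optimize_branch_lengths(best_tree, model, rate_model, patterns)
        best_lnl = compute_loglik(best_tree, model, rate_model, patterns).total_lnl
    report["best"] = best_lnl
    return best_tree, report
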