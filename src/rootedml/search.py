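"""Tree search: parsimony and NJ starting trees, hill-climbing NNI,
fast/default modes, constrained search and multiple independent runs.

The default search is a stochastic hill-climb: a number of rounds of random
NNI perturbation followed by NNI hill-climbing, keeping the best tree seen.
Ties are always broken toward the lexicographically smallest canonical
Newick string so results are reproducible from the seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .likelihood import compute_loglik, optimize_branch_lengths
from .models import RateModel, SubstitutionModel
from .treeio import Alignment, Node, PatternTable, Tree, compress_patterns


class SearchError(ValueError):
    pass


@dataclass
class SearchConfig:
    mode: str = "default"          # default | fast
    n_runs: int = 1
    constraint: Tree | None = None
    seed: int = 0
    root_radius: int | None = 2    # root search radius for nonreversible models
    perturb_rounds: int = 10       # default-mode exploration rounds

    def __post_init__(self):
        if self.n_runs < 1:
            raise SearchError("n_runs must be >= 1")


@dataclass
class RunRecord:
    run: int
    seed: int
    lnl: float
    tree: Tree

    @property
    def topology_hash(self) -> str:
        import hashlib
        return hashlib.sha1(
            self.tree.canonical_topology().encode()).hexdigest()[:12]


@dataclass
class SearchResult:
    best_tree: Tree
    best_lnl: float
    runs: list


# ---------------------------------------------------------------------------
# parsimony

def _pattern_masks(patterns: PatternTable) -> dict[str, np.ndarray]:
    """taxon -> uint32 bitmask per pattern (bit k = state k allowed)."""
    out = {}
    alph = patterns.alphabet
    for i, taxon in enumerate(patterns.taxa):
        masks = np.empty(patterns.n_patterns, dtype=np.uint32)
        for p, col in enumerate(patterns.columns):
            bits = 0
            for k, allowed in enumerate(alph.partial(col[i])):
                if allowed:
                    bits |= 1 << k
            masks[p] = bits
        out[i if taxon is None else taxon] = masks
    return out


def fitch_score(tree: Tree, patterns: PatternTable) -> int:
    """Minimum number of state changes (Fitch set-intersection DP), summed
    over patterns weighted by their multiplicities."""
    masks = getattr(patterns, "_fitch_masks", None)
    if masks is None:
        masks = _pattern_masks(patterns)
        patterns._fitch_masks = masks
    cost = np.zeros(patterns.n_patterns, dtype=int)
    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = masks[node.name]
            continue
        cur = None
        for child in node.children:
            m = sets[id(child)]
            if cur is None:
                cur = m
                continue
            inter = cur & m
            empty = inter == 0
            cost += empty.astype(int)
            cur = np.where(empty, cur | m, inter)
        sets[id(node)] = cur
    return int(cost @ patterns.weights)


def mp_starting_tree(patterns: PatternTable, seed: int = 0,
                     constraint: Tree | None = None) -> Tree:
    """Randomized stepwise addition under parsimony.

    Taxa are inserted in seeded-shuffled order, each at the placement with
    the lowest Fitch score (ties to the smallest canonical Newick). With a
    constraint tree, placements violating the constraint (restricted to the
    taxa inserted so far) are discarded.
    """
    taxa = list(patterns.taxa)
    if len(taxa) < 3:
        raise SearchError("stepwise addition needs at least 3 taxa")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(taxa))
    root = Node()
    for t in order[:3]:
        root.add(Node(t, 0.1))
    tree = Tree(root)
    for taxon in order[3:]:
        placed = set(tree.leaf_names()) | {taxon}
        best = None
        for edge in tree.edges():
            cand = _insert_leaf(tree, edge, taxon)
            if constraint is not None and not respects_constraint(
                    cand, constraint, partial_ok=True, taxa=placed):
                continue
            score = fitch_score(cand, patterns)
            key = (score, cand.canonical_topology())
            if best is None or key < best[0]:
                best = (key, cand)
        if best is None:
            raise SearchError(
                f"no constraint-compatible placement for taxon {taxon!r}")
        tree = best[1]
    return tree


def _node_path(tree: Tree, node: Node) -> tuple[int, ...]:
    path = []
    while node.parent is not None:
        path.append(node.parent.children.index(node))
        node = node.parent
    return tuple(reversed(path))


def _resolve(tree: Tree, path) -> Node:
    node = tree.root
    for i in path:
        node = node.children[i]
    return node


def _insert_leaf(tree: Tree, edge_child: Node, taxon: str) -> Tree:
    path = _node_path(tree, edge_child)
    t = tree.copy()
    child = _resolve(t, path)
    parent = child.parent
    L = child.length or 0.1
    parent.children[parent.children.index(child)] = (mid := Node(length=L / 2))
    mid.parent = parent
    child.parent = None
    mid.add(child)
    child.length = L / 2
    mid.add(Node(taxon, 0.1))
    return t


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dist: np.ndarray, labels) -> Tree:
    """Classic NJ agglomeration (scikit-bio); negative branch-length
    estimates are clamped to zero."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise SearchError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise SearchError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(dist)) > 1e-12) or np.any(dist < 0):
        raise SearchError("distances must be nonnegative with zero diagonal")
    dm = DistanceMatrix(dist, ids=list(labels))
    sk = nj(dm)
    buf = io.StringIO()
    sk.write(buf)
    tree = Tree.from_newick(buf.getvalue())
    for node in tree.postorder():
        if node is not tree.root and node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def p_distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise mismatch proportions over mutually resolved sites."""
    unknown = set("-?") | ({"N"} if aln.alphabet.name == "dna" else {"X"})
    n = aln.n_taxa
    arrs = [np.array(list(s)) for s in aln.seqs]
    known = [~np.isin(a, list(unknown)) for a in arrs]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = known[i] & known[j]
            m = int(both.sum())
            p = float((arrs[i][both] != arrs[j][both]).sum() / m) if m else 0.0
            D[i, j] = D[j, i] = p
    return D


DISTANCE_CEILING = 10.0


def corrected_distance_matrix(aln: Alignment) -> np.ndarray:
    """JC-corrected distances for DNA, Poisson-corrected for AA; saturated
    pairs (undefined corrections) are mapped to a ceiling of 10."""
    P = p_distance_matrix(aln)
    k = aln.alphabet.n_states
    frac = (k - 1) / k
    D = np.full_like(P, DISTANCE_CEILING)
    ok = P < frac
    D[ok] = -frac * np.log1p(-P[ok] / frac)
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# NNI

def _eligible_nni_edges(tree: Tree) -> list[Node]:
    """Internal edges eligible for NNI. In rooted trees the two root-adjacent
    branches are excluded (root placement is root_search's job)."""
    out = []
    for node in tree.internal_edges():
        if tree.is_rooted and node.parent is tree.root:
            continue
        out.append(node)
    return out


def nni_neighbors(tree: Tree, edge_child: Node) -> list[Tree]:
    """The two subtree swaps across an internal branch. Rooted trees keep
    their root and rootedness."""
    if edge_child.is_leaf:
        raise SearchError("NNI requires an internal branch")
    if edge_child.parent is None:
        raise SearchError("the root has no branch")
    if tree.is_rooted and edge_child.parent is tree.root:
        raise SearchError("root-adjacent branches are not NNI-eligible")
    path = _node_path(tree, edge_child)
    out = []
    for which in (0, 1):
        t = tree.copy()
        _apply_nni(t, path, which)
        out.append(t)
    return out


def _apply_nni(tree: Tree, path, which: int) -> None:
    """Swap child `which` of the edge's child node with the first sibling
    subtree on the parent side."""
    v = _resolve(tree, path)
    u = v.parent
    s = next(c for c in u.children if c is not v)
    c = v.children[which]
    iu, iv = u.children.index(s), v.children.index(c)
    u.children[iu], v.children[iv] = c, s
    c.parent, s.parent = u, v


def respects_constraint(tree: Tree, constraint: Tree,
                        partial_ok: bool = False, taxa=None) -> bool:
    """True iff every nontrivial split of the constraint, restricted to the
    shared taxa, is a split of `tree`. Polytomies in the constraint leave
    the corresponding resolution free."""
    tree_taxa = set(tree.leaf_names())
    cons_taxa = set(constraint.leaf_names())
    if not partial_ok and not cons_taxa <= tree_taxa:
        missing = cons_taxa - tree_taxa
        raise SearchError(f"constraint taxa absent from tree: {sorted(missing)}")
    shared = cons_taxa & tree_taxa
    if taxa is not None:
        shared &= set(taxa)
    if len(shared) < 4:
        return True
    tree_splits = tree.splits(taxa=shared)
    for split in constraint.splits(taxa=shared):
        if split not in tree_splits:
            return False
    return True


# ---------------------------------------------------------------------------
# hill climbing

def hill_climb_nni(tree: Tree, model: SubstitutionModel,
                   rate_model: RateModel | None, patterns: PatternTable,
                   constraint: Tree | None = None,
                   tol: float = 1e-4) -> tuple[Tree, list[float]]:
    """Evaluate all NNI neighbors with branch-length re-optimization, apply
    the best non-conflicting set of strictly improving moves, repeat until no
    move improves the likelihood by more than `tol`. The lnL trace is
    non-decreasing."""
    rate_model = rate_model or RateModel.uniform()
    tree, _ = optimize_branch_lengths(tree, model, rate_model, patterns)
    best_lnl = compute_loglik(tree, model, rate_model, patterns).total_lnl
    trace = [best_lnl]
    while True:
        moves = []  # (gain, path, which, candidate tree, lnl)
        for edge in _eligible_nni_edges(tree):
            path = _node_path(tree, edge)
            for which in (0, 1):
                cand = tree.copy()
                _apply_nni(cand, path, which)
                if constraint is not None and not respects_constraint(cand, constraint):
                    continue
                cand, _ = optimize_branch_lengths(
                    cand, model, rate_model, patterns, max_sweeps=2)
                lnl = compute_loglik(cand, model, rate_model, patterns).total_lnl
                if lnl > best_lnl + tol:
                    moves.append((lnl - best_lnl, path, which, cand, lnl))
        if not moves:
            break
        moves.sort(key=lambda m: (-m[0], m[1], m[2]))
        # moves whose affected regions (the subtree under the edge's parent
        # node) are disjoint commute and can be applied jointly
        chosen, regions = [], []
        for gain, path, which, cand, lnl in moves:
            region = path[:-1]
            if any(_prefix_overlap(region, r) for r in regions):
                continue
            chosen.append((path, which, cand, lnl))
            regions.append(region)
        if len(chosen) > 1:
            joint = tree.copy()
            for path, which, _, _ in chosen:
                _apply_nni(joint, path, which)
            if constraint is not None and not respects_constraint(joint, constraint):
                joint = None
            if joint is not None:
                joint, _ = optimize_branch_lengths(
                    joint, model, rate_model, patterns, max_sweeps=2)
                jl = compute_loglik(joint, model, rate_model, patterns).total_lnl
                if jl >= chosen[0][3]:
                    tree, best_lnl = joint, jl
                    trace.append(best_lnl)
                    continue
        tree, best_lnl = chosen[0][2], chosen[0][3]
        trace.append(best_lnl)
    tree, _ = optimize_branch_lengths(tree, model, rate_model, patterns)
    final = compute_loglik(tree, model, rate_model, patterns).total_lnl
    best_lnl = max(best_lnl, final)
    trace.append(best_lnl)
    return tree, trace


def _prefix_overlap(a: tuple, b: tuple) -> bool:
    k = min(len(a), len(b))
    return a[:k] == b[:k]


def _perturb(tree: Tree, rng, constraint=None) -> Tree:
    """Random NNI shake-up: about half the internal branches get a random
    swap."""
    t = tree.copy()
    edges = _eligible_nni_edges(t)
    if not edges:
        return t
    k = max(1, int(round(0.5 * len(edges))))
    idx = rng.choice(len(edges), size=min(k, len(edges)), replace=False)
    for i in idx:
        path = _node_path(t, edges[i])
        cand = t.copy()
        _apply_nni(cand, path, int(rng.integers(2)))
        if constraint is not None and not respects_constraint(cand, constraint):
            continue
        t = cand
    return t


# ---------------------------------------------------------------------------
# top-level search

def _lex_best(records):
    """Rank by lnL descending, ties toward the smallest canonical Newick."""
    return sorted(records, key=lambda r: (-round(r.lnl, 9),
                                          r.tree.canonical_topology()))


def run_search(alignment: Alignment, model: SubstitutionModel,
               rate_model: RateModel | None = None,
               config: SearchConfig | None = None) -> SearchResult:
    """Multiple independent seeded searches; per-run records ranked by lnL.

    Fast mode: optimize + NNI-hill-climb the MP and NJ starting trees, keep
    the better. Default mode additionally runs `perturb_rounds` rounds of
    random-NNI perturbation + hill-climb from the fast-mode tree.
    """
    config = config or SearchConfig()
    rate_model = rate_model or RateModel.uniform()
    patterns = compress_patterns(alignment)
    if alignment.n_taxa < 3:
        raise SearchError("tree search needs at least 3 taxa")

    needs_root = not model.reversible
    records = []
    for run in range(config.n_runs):
        run_seed = config.seed + run
        rng = np.random.default_rng(run_seed)
        if alignment.n_taxa == 3:
            root = Node()
            for t in alignment.taxa:
                root.add(Node(t, 0.1))
            tree = Tree(root)
            tree = _prepare(tree, needs_root)
            tree, _ = optimize_branch_lengths(tree, model, rate_model, patterns)
            lnl = compute_loglik(tree, model, rate_model, patterns).total_lnl
            records.append(RunRecord(run, run_seed, lnl, tree))
            continue
        starts = [mp_starting_tree(patterns, seed=run_seed,
                                   constraint=config.constraint)]
        njt = nj_tree(corrected_distance_matrix(alignment), alignment.taxa)
        if config.constraint is None or respects_constraint(njt, config.constraint):
            starts.append(njt)
        best = None
        for start in starts:
            start = _prepare(start, needs_root)
            tree, _ = hill_climb_nni(start, model, rate_model, patterns,
                                     constraint=config.constraint)
            lnl = compute_loglik(tree, model, rate_model, patterns).total_lnl
            cand = (lnl, tree)
            if best is None or _better(cand, best):
                best = cand
        if config.mode == "default":
            for _ in range(config.perturb_rounds):
                shaken = _perturb(best[1], rng, config.constraint)
                tree, _ = hill_climb_nni(shaken, model, rate_model, patterns,
                                         constraint=config.constraint)
                lnl = compute_loglik(tree, model, rate_model, patterns).total_lnl
                if _better((lnl, tree), best):
                    best = (lnl, tree)
        if needs_root:
            from .likelihood import root_search
            tree, report = root_search(best[1], model, rate_model, patterns,
                                       radius=config.root_radius)
            best = (report["best"], tree)
        records.append(RunRecord(run, run_seed, best[0], best[1]))

    ranked = _lex_best(records)
    return SearchResult(best_tree=ranked[0].tree, best_lnl=ranked[0].lnl,
                        runs=ranked)


def _better(cand, incumbent) -> bool:
    if cand[0] > incumbent[0] + 1e-9:
        return True
    if cand[0] < incumbent[0] - 1e-9:
        return False
    return (cand[1].canonical_topology() < incumbent[1].canonical_topology())


def _prepare(tree: Tree, needs_root: bool) -> Tree:
    """Root (deterministically, on the edge above the smallest leaf label)
    when the model requires it; otherwise keep the unrooted form."""
    if not needs_root:
        return tree
    if tree.is_rooted:
        return tree
    return tree.reroot_at_edge(min(tree.leaf_names()))


def summary_table(result: SearchResult) -> str:
    lines = ["run\tseed\tlnL\ttopology"]
    for r in result.runs:
        lines.append(f"{r.run}\t{r.seed}\t{r.lnl:.6f}\t{r.topology_hash}")
    return "\n".join(lines) + "\n"
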