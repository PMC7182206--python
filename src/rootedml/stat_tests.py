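"""Branch supports and tree topology tests over RELL resampling.

Branch supports compare the ML arrangement around an internal branch with
its two NNI alternatives: the parametric aLRT (one-sided mixture
0.5*chi2_0 + 0.5*chi2_1), the nonparametric SH-aLRT (RELL with per-
configuration centering) and the aBayes posterior under a uniform prior
over the three arrangements.

Topology tests (SH, AU, ELW) operate on a trees x sites matrix of site
log-likelihoods; bootstrap replicates resample estimated log-likelihoods
(RELL) rather than re-fitting. Site, gene and gene-site resampling schemes
are supported; one shared multinomial weight stream per replicate keeps the
comparisons paired across trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from .likelihood import compute_loglik, optimize_branch_lengths
from .models import RateModel, SubstitutionModel
from .search import _apply_nni, _node_path, nni_neighbors
from .treeio import PatternTable, Tree


class TestError(ValueError):
    pass


class AUDegeneracyError(TestError):
    pass


@dataclass
class BranchSupport:
    branch: str                 # leaf-set label of the child side
    alrt_statistic: float
    alrt_support: float         # [0, 1]
    sh_alrt_support: float | None = None   # percentage [0, 100]
    abayes_posterior: float | None = None  # [1/3, 1]


@dataclass
class TopologyTestReport:
    lnl: np.ndarray
    delta_lnl: np.ndarray
    sh_p: np.ndarray | None = None
    au_p: np.ndarray | None = None
    elw: np.ndarray | None = None
    scheme: str = "site"
    n_reps: int = 0
    seed: int = 0

    def to_tsv(self) -> str:
        cols = ["tree", "lnL", "deltaL"]
        if self.sh_p is not None:
            cols.append("p_SH")
        if self.au_p is not None:
            cols.append("p_AU")
        if self.elw is not None:
            cols.append("ELW")
        lines = ["\t".join(cols)]
        for i in range(len(self.lnl)):
            row = [str(i + 1), f"{self.lnl[i]:.6f}", f"{self.delta_lnl[i]:.6f}"]
            if self.sh_p is not None:
                row.append(f"{self.sh_p[i]:.4f}")
            if self.au_p is not None:
                row.append(f"{self.au_p[i]:.4f}")
            if self.elw is not None:
                row.append(f"{self.elw[i]:.4f}")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# site log-likelihood matrices

def site_lnl_matrix(trees, model: SubstitutionModel,
                    rate_model: RateModel | None, patterns: PatternTable,
                    optimize: bool = True) -> np.ndarray:
    """trees x sites matrix of per-site log-likelihoods (pattern-compressed
    internally, expanded back to sites). Row sums equal each tree's total."""
    taxa = None
    for t in trees:
        s = frozenset(t.leaf_names())
        if taxa is None:
            taxa = s
        elif s != taxa:
            raise TestError("all trees must share one taxon set")
    rows = []
    for t in trees:
        if optimize:
            t, _ = optimize_branch_lengths(t, model, rate_model, patterns)
        rows.append(compute_loglik(t, model, rate_model, patterns).per_site_lnl)
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# RELL resampling

def rell_resample(site_lnl: np.ndarray, scheme: str = "site",
                  partition_map=None, n_reps: int = 1000, seed: int = 0,
                  scale: float = 1.0) -> np.ndarray:
    """Replicate log-likelihoods (trees x reps) under the site, gene or
    gene-site bootstrap. Multinomial draws; one weight stream shared by all
    trees per replicate."""
    if scale <= 0:
        raise TestError("scale must be positive")
    M = np.asarray(site_lnl, dtype=float)
    n_trees, n_sites = M.shape
    rng = np.random.default_rng(seed)
    if scheme == "site":
        size = max(1, int(round(scale * n_sites)))
        counts = rng.multinomial(size, np.full(n_sites, 1.0 / n_sites),
                                 size=n_reps)
        return M @ counts.T
    if partition_map is None or not partition_map:
        raise TestError(f"{scheme} resampling needs a partition map")
    genes = list(partition_map)
    covered = sorted(i for g in genes for i in partition_map[g])
    if covered != list(range(n_sites)):
        raise TestError("partition map must cover every site exactly once")
    gene_sums = np.stack(
        [M[:, partition_map[g]].sum(axis=1) for g in genes], axis=1
    )  # trees x genes
    n_genes = len(genes)
    size = max(1, int(round(scale * n_genes)))
    gene_counts = rng.multinomial(size, np.full(n_genes, 1.0 / n_genes),
                                  size=n_reps)
    if scheme == "gene":
        return gene_sums @ gene_counts.T
    if scheme == "gene-site":
        out = np.zeros((n_trees, n_reps))
        for r in range(n_reps):
            for gi, g in enumerate(genes):
                reps_of_gene = gene_counts[r, gi]
                if reps_of_gene == 0:
                    continue
                sites = partition_map[g]
                L = len(sites)
                c = rng.multinomial(reps_of_gene * L, np.full(L, 1.0 / L))
                out[:, r] += M[:, sites] @ c
        return out
    raise TestError(f"unknown resampling scheme {scheme!r}")


# ---------------------------------------------------------------------------
# branch configurations

def _branch_configurations(tree: Tree, edge_child, model, rate_model,
                           patterns):
    """The fitted tree plus its two NNI rearrangements around the branch,
    branch lengths re-optimized (2 sweeps) for each."""
    base, _ = optimize_branch_lengths(tree, model, rate_model, patterns,
                                      max_sweeps=2)
    path = _node_path(tree, edge_child)
    configs = [base]
    for which in (0, 1):
        alt = tree.copy()
        _apply_nni(alt, path, which)
        alt, _ = optimize_branch_lengths(alt, model, rate_model, patterns,
                                         max_sweeps=2)
        configs.append(alt)
    return configs


def _branch_label(tree: Tree, edge_child) -> str:
    from .likelihood import _subtree_leaves
    return ",".join(sorted(l.name for l in _subtree_leaves(edge_child)))


def alrt(tree: Tree, edge_child, model: SubstitutionModel,
         rate_model: RateModel | None, patterns: PatternTable) -> BranchSupport:
    """Approximate likelihood-ratio branch test.

    statistic = 2(lnL_ML - lnL_second-best NNI); support = 1 - p under the
    0.5*chi2_0 + 0.5*chi2_1 mixture. A zero statistic maps to the mixture's
    mass-at-zero floor: support 0.
    """
    if edge_child.is_leaf:
        raise TestError("aLRT is defined for internal branches")
    configs = _branch_configurations(tree, edge_child, model, rate_model,
                                     patterns)
    lnls = np.array([
        compute_loglik(c, model, rate_model, patterns).total_lnl
        for c in configs
    ])
    stat = max(0.0, 2.0 * (lnls[0] - max(lnls[1], lnls[2])))
    support = 0.0 if stat <= 0 else 1.0 - 0.5 * chi2.sf(stat, df=1)
    return BranchSupport(branch=_branch_label(tree, edge_child),
                         alrt_statistic=stat, alrt_support=support)


def abayes(tree: Tree, edge_child, model: SubstitutionModel,
           rate_model: RateModel | None, patterns: PatternTable) -> float:
    """Bayesian-like branch support: exp-normalized (max-shifted) posterior
    of the ML arrangement under a uniform prior over the three."""
    configs = _branch_configurations(tree, edge_child, model, rate_model,
                                     patterns)
    lnls = np.array([
        compute_loglik(c, model, rate_model, patterns).total_lnl
        for c in configs
    ])
    w = np.exp(lnls - lnls.max())
    return float(w[0] / w.sum())


def sh_alrt(tree: Tree, edge_child, model: SubstitutionModel,
            rate_model: RateModel | None, patterns: PatternTable,
            n_reps: int = 1000, seed: int = 0) -> float:
    """SH-like nonparametric aLRT support (percentage).

    RELL replicates of the three arrangements' site lnLs are centered by
    their expected totals; the support is the percentage of replicates in
    which the observed statistic exceeds the centered null statistic.
    """
    configs = _branch_configurations(tree, edge_child, model, rate_model,
                                     patterns)
    M = np.vstack([
        compute_loglik(c, model, rate_model, patterns).per_site_lnl
        for c in configs
    ])
    totals = M.sum(axis=1)
    order = np.argsort(totals)[::-1]
    obs = 2.0 * (totals[order[0]] - totals[order[1]])
    R = rell_resample(M, "site", n_reps=n_reps, seed=seed)
    C = R - totals[:, None]          # centered replicate totals
    Cs = np.sort(C, axis=0)[::-1]
    null = 2.0 * (Cs[0] - Cs[1])
    eps = 1e-10
    return float(100.0 * np.mean(obs > null + eps))


# ---------------------------------------------------------------------------
# topology tests

def sh_test(site_lnl: np.ndarray, n_reps: int = 10_000, seed: int = 0) -> np.ndarray:
    """Shimodaira-Hasegawa test p-values per tree (centered RELL maxima)."""
    M = np.asarray(site_lnl, dtype=float)
    if M.shape[0] < 2:
        raise TestError("SH test needs at least 2 trees")
    totals = M.sum(axis=1)
    delta = totals.max() - totals
    R = rell_resample(M, "site", n_reps=n_reps, seed=seed)
    C = R - R.mean(axis=1, keepdims=True)   # center by mean replicate lnL
    null = C.max(axis=0)[None, :] - C       # trees x reps
    return (null >= delta[:, None]).mean(axis=1)


def elw(site_lnl: np.ndarray, n_reps: int = 10_000, seed: int = 0) -> np.ndarray:
    """Expected likelihood weights: mean exp-normalized replicate weight."""
    M = np.asarray(site_lnl, dtype=float)
    R = rell_resample(M, "site", n_reps=n_reps, seed=seed)
    W = np.exp(R - R.max(axis=0, keepdims=True))
    W = W / W.sum(axis=0, keepdims=True)
    return W.mean(axis=1)


AU_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))


def au_test(site_lnl: np.ndarray, scales=AU_SCALES, n_reps: int = 10_000,
            seed: int = 0) -> np.ndarray:
    """Approximately unbiased test p-values via multiscale RELL bootstrap.

    At each scale r the bootstrap proportion BP_r (replicates where the tree
    is best, ties split) is mapped to z = Phi^-1(1 - BP); z(r) = d*sqrt(r) +
    c/sqrt(r) is fitted by weighted least squares (binomial variance
    weights) and p_AU = 1 - Phi(d - c). Trees never/always best at every
    scale get p = 0 / 1 with a degeneracy warning.
    """
    M = np.asarray(site_lnl, dtype=float)
    if M.shape[0] < 2:
        raise TestError("AU test needs at least 2 trees")
    if len(scales) < 2:
        raise TestError("AU test needs at least 2 scales")
    n_trees = M.shape[0]
    bp = np.zeros((len(scales), n_trees))
    for si, r in enumerate(scales):
        R = rell_resample(M, "site", n_reps=n_reps, seed=seed + si,
                          scale=float(r))
        mx = R.max(axis=0, keepdims=True)
        ties = np.isclose(R, mx, rtol=0.0, atol=1e-9)
        bp[si] = (ties / ties.sum(axis=0, keepdims=True)).sum(axis=1) / n_reps
    p = np.empty(n_trees)
    for i in range(n_trees):
        p[i] = _au_fit(bp[:, i], np.asarray(scales, dtype=float), n_reps)
    return p


def _au_fit(bp: np.ndarray, scales: np.ndarray, n_reps: int) -> float:
    good = (bp > 0.0) & (bp < 1.0)
    if not np.any(good):
        warnings.warn("AU: bootstrap proportions degenerate at every scale")
        return 0.0 if bp.mean() < 0.5 else 1.0
    if good.sum() < 2:
        raise AUDegeneracyError("fewer than 2 non-degenerate scales")
    r = scales[good]
    z = norm.isf(bp[good])          # Phi^-1(1 - BP)
    dens = norm.pdf(z)
    var = bp[good] * (1.0 - bp[good]) / n_reps
    w = dens ** 2 / var
    X = np.stack([np.sqrt(r), 1.0 / np.sqrt(r)], axis=1)
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
    d, c = beta
    return float(norm.sf(d - c))


# ---------------------------------------------------------------------------
# convenience drivers

def topology_tests(trees, model, rate_model, patterns,
                   tests=("sh", "au", "elw"), n_reps: int = 10_000,
                   seed: int = 0) -> TopologyTestReport:
    M = site_lnl_matrix(trees, model, rate_model, patterns)
    totals = M.sum(axis=1)
    report = TopologyTestReport(
        lnl=totals, delta_lnl=totals.max() - totals,
        scheme="site", n_reps=n_reps, seed=seed,
    )
    if "sh" in tests:
        report.sh_p = sh_test(M, n_reps=n_reps, seed=seed)
    if "au" in tests:
        report.au_p = au_test(M, n_reps=n_reps, seed=seed)
    if "elw" in tests:
        report.elw = elw(M, n_reps=n_reps, seed=seed)
    return report


def branch_supports(tree: Tree, model, rate_model, patterns,
                    sh_reps: int = 1000, seed: int = 0,
                    do_abayes: bool = True) -> list[BranchSupport]:
    """aLRT + SH-aLRT (+ aBayes) for every NNI-eligible internal branch."""
    from .search import _eligible_nni_edges
    out = []
    for edge in _eligible_nni_edges(tree):
        sup = alrt(tree, edge, model, rate_model, patterns)
        sup.sh_alrt_support = sh_alrt(tree, edge, model, rate_model, patterns,
                                      n_reps=sh_reps, seed=seed)
        if do_abayes:
            sup.abayes_posterior = abayes(tree, edge, model, rate_model,
                                          patterns)
        out.append(sup)
    return out


def annotate_supports(tree: Tree, supports) -> Tree:
    """Write 'aLRT/SH-aLRT/aBayes' labels onto internal nodes (by the
    child-side leaf set)."""
    from .likelihood import _subtree_leaves
    t = tree.copy()
    by_label = {s.branch: s for s in supports}
    for node in t.postorder():
        if node.is_leaf or node is t.root:
            continue
        key = ",".join(sorted(l.name for l in _subtree_leaves(node)))
        if key in by_label:
            s = by_label[key]
            parts = [f"{s.alrt_support:.3f}"]
            if s.sh_alrt_support is not None:
                parts.append(f"{s.sh_alrt_support:.1f}")
            if s.abayes_posterior is not None:
                parts.append(f"{s.abayes_posterior:.3f}")
            node.name = "/".join(parts)
    return t
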