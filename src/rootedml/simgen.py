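"""Random trees and sequence simulation under any supported model.

Every fixture in the test suite is generated here, so no external data is
required. The random stream is consumed in a documented order (per-site rate
categories, then root states, then branch transitions in depth-first
preorder), making simulations reproducible from the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import RateModel, SubstitutionModel
from .transprob import spectral_decompose, transition_matrix
from .treeio import ALPHABETS, Alignment, Node, Tree


@dataclass
class SimSpec:
    tree: Tree
    model: SubstitutionModel
    rate_model: RateModel | None = None
    root_freqs: np.ndarray | None = None
    n_sites: int = 1000
    seed: int = 0
    # loci x taxa dropout: list of (site_range, [taxa missing]) entries
    missing: list = field(default_factory=list)


def random_tree(n_leaves: int, style: str = "yule", mean_length: float = 0.1,
                seed: int = 0, prefix: str = "t") -> Tree:
    """Rooted binary tree with exponential branch lengths.

    Styles: 'yule' (random splitting), 'balanced', 'caterpillar'.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i + 1}" for i in range(n_leaves)]

    if style == "yule":
        root = Node()
        tips = [root.add(Node(labels[0])), root.add(Node(labels[1]))]
        for lab in labels[2:]:
            tip = tips[rng.integers(len(tips))]
            left = Node(tip.name)
            right = Node(lab)
            tip.name = None
            tip.add(left)
            tip.add(right)
            tips.remove(tip)
            tips.extend([left, right])
    elif style == "caterpillar":
        root = Node()
        spine = root
        for lab in labels[:-2]:
            spine.add(Node(lab))
            nxt = Node()
            spine.add(nxt)
            spine = nxt
        # replace the trailing empty internal with the final cherry
        spine.add(Node(labels[-2]))
        spine.add(Node(labels[-1]))
    elif style == "balanced":
        def build(labs):
            if len(labs) == 1:
                return Node(labs[0])
            mid = len(labs) // 2
            n = Node()
            n.add(build(labs[:mid]))
            n.add(build(labs[mid:]))
            return n
        root = build(labels)
    else:
        raise ValueError(f"unknown tree style {style!r}")

    tree = Tree(root)
    for node in tree.postorder():
        if node is not tree.root:
            node.length = max(float(rng.exponential(mean_length)), 1e-8)
    return tree


def simulate_alignment(spec: SimSpec) -> Alignment:
    """Simulate characters down the tree.

    Root states are i.i.d. from the root frequencies; each site carries a
    rate category drawn from the rate model; children are drawn through
    P(t * r) along each branch in depth-first preorder. Missing-data entries
    blank out whole taxon rows within a site range.
    """
    model, tree = spec.model, spec.tree
    if not model.reversible and not tree.is_rooted:
        raise ValueError("nonreversible simulation requires a rooted tree")
    rate_model = spec.rate_model or RateModel.uniform()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    pi = (np.asarray(spec.root_freqs) if spec.root_freqs is not None
          else model.stationary_freqs)
    states = ALPHABETS[model.alphabet].states
    n_states = model.n_states

    cats = rng.choice(rate_model.n_categories, size=n, p=rate_model.category_weights)
    site_rates = rate_model.category_rates[cats]
    root_states = rng.choice(n_states, size=n, p=pi / pi.sum())

    cache = spectral_decompose(model.Q)
    unique_rates = np.unique(site_rates)
    assignments: dict[int, np.ndarray] = {id(tree.root): root_states}
    seqs: dict[str, np.ndarray] = {}
    stack = [tree.root]
    order = []
    while stack:  # preorder, children left-to-right
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(node.children))
    for node in order:
        if node is tree.root:
            continue
        parent_states = assignments[id(node.parent)]
        t = node.length or 0.0
        child_states = np.empty(n, dtype=int)
        for r in unique_rates:
            mask = site_rates == r
            P = transition_matrix(cache, t * r)
            rows = P / P.sum(axis=1, keepdims=True)
            sub = parent_states[mask]
            u = rng.random(sub.size)
            cdf = np.cumsum(rows, axis=1)
            child_states[mask] = np.minimum(
                (u[:, None] > cdf[sub]).sum(axis=1), n_states - 1
            )
        assignments[id(node)] = child_states
        if node.is_leaf:
            seqs[node.name] = child_states

    unknown = "?" if model.alphabet == "binary" else (
        "N" if model.alphabet == "dna" else "X")
    taxa = tree.leaf_names()
    rows = {t: np.array([states[s] for s in seqs[t]]) for t in taxa}
    for site_range, missing_taxa in spec.missing:
        idx = np.asarray(list(site_range))
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValueError("missing-data mask outside simulated sites")
        for t in missing_taxa:
            rows[t][idx] = unknown
    return Alignment(taxa, ["".join(rows[t]) for t in taxa],
                     ALPHABETS[model.alphabet])


def write_manifest(spec: SimSpec, path: str) -> None:
    """Plain-text key=value record of a simulation for test harnesses."""
    with open(path, "w") as fh:
        fh.write(f"model={spec.model.name or spec.model.kind}\n")
        fh.write(f"n_sites={spec.n_sites}\n")
        fh.write(f"seed={spec.seed}\n")
        rm = spec.rate_model or RateModel.uniform()
        fh.write(f"rate_mode={rm.mode}\n")
        if rm.gamma_shape is not None:
            fh.write(f"gamma_shape={rm.gamma_shape}\n")
        fh.write(f"tree={spec.tree.newick()}\n")
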