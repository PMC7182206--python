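"""Quartet likelihood mapping.

For each sampled quartet the exact ML value of the three resolved
topologies (12|34, 13|24, 14|23) is computed by optimizing all five branch
lengths with model parameters frozen at their full-alignment estimates. The
three log-likelihoods are exp-normalized into posterior weights, placed in
the barycentric simplex, and tallied over the classic seven regions: three
corner triangles (resolved signal), three edge rectangles (conflict between
two topologies) and a central triangle (star-like noise).

Region geometry: corner i is cut off by the line p_i = 2/3, the center is
the triangle where every weight exceeds 1/6, and the three quadrilaterals
between them are the edge regions. Boundary points go to the region with
the lexicographically smallest tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .likelihood import compute_loglik, optimize_branch_lengths
from .models import RateModel, SubstitutionModel
from .treeio import Alignment, Node, Tree, compress_patterns

REGION_TAGS = ("c1", "c2", "c3", "e12", "e13", "e23", "center")
TOPOLOGY_LABELS = ("12|34", "13|24", "14|23")


@dataclass
class QuartetResult:
    taxa: tuple
    lnl: np.ndarray          # 3 topologies
    posteriors: np.ndarray   # simplex-3
    region: str


@dataclass
class MappingResult:
    region_counts: dict
    quartets: list

    @property
    def n_quartets(self) -> int:
        return len(self.quartets)

    def corner_fraction(self) -> float:
        c = sum(self.region_counts[t] for t in ("c1", "c2", "c3"))
        return c / max(self.n_quartets, 1)


def _quartet_tree(a, b, c, d) -> Tree:
    """Unrooted quartet ab|cd with unit starting lengths."""
    root = Node()
    root.add(Node(a, 0.1))
    root.add(Node(b, 0.1))
    inner = root.add(Node(length=0.1))
    inner.add(Node(c, 0.1))
    inner.add(Node(d, 0.1))
    return Tree(root)


def quartet_ml(alignment: Alignment, taxa, model: SubstitutionModel,
               rate_model: RateModel | None = None) -> np.ndarray:
    """lnL of the three quartet topologies, branch lengths optimized, model
    parameters held fixed."""
    taxa = tuple(taxa)
    if len(set(taxa)) != 4:
        raise ValueError("quartet needs 4 distinct taxa")
    sub = alignment.subset_taxa(list(taxa))
    empty = set(sub.taxa) - set(sub.present_taxa())
    if empty:
        raise AllUnknownSequenceError(sorted(empty))
    patterns = compress_patterns(sub)
    a, b, c, d = taxa
    tops = [_quartet_tree(a, b, c, d), _quartet_tree(a, c, b, d),
            _quartet_tree(a, d, b, c)]
    out = np.empty(3)
    for k, tree in enumerate(tops):
        if not model.reversible:
            tree = tree.reroot_at_edge(min(taxa))
        opt, _ = optimize_branch_lengths(tree, model, rate_model, patterns)
        out[k] = compute_loglik(opt, model, rate_model, patterns).total_lnl
    return out


class AllUnknownSequenceError(ValueError):
    def __init__(self, taxa):
        self.taxa = taxa
        super().__init__(f"taxa with all-unknown sequences: {taxa}")


def quartet_posteriors(lnls) -> np.ndarray:
    """exp-normalized (max-shifted) posterior weights of the 3 topologies."""
    lnls = np.asarray(lnls, dtype=float)
    if not np.all(np.isfinite(lnls)):
        raise ValueError("quartet lnLs must be finite")
    w = np.exp(lnls - lnls.max())
    return w / w.sum()


def simplex_region(p) -> str:
    """Assign a barycentric point to one of the 7 likelihood-mapping
    regions."""
    p = np.asarray(p, dtype=float)
    if p.min() < -1e-9 or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("not a simplex point")
    sixth = 1.0 / 6.0
    if np.all(p > sixth):
        return "center"
    corners = [i for i in range(3) if p[i] >= 2.0 / 3.0]
    if corners:
        return f"c{min(corners) + 1}"
    # remaining band: edge region of the two dominant topologies
    k = int(np.argmin(p))
    pair = sorted({0, 1, 2} - {k})
    return f"e{pair[0] + 1}{pair[1] + 1}"


def likelihood_mapping(alignment: Alignment, model: SubstitutionModel,
                       rate_model: RateModel | None = None,
                       n_quartets="all", clusters=None,
                       seed: int = 0) -> MappingResult:
    """Tally quartet posteriors over the seven simplex regions.

    `n_quartets='all'` evaluates every quartet up to a cap of 10,000, above
    which that many are sampled without replacement. With 4 taxon clusters,
    quartets draw one taxon per cluster.
    """
    rng = np.random.default_rng(seed)
    taxa = list(alignment.taxa)
    if clusters is not None:
        clusters = [list(c) for c in clusters]
        if not 2 <= len(clusters) <= 4:
            raise ValueError("cluster mode supports 2-4 groups")
        flat = [t for c in clusters for t in c]
        if len(set(flat)) != len(flat):
            raise ValueError("clusters must be disjoint")
        pool = _cluster_quartets(clusters)
    else:
        if len(taxa) < 4:
            raise ValueError("need at least 4 taxa")
        pool = list(combinations(taxa, 4))

    cap = 10_000
    budget = cap if n_quartets == "all" else int(n_quartets)
    if budget >= len(pool):
        if n_quartets != "all" and budget > len(pool):
            warnings.warn("requested more quartets than exist; evaluating all")
        sample = pool
    else:
        idx = rng.choice(len(pool), size=budget, replace=False)
        sample = [pool[i] for i in sorted(idx)]

    counts = {t: 0 for t in REGION_TAGS}
    quartets = []
    for quartet in sample:
        try:
            lnls = quartet_ml(alignment, quartet, model, rate_model)
        except AllUnknownSequenceError as exc:
            warnings.warn(f"skipping quartet {quartet}: {exc}")
            continue
        post = quartet_posteriors(lnls)
        region = simplex_region(post)
        counts[region] += 1
        quartets.append(QuartetResult(tuple(quartet), lnls, post, region))
    return MappingResult(region_counts=counts, quartets=quartets)


def _cluster_quartets(clusters):
    """One taxon per cluster for 4 clusters; for 2-3 clusters the remaining
    slots are filled from distinct members of the same groups."""
    if len(clusters) == 4:
        out = []
        for a in clusters[0]:
            for b in clusters[1]:
                for c in clusters[2]:
                    for d in clusters[3]:
                        out.append((a, b, c, d))
        return out
    # 2 or 3 groups: draw pairs within groups to keep group contrast
    out = []
    if len(clusters) == 2:
        for a, b in combinations(clusters[0], 2):
            for c, d in combinations(clusters[1], 2):
                out.append((a, b, c, d))
    else:
        for a, b in combinations(clusters[0], 2):
            for c in clusters[1]:
                for d in clusters[2]:
                    out.append((a, b, c, d))
    return out


def mapping_report(result: MappingResult) -> str:
    n = max(result.n_quartets, 1)
    lines = ["region\tcount\tpercent"]
    for tag in REGION_TAGS:
        c = result.region_counts[tag]
        lines.append(f"{tag}\t{c}\t{100.0 * c / n:.2f}")
    lines.append(f"total\t{result.n_quartets}\t100.00")
    return "\n".join(lines) + "\n"


def quartet_table(result: MappingResult) -> str:
    head = ["taxon1", "taxon2", "taxon3", "taxon4",
            "lnL_12|34", "lnL_13|24", "lnL_14|23",
            "p_12|34", "p_13|24", "p_14|23", "region"]
    lines = ["\t".join(head)]
    for q in result.quartets:
        lines.append("\t".join(
            list(q.taxa)
            + [f"{v:.6f}" for v in q.lnl]
            + [f"{v:.6g}" for v in q.posteriors]
            + [q.region]
        ))
    return "\n".join(lines) + "\n"
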