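"""Missing-data machinery: induced single-locus trees, terrace detection,
per-locus inference and cost-ranked scheduling.

When loci are missing for some species, a species tree induces one tree per
locus by dropping the absent taxa. Two species trees whose induced
single-locus topologies coincide for every locus lie on the same
phylogenetic terrace: under an edge-unlinked partitioned model their
likelihoods are identical, so the data cannot distinguish them. Detection
here is pairwise over an explicit candidate set; agreement on a subset of
loci is reported as a partial terrace.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .treeio import (Alignment, Tree, compress_patterns, read_alignment,
                     read_partition_file)


class GenomicError(ValueError):
    pass


@dataclass
class CoverageMatrix:
    loci: list                 # locus names, order preserved
    taxa: list
    present: np.ndarray        # loci x taxa booleans
    site_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.loci), len(self.taxa)):
            raise GenomicError("coverage matrix shape mismatch")
        empty = [self.loci[i] for i in range(len(self.loci))
                 if not self.present[i].any()]
        if empty:
            raise GenomicError(f"loci with no present taxon: {empty}")

    def taxa_for(self, locus: str):
        i = self.loci.index(locus)
        return [t for t, p in zip(self.taxa, self.present[i]) if p]

    @classmethod
    def from_alignment(cls, aln: Alignment, partition: dict) -> "CoverageMatrix":
        """Presence = at least one resolved character within the locus."""
        unknown = set("-?") | ({"N"} if aln.alphabet.name == "dna" else {"X"})
        loci = list(partition)
        present = np.zeros((len(loci), aln.n_taxa), dtype=bool)
        counts = {}
        for i, locus in enumerate(loci):
            sites = partition[locus]
            counts[locus] = len(sites)
            for j, seq in enumerate(aln.seqs):
                present[i, j] = any(seq[s] not in unknown for s in sites)
        return cls(loci, list(aln.taxa), present, counts)


@dataclass
class LocusJob:
    locus: str
    n_sequences: int
    n_patterns: int
    n_states: int
    assigned_worker: int = -1

    @property
    def cost(self) -> int:
        return self.n_sequences * self.n_patterns * self.n_states


def induced_tree(tree: Tree, taxa) -> Tree:
    """Species tree restricted to the taxa present for a locus (degree-2
    nodes suppressed, branch lengths summed)."""
    taxa = list(taxa)
    if not taxa:
        raise GenomicError("empty taxon subset")
    return tree.restrict(taxa)


def on_same_terrace(tree_a: Tree, tree_b: Tree,
                    coverage: CoverageMatrix) -> tuple[bool, list[bool]]:
    """True iff every induced single-locus unrooted topology agrees; the
    per-locus agreement vector supports partial-terrace reporting."""
    if set(tree_a.leaf_names()) != set(tree_b.leaf_names()):
        raise GenomicError("trees must share one leaf set")
    agreement = []
    for locus in coverage.loci:
        taxa = coverage.taxa_for(locus)
        ta = induced_tree(tree_a, taxa)
        tb = induced_tree(tree_b, taxa)
        if len(taxa) <= 3:
            agreement.append(True)
            continue
        agreement.append(
            ta.canonical_topology(rooted=False) == tb.canonical_topology(rooted=False)
        )
    return all(agreement), agreement


@dataclass
class TerraceReport:
    members: list              # candidate trees on the ML tree's terrace
    agreements: list           # per-member per-locus agreement vectors
    loci: list

    def advice(self) -> str:
        if not self.members:
            return "No candidate tree lies on the ML tree's terrace.\n"
        lines = [
            f"{len(self.members)} candidate tree(s) lie on the same terrace "
            "as the ML tree; the data cannot distinguish them under an "
            "edge-unlinked partitioned model. Consider gathering more loci "
            "or filtering gappy taxa.",
        ]
        for k, agree in enumerate(self.agreements):
            n_ok = sum(agree)
            lines.append(f"  member {k + 1}: {n_ok}/{len(self.loci)} loci agree")
        return "\n".join(lines) + "\n"


def terrace_neighborhood(ml_tree: Tree, coverage: CoverageMatrix,
                         candidates) -> TerraceReport:
    """Filter candidate trees by terrace co-membership with the ML tree.
    Candidates topologically identical to the ML tree are not reported."""
    candidates = list(candidates)
    if not candidates:
        raise GenomicError("candidate set must be nonempty")
    ml_canon = ml_tree.canonical_topology(rooted=False)
    members, agreements = [], []
    for cand in candidates:
        if cand.canonical_topology(rooted=False) == ml_canon:
            continue
        same, agree = on_same_terrace(ml_tree, cand, coverage)
        if same:
            members.append(cand)
            agreements.append(agree)
    return TerraceReport(members=members, agreements=agreements,
                         loci=list(coverage.loci))


# ---------------------------------------------------------------------------
# scheduling

def schedule_loci(jobs, k: int) -> list[LocusJob]:
    """Longest-processing-time greedy assignment to k workers.

    Jobs are ranked by cost descending (ties by locus name ascending); the
    top k seed one worker each, then every next job goes to the earliest-
    finishing worker (simulated clock, ties to the lowest worker id).
    """
    if k < 1:
        raise GenomicError("need at least one worker")
    jobs = list(jobs)
    if not jobs:
        raise GenomicError("no jobs to schedule")
    ranked = sorted(jobs, key=lambda j: (-j.cost, j.locus))
    clock = [(0.0, w) for w in range(k)]
    import heapq
    heapq.heapify(clock)
    for job in ranked:
        t, w = heapq.heappop(clock)
        job.assigned_worker = w
        heapq.heappush(clock, (t + job.cost, w))
    return ranked


def makespan(jobs, k: int) -> float:
    loads = np.zeros(k)
    for j in jobs:
        loads[j.assigned_worker] += j.cost
    return float(loads.max())


# ---------------------------------------------------------------------------
# per-locus inference

def locus_alignments(source, alphabet=None) -> dict[str, Alignment]:
    """Loci from a directory of alignments or (alignment, partition-file)
    tuple/path pair."""
    out: dict[str, Alignment] = {}
    if isinstance(source, str) and os.path.isdir(source):
        for fname in sorted(os.listdir(source)):
            if fname.startswith("."):
                continue
            path = os.path.join(source, fname)
            if not os.path.isfile(path):
                continue
            name = os.path.splitext(fname)[0]
            out[name] = read_alignment(path, alphabet=alphabet)
        if not out:
            raise GenomicError(f"no locus alignments in {source}")
        return out
    aln, partition = source
    if isinstance(partition, str):
        partition = read_partition_file(partition)
    for locus, sites in partition.items():
        out[locus] = aln.subset_sites(sites)
    return out


def make_jobs(loci: dict[str, Alignment]) -> list[LocusJob]:
    """Cost model: sequences x distinct patterns x states, computed on each
    locus's present taxa only."""
    jobs = []
    for name, aln in loci.items():
        present = aln.present_taxa()
        sub = aln.subset_taxa(present) if present else aln
        n_pat = compress_patterns(sub).n_patterns if present else 0
        jobs.append(LocusJob(
            locus=name, n_sequences=len(present), n_patterns=n_pat,
            n_states=aln.alphabet.n_states,
        ))
    return jobs


def per_locus_inference(source, model_factory, rate_model=None, k: int = 1,
                        seed: int = 0, search_config=None) -> dict[str, Tree]:
    """Independent tree search per locus, scheduled by cost rank.

    `model_factory` is called per locus (alignments differ in composition).
    Loci with fewer than 3 present taxa are skipped with a warning. Results
    are independent of k: scheduling decides order and assignment, never
    the per-locus computation, which uses the shared base seed.
    """
    from .search import SearchConfig, run_search

    loci = locus_alignments(source)
    jobs = schedule_loci(make_jobs(loci), k)
    out: dict[str, Tree] = {}
    for job in jobs:
        aln = loci[job.locus]
        present = aln.present_taxa()
        if len(present) < 3:
            warnings.warn(f"locus {job.locus!r}: fewer than 3 taxa, skipped")
            continue
        sub = aln.subset_taxa(present)
        cfg = search_config or SearchConfig(mode="fast", seed=seed)
        model = model_factory(sub)
        result = run_search(sub, model, rate_model, cfg)
        out[job.locus] = result.best_tree
    return out


def write_locus_trees(trees: dict[str, Tree], path: str) -> None:
    with open(path, "w") as fh:
        for locus, tree in trees.items():
            fh.write(f"[{locus}] {tree.newick()}\n")
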