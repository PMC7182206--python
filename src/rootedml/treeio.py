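"""Trees, alignments and site-pattern compression.

Newick parsing is delegated to dendropy (quoted labels and bracket comments
honored, comments discarded); the in-memory tree is a light parent/child
structure tuned for rerooting, restriction and NNI surgery. Alignments are
read with Biopython (FASTA, sequential and interleaved PHYLIP) and compressed
to distinct site patterns with first-occurrence ordering.

Rootedness is structural: a root of out-degree 2 means rooted, a basal
trifurcation (out-degree >= 3) means unrooted. No flags are stored.
"""

from __future__ import annotations

import io
import sys
from dataclasses import dataclass, field

import numpy as np
import dendropy
from Bio import SeqIO

# deep trees use recursive copy/serialize helpers
sys.setrecursionlimit(max(sys.getrecursionlimit(), 20_000))


class NewickError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# alphabets

class Alphabet:
    """Character states plus ambiguity-code resolution.

    ``partial(c)`` returns the 0/1 state-indicator row used as a tip partial
    likelihood: fully unknown symbols ('-', '?', 'N'/'X') give all ones,
    IUPAC ambiguity codes give the indicated subset.
    """

    def __init__(self, name: str, states: str, ambiguity: dict[str, str]):
        self.name = name
        self.states = states
        self.n_states = len(states)
        self._index = {c: i for i, c in enumerate(states)}
        self._partials: dict[str, np.ndarray] = {}
        for c, members in ambiguity.items():
            row = np.zeros(self.n_states)
            for m in members:
                row[self._index[m]] = 1.0
            self._partials[c] = row
        for c in states:
            row = np.zeros(self.n_states)
            row[self._index[c]] = 1.0
            self._partials[c] = row
        for unknown in ("-", "?"):
            self._partials[unknown] = np.ones(self.n_states)

    def partial(self, c: str) -> np.ndarray:
        try:
            return self._partials[c]
        except KeyError:
            raise AlignmentError(f"unknown character {c!r} for alphabet {self.name}")

    def state_index(self, c: str) -> int:
        return self._index[c]

    def is_known(self, c: str) -> bool:
        return c in self._partials


DNA = Alphabet(
    "dna",
    "ACGT",
    {
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    },
)

AA = Alphabet(
    "aa",
    "ARNDCQEGHILKMFPSTWYV",
    {"B": "ND", "Z": "QE", "J": "IL", "X": "ARNDCQEGHILKMFPSTWYV"},
)

BINARY = Alphabet("binary", "01", {})

ALPHABETS = {"dna": DNA, "aa": AA, "binary": BINARY}


# ---------------------------------------------------------------------------
# trees

class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.name or '*'}>"


class Tree:
    """Rooted or unrooted phylogeny with nonnegative branch lengths."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dt = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise NewickError(f"malformed Newick: {exc}") from exc

        def convert(dn) -> Node:
            name = None
            if dn.taxon is not None:
                name = dn.taxon.label
            elif dn.label:
                name = dn.label
            node = Node(name=name, length=dn.edge.length)
            for ch in dn.child_nodes():
                node.add(convert(ch))
            return node

        root = convert(dt.seed_node)
        root.length = None
        tree = cls(root)
        labels = [l.name for l in tree.leaves()]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickError(f"duplicate leaf labels: {sorted(dupes)}")
        if any(l.name is None for l in tree.leaves()):
            raise NewickError("unlabeled leaf")
        for node in tree.postorder():
            if node is not tree.root and node.length is not None and node.length < 0:
                raise NewickError(f"negative branch length {node.length}")
        return tree

    def copy(self) -> "Tree":
        def dup(n: Node) -> Node:
            m = Node(n.name, n.length)
            for c in n.children:
                m.add(dup(c))
            return m

        return Tree(dup(self.root))

    # -- basic queries -----------------------------------------------------
    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def postorder(self):
        out = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Each edge is identified by its child node."""
        return [n for n in self.postorder() if n is not self.root]

    def internal_edges(self) -> list[Node]:
        return [n for n in self.edges() if not n.is_leaf]

    def find(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    # -- serialization -----------------------------------------------------
    def newick(self, lengths: bool = True, internal_names: bool = False,
               precision: int = 10) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                s = _quote(n.name or "")
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if internal_names and n.name:
                    s += _quote(n.name)
            if lengths and n.length is not None and n is not self.root:
                s += f":{n.length:.{precision}g}"
            return s

        return fmt(self.root) + ";"

    # -- surgery -----------------------------------------------------------
    def unroot(self) -> "Tree":
        """Return a copy with a basal trifurcation (no-op if already unrooted)."""
        t = self.copy()
        while len(t.root.children) == 2:
            a, b = t.root.children
            if b.is_leaf and a.is_leaf:
                break  # 2-taxon tree cannot be unrooted
            if b.is_leaf:
                a, b = b, a
            # merge the two root edges into one; b's children move up
            t.root.children = []
            for c in b.children:
                t.root.add(c)
            merged = (a.length or 0.0) + (b.length or 0.0)
            a.length = merged
            t.root.add(a)
            if t.root.name is None:
                t.root.name = b.name
        return t

    def reroot_at_edge(self, child_name_or_node, fraction: float = 0.5) -> "Tree":
        """Return a rooted copy with the root placed on the edge above `child`.

        `fraction` is the portion of the edge assigned to the child side.
        """
        t = self.copy()
        if isinstance(child_name_or_node, Node):
            # locate the corresponding node in the copy by path
            path = []
            n = child_name_or_node
            while n.parent is not None:
                path.append(n.parent.children.index(n))
                n = n.parent
            node = t.root
            for i in reversed(path):
                node = node.children[i]
        else:
            node = t.find(child_name_or_node)
        if node is t.root:
            raise ValueError("cannot reroot at the root itself")
        L = node.length if node.length is not None else 0.0
        upper = node.parent
        upper.children.remove(node)
        node.parent = None
        new_root = Node()
        new_root.add(node)
        node.length = L * fraction
        # reverse the path from `upper` back to the old root
        rest, extra = _reverse_path(upper, t.root)
        new_root.add(rest)
        rest.length = L * (1.0 - fraction) + extra
        return Tree(new_root)

    def restrict(self, taxa) -> "Tree":
        """Induced subtree on `taxa`: drop other leaves, suppress degree-2
        nodes summing branch lengths."""
        keep = set(taxa)
        missing = keep - set(self.leaf_names())
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        if not keep:
            raise ValueError("empty taxon subset")
        t = self.copy()

        def prune(n: Node) -> Node | None:
            if n.is_leaf:
                return n if n.name in keep else None
            kids = [prune(c) for c in n.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                k = kids[0]
                if n.length is not None or k.length is not None:
                    k.length = (n.length or 0.0) + (k.length or 0.0)
                return k
            m = Node(n.name, n.length)
            m.children = []
            for k in kids:
                m.add(k)
            return m

        root = prune(t.root)
        root.parent = None
        if root.is_leaf:
            root = root  # single-taxon: trivial tree
        root.length = None
        return Tree(root)

    # -- metrics -----------------------------------------------------------
    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """Pairwise path-length matrix over leaves (labels sorted)."""
        leaves = sorted(self.leaf_names())
        idx = {n: i for i, n in enumerate(leaves)}
        k = len(leaves)
        dist = np.zeros((k, k))
        below: dict[Node, dict[str, float]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[n] = {n.name: 0.0}
            else:
                acc: dict[str, float] = {}
                kids = [
                    {lab: d + (c.length or 0.0) for lab, d in below[c].items()}
                    for c in n.children
                ]
                for i in range(len(kids)):
                    for j in range(i + 1, len(kids)):
                        for la, da in kids[i].items():
                            for lb, db in kids[j].items():
                                dist[idx[la], idx[lb]] = dist[idx[lb], idx[la]] = da + db
                    acc.update(kids[i])
                below[n] = acc
        return leaves, dist

    def splits(self, taxa=None) -> set[frozenset]:
        """Nontrivial bipartition half-sets (the side not containing the
        reference taxon), optionally restricted to a taxon subset."""
        all_taxa = set(self.leaf_names())
        universe = all_taxa if taxa is None else (set(taxa) & all_taxa)
        ref = min(universe)
        out = set()
        for n in self.postorder():
            if n is self.root or n.is_leaf:
                continue
            side = {l.name for l in _leaves_under(n)} & universe
            if ref in side:
                side = universe - side
            if 2 <= len(side) <= len(universe) - 2:
                out.add(frozenset(side))
        return out

    def canonical_topology(self, rooted: bool | None = None) -> str:
        """Canonical topology string (lengths ignored). For unrooted
        comparison the tree is first rerooted on the edge above the smallest
        leaf label, so the string is invariant to the serialized rooting."""
        as_rooted = rooted if rooted is not None else self.is_rooted
        t = self
        if not as_rooted and len(self.leaf_names()) > 2:
            t = self.reroot_at_edge(min(self.leaf_names()))

        def canon(n: Node) -> str:
            if n.is_leaf:
                return n.name
            parts = sorted(canon(c) for c in n.children)
            return "(" + ",".join(parts) + ")"

        return canon(t.root) + ";"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _leaves_under(n: Node):
    stack, out = [n], []
    while stack:
        m = stack.pop()
        if m.is_leaf:
            out.append(m)
        stack.extend(m.children)
    return out


def _reverse_path(node: Node, old_root: Node) -> tuple[Node, float]:
    """Re-hang the tree so `node` becomes the apex of the non-child side of a
    new root. Returns (apex, extra_length): a suppressed degree-2 old root
    contributes its remaining child edge as `extra_length` to the caller's
    edge. The apex's own `length` is meaningless; the caller assigns it.
    """
    if node is old_root:
        if len(node.children) == 1:
            only = node.children[0]
            only.parent = None
            extra = only.length or 0.0
            return only, extra
        return node, 0.0
    parent = node.parent
    elen = node.length or 0.0
    parent.children.remove(node)
    node.parent = None
    sub, extra = _reverse_path(parent, old_root)
    node.add(sub)
    sub.length = elen + extra
    return node, 0.0


def parse_newick(text: str) -> Tree:
    return Tree.from_newick(text)


def write_newick(tree: Tree, path: str, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick(**kw) + "\n")


def read_trees(path: str) -> list[Tree]:
    """One Newick per (possibly wrapped) ';'-terminated statement."""
    with open(path) as fh:
        text = fh.read()
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            out.append(Tree.from_newick(chunk + ";"))
    return out


# ---------------------------------------------------------------------------
# alignments

@dataclass
class Alignment:
    taxa: list[str]
    seqs: list[str]
    alphabet: Alphabet

    def __post_init__(self):
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError("rows of unequal length")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def sequence(self, taxon: str) -> str:
        return self.seqs[self.taxa.index(taxon)]

    def subset_taxa(self, taxa) -> "Alignment":
        taxa = list(taxa)
        return Alignment(taxa, [self.sequence(t) for t in taxa], self.alphabet)

    def subset_sites(self, sites) -> "Alignment":
        sites = list(sites)
        return Alignment(
            self.taxa, ["".join(s[i] for i in sites) for s in self.seqs], self.alphabet
        )

    def present_taxa(self) -> list[str]:
        """Taxa with at least one resolved (non-fully-unknown) character."""
        unknown = {"-", "?", "N" if self.alphabet.name == "dna" else "X"}
        return [t for t, s in zip(self.taxa, self.seqs)
                if any(c not in unknown for c in s)]


def _guess_alphabet(seqs: list[str]) -> Alphabet:
    chars = set("".join(seqs)) - set("-?")
    if chars <= set("01"):
        return BINARY
    if chars <= set("ACGTUNRYSWKMBDHV"):
        return DNA
    return AA


def _normalize(seq: str, alphabet: Alphabet, record: str) -> str:
    s = seq.upper().replace(".", "-")
    if alphabet.name == "dna":
        s = s.replace("U", "T")
    bad = [(i, c) for i, c in enumerate(s) if not alphabet.is_known(c)]
    if bad:
        i, c = bad[0]
        raise AlignmentError(
            f"unknown character {c!r} at column {i + 1} of record {record!r}"
        )
    return s


def read_alignment(path: str, alphabet: str | Alphabet | None = None) -> Alignment:
    """Read FASTA or (relaxed/strict, sequential/interleaved) PHYLIP.

    Format is auto-detected from the first non-blank character; the alphabet
    from content unless given.
    """
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if not stripped:
        raise AlignmentError(f"empty alignment file {path}")
    records: list[tuple[str, str]] = []
    if stripped[0] == ">":
        raw = list(SeqIO.parse(io.StringIO(text), "fasta"))
        lengths = {len(r.seq) for r in raw}
        if len(lengths) > 1:
            shortest = min(raw, key=lambda r: len(r.seq))
            raise AlignmentError(
                f"ragged FASTA: record {shortest.id!r} has {len(shortest.seq)} sites"
            )
        records = [(r.id, str(r.seq)) for r in raw]
    else:
        last_err = None
        for schema in ("phylip-relaxed", "phylip", "phylip-sequential"):
            try:
                raw = list(SeqIO.parse(io.StringIO(text), schema))
                if raw:
                    records = [(r.id, str(r.seq)) for r in raw]
                    break
            except Exception as exc:
                last_err = exc
        if not records:
            raise AlignmentError(f"could not parse PHYLIP {path}: {last_err}")
    if isinstance(alphabet, str):
        alph = ALPHABETS[alphabet]
    elif alphabet is not None:
        alph = alphabet
    else:
        alph = _guess_alphabet([s.upper() for _, s in records])
    taxa = [name for name, _ in records]
    if len(set(taxa)) != len(taxa):
        raise AlignmentError("duplicate taxon names")
    seqs = [_normalize(s, alph, name) for name, s in records]
    return Alignment(taxa, seqs, alph)


def write_fasta(aln: Alignment, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t, s in zip(aln.taxa, aln.seqs):
            fh.write(f">{t}\n")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# site patterns

@dataclass
class PatternTable:
    taxa: list[str]
    columns: list[str]            # one string of characters per pattern, taxon order
    weights: np.ndarray           # positive ints, sum = n_sites
    site_to_pattern: np.ndarray   # len n_sites
    alphabet: Alphabet

    @property
    def n_patterns(self) -> int:
        return len(self.columns)

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())

    def tip_partials(self) -> dict[str, np.ndarray]:
        """taxon -> (n_patterns, n_states) 0/1 state indicators."""
        out = {}
        for i, t in enumerate(self.taxa):
            rows = [self.alphabet.partial(col[i]) for col in self.columns]
            out[t] = np.array(rows)
        return out

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern vector back to per-site order."""
        return np.asarray(per_pattern)[self.site_to_pattern]


def compress_patterns(aln: Alignment) -> PatternTable:
    if aln.n_sites == 0:
        raise AlignmentError("empty alignment")
    seen: dict[str, int] = {}
    columns: list[str] = []
    weights: list[int] = []
    site_to_pattern = np.empty(aln.n_sites, dtype=int)
    for j in range(aln.n_sites):
        col = "".join(s[j] for s in aln.seqs)
        k = seen.get(col)
        if k is None:
            k = len(columns)
            seen[col] = k
            columns.append(col)
            weights.append(0)
        weights[k] += 1
        site_to_pattern[j] = k
    return PatternTable(
        list(aln.taxa), columns, np.array(weights, dtype=int), site_to_pattern,
        aln.alphabet,
    )


# ---------------------------------------------------------------------------
# partitions

def read_partition_file(path: str) -> dict[str, list[int]]:
    """RAxML-style partition lines: ``DNA, locus1 = 1-500, 600-700``.

    Returns locus -> 0-based site indices, in file order (dicts preserve it).
    """
    out: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                head, spec = line.split("=", 1)
                parts = head.split(",", 1)
                name = parts[1].strip() if len(parts) == 2 else parts[0].strip()
                sites: list[int] = []
                for rng in spec.split(","):
                    rng = rng.strip()
                    if "-" in rng:
                        a, b = rng.split("-")
                        sites.extend(range(int(a) - 1, int(b)))
                    else:
                        sites.append(int(rng) - 1)
            except Exception as exc:
                raise AlignmentError(f"bad partition line {lineno}: {line!r}") from exc
            if name in out:
                raise AlignmentError(f"duplicate locus name {name!r}")
            out[name] = sites
    return out
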