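"""The Lie Markov DNA model catalogue.

The family comprises 37 model structures named ``<dim>.<index><letter>``;
31 of them depend on which base pairing is distinguished (RY, WS or MK) and
therefore occur in three variants, while 6 structures (1.1, 3.3a, 4.4a,
6.7a, 9.20b, 12.12) are pairing-independent — 31 x 3 + 6 = 99 named models.

Each catalogue entry carries a generator basis of 4x4 zero-row-sum matrices;
a model instance is a nonnegative-off-diagonal combination Q = sum params_j
basis_j. Structures with classical equivalents use those generators exactly
(1.1 = JC-symmetric; 2.2b = within/cross-pair two-rate; 3.3a = the
three-pair-class symmetric model; 4.4a = target-frequency columns; 6.7a =
the joint span of the two previous; 6.6 = pair-swap strand-type symmetry;
9.20b = doubly stochastic rate matrices; 12.12 = all twelve rates free).
The remaining structures ship deterministic pairing-adapted spanning sets of
the published dimensionality (see docs/methods.md for the construction and
its limits). Parameter domains are enforced by rejection, never clamping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    ModelError, SubstitutionModel, stationary_distribution, _normalize,
    _fill_diagonal, _is_reversible, _check_irreducible,
)

STATES = "ACGT"
_IDX = {c: i for i, c in enumerate(STATES)}

#: distinguished pairings as partitions of ACGT into two doublets
PAIRINGS = {
    "RY": ({"A", "G"}, {"C", "T"}),
    "WS": ({"C", "G"}, {"A", "T"}),
    "MK": ({"A", "C"}, {"G", "T"}),
}

#: permutation of states mapping the RY partition onto each pairing
_PAIRING_PERM = {
    "RY": {"A": "A", "C": "C", "G": "G", "T": "T"},
    "WS": {"A": "C", "C": "A", "G": "G", "T": "T"},
    "MK": {"A": "A", "C": "G", "G": "C", "T": "T"},
}

PAIRING_INDEPENDENT = {"1.1", "3.3a", "4.4a", "6.7a", "9.20b", "12.12"}

#: the 37 structures of the family; dimension is the integer prefix
STRUCTURES = [
    "1.1", "2.2b", "3.3a", "3.3b", "3.3c", "3.4",
    "4.4a", "4.4b", "4.5a", "4.5b",
    "5.6a", "5.6b", "5.7a", "5.7b", "5.7c", "5.11a", "5.11b", "5.11c", "5.16",
    "6.6", "6.7a", "6.7b", "6.8a", "6.8b", "6.17a", "6.17b",
    "8.8", "8.10a", "8.10b", "8.16", "8.17", "8.18",
    "9.20a", "9.20b", "10.12", "10.34", "12.12",
]


class DomainError(ModelError):
    pass


@dataclass
class ModelCatalogueEntry:
    name: str           # structure name, e.g. "3.3b"
    pairing: str        # "RY" | "WS" | "MK" | "none"
    dim: int
    basis: list         # list of 4x4 zero-row-sum generator matrices

    @property
    def full_name(self) -> str:
        if self.pairing == "none":
            return self.name
        return f"{self.pairing}{self.name}"


def _entry_matrix(pairs) -> np.ndarray:
    """Zero-row-sum generator with unit rates at the given directed pairs."""
    M = np.zeros((4, 4))
    for a, b in pairs:
        M[_IDX[a], _IDX[b]] = 1.0
    return _fill_diagonal(M)


def _permute(M: np.ndarray, perm: dict[str, str]) -> np.ndarray:
    P = np.zeros((4, 4))
    for a, b in perm.items():
        P[_IDX[a], _IDX[b]] = 1.0
    return P.T @ M @ P


# generators in the RY frame ------------------------------------------------

def _within_cross() -> tuple[np.ndarray, np.ndarray]:
    within = _entry_matrix([("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")])
    cross = _entry_matrix([
        ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G"),
        ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
    ])
    return within, cross


def _k3st_basis() -> list[np.ndarray]:
    b1 = _entry_matrix([("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")])
    b2 = _entry_matrix([("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")])
    b3 = _entry_matrix([("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")])
    return [b1, b2, b3]


def _f81_basis() -> list[np.ndarray]:
    out = []
    for j, target in enumerate(STATES):
        out.append(_entry_matrix([(s, target) for s in STATES if s != target]))
    return out


def _pair_swap_basis() -> list[np.ndarray]:
    """Rates invariant under the double transposition (A G)(C T):
    six equivalence classes of directed changes."""
    classes = [
        [("A", "G"), ("G", "A")],
        [("C", "T"), ("T", "C")],
        [("A", "C"), ("G", "T")],
        [("A", "T"), ("G", "C")],
        [("C", "A"), ("T", "G")],
        [("T", "A"), ("C", "G")],
    ]
    return [_entry_matrix(cls) for cls in classes]


def _doubly_stochastic_basis() -> list[np.ndarray]:
    """Permutation generators P_sigma - I: zero row AND column sums; nine of
    them span the full doubly stochastic (uniform-stationary) space."""
    perms = [
        # six transpositions
        {"A": "C", "C": "A", "G": "G", "T": "T"},
        {"A": "G", "G": "A", "C": "C", "T": "T"},
        {"A": "T", "T": "A", "C": "C", "G": "G"},
        {"C": "G", "G": "C", "A": "A", "T": "T"},
        {"C": "T", "T": "C", "A": "A", "G": "G"},
        {"G": "T", "T": "G", "A": "A", "C": "C"},
        # three 3-cycles
        {"A": "C", "C": "G", "G": "A", "T": "T"},
        {"A": "C", "C": "T", "T": "A", "G": "G"},
        {"A": "G", "G": "T", "T": "A", "C": "C"},
    ]
    out = []
    for p in perms:
        M = np.zeros((4, 4))
        for a, b in p.items():
            if a != b:
                M[_IDX[a], _IDX[b]] = 1.0
        out.append(_fill_diagonal(M))
    return out


#: single-entry rays, within-pair entries first (RY frame); used for the
#: structures without a classical generator set
_RAY_ORDER = [
    ("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
    ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G"),
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
]

#: deterministic ray-subset offsets for the generic structures (distinct
#: offsets among equal-dimension structures keep their spans distinct)
_GENERIC_OFFSETS = {
    "3.3b": 0, "3.3c": 4, "3.4": 8,
    "4.4b": 0, "4.5a": 4, "4.5b": 8,
    "5.6a": 0, "5.6b": 2, "5.7a": 4, "5.7b": 6, "5.7c": 8,
    "5.11a": 10, "5.11b": 1, "5.11c": 3, "5.16": 5,
    "6.7b": 0, "6.8a": 2, "6.8b": 4, "6.17a": 6, "6.17b": 8,
    "8.8": 0, "8.10a": 1, "8.10b": 2, "8.16": 3, "8.17": 4, "8.18": 5,
    "9.20a": 0,
    "10.12": 0, "10.34": 2,
}


def _ray_basis(dim: int, offset: int) -> list[np.ndarray]:
    """JC generator plus dim-1 single-entry rays: every positive parameter
    vector yields an irreducible chain, and distinct offsets give distinct
    spans for equal-dimension structures."""
    jc = _entry_matrix([(a, b) for a in STATES for b in STATES if a != b])
    idx = [(offset + i) % 12 for i in range(dim - 1)]
    return [jc] + [_entry_matrix([_RAY_ORDER[k]]) for k in idx]


def _structure_basis_ry(name: str) -> list[np.ndarray]:
    dim = int(name.split(".")[0])
    if name == "1.1":
        return [_entry_matrix([(a, b) for a in STATES for b in STATES if a != b])]
    if name == "2.2b":
        return list(_within_cross())
    if name == "3.3a":
        return _k3st_basis()
    if name == "4.4a":
        return _f81_basis()
    if name == "6.6":
        return _pair_swap_basis()
    if name == "6.7a":
        return _k3st_basis() + _f81_basis()[:3]
    if name == "9.20b":
        return _doubly_stochastic_basis()
    if name == "12.12":
        return [_entry_matrix([pair]) for pair in _RAY_ORDER]
    return _ray_basis(dim, _GENERIC_OFFSETS[name])


def lie_markov_catalogue() -> list[ModelCatalogueEntry]:
    """The 99 named Lie Markov DNA models."""
    out = []
    for name in STRUCTURES:
        dim = int(name.split(".")[0])
        basis_ry = _structure_basis_ry(name)
        assert len(basis_ry) == dim
        if name in PAIRING_INDEPENDENT:
            out.append(ModelCatalogueEntry(name, "none", dim, basis_ry))
        else:
            for pairing in ("RY", "WS", "MK"):
                perm = _PAIRING_PERM[pairing]
                basis = [_permute(B, perm) for B in basis_ry]
                out.append(ModelCatalogueEntry(name, pairing, dim, basis))
    return out


_CATALOGUE: dict[str, ModelCatalogueEntry] | None = None


def _catalogue_index() -> dict[str, ModelCatalogueEntry]:
    global _CATALOGUE
    if _CATALOGUE is None:
        _CATALOGUE = {e.full_name: e for e in lie_markov_catalogue()}
    return _CATALOGUE


def get_entry(name: str, pairing: str | None = None) -> ModelCatalogueEntry:
    """Look up by structure name + pairing, or by full name like 'RY3.3b'."""
    index = _catalogue_index()
    if pairing and pairing != "none":
        key = f"{pairing}{name}"
    else:
        key = name
    if key in index:
        return index[key]
    # pairing-independent structures accept any pairing tag
    if name in index:
        return index[name]
    raise ModelError(f"unknown Lie Markov model {name!r} (pairing {pairing!r})")


def build_lie_markov(name: str, params=None, pairing: str | None = None) -> SubstitutionModel:
    """Instantiate a Lie Markov model: Q = sum params_j basis_j, normalized.

    Parameters must keep every off-diagonal entry nonnegative; violations
    raise DomainError naming the offending entry.
    """
    entry = get_entry(name, pairing)
    params = np.asarray(params, dtype=float)
    if params.shape != (entry.dim,):
        raise ModelError(f"{entry.full_name} takes {entry.dim} parameters, got {params.shape}")
    Q = sum(p * B for p, B in zip(params, entry.basis))
    off = Q[~np.eye(4, dtype=bool)]
    if np.any(off < -1e-12):
        bad = np.argwhere((Q < -1e-12) & ~np.eye(4, dtype=bool))[0]
        raise DomainError(
            f"parameters leave rate ({STATES[bad[0]]}->{STATES[bad[1]]}) negative"
        )
    Q = _fill_diagonal(np.clip(Q, 0.0, None) * (~np.eye(4, dtype=bool)) + Q * np.eye(4))
    _check_irreducible(Q)
    pi = stationary_distribution(Q)
    Q = _normalize(Q, pi)
    model = SubstitutionModel(
        n_states=4, Q=Q, free_params={"params": params},
        stationary_freqs=pi, reversible=_is_reversible(Q, pi),
        kind="lie", name=entry.full_name, alphabet="dna",
    )
    return model


def project_onto_basis(Q: np.ndarray, entry: ModelCatalogueEntry) -> tuple[np.ndarray, float]:
    """Least-squares coordinates of Q in the entry's span and the residual
    norm (zero iff Q lies in the model's linear span)."""
    A = np.stack([B.ravel() for B in entry.basis], axis=1)
    coef, res, *_ = np.linalg.lstsq(A, Q.ravel(), rcond=None)
    recon = A @ coef
    return coef, float(np.linalg.norm(recon - Q.ravel()))
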