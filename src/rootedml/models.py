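"""Substitution models and among-site rate heterogeneity.

All rate matrices are normalized so the expected number of substitutions per
unit time at stationarity is one; branch lengths are therefore in expected
substitutions per site. Stationary frequencies of nonreversible models come
from a dense linear solve of pi Q = 0 with the simplex constraint appended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix
from scipy.special import gammainc, gammaincinv

try:  # py>=3.9
    from importlib.resources import files as _res_files
except ImportError:  # pragma: no cover
    _res_files = None

DETAILED_BALANCE_TOL = 1e-10


class ModelError(ValueError):
    pass


class InvalidFrequencyError(ModelError):
    pass


class IrreducibilityError(ModelError):
    pass


class AscertainmentError(ModelError):
    pass


# ---------------------------------------------------------------------------
# substitution models

@dataclass
class SubstitutionModel:
    """Continuous-time Markov substitution model.

    Q holds the normalized instantaneous rates; `free_params` the named
    parameterization used by the optimizer; `kind` dispatches re-construction
    when parameters change.
    """

    n_states: int
    Q: np.ndarray
    free_params: dict
    stationary_freqs: np.ndarray
    reversible: bool
    kind: str = "custom"
    name: str = ""
    alphabet: str = "dna"

    def updated(self, theta: np.ndarray) -> "SubstitutionModel":
        """Rebuild the model from an optimizer parameter vector."""
        theta = np.asarray(theta, dtype=float)
        if self.kind == "gtr":
            exch = np.append(np.exp(theta), 1.0)
            return build_gtr(exch, self.free_params["freqs"])
        if self.kind == "unrest":
            rates = np.append(np.exp(theta), 1.0)
            return build_unrest(rates)
        if self.kind == "lie":
            from .lie_markov import build_lie_markov
            return build_lie_markov(self.name, params=theta)
        if self.kind == "nonrev_aa":
            rates = np.append(np.exp(theta), 1.0)
            return build_nonrev_aa(rates)
        raise ModelError(f"model kind {self.kind!r} has no free parameterization")

    def param_vector(self) -> np.ndarray:
        if self.kind == "gtr":
            exch = np.asarray(self.free_params["exchangeabilities"], dtype=float)
            return np.log(exch[:-1] / exch[-1])
        if self.kind == "unrest":
            rates = np.asarray(self.free_params["rates"], dtype=float)
            return np.log(rates[:-1] / rates[-1])
        if self.kind == "lie":
            return np.asarray(self.free_params["params"], dtype=float)
        if self.kind == "nonrev_aa":
            rates = np.asarray(self.free_params["rates"], dtype=float)
            return np.log(rates[:-1] / rates[-1])
        raise ModelError(f"model kind {self.kind!r} has no free parameterization")


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Left null vector of Q on the simplex (dense least-squares solve)."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if pi.min() < -1e-9:
        raise IrreducibilityError("no positive stationary distribution")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _normalize(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    rate = -float(pi @ np.diag(Q))
    if rate <= 0:
        raise ModelError("degenerate rate matrix (zero total rate)")
    return Q / rate


def _is_reversible(Q: np.ndarray, pi: np.ndarray, tol: float = DETAILED_BALANCE_TOL) -> bool:
    F = pi[:, None] * Q
    return bool(np.max(np.abs(F - F.T)) < tol)


def _check_irreducible(Q: np.ndarray) -> None:
    adj = csr_matrix((Q > 0).astype(int))
    ncomp, _ = connected_components(adj, directed=True, connection="strong")
    if ncomp != 1:
        raise IrreducibilityError("rate matrix defines a reducible chain")


def _fill_diagonal(Q: np.ndarray) -> np.ndarray:
    Q = Q.copy()
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_gtr(exchangeabilities, freqs, alphabet: str = "dna") -> SubstitutionModel:
    """General time-reversible model: Q_ij = s_ij pi_j.

    DNA exchangeability order: AC, AG, AT, CG, CT, GT (upper triangle,
    row-major). For n states, n(n-1)/2 values in the same layout.
    """
    freqs = np.asarray(freqs, dtype=float)
    exch = np.asarray(exchangeabilities, dtype=float)
    n = len(freqs)
    if np.any(freqs <= 0):
        raise InvalidFrequencyError("state frequencies must be strictly positive")
    freqs = freqs / freqs.sum()
    if len(exch) != n * (n - 1) // 2:
        raise ModelError(f"expected {n * (n - 1) // 2} exchangeabilities, got {len(exch)}")
    if np.any(exch < 0) or not np.any(exch > 0):
        raise ModelError("exchangeabilities must be nonnegative with at least one positive")
    S = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    S[iu] = exch
    S = S + S.T
    Q = _fill_diagonal(S * freqs[None, :])
    Q = _normalize(Q, freqs)
    return SubstitutionModel(
        n_states=n, Q=Q,
        free_params={"exchangeabilities": exch, "freqs": freqs},
        stationary_freqs=freqs, reversible=True, kind="gtr",
        name="GTR" if n == 4 else f"GTR{n}",
        alphabet=alphabet,
    )


def jukes_cantor(n: int = 4, alphabet: str = "dna") -> SubstitutionModel:
    m = build_gtr(np.ones(n * (n - 1) // 2), np.full(n, 1.0 / n), alphabet=alphabet)
    m.kind = "fixed"   # no free rate parameters
    m.name = "JC"
    return m


#: row-major off-diagonal order over states ACGT
UNREST_ORDER = [
    ("A", "C"), ("A", "G"), ("A", "T"),
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("G", "A"), ("G", "C"), ("G", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
]


def build_unrest(rates) -> SubstitutionModel:
    """Unrestricted DNA model: all 12 off-diagonal rates free.

    Rate order is row-major over states ACGT (AC, AG, AT, CA, ...).
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (12,):
        raise ModelError("UNREST takes 12 rates")
    if np.any(rates <= 0):
        raise ModelError("UNREST rates must be strictly positive")
    Q = np.zeros((4, 4))
    k = 0
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = rates[k]
                k += 1
    Q = _fill_diagonal(Q)
    _check_irreducible(Q)
    pi = stationary_distribution(Q)
    Q = _normalize(Q, pi)
    return SubstitutionModel(
        n_states=4, Q=Q, free_params={"rates": rates},
        stationary_freqs=pi, reversible=_is_reversible(Q, pi),
        kind="unrest", name="UNREST", alphabet="dna",
    )


# ---------------------------------------------------------------------------
# amino-acid models

def load_paml_dat(name_or_path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-dat file: lower-triangle exchangeabilities then 20
    frequencies. Returns (symmetric 20x20 exchangeability matrix, freqs)."""
    path = name_or_path
    if _res_files is not None and "/" not in name_or_path and "\\" not in name_or_path:
        candidate = _res_files("rootedml").joinpath("data", name_or_path.upper() + ".dat")
        if candidate.is_file():
            path = str(candidate)
    with open(path) as fh:
        values = [float(v) for v in fh.read().split()]
    if len(values) < 190 + 20:
        raise ModelError(f"{name_or_path}: expected 190 exchangeabilities + 20 frequencies")
    tri, freqs = values[:190], np.array(values[190:210])
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    return S, freqs / freqs.sum()


def build_empirical_aa(name: str) -> SubstitutionModel:
    """Empirical reversible amino-acid model (LG, WAG, JTT)."""
    S, freqs = load_paml_dat(name)
    iu = np.triu_indices(20, 1)
    model = build_gtr(S[iu], freqs, alphabet="aa")
    model.name = name.upper()
    model.kind = "fixed"   # empirical exchangeabilities are not re-fitted
    return model


def build_nonrev_aa(rates=None, init_from: str | None = None) -> SubstitutionModel:
    """General nonreversible amino-acid model with 380 free off-diagonal
    rates (row-major). `init_from` seeds the rates from an empirical
    reversible matrix, so the flag starts reversible and diverges only when
    the parameters do."""
    if init_from is not None:
        S, freqs = load_paml_dat(init_from)
        Q0 = S * freqs[None, :]
        mask = ~np.eye(20, dtype=bool)
        rates = Q0[mask]
        rates = np.where(rates <= 0, 1e-8, rates)
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (380,):
        raise ModelError("NONREV takes 380 rates")
    if np.any(rates <= 0):
        raise ModelError("NONREV rates must be strictly positive")
    Q = np.zeros((20, 20))
    Q[~np.eye(20, dtype=bool)] = rates
    Q = _fill_diagonal(Q)
    _check_irreducible(Q)
    pi = stationary_distribution(Q)
    Q = _normalize(Q, pi)
    return SubstitutionModel(
        n_states=20, Q=Q, free_params={"rates": rates},
        stationary_freqs=pi, reversible=_is_reversible(Q, pi, 1e-8),
        kind="nonrev_aa", name="NONREV", alphabet="aa",
    )


# ---------------------------------------------------------------------------
# rate heterogeneity

@dataclass
class RateModel:
    """Discrete among-site rate-variation model, mean rate one."""

    category_rates: np.ndarray
    category_weights: np.ndarray
    mode: str = "uniform"  # uniform | gamma | gamma+inv | freerate
    gamma_shape: float | None = None
    p_invariant: float = 0.0

    def __post_init__(self):
        self.category_rates = np.asarray(self.category_rates, dtype=float)
        self.category_weights = np.asarray(self.category_weights, dtype=float)
        if np.any(self.category_rates < 0) or np.any(self.category_weights < 0):
            raise ModelError("rates and weights must be nonnegative")
        w = self.category_weights.sum()
        if abs(w - 1.0) > 1e-8:
            raise ModelError("category weights must sum to 1")
        self.category_weights = self.category_weights / w
        mean = float(self.category_weights @ self.category_rates)
        if abs(mean - 1.0) > 1e-8:
            raise ModelError(f"mean rate must be 1, got {mean}")
        # exact renormalization
        self.category_rates = self.category_rates / mean

    @property
    def n_categories(self) -> int:
        return len(self.category_rates)

    @classmethod
    def uniform(cls) -> "RateModel":
        return cls(np.ones(1), np.ones(1), mode="uniform")

    @classmethod
    def freerate(cls, rates, weights) -> "RateModel":
        rates = np.asarray(rates, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if np.any(np.diff(rates) <= 0):
            raise ModelError("FreeRate rates must be strictly increasing")
        weights = weights / weights.sum()
        rates = rates / (weights @ rates)
        return cls(rates, weights, mode="freerate")


def discretize_rates(alpha: float, p_inv: float = 0.0, k: int = 4) -> RateModel:
    """k equal-weight discrete-gamma categories (mean of each quantile slice,
    via regularized incomplete gamma functions), optionally plus a zero-rate
    invariant category of weight `p_inv`. Overall mean rate is one."""
    if alpha is None or alpha <= 0:
        raise ModelError("gamma shape must be positive")
    if not 0 <= p_inv < 1:
        raise ModelError("p_invariant must lie in [0, 1)")
    if k < 1:
        raise ModelError("need at least one category")
    # Gamma(shape=a, rate=a): slice boundaries at quantiles i/k; slice mean of
    # X over [b_i, b_{i+1}] is gammainc(a+1, c) evaluated at the same cuts.
    edges = np.array([gammaincinv(alpha, i / k) for i in range(1, k)])
    upper = gammainc(alpha + 1, edges)
    cum = np.concatenate([[0.0], upper, [1.0]])
    rates = k * np.diff(cum)
    weights = np.full(k, 1.0 / k)
    mode = "gamma"
    if p_inv > 0:
        rates = np.concatenate([[0.0], rates / (1.0 - p_inv)])
        weights = np.concatenate([[p_inv], weights * (1.0 - p_inv)])
        mode = "gamma+inv"
    return RateModel(rates, weights, mode=mode, gamma_shape=float(alpha),
                     p_invariant=float(p_inv))


# ---------------------------------------------------------------------------
# ascertainment bias

def constant_pattern_columns(patterns) -> list[int]:
    """1-based site numbers of columns compatible with a single constant
    state (the usage ASC corrections forbid)."""
    alph = patterns.alphabet
    bad_patterns = []
    for k, col in enumerate(patterns.columns):
        mask = np.ones(alph.n_states)
        for c in col:
            mask = mask * alph.partial(c)
        if mask.max() > 0:
            bad_patterns.append(k)
    bad = set(bad_patterns)
    return [int(i) + 1 for i, p in enumerate(patterns.site_to_pattern) if p in bad]


def ascertainment_correction(per_pattern_lnl, patterns, model, tree, rate_model) -> float:
    """Conditional likelihood for variable-sites-only data:
    lnL = sum_sites lnL_site - n_sites * ln(1 - p_const), with p_const the
    probability of a constant pattern under the same pruning kernel."""
    from .likelihood import compute_loglik
    from .treeio import Alignment, compress_patterns, ALPHABETS

    bad = constant_pattern_columns(patterns)
    if bad:
        raise AscertainmentError(
            f"alignment contains constant-compatible columns (1-based): {bad[:20]}"
        )
    alph = patterns.alphabet
    taxa = patterns.taxa
    consts = ["".join(s * len(taxa)) for s in alph.states]
    aln = Alignment(list(taxa), ["".join(row) for row in zip(*consts)], alph)
    cpat = compress_patterns(aln)
    res = compute_loglik(tree, model, rate_model, cpat)
    p_const = float(np.exp(res.per_pattern_lnl).sum())
    if p_const >= 1.0 - 1e-12:
        raise AscertainmentError("p_const = 1: correction undefined (no variable site possible)")
    total = float(np.dot(patterns.weights, per_pattern_lnl))
    return total - patterns.n_sites * np.log1p(-p_const)
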