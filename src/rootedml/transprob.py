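"""Transition probabilities P(t) = e^{Qt} for reversible and nonreversible Q.

Two routes: a complex eigen-decomposition (fast, occasionally unstable for
near-defective Q) and scaling-and-squaring (scipy's Pade implementation;
slow but stable). The eigen route is used whenever the decomposition
reconstructs Q accurately and the eigenvector matrix is well conditioned;
otherwise the matrix is flagged defective and the stable route takes over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

RECONSTRUCTION_TOL = 1e-8
CONDITION_LIMIT = 1e8
NEGATIVE_CLAMP = -1e-10
IMAG_RESIDUE_TOL = 1e-10


class TransitionError(ValueError):
    pass


@dataclass
class SpectralCache:
    eigenvalues: np.ndarray          # complex, length n
    right_eigenvectors: np.ndarray   # n x n complex
    inverse_eigenvectors: np.ndarray
    diagonalizable: bool
    condition_estimate: float
    Q: np.ndarray


def spectral_decompose(Q: np.ndarray) -> SpectralCache:
    """Eigen-decompose Q; flag defective when the reconstruction error or the
    eigenvector condition estimate exceeds its threshold (degeneracy is
    signaled, never raised)."""
    Q = np.asarray(Q, dtype=float)
    lam, V = np.linalg.eig(Q)
    try:
        Vinv = np.linalg.inv(V)
        cond = float(np.linalg.cond(V))
        recon = (V * lam) @ Vinv
        scale = max(np.abs(Q).max(), 1e-300)
        err = float(np.abs(recon - Q).max() / scale)
        ok = np.isfinite(cond) and cond <= CONDITION_LIMIT and err <= RECONSTRUCTION_TOL
    except np.linalg.LinAlgError:
        Vinv = np.zeros_like(V)
        cond = np.inf
        ok = False
    return SpectralCache(
        eigenvalues=lam, right_eigenvectors=V, inverse_eigenvectors=Vinv,
        diagonalizable=bool(ok), condition_estimate=cond, Q=Q,
    )


def _finalize(P: np.ndarray, n: int) -> np.ndarray:
    if P.min() < NEGATIVE_CLAMP:
        raise TransitionError(
            f"transition probability {P.min():.3e} below clamp threshold"
        )
    P = np.clip(P, 0.0, 1.0)
    return P


def transition_matrix(Q_or_cache, t: float) -> np.ndarray:
    """P(t) with automatic route choice; entries clamped into [0,1] (only
    rounding-level negatives are tolerated) and rows summing to one."""
    if t < 0:
        raise TransitionError("branch length must be nonnegative")
    if isinstance(Q_or_cache, SpectralCache):
        cache = Q_or_cache
    else:
        cache = spectral_decompose(np.asarray(Q_or_cache, dtype=float))
    n = cache.Q.shape[0]
    if t == 0.0:
        return np.eye(n)
    if cache.diagonalizable:
        P = transition_matrix_eigen(cache, t)
    else:
        P = transition_matrix_expm(cache.Q, t)
    return _finalize(P, n)


def transition_matrix_eigen(cache: SpectralCache, t: float) -> np.ndarray:
    Pc = (cache.right_eigenvectors * np.exp(cache.eigenvalues * t)) @ cache.inverse_eigenvectors
    resid = float(np.abs(Pc.imag).max())
    if resid > IMAG_RESIDUE_TOL:
        # fall back rather than silently discarding a real imaginary part
        return transition_matrix_expm(cache.Q, t)
    return Pc.real


def transition_matrix_expm(Q: np.ndarray, t: float) -> np.ndarray:
    return expm(Q * t)


class TransitionComputer:
    """Caches the spectral decomposition keyed by a fingerprint of Q, so the
    decomposition is redone only when model parameters change."""

    def __init__(self):
        self._key: bytes | None = None
        self._cache: SpectralCache | None = None

    def cache_for(self, Q: np.ndarray) -> SpectralCache:
        key = np.ascontiguousarray(Q).tobytes()
        if key != self._key:
            self._cache = spectral_decompose(Q)
            self._key = key
        return self._cache

    def __call__(self, Q: np.ndarray, t: float) -> np.ndarray:
        return transition_matrix(self.cache_for(Q), t)
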