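"""Bipartite resource-spreading operators (HeatS, ProbS, hybrid) and the
restart matrix of the walk.

All three operators share the same miRNA-to-miRNA core

    S_ij = sum_l a_il a_jl / k(d_l)

(two-step spreading: disease -> miRNA -> disease on the bipartite graph) and
differ only in the degree normalisation: HeatS divides by the receiver degree
k(m_i) (row-stochastic), ProbS by the sender degree k(m_j) (column-stochastic,
mass conserving), and the hybrid by the geometric interpolation
k(m_i)^(1-lambda) k(m_j)^lambda.  Entries involving a zero-degree miRNA are
zero by convention: an unconnected node neither sends nor receives resource.

The restart matrix P_A = W_hybrid @ A spreads each disease's known-miRNA
resource vector through the operator; its normalisation P_0 = P_A / sum(P_A)
is both the initial state and the restart term of the bi-random walk.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .datatypes import AssociationMatrix, ScoreMatrix
from .exceptions import DegenerateRestartError, ValidationError

__all__ = [
    "SpreadOperator",
    "degree_vector",
    "heats_operator",
    "probs_operator",
    "hybrid_operator",
    "restart_matrix",
    "normalize_restart",
]

_SPARSE_DENSITY_CUTOFF = 0.05


@dataclass(frozen=True)
class SpreadOperator:
    """A miRNA x miRNA resource-spreading operator on the bipartite network."""

    values: np.ndarray
    flavor: str  # heats | probs | hybrid
    lambda_mix: float | None = None


def degree_vector(assoc: AssociationMatrix, axis: str) -> np.ndarray:
    """Bipartite degrees: row sums for axis='mirna', column sums for axis='disease'."""
    if axis == "mirna":
        return assoc.values.sum(axis=1, dtype=np.int64)
    if axis == "disease":
        return assoc.values.sum(axis=0, dtype=np.int64)
    raise ValidationError(f"axis must be 'mirna' or 'disease', got {axis!r}")


def _spread_core(assoc: AssociationMatrix) -> np.ndarray:
    """S = A diag(1/k_d) A^T with zero-degree diseases contributing nothing."""
    a = assoc.values.astype(float)
    kd = degree_vector(assoc, "disease").astype(float)
    inv_kd = np.divide(1.0, kd, out=np.zeros_like(kd), where=kd > 0)
    if a.size and a.mean() < _SPARSE_DENSITY_CUTOFF:
        a_sp = sparse.csr_matrix(a)
        core = (a_sp.multiply(inv_kd[None, :]) @ a_sp.T).toarray()
    else:
        core = (a * inv_kd[None, :]) @ a.T
    return core


def _degree_factor(km: np.ndarray, exponent: float) -> np.ndarray:
    """km^-exponent with the convention that zero-degree miRNAs get factor 0."""
    factor = np.zeros(km.shape, dtype=float)
    pos = km > 0
    factor[pos] = km[pos].astype(float) ** (-exponent)
    return factor


_operator_cache: dict[tuple[bytes, tuple[int, int], float], np.ndarray] = {}
_OPERATOR_CACHE_MAX = 32


def _assoc_key(assoc: AssociationMatrix) -> tuple[bytes, tuple[int, int]]:
    digest = hashlib.sha1(np.ascontiguousarray(assoc.values).tobytes()).digest()
    return digest, assoc.values.shape


def hybrid_operator(assoc: AssociationMatrix, lambda_mix: float) -> SpreadOperator:
    """Hybrid operator W_ij = S_ij / (k(m_i)^(1-lambda) k(m_j)^lambda).

    lambda=0 reproduces HeatS exactly, lambda=1 ProbS.  Operators are cached
    keyed on (association-matrix hash, lambda): the cross-validation loop
    rebuilds A once per fold but reuses the operator across diseases.
    """
    if not 0.0 <= lambda_mix <= 1.0:
        raise ValidationError(f"lambda_mix must be in [0, 1], got {lambda_mix}")
    key = (*_assoc_key(assoc), float(lambda_mix))
    cached = _operator_cache.get(key)
    if cached is None:
        km = degree_vector(assoc, "mirna")
        row = _degree_factor(km, 1.0 - lambda_mix)
        col = _degree_factor(km, lambda_mix)
        w = row[:, None] * _spread_core(assoc) * col[None, :]
        # zero-degree miRNAs neither send nor receive, also at lambda in {0, 1}
        # where one exponent is 0 and km^0 would otherwise be 1
        zero = km == 0
        w[zero, :] = 0.0
        w[:, zero] = 0.0
        if len(_operator_cache) >= _OPERATOR_CACHE_MAX:
            _operator_cache.pop(next(iter(_operator_cache)))
        _operator_cache[key] = w
        cached = w
    return SpreadOperator(cached.copy(), flavor="hybrid", lambda_mix=float(lambda_mix))


def heats_operator(assoc: AssociationMatrix) -> SpreadOperator:
    """HeatS: W_ij = (1/k(m_i)) sum_l a_il a_jl / k(d_l); rows of
    positive-degree miRNAs sum to 1."""
    w = hybrid_operator(assoc, 0.0)
    return SpreadOperator(w.values, flavor="heats")


def probs_operator(assoc: AssociationMatrix) -> SpreadOperator:
    """ProbS: W_ij = (1/k(m_j)) sum_l a_il a_jl / k(d_l); columns of
    positive-degree miRNAs sum to 1 (resource conservation)."""
    w = hybrid_operator(assoc, 1.0)
    return SpreadOperator(w.values, flavor="probs")


def restart_matrix(assoc: AssociationMatrix, lambda_mix: float) -> ScoreMatrix:
    """P_A = W_hybrid @ A: column j is the spread resource vector for disease j,
    starting from its known-miRNA indicator column of A."""
    w = hybrid_operator(assoc, lambda_mix)
    p_a = w.values @ assoc.values.astype(float)
    return ScoreMatrix(
        p_a, list(assoc.mirna_ids), list(assoc.disease_ids), stage="restart_raw"
    )


def normalize_restart(p_a: ScoreMatrix) -> ScoreMatrix:
    """P_0 = P_A / sum(P_A), total mass 1; positive scaling preserves all
    within-column score orderings."""
    if p_a.stage != "restart_raw":
        raise ValidationError(f"expected a restart_raw score matrix, got {p_a.stage!r}")
    total = float(p_a.values.sum())
    if total <= 0.0:
        raise DegenerateRestartError(
            "restart matrix has zero total mass (no known associations)"
        )
    return ScoreMatrix(
        p_a.values / total,
        list(p_a.mirna_ids),
        list(p_a.disease_ids),
        stage="restart_normalized",
    )
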