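"""Similarity-network transition matrices and the unbalanced bi-random walk.

The walk iterates, from the normalised restart matrix P_0,

    miRNA side:   P_tM = (1 - alpha) M P_{t-1} + alpha P_0
    disease side: P_tD = (1 - alpha) P_{t-1} D + alpha P_0

for t = 1 .. max(r, l), combining the two side-updates by their arithmetic
mean while both sides are still active (t <= r and t <= l), and using the
single active side once the other's step budget is exhausted.  M and D are
the column-normalised integrated miRNA / disease similarity matrices.  r and
l are maximal step counts, not convergence tolerances: there is no stopping
rule beyond T = max(r, l).  The recursion is linear with nonnegative
coefficients in P_0, so scaling P_0 scales the output and the final ranking
does not depend on the normalisation constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import AssociationMatrix, ScoreMatrix, SimilarityMatrix
from .exceptions import ValidationError

__all__ = ["TransitionMatrix", "WalkTrace", "transition_from_similarity",
           "birandom_walk", "rank_candidates"]


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic (where possible) transition matrix of one similarity
    network; columns whose similarity column is all zero stay all zero."""

    values: np.ndarray
    side: str  # mirna | disease

    @property
    def n(self) -> int:
        return self.values.shape[0]


def transition_from_similarity(sim: SimilarityMatrix, side: str) -> TransitionMatrix:
    """Column-normalise a similarity matrix into a transition matrix."""
    if side not in ("mirna", "disease"):
        raise ValidationError(f"side must be 'mirna' or 'disease', got {side!r}")
    s = sim.values
    if s.size and s.min() < 0:
        raise ValidationError("similarity entries must be nonnegative")
    col_sums = s.sum(axis=0)
    t = np.divide(s, col_sums[None, :], out=np.zeros_like(s), where=col_sums > 0)
    return TransitionMatrix(t, side=side)


@dataclass
class WalkTrace:
    """Per-iteration snapshots of the two side-updates and the combined state."""

    p_mirna_side: list[np.ndarray] = field(default_factory=list)
    p_disease_side: list[np.ndarray] = field(default_factory=list)
    p_combined: list[np.ndarray] = field(default_factory=list)

    @property
    def iterations(self) -> int:
        return len(self.p_combined)

    def deltas(self) -> list[float]:
        """Max-abs change between consecutive combined states, for stability
        inspection (the step-limited recursion has no convergence test)."""
        states = self.p_combined
        return [
            float(np.abs(states[t] - states[t - 1]).max()) for t in range(1, len(states))
        ]


def birandom_walk(
    p0: ScoreMatrix,
    m_trans: TransitionMatrix,
    d_trans: TransitionMatrix,
    alpha: float,
    r_steps: int,
    l_steps: int,
) -> tuple[ScoreMatrix, WalkTrace]:
    """Run the unbalanced bi-random walk; returns (P_T, trace), T = max(r, l).

    The restart term alpha * P_0 uses the normalised restart matrix, which is
    also the initial state.  With r = l = 0 the walk is a no-op and P_0 is
    returned unchanged; with alpha = 1 every iterate equals P_0 exactly.
    """
    if p0.stage != "restart_normalized":
        raise ValidationError(f"walk expects a restart_normalized P_0, got {p0.stage!r}")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    if r_steps < 0 or l_steps < 0:
        raise ValidationError("step counts must be nonnegative")
    n_m, n_d = p0.values.shape
    if m_trans.values.shape != (n_m, n_m):
        raise ValidationError(
            f"miRNA transition matrix is {m_trans.values.shape}, expected {(n_m, n_m)}"
        )
    if d_trans.values.shape != (n_d, n_d):
        raise ValidationError(
            f"disease transition matrix is {d_trans.values.shape}, expected {(n_d, n_d)}"
        )

    p_restart = p0.values
    p = p_restart.copy()
    trace = WalkTrace()
    m, d = m_trans.values, d_trans.values
    for t in range(1, max(r_steps, l_steps) + 1):
        p_m = (1.0 - alpha) * (m @ p) + alpha * p_restart
        p_d = (1.0 - alpha) * (p @ d) + alpha * p_restart
        if t <= r_steps and t <= l_steps:
            p_next = (p_m + p_d) / 2.0
        elif t <= r_steps:
            p_next = p_m
        else:  # t <= l_steps
            p_next = p_d
        trace.p_mirna_side.append(p_m)
        trace.p_disease_side.append(p_d)
        trace.p_combined.append(p_next)
        p = p_next
    out = ScoreMatrix(
        p, list(p0.mirna_ids), list(p0.disease_ids), stage="walk_output"
    )
    return out, trace


def rank_candidates(
    scores: ScoreMatrix, assoc: AssociationMatrix, disease_id: str
) -> list[tuple[str, float, int]]:
    """Rank candidate miRNAs for one disease by descending score.

    miRNAs already associated with the disease in the (training) association
    matrix are excluded.  Ties are broken by lexicographic miRNA id so the
    ranking is deterministic across runs.  Returns (miRNA id, score, rank)
    with 1-based ranks.
    """
    if scores.mirna_ids != assoc.mirna_ids or scores.disease_ids != assoc.disease_ids:
        raise ValidationError("score and association matrices have different labels")
    j = assoc.disease_index(disease_id)
    col = scores.values[:, j]
    known = assoc.values[:, j] == 1
    candidates = [
        (assoc.mirna_ids[i], float(col[i])) for i in range(assoc.n_mirnas) if not known[i]
    ]
    candidates.sort(key=lambda item: (-item[1], item[0]))
    return [(mid, score, rank) for rank, (mid, score) in enumerate(candidates, start=1)]
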