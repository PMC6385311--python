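"""End-to-end scoring pipeline: kernels -> integration -> restart -> walk."""

from __future__ import annotations

from .datatypes import AssociationMatrix, RunConfig, ScoreMatrix, SimilarityMatrix
from .exceptions import ValidationError
from .recommender import normalize_restart, restart_matrix
from .similarity import (
    gip_disease_similarity,
    gip_mirna_similarity,
    integrate_disease_similarity,
    integrate_mirna_similarity,
)
from .walk import birandom_walk, transition_from_similarity

__all__ = ["score_associations"]


def score_associations(
    assoc: AssociationMatrix,
    dss: SimilarityMatrix,
    mfs: SimilarityMatrix,
    config: RunConfig | None = None,
    restart: str = "hybrid",
    disease_kernel: SimilarityMatrix | None = None,
) -> ScoreMatrix:
    """Score all miRNA-disease pairs on the heterogeneous network.

    Steps: (1) GIP kernels from the association matrix for both node sets;
    (2) integration with the semantic (DSS) and functional (MFS) inputs;
    (3) hybrid-recommender restart matrix P_A and its normalisation P_0;
    (4) unbalanced bi-random walk over the two transition matrices.

    Parameters
    ----------
    restart
        ``"hybrid"`` uses P_A = W_hybrid @ A (the full method); ``"plain"``
        replaces it with the raw association matrix A, the ablated variant
        without the recommender spreading.
    disease_kernel
        Optional precomputed disease GIP kernel.  When given it is used
        instead of recomputing the kernel from ``assoc`` — the
        cross-validation harness uses this to optionally freeze the
        disease-side kernel while the miRNA side is recomputed per fold.
    """
    if config is None:
        config = RunConfig()
    if restart not in ("hybrid", "plain"):
        raise ValidationError(f"restart must be 'hybrid' or 'plain', got {restart!r}")

    mgs = gip_mirna_similarity(assoc, config.bandwidth_m)
    dgs = disease_kernel if disease_kernel is not None else gip_disease_similarity(
        assoc, config.bandwidth_d
    )
    m_s = integrate_mirna_similarity(mfs, mgs)
    d_s = integrate_disease_similarity(dss, dgs)
    m_trans = transition_from_similarity(m_s, side="mirna")
    d_trans = transition_from_similarity(d_s, side="disease")

    if restart == "hybrid":
        p_a = restart_matrix(assoc, config.lambda_mix)
    else:
        p_a = ScoreMatrix(
            assoc.values.astype(float),
            list(assoc.mirna_ids),
            list(assoc.disease_ids),
            stage="restart_raw",
        )
    p0 = normalize_restart(p_a)
    scores, _ = birandom_walk(
        p0, m_trans, d_trans, config.alpha, config.r_steps, config.l_steps
    )
    return scores
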