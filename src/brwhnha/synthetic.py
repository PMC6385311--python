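"""Planted-block synthetic heterogeneous networks.

The generator emulates the data regime the method targets: a sparse binary
bipartite association matrix with community structure, and two symmetric
similarity matrices whose block structure is correlated with the planted
associations (the guilt-by-association assumption: functionally similar
miRNAs associate with semantically similar diseases).  A configurable
fraction of off-diagonal similarity entries is zeroed to emulate the sparse,
partially-isolated upstream semantic/functional matrices that the kernel
fallback is designed to repair.

Block membership of both node sets is the planted signal: a miRNA-disease
pair in the same block is associated with probability
``within_block_assoc_prob``, any other pair with ``background_assoc_prob``.
All randomness flows from one seed through a fixed draw order (miRNA blocks,
disease blocks, associations, DSS, DSS zero mask, MFS, MFS zero mask), so a
given configuration is bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationMatrix, SimilarityMatrix
from .exceptions import ValidationError

__all__ = ["SynthConfig", "generate_network", "holdout_planted"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the planted-block generator.

    Defaults define the canonical test network: 200 miRNAs x 40 diseases in
    5 blocks, within-block association probability 0.15 against a 0.01
    background (overall density about 0.038), similarity means 0.6 within /
    0.1 between blocks with Gaussian noise sd 0.1, and 30% of off-diagonal
    similarity entries zeroed, seed 7.
    """

    n_mirnas: int = 200
    n_diseases: int = 40
    n_blocks: int = 5
    within_block_assoc_prob: float = 0.15
    background_assoc_prob: float = 0.01
    sim_within: float = 0.6
    sim_between: float = 0.1
    sim_noise: float = 0.1
    frac_zero_similarity: float = 0.3
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("within_block_assoc_prob", "background_assoc_prob",
                     "frac_zero_similarity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.within_block_assoc_prob < self.background_assoc_prob:
            raise ValidationError(
                "within_block_assoc_prob must be >= background_assoc_prob "
                "(the block structure is the planted signal)"
            )
        if self.n_blocks < 1 or self.n_mirnas < 1 or self.n_diseases < 1:
            raise ValidationError("network sizes and block count must be positive")
        if self.sim_noise < 0:
            raise ValidationError("sim_noise must be nonnegative")


def _block_assignment(n: int, n_blocks: int, rng: np.random.Generator) -> np.ndarray:
    """Random block labels with near-equal block sizes."""
    labels = np.repeat(np.arange(n_blocks), int(np.ceil(n / n_blocks)))[:n]
    return labels[rng.permutation(n)]


def _block_similarity(
    blocks: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    n = blocks.size
    same = blocks[:, None] == blocks[None, :]
    mean = np.where(same, cfg.sim_within, cfg.sim_between)
    noise = rng.normal(0.0, cfg.sim_noise, size=(n, n))
    upper = np.triu(mean + noise, k=1)
    s = upper + upper.T
    np.clip(s, 0.0, 1.0, out=s)
    # zero a seeded fraction of off-diagonal PAIRS (symmetric zeroing), to
    # exercise the integrated-similarity kernel fallback downstream
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = iu.size
    n_zero = int(round(cfg.frac_zero_similarity * n_pairs))
    if n_zero:
        chosen = rng.choice(n_pairs, size=n_zero, replace=False)
        s[iu[chosen], ju[chosen]] = 0.0
        s[ju[chosen], iu[chosen]] = 0.0
    np.fill_diagonal(s, 1.0)
    return s


def generate_network(
    cfg: SynthConfig | None = None,
) -> tuple[AssociationMatrix, SimilarityMatrix, SimilarityMatrix, set[tuple[str, str]]]:
    """Generate (association matrix, DSS, MFS, planted edge set).

    The planted edge set contains the drawn associations whose endpoints
    share a block — the signal edges that recovery experiments hold out.
    """
    if cfg is None:
        cfg = SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    mirna_ids = [f"m{i + 1:0{len(str(cfg.n_mirnas))}d}" for i in range(cfg.n_mirnas)]
    disease_ids = [f"d{j + 1:0{len(str(cfg.n_diseases))}d}" for j in range(cfg.n_diseases)]

    m_blocks = _block_assignment(cfg.n_mirnas, cfg.n_blocks, rng)
    d_blocks = _block_assignment(cfg.n_diseases, cfg.n_blocks, rng)

    same_block = m_blocks[:, None] == d_blocks[None, :]
    prob = np.where(same_block, cfg.within_block_assoc_prob, cfg.background_assoc_prob)
    a = (rng.random((cfg.n_mirnas, cfg.n_diseases)) < prob).astype(np.int8)
    assoc = AssociationMatrix(a, mirna_ids, disease_ids)

    dss = SimilarityMatrix(_block_similarity(d_blocks, cfg, rng), disease_ids, "semantic")
    mfs = SimilarityMatrix(_block_similarity(m_blocks, cfg, rng), mirna_ids, "functional")

    planted = {
        (mirna_ids[i], disease_ids[j])
        for i, j in zip(*np.nonzero(a & same_block))
    }
    return assoc, dss, mfs, planted


def holdout_planted(
    assoc: AssociationMatrix,
    planted: set[tuple[str, str]],
    fraction: float,
    seed: int = 0,
) -> tuple[AssociationMatrix, set[tuple[str, str]]]:
    """Remove a seeded random fraction of the planted edges from the matrix.

    Returns the masked copy and the held-out edge set, for recovery
    experiments outside the cross-validation harness.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    edges = sorted(planted)
    missing = [e for e in edges if assoc.values[assoc.mirna_index(e[0]),
                                                assoc.disease_index(e[1])] != 1]
    if missing:
        raise ValidationError(f"planted edges absent from the matrix: {missing[:5]}")
    rng = np.random.default_rng(seed)
    n_remove = int(round(fraction * len(edges)))
    chosen = rng.choice(len(edges), size=n_remove, replace=False)
    held_out = {edges[i] for i in chosen}
    masked = assoc.copy()
    for mid, did in held_out:
        masked.values[assoc.mirna_index(mid), assoc.disease_index(did)] = 0
    return masked, held_out
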