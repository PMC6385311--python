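"""Core labelled-matrix containers shared across the pipeline.

The three-layer heterogeneous network is carried as plain numpy arrays with
explicit identifier lists: an :class:`AssociationMatrix` for the bipartite
miRNA-disease layer, :class:`SimilarityMatrix` for each single-node-set
similarity layer, and :class:`ScoreMatrix` for association-score matrices at
the successive pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import ValidationError

SIMILARITY_KINDS = ("semantic", "functional", "gip", "integrated")
SCORE_STAGES = ("restart_raw", "restart_normalized", "walk_output")

_SYMMETRY_TOL = 1e-10


def _check_unique(ids: Sequence[str], axis: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {axis} identifiers: {dupes[:5]}")
    return ids


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease adjacency matrix A.

    Rows index miRNAs, columns index diseases.  ``values[i, j] == 1`` means
    miRNA ``mirna_ids[i]`` is a known (experimentally confirmed) partner of
    disease ``disease_ids[j]``.  Column j is the interaction profile IP(d_j)
    of that disease; row i is IP(m_i).
    """

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("association matrix must be 2-dimensional")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"({len(self.mirna_ids)} miRNAs, {len(self.disease_ids)} diseases)"
            )

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    def mirna_index(self, mirna_id: str) -> int:
        try:
            return self.mirna_ids.index(mirna_id)
        except ValueError:
            raise KeyError(f"unknown miRNA id: {mirna_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease id: {disease_id!r}") from None

    def edges(self) -> set[tuple[str, str]]:
        """The association list as a set of (miRNA id, disease id) pairs."""
        rows, cols = np.nonzero(self.values)
        return {(self.mirna_ids[i], self.disease_ids[j]) for i, j in zip(rows, cols)}

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.mirna_ids), list(self.disease_ids)
        )


@dataclass
class SimilarityMatrix:
    """Square nonnegative similarity matrix over one node set.

    ``kind`` records the provenance of the scores: upstream semantic
    (disease) or functional (miRNA) similarity, a Gaussian interaction
    profile kernel, or the integrated matrix that patches zero semantic /
    functional entries with the kernel value.
    """

    values: np.ndarray
    ids: list[str]
    kind: str = "semantic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError(f"similarity matrix must be square, got {self.values.shape}")
        self.ids = _check_unique(self.ids, "similarity")
        if len(self.ids) != self.values.shape[0]:
            raise ValidationError("id list length does not match matrix size")
        if self.kind not in SIMILARITY_KINDS:
            raise ValidationError(f"kind must be one of {SIMILARITY_KINDS}, got {self.kind!r}")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("similarity entries must be nonnegative")
        if self.values.size:
            asym = np.abs(self.values - self.values.T).max()
            if asym > _SYMMETRY_TOL:
                raise ValidationError(
                    f"similarity matrix asymmetric (max |S - S^T| = {asym:.3e})"
                )
        if self.kind == "gip" and self.values.size and self.values.max() > 1 + 1e-12:
            raise ValidationError("GIP kernel entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "SimilarityMatrix":
        return SimilarityMatrix(self.values.copy(), list(self.ids), self.kind)


@dataclass
class ScoreMatrix:
    """miRNA x disease association-score matrix at a given pipeline stage.

    Stages: ``restart_raw`` (P_A, the hybrid-operator-spread associations),
    ``restart_normalized`` (P_0 = P_A / sum(P_A), total mass 1) and
    ``walk_output`` (P_T after the bi-random walk).
    """

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]
    stage: str = "walk_output"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("score matrix must be 2-dimensional")
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValidationError("score matrix shape does not match identifier lists")
        if self.stage not in SCORE_STAGES:
            raise ValidationError(f"stage must be one of {SCORE_STAGES}, got {self.stage!r}")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("scores must be nonnegative")
        if self.stage == "restart_normalized" and self.values.size:
            total = self.values.sum()
            if abs(total - 1.0) > 1e-10:
                raise ValidationError(
                    f"restart_normalized scores must sum to 1, got {total!r}"
                )

    def disease_column(self, disease_id: str) -> np.ndarray:
        try:
            j = self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease id: {disease_id!r}") from None
        return self.values[:, j]

    def with_stage(self, stage: str) -> "ScoreMatrix":
        return replace(self, stage=stage)


@dataclass
class RunConfig:
    """Run parameters for the full scoring pipeline.

    lambda_mix interpolates between the HeatS (0) and ProbS (1) degree
    normalisations of the bipartite spread operator; alpha is the restart
    weight of the walk; r_steps / l_steps are the maximal walk step counts on
    the miRNA- and disease-similarity networks; bandwidth_m / bandwidth_d are
    the raw Gaussian-kernel bandwidth parameters r'_m and r'_d.  Defaults are
    the best-performing setting of the grid sweep: lambda=0.6, alpha=0.4,
    r=2, l=1, with unit raw bandwidths.
    """

    lambda_mix: float = 0.6
    alpha: float = 0.4
    r_steps: int = 2
    l_steps: int = 1
    bandwidth_m: float = 1.0
    bandwidth_d: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValidationError(f"lambda_mix must be in [0, 1], got {self.lambda_mix}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.r_steps < 0 or int(self.r_steps) != self.r_steps:
            raise ValidationError(f"r_steps must be a nonnegative integer, got {self.r_steps}")
        if self.l_steps < 0 or int(self.l_steps) != self.l_steps:
            raise ValidationError(f"l_steps must be a nonnegative integer, got {self.l_steps}")
        self.r_steps = int(self.r_steps)
        self.l_steps = int(self.l_steps)
        if self.bandwidth_m <= 0 or self.bandwidth_d <= 0:
            raise ValidationError("raw bandwidths must be positive")
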