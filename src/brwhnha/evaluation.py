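"""Cross-validated evaluation of the scoring pipeline.

Protocol: for each disease with at least ``min_degree`` known miRNAs, the
known miRNAs are split into five near-equal folds.  Each fold in turn is
masked out of the association matrix (only that disease's test edges are
removed), the interaction-profile kernels are recomputed from the masked
matrix, the pipeline is rerun, and the test miRNAs are ranked among all
candidates (test positives plus miRNAs never associated with the disease;
training positives are excluded).  AUC is the Mann-Whitney pairwise statistic
on the resulting ranking, computed per fold and then averaged.  The whole
procedure is repeated with fresh fold plans and every repetition is
deterministic given the run seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AssociationMatrix, RunConfig, ScoreMatrix, SimilarityMatrix
from .exceptions import ValidationError
from .pipeline import score_associations
from .similarity import gip_disease_similarity
from .walk import rank_candidates

__all__ = [
    "FoldPlan",
    "CVReport",
    "TTestResult",
    "select_evaluable_diseases",
    "make_folds",
    "auc_from_ranking",
    "precision_recall_at_k",
    "paired_t_test",
    "run_cv",
    "DEFAULT_KS",
]

logger = logging.getLogger(__name__)

DEFAULT_KS = tuple(range(10, 101, 10))

Scorer = Callable[
    [AssociationMatrix, SimilarityMatrix, SimilarityMatrix, RunConfig], ScoreMatrix
]


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint near-equal split of one disease's known miRNAs."""

    disease_id: str
    folds: tuple[tuple[str, ...], ...]
    repeat: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        flat = [m for fold in self.folds for m in fold]
        if len(set(flat)) != len(flat):
            raise ValidationError("fold subsets are not pairwise disjoint")
        sizes = [len(f) for f in self.folds]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValidationError(f"fold sizes {sizes} differ by more than 1")


def select_evaluable_diseases(
    assoc: AssociationMatrix, min_degree: int = 60
) -> list[str]:
    """Diseases with at least ``min_degree`` known miRNAs, in matrix order."""
    degrees = assoc.values.sum(axis=0)
    return [d for d, k in zip(assoc.disease_ids, degrees) if k >= min_degree]


def make_folds(
    known_mirnas: Sequence[str],
    n_folds: int = 5,
    seed: int | np.random.Generator = 0,
    disease_id: str = "",
    repeat: int = 0,
) -> FoldPlan:
    """Seeded shuffle then round-robin split into ``n_folds`` subsets.

    Sizes differ by at most one; the same seed always yields the same plan.
    """
    known = list(known_mirnas)
    if len(known) < n_folds:
        raise ValidationError(
            f"{len(known)} known miRNAs cannot be split into {n_folds} folds"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(known))
    shuffled = [known[i] for i in order]
    folds = tuple(tuple(shuffled[i::n_folds]) for i in range(n_folds))
    seed_val = 0 if isinstance(seed, np.random.Generator) else int(seed)
    return FoldPlan(disease_id=disease_id, folds=folds, repeat=repeat, seed=seed_val)


def auc_from_ranking(positive_ranks: Iterable[int], n_candidates: int) -> float:
    """Mann-Whitney AUC from the 1-based ranks of the positives.

    Fraction of (positive, negative) pairs in which the positive outranks
    (has a smaller rank than) the negative.  Ranks must be distinct, so no
    tie handling is needed here; tied scores are resolved deterministically
    upstream by the ranking rule.
    """
    ranks = sorted(int(r) for r in positive_ranks)
    n_pos = len(ranks)
    n_neg = n_candidates - n_pos
    if n_pos == 0 or n_neg <= 0:
        raise ValidationError("AUC needs at least one positive and one negative")
    if len(set(ranks)) != n_pos or ranks[0] < 1 or ranks[-1] > n_candidates:
        raise ValidationError("positive ranks must be distinct 1-based ranks <= n_candidates")
    wins = 0
    for i, r in enumerate(ranks):
        # negatives ranked below positive r: all ranks > r minus the positives below it
        positives_below = n_pos - 1 - i
        wins += (n_candidates - r) - positives_below
    return wins / (n_pos * n_neg)


def precision_recall_at_k(
    ranking: Sequence[str], positives: set[str], ks: Sequence[int] = DEFAULT_KS
) -> dict[int, tuple[float, float]]:
    """precision@k = hits/k and recall@k = hits/|positives| for each cutoff."""
    ks = list(ks)
    if ks != sorted(ks) or any(k <= 0 for k in ks):
        raise ValidationError("ks must be positive and sorted ascending")
    if not positives:
        raise ValidationError("positives set is empty")
    out: dict[int, tuple[float, float]] = {}
    for k in ks:
        hits = sum(1 for mid in ranking[:k] if mid in positives)
        out[k] = (hits / k, hits / len(positives))
    return out


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    degenerate_variance: bool = False


def paired_t_test(auc_a: Sequence[float], auc_b: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test on per-disease AUC vectors.

    Zero-variance differences cannot be tested: identical vectors return
    (t=0, p=1) and a constant nonzero difference returns the p -> 0 limit,
    both with the degenerate-variance flag set.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("paired t-test needs two equal-length vectors of length >= 2")
    diff = a - b
    mean = float(diff.mean())
    # float tolerance: a "constant" difference vector carries rounding noise
    if diff.std(ddof=1) <= 1e-12 * max(1.0, abs(mean)):
        if abs(mean) <= 1e-15:
            return TTestResult(0.0, 1.0, degenerate_variance=True)
        return TTestResult(np.inf if mean > 0 else -np.inf, 0.0, degenerate_variance=True)
    res = stats.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(res.pvalue), degenerate_variance=False)


@dataclass
class CVReport:
    """Long-form per-(disease, repeat, fold) records plus aggregates."""

    records: pd.DataFrame
    n_folds: int
    repeats: int
    min_degree: int
    config: RunConfig = field(default_factory=RunConfig)

    def per_disease(self) -> pd.DataFrame:
        """Mean AUC per disease over all repeats and folds."""
        return (
            self.records.groupby("disease_id", sort=False)["auc"]
            .mean()
            .reset_index(name="mean_auc")
        )

    @property
    def mean_auc(self) -> float:
        """Grand mean: average over diseases of the per-disease mean AUC."""
        return float(self.per_disease()["mean_auc"].mean())

    @property
    def best_repeat_auc(self) -> float:
        """Maximum over repeats of that repeat's grand mean AUC."""
        per_rep = (
            self.records.groupby(["repeat", "disease_id"], sort=False)["auc"]
            .mean()
            .groupby("repeat")
            .mean()
        )
        return float(per_rep.max())

    def mean_precision_recall(self) -> pd.DataFrame:
        """Mean precision@k / recall@k over all records, long form by k."""
        ks = sorted(
            int(c.split("_")[1]) for c in self.records.columns if c.startswith("precision_")
        )
        rows = [
            {
                "k": k,
                "precision": float(self.records[f"precision_{k}"].mean()),
                "recall": float(self.records[f"recall_{k}"].mean()),
            }
            for k in ks
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def run_cv(
    assoc: AssociationMatrix,
    dss: SimilarityMatrix,
    mfs: SimilarityMatrix,
    config: RunConfig | None = None,
    n_folds: int = 5,
    repeats: int = 100,
    min_degree: int = 60,
    ks: Sequence[int] = DEFAULT_KS,
    scorer: Scorer | None = None,
    freeze_disease_kernel: bool = False,
) -> CVReport:
    """Per-disease k-fold cross-validation with per-fold kernel recomputation.

    Only the evaluated disease's test edges are masked in each fold; all
    other associations stay in the training matrix.  Both interaction-profile
    kernels are recomputed from the masked matrix by default; with
    ``freeze_disease_kernel`` the disease-side kernel from the full matrix is
    reused (sensitivity switch).  ``scorer`` replaces the default pipeline;
    it receives (masked association matrix, DSS, MFS, config).
    """
    if config is None:
        config = RunConfig()
    if scorer is None:
        frozen_dgs = (
            gip_disease_similarity(assoc, config.bandwidth_d)
            if freeze_disease_kernel
            else None
        )

        def scorer(a, d, m, c):  # noqa: ANN001 - local default
            return score_associations(a, d, m, c, disease_kernel=frozen_dgs)

    diseases = select_evaluable_diseases(assoc, min_degree)
    rows: list[dict] = []
    for rep in range(repeats):
        for di, disease_id in enumerate(diseases):
            j = assoc.disease_index(disease_id)
            known = [
                assoc.mirna_ids[i]
                for i in range(assoc.n_mirnas)
                if assoc.values[i, j] == 1
            ]
            rng = np.random.default_rng([config.seed, rep, di])
            plan = make_folds(known, n_folds, rng, disease_id=disease_id, repeat=rep)
            for fold_idx, test_fold in enumerate(plan.folds):
                masked = assoc.copy()
                test_rows = [assoc.mirna_index(m) for m in test_fold]
                masked.values[test_rows, j] = 0
                if masked.values[:, j].sum() == 0:
                    logger.warning(
                        "skipping %s repeat %d fold %d: no training associations left",
                        disease_id, rep, fold_idx,
                    )
                    continue
                scores = scorer(masked, dss, mfs, config)
                ranking = rank_candidates(scores, masked, disease_id)
                ranked_ids = [mid for mid, _, _ in ranking]
                rank_of = {mid: rank for mid, _, rank in ranking}
                positives = set(test_fold)
                n_candidates = len(ranking)
                if n_candidates - len(positives) <= 0:
                    logger.warning(
                        "skipping %s repeat %d fold %d: no negative candidates",
                        disease_id, rep, fold_idx,
                    )
                    continue
                auc = auc_from_ranking([rank_of[m] for m in positives], n_candidates)
                pr = precision_recall_at_k(ranked_ids, positives, ks)
                row = {
                    "disease_id": disease_id,
                    "repeat": rep,
                    "fold": fold_idx,
                    "n_test": len(positives),
                    "n_candidates": n_candidates,
                    "auc": auc,
                }
                for k, (prec, rec) in pr.items():
                    row[f"precision_{k}"] = prec
                    row[f"recall_{k}"] = rec
                rows.append(row)
    records = pd.DataFrame(rows)
    return CVReport(
        records=records,
        n_folds=n_folds,
        repeats=repeats,
        min_degree=min_degree,
        config=config,
    )
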