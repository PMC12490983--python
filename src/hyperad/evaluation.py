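"""Ranking metrics, repeated stratified cross-validation, and prioritization.

The evaluation protocol is repeated stratified k-fold cross-validation
(default ten repetitions of five folds) over a fixed positive gene list and
a pool of presumed non-disease genes.  Per repetition a negative set is
sampled from the pool (resampled each repetition by default; a fixed-once
mode is available), folds are stratified by class, and within each fold the
hyperedge weights and the model are fit on training genes only before
scoring the held-out genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .hypergraph import Hypergraph, LabelSet
from .model import ModelConfig, RiskScores, train

__all__ = ["CVConfig", "CVResult", "auroc", "auprc", "cross_validate", "prioritize"]


@dataclass(frozen=True)
class CVConfig:
    n_repetitions: int = 10
    n_folds: int = 5
    seed: int = 0
    negative_pool_size: int = 1000
    resample_negatives: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass(frozen=True)
class CVResult:
    """Per-fold AUROC/AUPRC, shape (n_repetitions, n_folds)."""

    auroc: np.ndarray
    auprc: np.ndarray

    @property
    def auroc_mean(self) -> float:
        return float(self.auroc.mean())

    @property
    def auroc_std(self) -> float:
        return float(self.auroc.std(ddof=1)) if self.auroc.size > 1 else 0.0

    @property
    def auprc_mean(self) -> float:
        return float(self.auprc.mean())

    @property
    def auprc_std(self) -> float:
        return float(self.auprc.std(ddof=1)) if self.auprc.size > 1 else 0.0


def _check_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute a ranking metric")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, counting ties as one half.
    """
    labels = np.asarray(labels)
    _check_two_class(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve, by the average-precision
    step rule (no trapezoidal interpolation, which is optimistic)."""
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise ValueError("at least one positive is required for AUPRC")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def cross_validate(
    hg: Hypergraph,
    positives: Iterable[str],
    negative_pool: Iterable[str],
    model_config: ModelConfig,
    cv_config: CVConfig,
) -> CVResult:
    """Repeated stratified k-fold CV of the model on one hypergraph.

    Deterministic under ``cv_config.seed``: repetition r uses negative sample
    seed ``seed + r`` (or the repetition-0 sample when
    ``resample_negatives=False``), fold assignment seed ``seed + r``, and a
    model seed derived from (seed, repetition, fold).
    """
    positives = sorted(set(positives) & set(hg.genes))
    pool = sorted((set(negative_pool) - set(positives)) & set(hg.genes))
    if not positives:
        raise ValueError("no positive genes present in the hypergraph")
    if not pool:
        raise ValueError("empty negative pool after restriction to the hypergraph")

    idx = hg.gene_index
    auc = np.empty((cv_config.n_repetitions, cv_config.n_folds))
    ap = np.empty_like(auc)
    for rep in range(cv_config.n_repetitions):
        sample_rep = rep if cv_config.resample_negatives else 0
        rng = np.random.default_rng((cv_config.seed + sample_rep) % (2**31))
        k = min(cv_config.negative_pool_size, len(pool))
        negatives = sorted(rng.choice(pool, size=k, replace=False))

        genes = np.array(positives + negatives)
        y = np.array([1] * len(positives) + [0] * len(negatives))
        skf = StratifiedKFold(
            n_splits=cv_config.n_folds, shuffle=True,
            random_state=(cv_config.seed + rep) % (2**31),
        )
        for fold, (tr, te) in enumerate(skf.split(genes, y)):
            if len(np.unique(y[te])) < 2:
                raise ValueError(f"fold {fold} of repetition {rep} contains a single class")
            labels = LabelSet(
                positives=frozenset(genes[tr][y[tr] == 1]),
                negatives=frozenset(genes[tr][y[tr] == 0]),
            )
            fold_seed = (cv_config.seed * 1_000_003 + rep * 101 + fold) % (2**31)
            result = train(hg, labels, replace(model_config, seed=fold_seed))
            test_scores = result.scores.risk[[idx[g] for g in genes[te]]]
            auc[rep, fold] = auroc(test_scores, y[te])
            ap[rep, fold] = auprc(test_scores, y[te])
    return CVResult(auroc=auc, auprc=ap)


def prioritize(scores: RiskScores, exclude: Iterable[str] = ()) -> list[str]:
    """Genes ordered by descending risk score, known positives excluded.

    Ties are broken lexicographically by gene symbol so the ranking is
    deterministic.
    """
    exclude = set(exclude)
    lookup = scores.as_dict()
    return sorted(
        (g for g in scores.genes if g not in exclude),
        key=lambda g: (-lookup[g], g),
    )
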