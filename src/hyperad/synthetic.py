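"""Seeded generators for desk-scale benchmark data.

Real inputs to the pipeline — gene-set collections, curated disease-gene
lists, interaction networks, staged expression cohorts — are external
resources.  These generators emulate their structure at a scale that trains
in seconds, so every statistic in the package can be exercised end to end:

* a hypergraph with a *planted disease module*: a subset of genes that
  co-occur in "relevant" hyperedges much more often than chance, alongside
  uniform background hyperedges;
* a staged expression matrix with monotone mean trends planted in a known
  gene subset across ordered cognitive-stage groups;
* a toy undirected gene network with planted candidate-known edges over an
  Erdos-Renyi background.

Every generator is a pure function of its spec (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypergraph import GeneSet, Hypergraph, LabelSet, build_hypergraph

__all__ = [
    "PlantedHypergraphSpec",
    "StagedExpressionSpec",
    "StagedExpression",
    "generate_planted_hypergraph",
    "generate_staged_expression",
    "generate_toy_network",
]


@dataclass(frozen=True)
class PlantedHypergraphSpec:
    """Planted-module hypergraph parameters.

    Each member of a *relevant* hyperedge is drawn from the disease genes
    with probability ``p_disease_in_relevant`` and uniformly from all genes
    otherwise; *background* hyperedges draw all members uniformly.  The
    defaults give a benchmark that trains in well under a minute on one CPU.
    """

    n_genes: int = 300
    n_disease_genes: int = 30
    n_relevant_sets: int = 40
    n_background_sets: int = 120
    p_disease_in_relevant: float = 0.8
    set_size_range: tuple[int, int] = (5, 25)
    positive_fraction: float = 0.5
    n_negatives: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_disease_in_relevant <= 1:
            raise ValueError("p_disease_in_relevant must lie in [0, 1]")
        if not 0 < self.positive_fraction <= 1:
            raise ValueError("positive_fraction must lie in (0, 1]")
        if self.n_disease_genes >= self.n_genes:
            raise ValueError("n_disease_genes must be smaller than n_genes")
        lo, hi = self.set_size_range
        if not 2 <= lo <= hi:
            raise ValueError("set_size_range must satisfy 2 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("maximum set size exceeds the number of genes")
        if self.n_negatives > self.n_genes - self.n_disease_genes:
            raise ValueError("not enough non-disease genes for the negative sample")


@dataclass(frozen=True)
class StagedExpressionSpec:
    """Staged expression parameters.

    Group sizes default to a 174/100/104 three-stage cohort.  Trend genes
    get their group mean shifted by ``effect_size`` per stage step (sign
    randomized per gene and recorded); all genes receive iid Gaussian noise
    with standard deviation ``noise_sd``.
    """

    n_genes: int = 500
    n_trend_genes: int = 50
    group_sizes: tuple[int, ...] = (174, 100, 104)
    effect_size: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trend_genes > self.n_genes:
            raise ValueError("n_trend_genes must be <= n_genes")
        if len(self.group_sizes) < 2 or any(g < 2 for g in self.group_sizes):
            raise ValueError("need >= 2 stage groups of size >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class StagedExpression:
    expression: pd.DataFrame          # genes x samples
    stage: np.ndarray                 # ordinal stage code per sample
    trend_genes: frozenset[str]
    signs: dict[str, int]             # +1 increasing / -1 decreasing per trend gene


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sample_set(
    rng: np.random.Generator,
    size: int,
    disease: np.ndarray,
    all_genes: np.ndarray,
    p_disease: float,
) -> tuple[str, ...]:
    """Draw ``size`` distinct members, each from the disease pool with
    probability ``p_disease`` and uniformly otherwise."""
    chosen: list[str] = []
    taken: set[str] = set()
    while len(chosen) < size:
        pool = disease if rng.random() < p_disease else all_genes
        g = pool[rng.integers(len(pool))]
        if g not in taken:
            taken.add(g)
            chosen.append(g)
    return tuple(chosen)


def generate_planted_hypergraph(
    spec: PlantedHypergraphSpec = PlantedHypergraphSpec(),
) -> tuple[Hypergraph, LabelSet, frozenset[str]]:
    """Hypergraph with a planted disease module, labels, and the ground truth.

    Returns ``(hypergraph, labels, disease_genes)``.  A fraction
    ``positive_fraction`` of the disease genes (those present in the built
    universe) is exposed as training positives; the rest are held out as
    discoverable.  Negatives are sampled uniformly from non-disease genes.
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array(_gene_names(spec.n_genes))
    disease_idx = rng.choice(spec.n_genes, size=spec.n_disease_genes, replace=False)
    disease = genes[np.sort(disease_idx)]
    disease_set = frozenset(disease)

    lo, hi = spec.set_size_range
    sets: list[GeneSet] = []
    for b in range(spec.n_relevant_sets):
        size = int(rng.integers(lo, hi + 1))
        members = _sample_set(rng, size, disease, genes, spec.p_disease_in_relevant)
        sets.append(GeneSet(f"REL{b:04d}", "planted relevant set", members, "REL"))
    for b in range(spec.n_background_sets):
        size = int(rng.integers(lo, hi + 1))
        members = _sample_set(rng, size, disease, genes, 0.0)
        sets.append(GeneSet(f"BG{b:04d}", "background set", members, "BG"))

    hg = build_hypergraph(sets, min_size=2)
    universe = set(hg.genes)

    disease_in_universe = [g for g in disease if g in universe]
    n_pos = max(1, int(round(spec.positive_fraction * len(disease_in_universe))))
    pos = frozenset(rng.choice(disease_in_universe, size=n_pos, replace=False))
    non_disease = [g for g in hg.genes if g not in disease_set]
    k = min(spec.n_negatives, len(non_disease))
    neg = frozenset(rng.choice(non_disease, size=k, replace=False))
    return hg, LabelSet(positives=pos, negatives=neg), disease_set


def generate_staged_expression(
    spec: StagedExpressionSpec = StagedExpressionSpec(),
) -> StagedExpression:
    """Expression matrix with planted monotone stage trends.

    Trend gene g in stage s has mean ``sign(g) * effect_size * s``; all
    other genes have mean zero at every stage.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    stage = np.repeat(np.arange(len(spec.group_sizes)), spec.group_sizes)
    n_samples = int(stage.size)

    trend_idx = np.sort(rng.choice(spec.n_genes, size=spec.n_trend_genes, replace=False))
    signs_arr = rng.choice([-1, 1], size=spec.n_trend_genes)
    means = np.zeros((spec.n_genes, n_samples))
    for i, s in zip(trend_idx, signs_arr):
        means[i] = s * spec.effect_size * stage
    noise = rng.normal(0.0, spec.noise_sd, size=means.shape) if spec.noise_sd > 0 else 0.0
    expr = pd.DataFrame(
        means + noise,
        index=genes,
        columns=[f"S{j:04d}" for j in range(n_samples)],
    )
    trend_genes = frozenset(genes[i] for i in trend_idx)
    signs = {genes[i]: int(s) for i, s in zip(trend_idx, signs_arr)}
    return StagedExpression(expression=expr, stage=stage, trend_genes=trend_genes, signs=signs)


def generate_toy_network(
    genes: list[str],
    planted_pairs: list[tuple[str, str]] = (),
    background_edge_prob: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Undirected edge list: planted pairs plus Erdos-Renyi background.

    With ``background_edge_prob=0`` the edge set equals the planted pairs;
    with 1 it is the complete graph on ``genes`` (plus any planted pairs
    involving outside genes).  Edges are returned deduplicated, endpoints
    sorted, in deterministic order.
    """
    if not 0 <= background_edge_prob <= 1:
        raise ValueError("background_edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges: set[tuple[str, str]] = set()
    for u, v in planted_pairs:
        if u != v:
            edges.add((min(u, v), max(u, v)))
    n = len(genes)
    if background_edge_prob > 0 and n > 1:
        # one Bernoulli draw per unordered pair, in deterministic pair order
        draws = rng.random(n * (n - 1) // 2)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                if draws[k] < background_edge_prob:
                    u, v = genes[i], genes[j]
                    edges.add((min(u, v), max(u, v)))
                k += 1
    return sorted(edges)
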