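"""Downstream validation statistics for a ranked gene list.

Three independent lines of evidence that a prioritization is biologically
meaningful, each reproduced here as a reusable statistic:

* **Decile enrichment** — does a functional gene set concentrate in the top
  10% of the ranking?  Hypergeometric upper-tail test on the first decile,
  Benjamini-Hochberg corrected across terms.
* **Network association** — do the top candidates share more edges with an
  established disease-gene set than size-matched random gene sets drawn
  from the network?  Empirical permutation p-value.
* **Monotone expression trend** — does a gene's expression change
  monotonically across ordered disease stages?  Kendall's tau-b per gene
  with tie corrections, normal-approximation p-values, BH FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hypergraph import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "DecileEnrichment",
    "NetworkAssociationResult",
    "decile_enrichment",
    "network_association_test",
    "kendall_taub_trend",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class DecileEnrichment:
    term_id: str
    bin_fractions: tuple[float, ...]
    first_bin_overlap: int
    n_in_universe: int
    pvalue: float
    fdr: float


@dataclass(frozen=True)
class NetworkAssociationResult:
    observed: int
    null_mean: float
    null_sd: float
    pvalue: float
    n_candidates_in_network: int


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _bin_sizes(n: int, n_bins: int) -> list[int]:
    """Near-equal contiguous bins; the remainder goes to the earlier bins."""
    q, r = divmod(n, n_bins)
    return [q + 1] * r + [q] * (n_bins - r)


def decile_enrichment(
    ranking: Sequence[str],
    term_sets: Iterable[GeneSet],
    n_bins: int = 10,
) -> list[DecileEnrichment]:
    """First-decile hypergeometric enrichment of each term in a ranked list.

    The ranking is split into ``n_bins`` near-equal contiguous bins.  For
    each term the fraction of its in-universe members falling in each bin
    is reported, along with the upper-tail hypergeometric p-value
    P(X >= overlap) for the first bin and the BH-adjusted FDR across terms.
    Terms with no member in the ranking universe are skipped with a warning.
    """
    if not ranking:
        raise ValueError("ranking is empty")
    if len(set(ranking)) != len(ranking):
        raise ValueError("ranking contains duplicate genes")
    universe = set(ranking)
    M = len(ranking)
    sizes = _bin_sizes(M, n_bins)
    edges = np.cumsum([0] + sizes)
    bin_of = {}
    for b in range(n_bins):
        for pos in range(edges[b], edges[b + 1]):
            bin_of[ranking[pos]] = b

    rows: list[tuple[str, tuple[float, ...], int, int, float]] = []
    for term in term_sets:
        in_universe = [g for g in term.members if g in universe]
        if not in_universe:
            logger.warning("term %s has no genes in the ranking universe; skipped", term.set_id)
            continue
        counts = np.zeros(n_bins, dtype=int)
        for g in in_universe:
            counts[bin_of[g]] += 1
        K = len(in_universe)
        overlap = int(counts[0])
        # P(X >= overlap) drawing bin-1 genes without replacement
        p = float(stats.hypergeom.sf(overlap - 1, M, K, sizes[0]))
        rows.append((term.set_id, tuple(counts / K), overlap, K, min(p, 1.0)))

    if not rows:
        return []
    fdrs = benjamini_hochberg([r[4] for r in rows])
    return [
        DecileEnrichment(term_id=r[0], bin_fractions=r[1], first_bin_overlap=r[2],
                         n_in_universe=r[3], pvalue=r[4], fdr=float(f))
        for r, f in zip(rows, fdrs)
    ]


def network_association_test(
    candidates: Iterable[str],
    known: Iterable[str],
    edges: Iterable[tuple[str, str]],
    n_perm: int = 10_000,
    seed: int = 0,
) -> NetworkAssociationResult:
    """Permutation test of candidate-to-known connectivity in a gene network.

    The statistic is the number of network edges with one endpoint among the
    candidates and the other among the known disease genes.  The null draws
    size-matched gene sets uniformly from the network genes excluding the
    known set; p = (1 + #{null >= observed}) / (1 + n_perm), so the smallest
    attainable p is 1/(n_perm + 1).

    Candidates absent from the network are dropped (the null is matched to
    the present subset) and reported via ``n_candidates_in_network``.
    """
    candidates = set(candidates)
    known = set(known)
    if candidates & known:
        raise ValueError("candidate and known gene sets must be disjoint")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    # neighbors-in-known count per gene: the statistic for any candidate set
    # disjoint from `known` is the sum of these counts over its members.
    known_links: dict[str, int] = {}
    network_genes: set[str] = set()
    seen: set[frozenset[str]] = set()
    for u, v in edges:
        if u == v:
            continue
        pair = frozenset((u, v))
        if pair in seen:
            continue  # undirected network: count each edge once
        seen.add(pair)
        network_genes.update((u, v))
        if v in known:
            known_links[u] = known_links.get(u, 0) + 1
        if u in known:
            known_links[v] = known_links.get(v, 0) + 1

    present = sorted(candidates & network_genes)
    if len(present) < len(candidates):
        logger.warning(
            "%d of %d candidates absent from the network; statistic computed on the rest",
            len(candidates) - len(present), len(candidates),
        )
    if not present:
        raise ValueError("no candidate gene is present in the network")
    observed = sum(known_links.get(g, 0) for g in present)

    pool = np.array(sorted(network_genes - known))
    if len(pool) < len(present):
        raise ValueError("network too small to draw size-matched null sets")
    counts = np.array([known_links.get(g, 0) for g in pool])
    rng = np.random.default_rng(seed % (2**31))
    null = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(pool), size=len(present), replace=False)
        null[i] = counts[pick].sum()
    pvalue = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return NetworkAssociationResult(
        observed=int(observed),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        pvalue=float(pvalue),
        n_candidates_in_network=len(present),
    )


def kendall_taub_trend(
    expression: pd.DataFrame,
    stage: Sequence[int],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Kendall tau-b monotone-trend test against an ordinal stage.

    Parameters
    ----------
    expression
        Genes x samples matrix (rows indexed by gene symbol).
    stage
        Ordinal stage code per sample (e.g. 0 = no impairment, 1 = mild
        impairment, 2 = disease), aligned with the columns.
    fdr_threshold
        BH FDR below which a gene is called trending; its direction is the
        sign of tau.

    Returns a DataFrame indexed by gene with columns ``tau``, ``pvalue``,
    ``fdr`` and ``direction`` (``increasing`` / ``decreasing`` / ``none``).
    A constant expression vector has undefined tau; it is recorded with
    tau = NaN, p = 1 and direction ``none``.  Missing expression values are
    handled pairwise-complete (samples with NaN dropped for that gene).
    """
    stage = np.asarray(stage)
    if stage.ndim != 1 or len(stage) != expression.shape[1]:
        raise ValueError("stage vector must align with expression columns")
    if len(np.unique(stage)) < 2:
        raise ValueError("at least two distinct stages are required")
    if np.any(pd.isna(stage)):
        raise ValueError("stage labels must not be missing")

    taus = np.full(len(expression), np.nan)
    pvals = np.ones(len(expression))
    X = expression.to_numpy(dtype=float)
    for i in range(len(expression)):
        x = X[i]
        mask = np.isfinite(x)
        xs, ss = x[mask], stage[mask]
        if len(xs) < 2 or np.all(xs == xs[0]) or len(np.unique(ss)) < 2:
            continue  # tau undefined: keep NaN / p=1
        tau, p = stats.kendalltau(xs, ss, method="asymptotic")
        taus[i], pvals[i] = tau, p
    fdr = benjamini_hochberg(pvals)
    significant = (fdr < fdr_threshold) & np.isfinite(taus) & (taus != 0)
    direction = np.where(
        significant & (taus > 0), "increasing",
        np.where(significant & (taus < 0), "decreasing", "none"),
    )
    return pd.DataFrame(
        {"tau": taus, "pvalue": pvals, "fdr": fdr, "direction": direction},
        index=expression.index,
    )
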