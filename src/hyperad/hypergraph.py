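"""Gene-set hypergraphs.

Genes are nodes and annotated gene sets (GMT lines, e.g. MSigDB collections)
are hyperedges.  The incidence matrix ``H`` is the N x M binary matrix with
``H[a, b] = 1`` iff gene ``a`` belongs to gene set ``b``.  All downstream
quantities — node degrees d(v), hyperedge degrees delta(e), disease-specific
hyperedge weights w(e), and the normalized hypergraph Laplacian — are derived
from ``H`` here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "Hypergraph",
    "LabelSet",
    "HyperedgeWeights",
    "DegreeVectors",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "filter_collections",
    "build_hypergraph",
    "degrees",
    "compute_hyperedge_weights",
    "hypergraph_laplacian",
]


class GmtParseError(ValueError):
    """Raised for malformed GMT input (line number included in the message)."""


@dataclass(frozen=True)
class GeneSet:
    """One annotated gene set: a named collection of gene symbols.

    Members are kept in first-occurrence order and are unique; symbols are
    taken verbatim (no case folding, no alias mapping).
    """

    set_id: str
    description: str
    members: tuple[str, ...]
    collection_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.set_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Hypergraph:
    """Gene/gene-set incidence structure.

    Attributes
    ----------
    genes
        Ordered (lexicographic) unique gene symbols; row order of ``incidence``.
    set_ids
        Gene-set identifiers in input order; column order of ``incidence``.
    incidence
        Sparse binary N x M CSR matrix.
    collection_tags
        Per-set collection tag (``None`` where untagged).
    """

    genes: tuple[str, ...]
    set_ids: tuple[str, ...]
    incidence: sp.csr_matrix
    collection_tags: tuple[str | None, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.collection_tags is None:
            object.__setattr__(self, "collection_tags", (None,) * len(self.set_ids))
        if self.incidence.shape != (len(self.genes), len(self.set_ids)):
            raise ValueError(
                f"incidence shape {self.incidence.shape} does not match "
                f"{len(self.genes)} genes x {len(self.set_ids)} sets"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_sets(self) -> int:
        return len(self.set_ids)

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def members(self, set_idx: int) -> tuple[str, ...]:
        """Gene symbols incident to hyperedge ``set_idx`` (row-order)."""
        rows = self.incidence.getcol(set_idx).tocoo().row
        return tuple(self.genes[i] for i in sorted(rows))


@dataclass(frozen=True)
class LabelSet:
    """Positive / negative gene partition used for transductive training."""

    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "negatives", frozenset(self.negatives))
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"genes labeled both positive and negative: {sorted(overlap)[:5]}")

    def restrict_to(self, genes: Iterable[str]) -> "LabelSet":
        """Drop labels for genes outside the hypergraph universe (logged)."""
        universe = set(genes)
        dropped = (self.positives | self.negatives) - universe
        if dropped:
            logger.warning("dropping %d labeled genes outside the hypergraph universe", len(dropped))
        return LabelSet(self.positives & universe, self.negatives & universe)


@dataclass(frozen=True)
class HyperedgeWeights:
    """Per-hyperedge relevance w(e) in [0, 1].

    w(e) is the fraction of the hyperedge's member genes that are known
    disease genes: 0 iff none of the members is a positive, 1 iff all are.
    """

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("hyperedge weights must lie in [0, 1]")

    @classmethod
    def identity(cls, n_sets: int) -> "HyperedgeWeights":
        return cls(np.ones(n_sets))

    def __len__(self) -> int:
        return len(self.w)


@dataclass(frozen=True)
class DegreeVectors:
    """Node degrees d(v) (under a weight mode) and hyperedge degrees delta(e)."""

    node_degree: np.ndarray
    edge_degree: np.ndarray


def read_gmt(path: str | Path, collection_tag: str | None = None) -> list[GeneSet]:
    """Parse a GMT file (tab-separated: name, description, member genes...).

    Duplicate gene symbols within a line are removed keeping the first
    occurrence; symbols are read verbatim.  A line with fewer than three
    fields, or a repeated set id, raises :class:`GmtParseError`.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            set_id, description = fields[0], fields[1]
            if set_id in seen:
                raise GmtParseError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            seen.add(set_id)
            members = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise GmtParseError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            sets.append(GeneSet(set_id, description, members, collection_tag))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets in GMT format (round-trips through :func:`read_gmt`)."""
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write("\t".join((s.set_id, s.description, *s.members)) + "\n")


def filter_collections(sets: Sequence[GeneSet], tags: Iterable[str]) -> list[GeneSet]:
    """Keep only gene sets whose ``collection_tag`` is in ``tags``."""
    wanted = set(tags)
    return [s for s in sets if s.collection_tag in wanted]


def build_hypergraph(
    sets: Sequence[GeneSet],
    min_size: int = 2,
    max_size: int | None = None,
) -> Hypergraph:
    """Assemble the incidence structure from gene sets.

    Sets with fewer than ``min_size`` or more than ``max_size`` members are
    dropped before construction (singletons carry no relational information).
    The gene universe is the union of the retained sets' members; genes are
    ordered lexicographically, sets keep input order, so the incidence matrix
    is deterministic.
    """
    if not sets:
        raise ValueError("no gene sets provided")
    retained = [
        s
        for s in sets
        if len(s) >= min_size and (max_size is None or len(s) <= max_size)
    ]
    if not retained:
        raise ValueError(
            f"all {len(sets)} gene sets filtered out by size bounds "
            f"[{min_size}, {max_size if max_size is not None else 'inf'}]"
        )
    ids = [s.set_id for s in retained]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate set ids among retained gene sets")

    genes = tuple(sorted({g for s in retained for g in s.members}))
    gene_index = {g: i for i, g in enumerate(genes)}
    rows: list[int] = []
    cols: list[int] = []
    for b, s in enumerate(retained):
        for g in s.members:
            rows.append(gene_index[g])
            cols.append(b)
    incidence = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(genes), len(retained)),
    )
    return Hypergraph(
        genes=genes,
        set_ids=tuple(ids),
        incidence=incidence,
        collection_tags=tuple(s.collection_tag for s in retained),
    )


def degrees(hg: Hypergraph, w: HyperedgeWeights | None = None) -> DegreeVectors:
    """Node degrees d(v) = sum_e w(e) H(v,e) and hyperedge degrees delta(e).

    With ``w=None`` (identity weights) node degrees are the plain incident
    hyperedge counts, i.e. the incidence row sums.
    """
    H = hg.incidence
    if w is None:
        node_degree = np.asarray(H.sum(axis=1)).ravel()
    else:
        if len(w) != hg.n_sets:
            raise ValueError(f"weights length {len(w)} != number of hyperedges {hg.n_sets}")
        node_degree = H @ w.w
    edge_degree = np.asarray(H.sum(axis=0)).ravel().astype(int)
    return DegreeVectors(node_degree=np.asarray(node_degree, dtype=float), edge_degree=edge_degree)


def compute_hyperedge_weights(hg: Hypergraph, positives: Iterable[str]) -> HyperedgeWeights:
    """Disease-specific hyperedge weights w(e) = |members(e) ∩ positives| / delta(e).

    Positives not present in the hypergraph universe are ignored with a
    logged warning.  The denominator is the hyperedge degree over the
    constructed universe, so genes dropped at construction never inflate it.
    """
    positives = set(positives)
    known = positives & set(hg.genes)
    missing = len(positives) - len(known)
    if missing:
        logger.warning("%d positive genes not in the hypergraph universe; ignored", missing)
    idx = hg.gene_index
    indicator = np.zeros(hg.n_genes)
    indicator[[idx[g] for g in known]] = 1.0
    H = hg.incidence
    pos_counts = H.T @ indicator
    edge_degree = np.asarray(H.sum(axis=0)).ravel()
    if np.any(edge_degree == 0):
        raise AssertionError("hyperedge with zero degree survived construction")
    return HyperedgeWeights(pos_counts / edge_degree)


def hypergraph_laplacian(hg: Hypergraph, w: HyperedgeWeights) -> np.ndarray:
    """Normalized hypergraph Laplacian.

    Delta = I - D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}, with node degrees
    computed under the same weights ``w``.  Delta is symmetric, positive
    semidefinite, and annihilates D_v^{1/2} 1.
    """
    deg = degrees(hg, w)
    if np.any(deg.node_degree <= 0):
        bad = [hg.genes[i] for i in np.flatnonzero(deg.node_degree <= 0)[:5]]
        raise ValueError(
            "node(s) with zero weighted degree, e.g. "
            f"{bad}; restrict to the positive-degree sub-hypergraph or use identity weights"
        )
    H = hg.incidence.toarray()
    dv_isqrt = 1.0 / np.sqrt(deg.node_degree)
    de_inv = 1.0 / deg.edge_degree
    theta = (dv_isqrt[:, None] * H) @ (np.diag(w.w * de_inv)) @ (H.T * dv_isqrt[None, :])
    lap = np.eye(hg.n_genes) - theta
    return (lap + lap.T) / 2.0
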