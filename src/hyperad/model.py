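"""Two-stage hypergraph message-passing network for gene prioritization.

The architecture learns one embedding per gene and refines it through
stacked blocks, each of which (i) aggregates normalized node features into
hyperedge features (gene -> gene set) and (ii) aggregates hyperedge features
back into nodes (gene set -> gene), modulated by a disease-specific
hyperedge weight and a residual connection.  A softmax head converts the
final embeddings into a two-class risk score per gene.

Formally, with incidence H (N x M), node degrees d(v), hyperedge weights
w(e), and learnable matrices Theta:

    x_v^(0)    = relu(Theta0[v] + b0)                        (one-hot lookup)
    y_e^(l)    = relu( sum_{v in N(e)} x_v^(l) / d(v) . Theta_ve^(l) )
    x_v^(l+1)  = relu( sum_{e in E(v)} w(e) y_e^(l) . Theta_ev^(l) + x_v^(l) )
    Z          = softmax( x^(L) . Theta1 + b1 )

Training is transductive: the full hypergraph participates in every forward
pass, the cross-entropy loss touches only labeled training genes, and the
hyperedge weights are computed from the training-fold positives only.
Everything is plain numpy with analytically derived gradients and Adam, so
a fixed seed reproduces the loss trace and scores bit-for-bit on one device.

The classic hypergraph-convolution layer
``sigma(D_v^-1/2 H W D_e^-1 H^T D_v^-1/2 X Theta)`` is provided as
:func:`hgnn_layer` for architecture-comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import scipy.sparse as sp

from .hypergraph import (
    DegreeVectors,
    Hypergraph,
    HyperedgeWeights,
    LabelSet,
    compute_hyperedge_weights,
    degrees,
)

__all__ = [
    "ModelConfig",
    "ModelState",
    "RiskScores",
    "TrainResult",
    "init_state",
    "init_embeddings",
    "node_to_edge",
    "edge_to_node",
    "forward",
    "hgnn_layer",
    "train",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the network and its optimizer.

    ``weight_mode`` selects disease-specific hyperedge weights
    (``"ad_weighted"``) or the unweighted ablation (w(e) = 1 for all e).
    ``degree_norm_mode`` selects the d(v) used to normalize node messages:
    ``"unweighted"`` counts incident hyperedges (numerically safe — never
    zero for a constructed hypergraph), ``"weighted"`` uses
    sum_e w(e) H(v,e) and errors if any incident node degree vanishes.
    """

    embed_dim: int = 128
    n_blocks: int = 2
    activation: Literal["relu"] = "relu"
    learning_rate: float = 1e-3
    epochs: int = 200
    seed: int = 0
    weight_mode: Literal["ad_weighted", "unweighted"] = "ad_weighted"
    degree_norm_mode: Literal["unweighted", "weighted"] = "unweighted"

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")


@dataclass
class ModelState:
    """All learnable parameters.

    ``embed`` (N x d) plays the role of the one-hot input layer: because the
    input features are one-hot gene indicators, ``x . Theta0`` is exactly a
    row lookup into Theta0, so the N x N one-hot matrix is never formed.
    Per-block matrices are d x d, as required by the residual connection.
    """

    embed: np.ndarray          # N x d  (Theta0)
    b0: np.ndarray             # d
    theta_ve: list[np.ndarray]  # per block, d x d (node -> edge)
    theta_ev: list[np.ndarray]  # per block, d x d (edge -> node)
    theta_out: np.ndarray      # d x 2  (Theta1)
    b_out: np.ndarray          # 2

    def parameters(self) -> list[np.ndarray]:
        return [self.embed, self.b0, *self.theta_ve, *self.theta_ev, self.theta_out, self.b_out]


@dataclass(frozen=True)
class RiskScores:
    """Softmax output Z (N x 2); ``risk`` is the positive-class probability."""

    genes: tuple[str, ...]
    Z: np.ndarray

    @property
    def risk(self) -> np.ndarray:
        return self.Z[:, 1]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.genes, self.risk))


@dataclass(frozen=True)
class TrainResult:
    state: ModelState
    scores: RiskScores
    loss_trace: np.ndarray
    weights: HyperedgeWeights


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _xavier_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def init_state(n_genes: int, config: ModelConfig) -> ModelState:
    """Xavier-uniform matrices, zero biases, seeded by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    d = config.embed_dim
    return ModelState(
        embed=_xavier_uniform(rng, (n_genes, d)),
        b0=np.zeros(d),
        theta_ve=[_xavier_uniform(rng, (d, d)) for _ in range(config.n_blocks)],
        theta_ev=[_xavier_uniform(rng, (d, d)) for _ in range(config.n_blocks)],
        theta_out=_xavier_uniform(rng, (d, 2)),
        b_out=np.zeros(2),
    )


def init_embeddings(state: ModelState) -> np.ndarray:
    """Initial embeddings x^(0) = relu(Theta0 + b0) via one-hot row lookup."""
    return _relu(state.embed + state.b0)


def _operators(
    hg: Hypergraph, w: HyperedgeWeights, deg: DegreeVectors
) -> tuple[sp.spmatrix, sp.spmatrix]:
    """Sparse aggregation operators.

    A (M x N): row e holds H(v,e)/d(v) — node-to-edge normalized incidence.
    B (N x M): column e holds w(e) H(v,e) — weighted edge-to-node incidence.
    """
    if np.any(deg.node_degree <= 0):
        raise ValueError(
            "zero node degree under the requested weight mode; "
            "use degree_norm_mode='unweighted'"
        )
    H = hg.incidence
    A = (H.multiply(1.0 / deg.node_degree[:, None])).T.tocsr()
    B = H.multiply(w.w[None, :]).tocsr()
    return A, B


def node_to_edge(
    X: np.ndarray,
    hg: Hypergraph,
    deg: DegreeVectors,
    theta: np.ndarray,
    activation: Callable[[np.ndarray], np.ndarray] = _relu,
) -> np.ndarray:
    """Hyperedge features y_e = sigma( sum_{v in N(e)} x_v / d(v) . Theta )."""
    A, _ = _operators(hg, HyperedgeWeights.identity(hg.n_sets), deg)
    return activation((A @ X) @ theta)


def edge_to_node(
    Y: np.ndarray,
    X: np.ndarray,
    hg: Hypergraph,
    w: HyperedgeWeights,
    theta: np.ndarray,
    activation: Callable[[np.ndarray], np.ndarray] = _relu,
) -> np.ndarray:
    """Node update x_v' = sigma( sum_{e in E(v)} w(e) y_e . Theta + x_v ).

    The residual is added before the activation; a hyperedge with w(e) = 0
    contributes nothing, and a node in no hyperedge reduces to sigma(x_v).
    """
    B = hg.incidence.multiply(w.w[None, :]).tocsr()
    return activation((B @ Y) @ theta + X)


@dataclass
class _ForwardCache:
    X_pre: np.ndarray            # embed + b0 (pre-relu)
    X: list[np.ndarray]          # X^(0) .. X^(L) post-activation
    U: list[np.ndarray]          # A @ X per block
    P: list[np.ndarray]          # U @ theta_ve (pre-relu)
    Y: list[np.ndarray]          # relu(P)
    Q: list[np.ndarray]          # B @ Y
    R: list[np.ndarray]          # Q @ theta_ev + X (pre-relu)
    logits: np.ndarray
    Z: np.ndarray


def _forward(
    hg: Hypergraph,
    w: HyperedgeWeights,
    state: ModelState,
    config: ModelConfig,
    A: sp.spmatrix,
    B: sp.spmatrix,
) -> _ForwardCache:
    X_pre = state.embed + state.b0
    X = [_relu(X_pre)]
    U, P, Y, Q, R = [], [], [], [], []
    for block in range(config.n_blocks):
        u = A @ X[-1]
        p = u @ state.theta_ve[block]
        y = _relu(p)
        q = B @ y
        r = q @ state.theta_ev[block] + X[-1]
        x_next = _relu(r)
        if not np.all(np.isfinite(x_next)):
            raise FloatingPointError(f"non-finite activations in block {block}")
        U.append(u); P.append(p); Y.append(y); Q.append(q); R.append(r)
        X.append(x_next)
    logits = X[-1] @ state.theta_out + state.b_out
    logits_shift = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits_shift)
    Z = expl / expl.sum(axis=1, keepdims=True)
    return _ForwardCache(X_pre=X_pre, X=X, U=U, P=P, Y=Y, Q=Q, R=R, logits=logits, Z=Z)


def _resolve_weights(
    hg: Hypergraph, positives: set[str], config: ModelConfig
) -> tuple[HyperedgeWeights, DegreeVectors]:
    if config.weight_mode == "ad_weighted":
        w = compute_hyperedge_weights(hg, positives)
    else:
        w = HyperedgeWeights.identity(hg.n_sets)
    deg = degrees(hg, w if config.degree_norm_mode == "weighted" else None)
    return w, deg


def forward(
    hg: Hypergraph,
    w: HyperedgeWeights,
    state: ModelState,
    config: ModelConfig,
) -> RiskScores:
    """Full forward pass; rows of the returned Z sum to one."""
    deg = degrees(hg, w if config.degree_norm_mode == "weighted" else None)
    A, B = _operators(hg, w, deg)
    cache = _forward(hg, w, state, config, A, B)
    return RiskScores(genes=hg.genes, Z=cache.Z)


def hgnn_layer(
    X: np.ndarray,
    hg: Hypergraph,
    w: HyperedgeWeights,
    theta: np.ndarray,
    activation: Callable[[np.ndarray], np.ndarray] = _relu,
) -> np.ndarray:
    """Baseline hypergraph convolution:

    sigma( D_v^-1/2 H W D_e^-1 H^T D_v^-1/2 X Theta ), degrees under ``w``.
    """
    deg = degrees(hg, w)
    if np.any(deg.node_degree <= 0):
        raise ValueError("zero node degree; restrict to the positive-degree sub-hypergraph")
    H = hg.incidence
    dv_isqrt = 1.0 / np.sqrt(deg.node_degree)
    Xn = X * dv_isqrt[:, None]
    edge_feat = (H.T @ Xn) * (w.w / deg.edge_degree)[:, None]
    prop = (H @ edge_feat) * dv_isqrt[:, None]
    return activation(prop @ theta)


def _backward(
    cache: _ForwardCache,
    state: ModelState,
    config: ModelConfig,
    A: sp.spmatrix,
    B: sp.spmatrix,
    train_idx: np.ndarray,
    targets: np.ndarray,
) -> list[np.ndarray]:
    """Analytic gradients of the mean cross-entropy over ``train_idx``.

    Returns gradients in the order of :meth:`ModelState.parameters`.
    """
    n = len(train_idx)
    G = np.zeros_like(cache.Z)
    G[train_idx] = cache.Z[train_idx]
    G[train_idx, targets] -= 1.0
    G /= n

    d_theta_out = cache.X[-1].T @ G
    d_b_out = G.sum(axis=0)
    dX = G @ state.theta_out.T

    d_theta_ve = [np.empty(0)] * config.n_blocks
    d_theta_ev = [np.empty(0)] * config.n_blocks
    for block in reversed(range(config.n_blocks)):
        dR = dX * (cache.R[block] > 0)
        d_theta_ev[block] = cache.Q[block].T @ dR
        dQ = dR @ state.theta_ev[block].T
        dY = B.T @ dQ
        dP = dY * (cache.P[block] > 0)
        d_theta_ve[block] = cache.U[block].T @ dP
        dU = dP @ state.theta_ve[block].T
        dX = A.T @ dU + dR  # message path + residual path

    dX0_pre = dX * (cache.X_pre > 0)
    d_embed = dX0_pre
    d_b0 = dX0_pre.sum(axis=0)
    return [d_embed, d_b0, *d_theta_ve, *d_theta_ev, d_theta_out, d_b_out]


class _Adam:
    """Standard Adam on a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(
    hg: Hypergraph,
    labels: LabelSet,
    config: ModelConfig,
) -> TrainResult:
    """Fit the network transductively on the labeled genes.

    Hyperedge weights (in ``ad_weighted`` mode) come from ``labels.positives``
    only — in cross-validation these are the training-fold positives, so
    held-out labels never influence the fit.  Raises on non-finite loss with
    the epoch index.
    """
    labels = labels.restrict_to(hg.genes)
    if not labels.positives or not labels.negatives:
        raise ValueError("training requires at least one positive and one negative gene")
    w, deg = _resolve_weights(hg, set(labels.positives), config)
    A, B = _operators(hg, w, deg)

    idx = hg.gene_index
    pos_idx = sorted(idx[g] for g in labels.positives)
    neg_idx = sorted(idx[g] for g in labels.negatives)
    train_idx = np.array(pos_idx + neg_idx)
    targets = np.array([1] * len(pos_idx) + [0] * len(neg_idx))

    state = init_state(hg.n_genes, config)
    opt = _Adam(state.parameters(), config.learning_rate)
    trace = np.empty(config.epochs)
    for epoch in range(config.epochs):
        cache = _forward(hg, w, state, config, A, B)
        probs = cache.Z[train_idx, targets]
        loss = -np.mean(np.log(np.clip(probs, 1e-12, None)))
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        trace[epoch] = loss
        grads = _backward(cache, state, config, A, B, train_idx, targets)
        opt.step(grads)

    cache = _forward(hg, w, state, config, A, B)
    return TrainResult(
        state=state,
        scores=RiskScores(genes=hg.genes, Z=cache.Z),
        loss_trace=trace,
        weights=w,
    )
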