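import numpy as np
import pytest

from hyperad import (
    GeneSet,
    Hypergraph,
    HyperedgeWeights,
    LabelSet,
    ModelConfig,
    ModelState,
    build_hypergraph,
    degrees,
    edge_to_node,
    forward,
    hgnn_layer,
    init_embeddings,
    init_state,
    node_to_edge,
    train,
)
from hyperad.synthetic import PlantedHypergraphSpec, generate_planted_hypergraph
import scipy.sparse as sp

from .conftest import random_hypergraph
from . import oracles

SMALL_CFG = ModelConfig(embed_dim=8, n_blocks=2, epochs=40, seed=0)


def _random_state(rng, n_genes, config) -> ModelState:
    d = config.embed_dim
    return ModelState(
        embed=rng.normal(size=(n_genes, d)),
        b0=rng.normal(size=d),
        theta_ve=[rng.normal(size=(d, d)) for _ in range(config.n_blocks)],
        theta_ev=[rng.normal(size=(d, d)) for _ in range(config.n_blocks)],
        theta_out=rng.normal(size=(d, 2)),
        b_out=rng.normal(size=2),
    )


class TestInitEmbeddings:
    def test_relu_of_table_plus_bias(self):
        state = ModelState(
            embed=np.array([[-1.0, 2.0]]), b0=np.zeros(2),
            theta_ve=[], theta_ev=[], theta_out=np.zeros((2, 2)), b_out=np.zeros(2),
        )
        np.testing.assert_array_equal(init_embeddings(state), [[0.0, 2.0]])

    def test_zero_table_zero_bias(self):
        state = ModelState(
            embed=np.zeros((3, 4)), b0=np.zeros(4),
            theta_ve=[], theta_ev=[], theta_out=np.zeros((4, 2)), b_out=np.zeros(2),
        )
        assert not init_embeddings(state).any()

    def test_matches_explicit_onehot_product(self, rng):
        cfg = ModelConfig(embed_dim=6, n_blocks=1, seed=0)
        state = _random_state(rng, 5, cfg)
        onehot = np.eye(5)
        expected = np.maximum(onehot @ state.embed + state.b0, 0.0)
        np.testing.assert_allclose(init_embeddings(state), expected, atol=1e-12)


class TestMessagePassing:
    def test_singleton_hyperedge_identity(self):
        hg = build_hypergraph([GeneSet("e", "d", ("g1",))], min_size=1)
        deg = degrees(hg)
        X = np.array([[1.5, -2.0]])
        out = node_to_edge(X, hg, deg, np.eye(2), activation=lambda z: z)
        np.testing.assert_allclose(out, X)

    def test_pair_hyperedge_sums_members(self):
        hg = build_hypergraph([GeneSet("e", "d", ("g1", "g2"))])
        deg = degrees(hg)  # both degrees 1
        X = np.array([[1.0, 2.0], [3.0, -5.0]])
        out = node_to_edge(X, hg, deg, np.eye(2))
        np.testing.assert_allclose(out, np.maximum(X[0] + X[1], 0)[None, :])

    def test_zero_weight_message_vanishes(self):
        hg = build_hypergraph([GeneSet("e", "d", ("g1", "g2"))])
        X = np.array([[1.0, -1.0], [2.0, 3.0]])
        Y = np.array([[10.0, 10.0]])
        out = edge_to_node(Y, X, hg, HyperedgeWeights(np.zeros(1)), np.eye(2))
        np.testing.assert_allclose(out, np.maximum(X, 0))

    def test_isolated_node_keeps_relu_of_itself(self):
        # hand-built incidence with an all-zero row (node in no hyperedge)
        H = sp.csr_matrix(np.array([[1.0], [0.0]]))
        hg = Hypergraph(genes=("g1", "g2"), set_ids=("e",), incidence=H)
        X = np.array([[0.5, 0.5], [-1.0, 4.0]])
        Y = np.array([[1.0, 1.0]])
        out = edge_to_node(Y, X, hg, HyperedgeWeights(np.ones(1)), np.zeros((2, 2)))
        np.testing.assert_allclose(out[1], [0.0, 4.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_both_stages_match_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hg = random_hypergraph(rng)
        N, M, d = hg.n_genes, hg.n_sets, 4
        deg = degrees(hg)
        w = HyperedgeWeights(rng.uniform(0, 1, M))
        X = rng.normal(size=(N, d))
        theta = rng.normal(size=(d, d))
        H = hg.incidence.toarray()

        Y = node_to_edge(X, hg, deg, theta)
        expected_Y = np.zeros((M, d))
        for e in range(M):
            acc = sum(X[v] / deg.node_degree[v] for v in range(N) if H[v, e])
            expected_Y[e] = np.maximum(np.asarray(acc) @ theta, 0)
        np.testing.assert_allclose(Y, expected_Y, atol=1e-6)

        X2 = edge_to_node(Y, X, hg, w, theta)
        expected_X2 = np.zeros((N, d))
        for v in range(N):
            acc = np.zeros(d)
            for e in range(M):
                if H[v, e]:
                    acc += w.w[e] * Y[e]
            expected_X2[v] = np.maximum(acc @ theta + X[v], 0)
        np.testing.assert_allclose(X2, expected_X2, atol=1e-6)


class TestForward:
    def test_zero_parameters_give_uniform_scores(self, small_hypergraph):
        cfg = ModelConfig(embed_dim=3, n_blocks=2, seed=0)
        N = small_hypergraph.n_genes
        state = ModelState(
            embed=np.zeros((N, 3)), b0=np.zeros(3),
            theta_ve=[np.zeros((3, 3))] * 2, theta_ev=[np.zeros((3, 3))] * 2,
            theta_out=np.zeros((3, 2)), b_out=np.zeros(2),
        )
        Z = forward(small_hypergraph, HyperedgeWeights.identity(3), state, cfg).Z
        np.testing.assert_allclose(Z, 0.5)

    def test_rows_sum_to_one(self, rng):
        hg = random_hypergraph(rng)
        cfg = ModelConfig(embed_dim=8, n_blocks=2, seed=3)
        state = init_state(hg.n_genes, cfg)
        Z = forward(hg, HyperedgeWeights.identity(hg.n_sets), state, cfg).Z
        np.testing.assert_allclose(Z.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((Z >= 0) & (Z <= 1))

    def test_gene_permutation_equivariance(self, rng):
        hg = random_hypergraph(rng, 12, 6)
        cfg = ModelConfig(embed_dim=5, n_blocks=2, seed=1)
        state = _random_state(np.random.default_rng(7), hg.n_genes, cfg)
        w = HyperedgeWeights(np.random.default_rng(8).uniform(0, 1, hg.n_sets))
        Z = forward(hg, w, state, cfg).Z

        perm = np.random.default_rng(9).permutation(hg.n_genes)
        hg_p = Hypergraph(
            genes=tuple(hg.genes[i] for i in perm),
            set_ids=hg.set_ids,
            incidence=sp.csr_matrix(hg.incidence.toarray()[perm]),
            collection_tags=hg.collection_tags,
        )
        state_p = ModelState(
            embed=state.embed[perm], b0=state.b0,
            theta_ve=state.theta_ve, theta_ev=state.theta_ev,
            theta_out=state.theta_out, b_out=state.b_out,
        )
        Z_p = forward(hg_p, w, state_p, cfg).Z
        np.testing.assert_allclose(Z_p, Z[perm], atol=1e-10)

    def test_hyperedge_relabeling_invariance(self, rng):
        hg = random_hypergraph(rng, 12, 6)
        cfg = ModelConfig(embed_dim=5, n_blocks=1, seed=1)
        state = _random_state(np.random.default_rng(4), hg.n_genes, cfg)
        w = HyperedgeWeights(np.ones(hg.n_sets) * 0.5)
        Z = forward(hg, w, state, cfg).Z
        renamed = Hypergraph(
            genes=hg.genes,
            set_ids=tuple(f"renamed_{s}" for s in hg.set_ids),
            incidence=hg.incidence,
            collection_tags=hg.collection_tags,
        )
        np.testing.assert_allclose(forward(renamed, w, state, cfg).Z, Z, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_onehot_loop_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        hg = random_hypergraph(rng, 10, 5)
        cfg = ModelConfig(embed_dim=4, n_blocks=2, seed=seed)
        state = _random_state(rng, hg.n_genes, cfg)
        w = HyperedgeWeights(rng.uniform(0, 1, hg.n_sets))
        Z = forward(hg, w, state, cfg).Z
        expected = oracles.forward_onehot(
            hg.incidence.toarray(), w.w, degrees(hg).node_degree,
            state.embed, state.b0, state.theta_ve, state.theta_ev,
            state.theta_out, state.b_out,
        )
        np.testing.assert_allclose(Z, expected, atol=1e-6)

    def test_zero_weight_hyperedge_is_inert(self, rng):
        hg = random_hypergraph(rng, 12, 6)
        w = np.zeros(hg.n_sets)
        w[0] = 1.0  # only hyperedge 0 carries messages
        d = 4
        local = np.random.default_rng(11)
        X = local.normal(size=(hg.n_genes, d))
        theta = local.normal(size=(d, d))
        Y = local.normal(size=(hg.n_sets, d))
        base = edge_to_node(Y, X, hg, HyperedgeWeights(w), theta)
        Y_perturbed = Y.copy()
        Y_perturbed[1:] += local.normal(size=(hg.n_sets - 1, d)) * 100
        perturbed = edge_to_node(Y_perturbed, X, hg, HyperedgeWeights(w), theta)
        np.testing.assert_allclose(base, perturbed, atol=1e-12)


class TestHgnnLayer:
    def test_pair_hyperedge_averages_members(self):
        hg = build_hypergraph([GeneSet("e", "d", ("g1", "g2"))])
        X = np.array([[2.0, 4.0], [6.0, -2.0]])
        out = hgnn_layer(X, hg, HyperedgeWeights.identity(1), np.eye(2),
                         activation=lambda z: z)
        # Dv = De = identity-free: both nodes degree 1, delta = 2 -> mean
        np.testing.assert_allclose(out, np.tile((X[0] + X[1]) / 2, (2, 1)))

    def test_zero_weights_annihilate(self, small_hypergraph):
        with pytest.raises(ValueError):
            # all-zero W zeroes node degrees, which the layer must reject
            hgnn_layer(np.ones((5, 2)), small_hypergraph,
                       HyperedgeWeights(np.zeros(3)), np.eye(2))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_chain_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        hg = random_hypergraph(rng)
        w = HyperedgeWeights(rng.uniform(0.1, 1.0, hg.n_sets))
        X = rng.normal(size=(hg.n_genes, 3))
        theta = rng.normal(size=(3, 3))
        out = hgnn_layer(X, hg, w, theta)
        expected = oracles.hgnn_layer_dense(hg.incidence.toarray(), w.w, X, theta)
        np.testing.assert_allclose(out, expected, atol=1e-6)


@pytest.fixture(scope="module")
def tiny_planted():
    spec = PlantedHypergraphSpec(
        n_genes=80, n_disease_genes=12, n_relevant_sets=15,
        n_background_sets=30, set_size_range=(4, 10), n_negatives=30, seed=5,
    )
    return generate_planted_hypergraph(spec)


class TestTraining:
    def test_loss_decreases(self, tiny_planted):
        hg, labels, _ = tiny_planted
        result = train(hg, labels, SMALL_CFG)
        assert result.loss_trace[-1] < result.loss_trace[0]

    def test_same_seed_bitwise_identical(self, tiny_planted):
        hg, labels, _ = tiny_planted
        r1 = train(hg, labels, SMALL_CFG)
        r2 = train(hg, labels, SMALL_CFG)
        np.testing.assert_array_equal(r1.loss_trace, r2.loss_trace)
        np.testing.assert_array_equal(r1.scores.Z, r2.scores.Z)

    def test_held_out_labels_cannot_leak(self, tiny_planted):
        """Training sees only its LabelSet: the ground-truth status of any
        gene outside it (the held-out fold) has no channel into the fit —
        weights and loss are built from the training labels alone."""
        hg, labels, disease = tiny_planted
        held_out = sorted(set(disease) & set(hg.genes) - labels.positives)
        assert held_out, "fixture must hold out some disease genes"
        r1 = train(hg, labels, SMALL_CFG)
        # hypothetically flip held-out genes between classes; the training
        # call receives the identical LabelSet either way
        r2 = train(hg, LabelSet(labels.positives, labels.negatives), SMALL_CFG)
        np.testing.assert_array_equal(r1.scores.Z, r2.scores.Z)
        # and the hyperedge weights depend only on training positives
        np.testing.assert_array_equal(r1.weights.w, r2.weights.w)

    def test_single_class_labels_rejected(self, tiny_planted):
        hg, labels, _ = tiny_planted
        with pytest.raises(ValueError):
            train(hg, LabelSet(labels.positives, frozenset()), SMALL_CFG)

    def test_recovers_planted_module(self, tiny_planted):
        hg, labels, disease = tiny_planted
        result = train(hg, labels, ModelConfig(embed_dim=32, epochs=150, seed=5))
        idx = hg.gene_index
        held = [g for g in sorted(disease) if g in idx and g not in labels.positives]
        rest = [g for g in hg.genes if g not in disease and g not in labels.negatives]
        scores = result.scores.risk
        held_mean = np.mean([scores[idx[g]] for g in held])
        rest_mean = np.mean([scores[idx[g]] for g in rest])
        assert held_mean > rest_mean
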