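"""Relational GCN layer vs dense oracles, decoders, and encoder training."""

import numpy as np
import pytest

import gcsenet as g
from oracles import dense_layer_oracle
from gcsenet.autodiff import Tensor
from gcsenet.gcn import (
    RELATIONS,
    GCNError,
    decode_all,
    gcn_layer,
    relation_adjacencies,
    self_coefficients,
)

NODE_TYPES = ("disease", "gene", "mirna")


def _layer(net, c_in_map, c_out, seed=0, identity=False):
    rng = np.random.default_rng(seed)
    layer = {"rel": {}, "self": {}}
    for name, (_dst, src) in RELATIONS.items():
        w = np.eye(c_out) if identity else rng.normal(size=(c_out, c_in_map[src]))
        layer["rel"][name] = Tensor.param(w)
    for t in NODE_TYPES:
        w = np.eye(c_out) if identity else rng.normal(size=(c_out, c_in_map[t]))
        layer["self"][t] = Tensor.param(w)
    return layer


def test_single_dd_edge_layer_matches_hand_computation():
    # one disease-disease edge of weight 1: self-inclusive degrees are 2,
    # so h_A = (z_A + z_B) / 2 before ReLU under shared identity weights
    net = g.HetNet(("A", "B"), ("g",), ("m",),
                   {"dd": frozenset({("A", "B", 1.0)}), "mm": frozenset(),
                    "gg": frozenset(), "dg": frozenset({("A", "g", 1.0)}),
                    "mg": frozenset({("m", "g", 1.0)})})
    z = {"disease": np.array([[1.0, 2.0], [3.0, 4.0]]),
         "gene": np.zeros((1, 2)), "mirna": np.zeros((1, 2))}
    layer = _layer(net, {t: 2 for t in NODE_TYPES}, 2, identity=True)
    out = gcn_layer(z, net, layer)
    np.testing.assert_allclose(out["disease"][0], (z["disease"][0] + z["disease"][1]) / 2,
                               atol=1e-12)
    np.testing.assert_allclose(out["disease"][1], (z["disease"][0] + z["disease"][1]) / 2,
                               atol=1e-12)


def test_mixed_type_layer_equals_dense_oracle(tiny_net):
    rng = np.random.default_rng(11)
    c = 5
    z = {"disease": rng.normal(size=(len(tiny_net.diseases), c)),
         "gene": rng.normal(size=(len(tiny_net.genes), c)),
         "mirna": rng.normal(size=(len(tiny_net.mirnas), c))}
    layer = _layer(tiny_net, {t: c for t in NODE_TYPES}, 4, seed=2)
    got = gcn_layer(z, tiny_net, layer)
    want = dense_layer_oracle(tiny_net, z, layer)
    for t in NODE_TYPES:
        np.testing.assert_allclose(got[t], want[t], atol=1e-6)


def test_homogeneous_reduction_to_symmetric_normalised_form():
    # single-type graph with unit weights and shared W: the layer must equal
    # ReLU(D^-1/2 (A + I) D^-1/2 H W) computed densely
    rng = np.random.default_rng(3)
    n, c = 6, 4
    diseases = tuple(f"d{i}" for i in range(n))
    pairs = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5), (1, 4)]
    dd = frozenset((f"d{i}", f"d{j}", 1.0) for i, j in pairs)
    net = g.HetNet(diseases, ("g",), ("m",),
                   {"dd": dd, "mm": frozenset(), "gg": frozenset(),
                    "dg": frozenset({("d0", "g", 1.0)}), "mg": frozenset({("m", "g", 1.0)})})
    w = rng.normal(size=(c, c))
    layer = {"rel": {name: Tensor.param(w.copy()) for name in RELATIONS},
             "self": {t: Tensor.param(w.copy()) for t in NODE_TYPES}}
    h = rng.normal(size=(n, c))
    # zero out bipartite influence by zeroing gene/mirna features
    z = {"disease": h, "gene": np.zeros((1, c)), "mirna": np.zeros((1, c))}
    got = gcn_layer(z, net, layer)["disease"]
    a = np.zeros((n, n))
    for i, j in pairs:
        a[i, j] = a[j, i] = 1.0
    a_tilde = a + np.eye(n)
    d_inv = np.diag(1.0 / np.sqrt(a_tilde.sum(axis=1)))
    want = np.maximum(d_inv @ a_tilde @ d_inv @ h @ w.T, 0.0)
    # d0 receives an extra dg message; exclude it from the comparison
    np.testing.assert_allclose(got[1:], want[1:], atol=1e-6)


def test_zero_params_give_zero_embeddings(tiny_net):
    params = g.init_params(tiny_net, c=4, n_layers=3, seed=0)
    for t in params.all_tensors():
        t.data[:] = 0.0
    emb = g.encode(tiny_net, params)
    assert not emb.z_d.any() and not emb.z_g.any() and not emb.z_m.any()


def test_init_is_seed_deterministic(tiny_net):
    p1 = g.init_params(tiny_net, c=8, seed=5)
    p2 = g.init_params(tiny_net, c=8, seed=5)
    for a, b in zip(p1.all_tensors(), p2.all_tensors()):
        np.testing.assert_array_equal(a.data, b.data)
    p3 = g.init_params(tiny_net, c=8, seed=6)
    assert any((a.data != b.data).any() for a, b in zip(p1.all_tensors(), p3.all_tensors()))


def test_decode_edge_closed_forms():
    e = np.zeros(4)
    e[0] = 1.0
    assert g.decode_edge(e, e, np.eye(4)) == pytest.approx(1 / (1 + np.exp(-1.0)))
    # orthogonal to W z_b -> sigma(0) = 0.5
    z_a = np.array([0.0, 1.0, 0.0, 0.0])
    assert g.decode_edge(z_a, e, np.eye(4)) == 0.5
    with pytest.raises(GCNError):
        g.decode_edge(np.ones(3), np.ones(4), np.eye(4))


def test_decode_edge_transpose_symmetry():
    rng = np.random.default_rng(0)
    z_a, z_b = rng.normal(size=4), rng.normal(size=4)
    w = rng.normal(size=(4, 4))
    assert g.decode_edge(z_a, z_b, w) == pytest.approx(g.decode_edge(z_b, z_a, w.T), rel=1e-12)
    assert 0.0 < g.decode_edge(z_a * 5, z_b * 5, w) < 1.0


def test_parameters_shared_per_relation_not_per_node(tiny_net):
    params = g.init_params(tiny_net, c=4, seed=0)
    for layer in params.layers:
        assert set(layer["rel"]) == set(RELATIONS)
        assert set(layer["self"]) == set(NODE_TYPES)
        # weight shapes depend on relation/type only, never on node count
        # beyond the input feature dimension
        for name, t in layer["rel"].items():
            assert t.data.shape[0] == 4


def test_permuting_registry_permutes_embeddings():
    base = g.generate_hetnet(6, 10, 7, latent_dim=3, seed=2, knn_k=2, label_fraction=0.2)
    net = base.hetnet
    perm_d = tuple(reversed(net.diseases))
    net2 = g.HetNet(perm_d, net.genes, net.mirnas, net.edges)
    params = g.init_params(net, c=4, seed=1)
    emb1 = g.encode(net, params)
    # adjacency rows permute with the registry, parameters are per-relation:
    # re-encoding with a permuted registry must permute embedding rows the
    # same way, except the first-layer one-hot input follows registry order,
    # so permute the layer-0 input columns accordingly
    params2 = g.init_params(net2, c=4, seed=1)
    order = [net2.diseases.index(d) for d in net.diseases]
    col_of = np.argsort(order)  # net2 registry position -> net registry position
    for k in range(3):
        for name, (_dst, src) in RELATIONS.items():
            w = params.layers[k]["rel"][name].data
            if k == 0 and src == "disease":
                w = w[:, col_of]
            params2.layers[k]["rel"][name].data[:] = w
        for t in NODE_TYPES:
            w = params.layers[k]["self"][t].data
            if k == 0 and t == "disease":
                w = w[:, col_of]
            params2.layers[k]["self"][t].data[:] = w
    emb2 = g.encode(net2, params2)
    for d in net.diseases:
        np.testing.assert_allclose(emb1.vec(d), emb2.vec(d), atol=1e-10)


def test_training_is_seed_deterministic(tiny_net):
    cfg = g.RunConfig(embed_dim=8, encoder_epochs=5, seed=3)
    p1, t1 = g.train_encoder(tiny_net, cfg)
    p2, t2 = g.train_encoder(tiny_net, cfg)
    assert abs(t1[-1] - t2[-1]) < 1e-6  # seeded determinism
    for a, b in zip(p1.all_tensors(), p2.all_tensors()):
        np.testing.assert_array_equal(a.data, b.data)


def test_loss_trace_non_increasing_early(study_ds):
    cfg = g.RunConfig(encoder_epochs=5, seed=42)
    _, trace = g.train_encoder(study_ds.hetnet, cfg)
    assert all(trace[i + 1] <= trace[i] for i in range(4)), trace


def test_zero_lr_leaves_parameters_at_init(tiny_net):
    cfg = g.RunConfig(embed_dim=4, encoder_epochs=2, seed=9, lr=0.0, l2=0.0)
    params, _ = g.train_encoder(tiny_net, cfg)
    init = g.init_params(tiny_net, 4, cfg.gcn_layers, cfg.seed)
    for a, b in zip(params.all_tensors(), init.all_tensors()):
        np.testing.assert_array_equal(a.data, b.data)


def test_encoder_requires_bipartite_edges(tiny_net):
    empty = g.HetNet(tiny_net.diseases, tiny_net.genes, tiny_net.mirnas,
                     {**dict(tiny_net.edges), "mg": frozenset()})
    with pytest.raises(GCNError):
        g.train_encoder(empty, g.RunConfig(embed_dim=4, encoder_epochs=1))


def test_decode_all_matches_scalar_decode(tiny_encoder, tiny_net):
    params, _, emb = tiny_encoder
    p = decode_all(emb, params.decoders["dg"].data, "disease")
    for i, d in enumerate(tiny_net.diseases[:3]):
        for j, gene in enumerate(tiny_net.genes[:3]):
            assert p[i, j] == pytest.approx(
                g.decode_edge(emb.vec(d), emb.vec(gene), params.decoders["dg"].data),
                rel=1e-10,
            )
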