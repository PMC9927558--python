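"""Equivariance, oracle equivalence and reproducibility of the network."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import permute_graph, rebuild_transformed
from grank import _autodiff as ad
from grank._autodiff import Tensor
from grank.gvp_model import (GraphBatch, GVPModel, GVPSpec, ModelConfig,
                             ModelState, gvp_forward, init_gvp_params,
                             layer_norm_tuple, score_graph)


def random_rotations(n, seed, include_reflections=False):
    rng = np.random.default_rng(seed)
    mats = Rotation.random(n, rng=rng).as_matrix()
    if include_reflections:
        mats[::2] *= -1.0  # improper transforms
    return mats


@pytest.fixture(scope="module")
def gvp():
    spec = GVPSpec("g", (7, 4), (6, 3))
    params = init_gvp_params(spec, np.random.default_rng(0))
    return spec, params


def test_gvp_vector_equivariance_and_scalar_invariance(gvp):
    spec, params = gvp
    rng = np.random.default_rng(1)
    s = Tensor(rng.normal(size=(5, 7)))
    V = rng.normal(size=(5, 4, 3))
    s0, V0 = gvp_forward(params, spec, s, Tensor(V))
    worst_s, worst_v = 0.0, 0.0
    for R in random_rotations(100, seed=2):
        s1, V1 = gvp_forward(params, spec, s, Tensor(V @ R.T))
        worst_s = max(worst_s, np.abs(s1.data - s0.data).max())
        worst_v = max(worst_v, np.abs(V1.data - V0.data @ R.T).max())
    assert worst_s <= 1e-5
    assert worst_v <= 1e-5


def test_gvp_zero_vectors_reduce_to_scalar_path(gvp):
    spec, params = gvp
    rng = np.random.default_rng(3)
    s = rng.normal(size=(4, 7))
    V = np.zeros((4, 4, 3))
    s_out, V_out = gvp_forward(params, spec, Tensor(s), Tensor(V))
    # zero vectors have zero norms: scalars equal the pure scalar slice of Wm
    Wm = params["g.Wm"].data
    manual = np.maximum(s @ Wm[:7] + params["g.Wm_b"].data, 0.0)
    np.testing.assert_allclose(s_out.data, manual, atol=1e-12)
    np.testing.assert_allclose(V_out.data, 0.0, atol=1e-12)


def test_gvp_dim_mismatch_raises(gvp):
    spec, params = gvp
    with pytest.raises(ValueError):
        gvp_forward(params, spec, Tensor(np.zeros((2, 3))),
                    Tensor(np.zeros((2, 4, 3))))


def test_gradients_match_finite_differences(gvp):
    spec, params = gvp
    rng = np.random.default_rng(4)
    s = Tensor(rng.normal(size=(3, 7)))
    V = Tensor(rng.normal(size=(3, 4, 3)))

    def loss_value():
        so, Vo = gvp_forward(params, spec, s, V)
        n = ad.safe_norm(Vo, axis=2)
        return ad.tsum(ad.add(ad.tsum(ad.mul(so, so)), ad.tsum(ad.mul(n, n))))

    loss = loss_value()
    for p in params.values():
        p.zero_grad()
    loss.backward()
    eps = 1e-6
    for name in ("g.Wh", "g.Wm", "g.Wm_b", "g.Wg"):
        p = params[name]
        flat_idx = np.unravel_index(np.argmax(np.abs(p.grad)), p.data.shape)
        orig = p.data[flat_idx]
        p.data[flat_idx] = orig + eps
        up = loss_value().data
        p.data[flat_idx] = orig - eps
        down = loss_value().data
        p.data[flat_idx] = orig
        numeric = (up - down) / (2 * eps)
        assert p.grad[flat_idx] == pytest.approx(float(numeric), rel=1e-4)


def _random_graph(rng, n_nodes, cfg):
    from conftest import random_cloud_complex
    from grank.interface_graph import build_graph
    cplx = random_cloud_complex(rng, n_a=max(n_nodes // 2, 1),
                                n_b=max(n_nodes - n_nodes // 2, 1), box=8.0)
    return build_graph(cplx, n_rbf=cfg.n_rbf)


def _loop_propagate(model, block, s, V, e_s, e_V, edges, n_nodes):
    """Naive per-node reference for the graph propagation layer."""
    cfg = model.config
    prefixes = [f"block{block}.msg{k}" for k in range(cfg.n_message_gvps)]
    new_s = np.empty_like(s)
    new_V = np.empty_like(V)
    for i in range(n_nodes):
        incoming = [e for e in range(len(edges)) if edges[e][1] == i]
        hs, hV = s[i:i + 1].copy(), V[i:i + 1].copy()
        if incoming:
            acc_s, acc_V = 0.0, 0.0
            for e in incoming:
                j = edges[e][0]
                ms = Tensor(np.concatenate([s[j:j + 1], e_s[e:e + 1]], axis=1))
                mV = Tensor(np.concatenate([V[j:j + 1], e_V[e:e + 1]], axis=1))
                for p in prefixes:
                    ms, mV = gvp_forward(model.params, model.specs[p], ms, mV)
                acc_s = acc_s + ms.data
                acc_V = acc_V + mV.data
            hs = hs + acc_s / len(incoming)
            hV = hV + acc_V / len(incoming)
        so, Vo = layer_norm_tuple(model.params, f"block{block}.norm0",
                                  Tensor(hs), Tensor(hV))
        new_s[i] = so.data
        new_V[i] = Vo.data
    return new_s, new_V


def _loop_feed_forward(model, block, s, V):
    cfg = model.config
    prefixes = [f"block{block}.ff{k}" for k in range(cfg.n_ff_gvps)]
    new_s = np.empty_like(s)
    new_V = np.empty_like(V)
    for i in range(len(s)):
        fs, fV = Tensor(s[i:i + 1]), Tensor(V[i:i + 1])
        for p in prefixes:
            fs, fV = gvp_forward(model.params, model.specs[p], fs, fV)
        so, Vo = layer_norm_tuple(model.params, f"block{block}.norm1",
                                  Tensor(s[i:i + 1] + fs.data),
                                  Tensor(V[i:i + 1] + fV.data))
        new_s[i] = so.data
        new_V[i] = Vo.data
    return new_s, new_V


def _embed(model, graph):
    s, V = gvp_forward(model.params, model.specs["node_embed"],
                       Tensor(graph.node_scalar), Tensor(graph.node_vector))
    e_s, e_V = gvp_forward(model.params, model.specs["edge_embed"],
                           Tensor(graph.edge_scalar),
                           Tensor(graph.edge_vector))
    return s, V, e_s, e_V


@pytest.mark.parametrize("seed", range(6))
def test_propagate_matches_per_node_loop(small_model, seed):
    rng = np.random.default_rng(200 + seed)
    g = _random_graph(rng, n_nodes=12, cfg=small_model.config)
    s, V, e_s, e_V = _embed(small_model, g)
    got_s, got_V = small_model.propagate(0, s, V, e_s, e_V, g.edges,
                                         g.n_nodes)
    ref_s, ref_V = _loop_propagate(small_model, 0, s.data, V.data,
                                   e_s.data, e_V.data, g.edges, g.n_nodes)
    np.testing.assert_allclose(got_s.data, ref_s, atol=1e-6)
    np.testing.assert_allclose(got_V.data, ref_V, atol=1e-6)


@pytest.mark.parametrize("seed", range(3))
def test_feed_forward_matches_per_node_loop(small_model, seed):
    rng = np.random.default_rng(300 + seed)
    g = _random_graph(rng, n_nodes=10, cfg=small_model.config)
    s, V, e_s, e_V = _embed(small_model, g)
    s, V = small_model.propagate(0, s, V, e_s, e_V, g.edges, g.n_nodes)
    got_s, got_V = small_model.feed_forward(0, s, V)
    ref_s, ref_V = _loop_feed_forward(small_model, 0, s.data, V.data)
    np.testing.assert_allclose(got_s.data, ref_s, atol=1e-6)
    np.testing.assert_allclose(got_V.data, ref_V, atol=1e-6)


def test_propagate_isolated_node_is_layernorm_only(small_model):
    # node 2 sits beyond the edge cutoff: its update must be LN(h) alone
    from conftest import cloud_complex
    from grank.interface_graph import build_graph
    cplx = cloud_complex([[0, 0, 0], [2, 0, 0]], [[3.5, 0, 0], [40, 0, 0]])
    g = build_graph(cplx, n_rbf=small_model.config.n_rbf)
    assert not np.any(g.edges == 3)  # node 3 isolated
    s, V, e_s, e_V = _embed(small_model, g)
    got_s, got_V = small_model.propagate(0, s, V, e_s, e_V, g.edges,
                                         g.n_nodes)
    ln_s, ln_V = layer_norm_tuple(small_model.params, "block0.norm0",
                                  Tensor(s.data[3:4]), Tensor(V.data[3:4]))
    np.testing.assert_allclose(got_s.data[3], ln_s.data[0], atol=1e-12)
    np.testing.assert_allclose(got_V.data[3], ln_V.data[0], atol=1e-12)


def test_disconnected_copies_update_identically(small_model):
    from grank.interface_graph import InterfaceGraph
    rng = np.random.default_rng(17)
    g = _random_graph(rng, n_nodes=8, cfg=small_model.config)
    n = g.n_nodes
    doubled = InterfaceGraph(
        node_coords=np.vstack([g.node_coords, g.node_coords + 500.0]),
        node_scalar=np.vstack([g.node_scalar] * 2),
        node_vector=np.vstack([g.node_vector] * 2),
        edges=np.vstack([g.edges, g.edges + n]),
        edge_scalar=np.vstack([g.edge_scalar] * 2),
        edge_vector=np.vstack([g.edge_vector] * 2),
    )
    s, V, e_s, e_V = _embed(small_model, doubled)
    got_s, _ = small_model.propagate(0, s, V, e_s, e_V, doubled.edges, 2 * n)
    np.testing.assert_allclose(got_s.data[:n], got_s.data[n:], atol=1e-12)


def test_score_invariant_under_rigid_transforms(small_model, small_interface,
                                                small_graph):
    base = score_graph(small_graph, small_model)
    worst = 0.0
    for k, R in enumerate(random_rotations(20, seed=5,
                                           include_reflections=True)):
        t = np.random.default_rng(k).uniform(-50, 50, 3)
        g = rebuild_transformed(small_interface, R, t,
                                n_rbf=small_model.config.n_rbf)
        worst = max(worst, abs(score_graph(g, small_model) - base))
    assert worst <= 1e-4


def test_score_invariant_under_node_permutation(small_model, small_graph):
    base = score_graph(small_graph, small_model)
    rng = np.random.default_rng(9)
    for _ in range(3):
        perm = rng.permutation(small_graph.n_nodes)
        assert score_graph(permute_graph(small_graph, perm),
                           small_model) == pytest.approx(base, abs=1e-6)


def test_single_node_score_equals_hand_composed_forward(small_model):
    from grank.interface_graph import InterfaceGraph
    g = InterfaceGraph(
        node_coords=np.zeros((1, 3)),
        node_scalar=np.array([[0.0, 1.0, 0.0, 0.0, 0.0]]),
        node_vector=np.zeros((1, 0, 3)),
        edges=np.zeros((0, 2), dtype=np.intp),
        edge_scalar=np.zeros((0, small_model.config.n_rbf)),
        edge_vector=np.zeros((0, 1, 3)),
    )
    m = small_model
    s, V = gvp_forward(m.params, m.specs["node_embed"],
                       Tensor(g.node_scalar), Tensor(g.node_vector))
    for b in range(m.config.n_blocks):
        s, V = layer_norm_tuple(m.params, f"block{b}.norm0", s, V)
        fs, fV = s, V
        for k in range(m.config.n_ff_gvps):
            fs, fV = gvp_forward(m.params, m.specs[f"block{b}.ff{k}"], fs, fV)
        s, V = layer_norm_tuple(m.params, f"block{b}.norm1",
                                ad.add(s, fs), ad.add(V, fV))
    s, _ = gvp_forward(m.params, m.specs["out_gvp"], s, V)
    h = np.maximum(s.data @ m.params["dense0.W"].data
                   + m.params["dense0.b"].data, 0)
    expected = float((h @ m.params["dense1.W"].data
                      + m.params["dense1.b"].data)[0, 0])
    assert score_graph(g, m) == pytest.approx(expected, abs=1e-9)


def test_batch_scores_independent_of_batch_composition(small_model,
                                                       small_graph):
    rng = np.random.default_rng(33)
    others = [_random_graph(rng, 10, small_model.config) for _ in range(3)]
    alone = score_graph(small_graph, small_model)
    batch = GraphBatch.from_graphs(others[:1] + [small_graph] + others[1:])
    with ad.no_grad():
        batched = small_model.forward_batch(batch).data[1]
    assert batched == pytest.approx(alone, abs=1e-6)


def test_state_roundtrip_is_bit_exact(tmp_path, small_model, small_graph):
    base = score_graph(small_graph, small_model)
    path = tmp_path / "state.npz"
    small_model.state().save(path)
    reloaded = GVPModel.from_state(ModelState.load(path))
    for k, v in small_model.params.items():
        np.testing.assert_array_equal(reloaded.params[k].data, v.data)
    assert score_graph(small_graph, reloaded) == base  # bit reproducible


def test_same_seed_same_init_different_seed_different():
    cfg = ModelConfig(node_dims=(8, 2), edge_dims=(4, 1), n_blocks=1, seed=1)
    a, b = GVPModel(cfg), GVPModel(cfg)
    for k in a.params:
        np.testing.assert_array_equal(a.params[k].data, b.params[k].data)
    c = GVPModel(ModelConfig(node_dims=(8, 2), edge_dims=(4, 1), n_blocks=1,
                             seed=2))
    assert any(not np.array_equal(a.params[k].data, c.params[k].data)
               for k in a.params)


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(n_blocks=0)
    with pytest.raises(ValueError):
        ModelConfig(dropout_rate=1.0)
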