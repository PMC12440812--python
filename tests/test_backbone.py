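"""Envelope, radial basis, edge embeddings, interaction layers, readout."""

import numpy as np
import pytest

from celliq import autodiff as ad
from celliq.backbone import (BackboneConfig, EdgeLatents, EnvelopePolynomial,
                             ScalarBackbone, bessel_ad, edge_environment,
                             envelope, envelope_ad)
from celliq.nn import ParamStore
from celliq.systems import AtomicSystem, build_neighbor_list

from conftest import random_open_system


def _backbone(species=(11, 17), seed=0, **kw):
    cfg = BackboneConfig(species=species, seed=seed, **kw)
    store = ParamStore()
    bb = ScalarBackbone(cfg, store, np.random.default_rng(seed))
    return bb, store, cfg


def _edge_tensors(system, cutoff):
    nbrs = build_neighbor_list(system, cutoff)
    r = ad.constant(nbrs.distances)
    return nbrs, r


# ---------------------------------------------------------------------------
# envelope and basis
# ---------------------------------------------------------------------------

def test_envelope_boundary_values():
    env = EnvelopePolynomial(p=6, cutoff=4.0)
    assert envelope(0.0, env) == 1.0
    assert envelope(4.0, env) == 0.0
    assert envelope(5.0, env) == 0.0


def test_envelope_midpoint_value_p6():
    # exact rational value of the polynomial at u = 1/2, p = 6:
    # 1 - 28 (1/2)^6 + 48 (1/2)^7 - 21 (1/2)^8 = 219/256
    env = EnvelopePolynomial(p=6, cutoff=2.0)
    assert np.isclose(envelope(1.0, env), 219.0 / 256.0, rtol=1e-15)


def test_envelope_first_derivative_vanishes_at_cutoff():
    env = EnvelopePolynomial(p=6, cutoff=3.0)
    h = 1e-6
    assert abs(envelope(3.0 - h, env) / h) < 1e-4   # slope -> 0 at r_c


def test_envelope_rejects_negative_distance():
    with pytest.raises(ValueError):
        envelope(-0.1, EnvelopePolynomial(p=6, cutoff=3.0))


def test_envelope_ad_matches_numpy_inside_cutoff(rng):
    env = EnvelopePolynomial(p=6, cutoff=4.0)
    r = rng.uniform(0.1, 3.9, 17)
    assert np.allclose(envelope_ad(ad.constant(r), env).data,
                       envelope(r, env), rtol=1e-14)


def test_bessel_features_vanish_toward_cutoff():
    from celliq.backbone import RadialBasis
    basis = RadialBasis(count=8, cutoff=4.0)
    vals = bessel_ad(ad.constant(np.array([3.999999])), basis).data
    assert np.max(np.abs(vals)) < 1e-4


# ---------------------------------------------------------------------------
# embeddings and layers
# ---------------------------------------------------------------------------

def test_identical_local_geometry_gives_identical_edge_features():
    # two A-B pairs with the same bond length, far apart
    s = AtomicSystem(species=[11, 17, 11, 17],
                     positions=[[0, 0, 0], [2.0, 0, 0],
                                [50, 0, 0], [52.0, 0, 0]])
    bb, _, cfg = _backbone()
    nbrs, r = _edge_tensors(s, cfg.cutoff)
    x0 = bb.embed_edges(s, nbrs, r)
    # edges: (0,1),(1,0),(2,3),(3,2)
    assert np.allclose(x0.features.data[0], x0.features.data[2], atol=1e-12)
    assert np.allclose(x0.features.data[1], x0.features.data[3], atol=1e-12)


def test_unknown_species_error_names_element():
    s = AtomicSystem(species=[79, 11], positions=[[0, 0, 0], [2, 0, 0]])
    bb, _, cfg = _backbone()
    nbrs, r = _edge_tensors(s, cfg.cutoff)
    with pytest.raises(ValueError, match="79"):
        bb.embed_edges(s, nbrs, r)


def test_embedding_deterministic_across_instances(rng):
    s = random_open_system(rng, n=3)
    feats = []
    for _ in range(2):
        bb, _, cfg = _backbone(seed=7)
        nbrs, r = _edge_tensors(s, cfg.cutoff)
        feats.append(bb.embed_edges(s, nbrs, r).features.data)
    assert np.array_equal(feats[0], feats[1])


def test_environment_sum_invariant_under_neighbor_permutation(rng):
    s = random_open_system(rng, n=5, box=4.0, min_dist=1.2)
    bb, _, cfg = _backbone()
    nbrs, r = _edge_tensors(s, cfg.cutoff)
    x0 = bb.embed_edges(s, nbrs, r)
    pc, pe = edge_environment(nbrs)
    out1 = bb.interaction_layer(x0, pc, pe, layer_index=0).features.data
    perm = np.random.default_rng(0).permutation(len(pc))
    out2 = bb.interaction_layer(x0, pc[perm], pe[perm],
                                layer_index=0).features.data
    assert np.allclose(out1, out2, atol=1e-12)


def test_single_edge_environment_is_self_pair():
    s = AtomicSystem(species=[11, 17], positions=[[0, 0, 0], [2.2, 0, 0]])
    bb, _, cfg = _backbone()
    nbrs, r = _edge_tensors(s, cfg.cutoff)
    pc, pe = edge_environment(nbrs)
    # each directed edge's only environment member is itself
    assert np.array_equal(pc, pe)
    x0 = bb.embed_edges(s, nbrs, r)
    x = bb.interaction_layer(x0, pc, pe, layer_index=0)
    assert np.isfinite(x.features.data).all()


def test_interaction_layer_matches_hand_unrolled_sum(rng):
    """With the layer MLPs replaced by known tiny linear maps, the update
    equals an explicit loop over environment edges."""
    s = random_open_system(rng, n=4, box=4.0, min_dist=1.2)
    bb, store, cfg = _backbone()
    nbrs, r = _edge_tensors(s, cfg.cutoff)
    x0 = bb.embed_edges(s, nbrs, r)
    pc, pe = edge_environment(nbrs)
    # overwrite with deterministic weights; biases stay zero
    w = cfg.feature_width
    for name, t in store.items():
        if ".w" in name and ("layer0.W" in name or "layer0.U" in name):
            shape = t.data.shape
            t.data = (np.arange(np.prod(shape)).reshape(shape) % 5 - 2) * 0.01
    beta = store["backbone.layer0.beta"]
    beta.data = np.array(0.7)
    out = bb.interaction_layer(x0, pc, pe, layer_index=0).features.data

    def mlp(weights, x):
        h = x
        for k, wm in enumerate(weights):
            h = h @ wm
            if k != len(weights) - 1:
                h = h / (1 + np.exp(-h))
        return h

    w_ws = [store[f"backbone.layer0.W.w{k}"].data for k in range(3)]
    u_ws = [store[f"backbone.layer0.U.w{k}"].data for k in range(3)]
    x = x0.features.data
    expected = np.zeros_like(x)
    for e in range(len(nbrs)):
        wsum = np.zeros(w)
        for p in range(len(pc)):
            if pc[p] == e:
                wsum += mlp(w_ws, np.concatenate([x[e], x[pe[p]]]))
        upd = mlp(u_ws, np.concatenate([wsum, x[e]]))
        expected[e] = (x[e] + 0.7 * upd) / np.sqrt(1 + 0.49)
    assert np.allclose(out, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# readout
# ---------------------------------------------------------------------------

def test_zero_initialized_readout_gives_zero_correction(rng):
    s = random_open_system(rng, n=5)
    bb, _, cfg = _backbone()
    nbrs, r = _edge_tensors(s, cfg.cutoff)
    x = bb.embed_edges(s, nbrs, r)
    du = bb.readout(x, r, np.zeros(len(nbrs), np.int64), 1)
    assert du.data[0] == 0.0


def test_readout_is_extensive_over_noninteracting_copies(rng):
    s = random_open_system(rng, n=4, box=4.0)
    s2 = AtomicSystem(species=np.concatenate([s.species, s.species]),
                      positions=np.concatenate([s.positions,
                                                s.positions + 100.0]))
    bb, store, cfg = _backbone(seed=3)
    store["backbone.readout.w1"].data = np.random.default_rng(0).normal(
        size=store["backbone.readout.w1"].data.shape)

    def total_du(sys_):
        nbrs, r = _edge_tensors(sys_, cfg.cutoff)
        x = bb.embed_edges(sys_, nbrs, r)
        pc, pe = edge_environment(nbrs)
        for l in range(cfg.n_layers):
            x = bb.interaction_layer(x, pc, pe, layer_index=l)
        return float(bb.readout(x, r, np.zeros(len(nbrs), np.int64), 1).data[0])

    assert np.isclose(total_du(s2), 2 * total_du(s), atol=1e-10)


def test_rotation_invariance_of_correction_energy(rng):
    s = random_open_system(rng, n=5)
    bb, store, cfg = _backbone(seed=3)
    store["backbone.readout.w1"].data = np.random.default_rng(0).normal(
        size=store["backbone.readout.w1"].data.shape)

    def total_du(sys_):
        nbrs, r = _edge_tensors(sys_, cfg.cutoff)
        x = bb.embed_edges(sys_, nbrs, r)
        pc, pe = edge_environment(nbrs)
        for l in range(cfg.n_layers):
            x = bb.interaction_layer(x, pc, pe, layer_index=l)
        return float(bb.readout(x, r, np.zeros(len(nbrs), np.int64), 1).data[0])

    a = rng.normal(size=(3, 3))
    qmat, _ = np.linalg.qr(a)
    s_rot = AtomicSystem(species=s.species, positions=s.positions @ qmat.T + 3.0)
    assert abs(total_du(s) - total_du(s_rot)) < 1e-8


def test_strict_locality_far_atom_cannot_affect_edge(rng):
    """An atom beyond n_layers * r_c from an edge changes nothing exactly."""
    base = AtomicSystem(species=[11, 17, 11],
                        positions=[[0, 0, 0], [2.2, 0, 0], [4.0, 0, 0]])
    moved = AtomicSystem(species=[11, 17, 11],
                         positions=[[0, 0, 0], [2.2, 0, 0], [4.1, 0, 0]])
    far = AtomicSystem(species=[11, 17, 11, 17],
                       positions=[[0, 0, 0], [2.2, 0, 0], [4.0, 0, 0],
                                  [100.0, 0, 0]])
    bb, store, cfg = _backbone(seed=2, n_layers=2)
    for l in range(cfg.n_layers):   # activate the residual updates
        store[f"backbone.layer{l}.beta"].data = np.array(0.5)

    def edge01_feature(sys_):
        nbrs, r = _edge_tensors(sys_, cfg.cutoff)
        x = bb.embed_edges(sys_, nbrs, r)
        pc, pe = edge_environment(nbrs)
        for l in range(cfg.n_layers):
            x = bb.interaction_layer(x, pc, pe, layer_index=l)
        e01 = np.nonzero((nbrs.edges == [0, 1]).all(axis=1))[0][0]
        return x.features.data[e01]

    # moving the in-range atom changes the edge; the distant atom does not
    assert not np.allclose(edge01_feature(base), edge01_feature(moved))
    assert np.array_equal(edge01_feature(base), edge01_feature(far))


# ---------------------------------------------------------------------------
# node (adapter) mode
# ---------------------------------------------------------------------------

def test_node_mode_update_epsilon_zero_is_identity(rng):
    s = random_open_system(rng, n=4)
    bb, store, cfg = _backbone(mode="node_adapter")
    nbrs, r = _edge_tensors(s, cfg.cutoff)
    h = bb.embed_nodes(s)
    edge_out = EdgeLatents(ad.constant(
        np.random.default_rng(0).normal(size=(len(nbrs), cfg.feature_width))))
    out = bb.node_mode_update(h, edge_out, nbrs, epsilon=ad.constant(0.0))
    assert np.array_equal(out.features.data, h.features.data)


def test_node_mode_update_matches_hand_aggregation(rng):
    s = AtomicSystem(species=[11, 17], positions=[[0, 0, 0], [2.0, 0, 0]])
    bb, store, cfg = _backbone(mode="node_adapter")
    nbrs, r = _edge_tensors(s, cfg.cutoff)
    h = bb.embed_nodes(s)
    e_feat = np.random.default_rng(1).normal(size=(2, cfg.feature_width))
    out = bb.node_mode_update(h, EdgeLatents(ad.constant(e_feat)), nbrs,
                              epsilon=ad.constant(0.3))
    expected = h.features.data.copy()
    for (i, j), f in zip(nbrs.edges, e_feat):
        expected[i] += 0.3 * f
    assert np.allclose(out.features.data, expected, atol=1e-14)


def test_node_mode_update_isolated_node_unchanged():
    s = AtomicSystem(species=[11, 17, 11],
                     positions=[[0, 0, 0], [2.0, 0, 0], [90, 0, 0]])
    bb, _, cfg = _backbone(mode="node_adapter")
    nbrs, r = _edge_tensors(s, cfg.cutoff)
    h = bb.embed_nodes(s)
    e_feat = np.ones((len(nbrs), cfg.feature_width))
    out = bb.node_mode_update(h, EdgeLatents(ad.constant(e_feat)), nbrs)
    assert np.array_equal(out.features.data[2], h.features.data[2])


def test_node_mode_dimension_mismatch_rejected(rng):
    s = AtomicSystem(species=[11, 17], positions=[[0, 0, 0], [2.0, 0, 0]])
    bb, _, cfg = _backbone(mode="node_adapter")
    nbrs, r = _edge_tensors(s, cfg.cutoff)
    h = bb.embed_nodes(s)
    bad = EdgeLatents(ad.constant(np.ones((2, cfg.feature_width + 1))))
    with pytest.raises(ValueError, match="width"):
        bb.node_mode_update(h, bad, nbrs)
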