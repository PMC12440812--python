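"""The charge-equilibration block: softplus constructions, environment and
charge embeddings, the composed forward pass."""

import math

import numpy as np
import pytest

from celliq import autodiff as ad
from celliq.backbone import BackboneConfig, ScalarBackbone, edge_environment
from celliq.celli import CelliBlock, CelliConfig, generalized_softplus
from celliq.model import PotentialModel, prepare_batch
from celliq.nn import ParamStore
from celliq.systems import AtomicSystem, build_neighbor_list

from conftest import random_open_system


def _block(edge_dim=16, species=(11, 17), seed=0, **cfg_kw):
    cfg = CelliConfig(**cfg_kw)
    store = ParamStore()
    bb_cfg = BackboneConfig(species=species, seed=seed)
    bb = ScalarBackbone(bb_cfg, store, np.random.default_rng(seed))
    block = CelliBlock(cfg, species, edge_dim, bb.env, store,
                       np.random.default_rng(seed + 1))
    return block, bb, store, bb_cfg


# ---------------------------------------------------------------------------
# generalized softplus
# ---------------------------------------------------------------------------

def test_generalized_softplus_identities():
    assert np.isclose(generalized_softplus(0.0), math.log(2.0), rtol=1e-15)
    assert generalized_softplus() == 0.0
    assert abs(generalized_softplus(50.0) - 50.0) < 1e-12  # overflow-safe
    assert abs(generalized_softplus(900.0) - 900.0) < 1e-9


def test_generalized_softplus_multiple_arguments():
    # independent evaluation of log(1 + e^1 + e^2)
    expected = math.log(1.0 + math.e + math.e ** 2)
    assert np.isclose(generalized_softplus(1.0, 2.0), expected, rtol=1e-14)


# ---------------------------------------------------------------------------
# species-side embeddings
# ---------------------------------------------------------------------------

def test_species_hardness_log2_at_zero_raw():
    block, _, store, _ = _block(hardness_init=0.0)
    j = block.species_hardness(np.array([0, 1]), None)
    assert np.allclose(j.data, math.log(2.0), rtol=1e-14)


def test_species_hardness_env_off_depends_on_species_only(rng):
    block, _, store, _ = _block(env_hardness=False)
    env_sums = ad.constant(rng.normal(size=4))
    j = block.species_hardness(np.array([0, 1, 0, 1]), env_sums)
    assert np.isclose(j.data[0], j.data[2]) and np.isclose(j.data[1], j.data[3])


def test_species_hardness_env_on_two_argument_softplus():
    block, _, store, _ = _block(env_hardness=True, hardness_init=1.0)
    j = block.species_hardness(np.array([0]), ad.constant(np.array([2.0])))
    assert np.isclose(j.data[0], math.log(1 + math.e + math.e ** 2), rtol=1e-13)


def test_species_radii_identity_at_zero_and_monotone_limit():
    block, _, store, _ = _block()
    g0 = block.species_radii(np.array([0, 1]))
    assert np.allclose(g0.data, block.embed.covalent_radii, rtol=1e-14)
    store["celli.radius_raw"].data = np.array([-30.0, 1.0])
    g = block.species_radii(np.array([0, 1]))
    assert 0 < g.data[0] < 1e-8          # s -> -inf gives gamma -> 0+
    factor = math.log(1 + math.e) / math.log(2)
    assert np.isclose(g.data[1], factor * block.embed.covalent_radii[1],
                      rtol=1e-13)


def test_missing_covalent_radius_names_element():
    from celliq.periodic_table import UnknownElementError
    with pytest.raises(UnknownElementError, match="118"):
        _block(species=(11, 118))


# ---------------------------------------------------------------------------
# environment embedding
# ---------------------------------------------------------------------------

def _latents_for(system, bb, cutoff):
    nbrs = build_neighbor_list(system, cutoff)
    r = ad.constant(nbrs.distances)
    return nbrs, r, bb.embed_edges(system, nbrs, r)


def test_environment_embedding_f_zero_gives_zero_chi(rng):
    s = random_open_system(rng, n=4)
    block, bb, store, bb_cfg = _block()
    store["celli.f"].data = np.array(0.0)
    store["celli.mlp_r.w2"].data = rng.normal(
        size=store["celli.mlp_r.w2"].data.shape)
    nbrs, r, x = _latents_for(s, bb, bb_cfg.cutoff)
    chi, _ = block.environment_embedding(x, nbrs, len(s))
    assert np.all(chi.data == 0.0)


def test_environment_embedding_symmetric_atoms_equal_chi():
    s = AtomicSystem(species=[11, 17, 11],
                     positions=[[0, 0, 0], [2.2, 0, 0], [4.4, 0, 0]])
    block, bb, store, bb_cfg = _block()
    store["celli.mlp_r.w2"].data = np.random.default_rng(0).normal(
        size=store["celli.mlp_r.w2"].data.shape)
    nbrs, r, x = _latents_for(s, bb, bb_cfg.cutoff)
    chi, _ = block.environment_embedding(x, nbrs, len(s))
    assert np.isclose(chi.data[0], chi.data[2], atol=1e-12)


def test_environment_embedding_matches_hand_sum(rng):
    s = AtomicSystem(species=[11, 17, 11],
                     positions=[[0, 0, 0], [2.2, 0, 0], [4.4, 0, 0]])
    block, bb, store, bb_cfg = _block()
    store["celli.mlp_r.w2"].data = rng.normal(
        size=store["celli.mlp_r.w2"].data.shape, scale=0.1)
    store["celli.f"].data = np.array(0.7)
    nbrs, r, x = _latents_for(s, bb, bb_cfg.cutoff)
    chi, _ = block.environment_embedding(x, nbrs, len(s))
    out = block.mlp_r(x.features).data       # (E, 2)
    expected = np.zeros(3)
    for e, (i, j) in enumerate(nbrs.edges):
        expected[i] += out[e, 0]
    assert np.allclose(chi.data, 0.7 * expected, atol=1e-12)


def test_isolated_atom_gets_zero_chi_but_carries_charge(rng):
    s = AtomicSystem(species=[11, 17, 11],
                     positions=[[0, 0, 0], [2.2, 0, 0], [90, 0, 0]],
                     total_charge=1.0)
    model = PotentialModel(BackboneConfig(species=(11, 17)), CelliConfig(),
                           seed=0)
    _, _, q = model.predict(s)
    assert abs(q.sum() - 1.0) < 1e-10
    assert q[2] != 0.0        # the constraint still assigns it charge


# ---------------------------------------------------------------------------
# charge embedding update
# ---------------------------------------------------------------------------

def test_charge_embedding_vanishes_at_cutoff(rng):
    block, bb, store, bb_cfg = _block()
    rc = bb_cfg.cutoff
    s = AtomicSystem(species=[11, 17],
                     positions=[[0, 0, 0], [rc - 1e-9, 0, 0]])
    nbrs, r, x = _latents_for(s, bb, rc)
    out = block.charge_embedding_update(
        x, ad.constant(np.array([0.3, -0.3])), np.array([0, 1]), nbrs, r)
    assert np.max(np.abs(out.features.data)) < 1e-6


def test_charge_embedding_matches_hand_computation(rng):
    s = AtomicSystem(species=[11, 17], positions=[[0, 0, 0], [2.0, 0, 0]])
    block, bb, store, bb_cfg = _block()
    nbrs, r, x = _latents_for(s, bb, bb_cfg.cutoff)
    q = np.array([0.25, -0.25])
    codes = np.array([0, 1])
    out = block.charge_embedding_update(x, ad.constant(q), codes, nbrs, r)

    def np_mlp(prefix, v, n_layers=3):
        h = v
        for k in range(n_layers):
            h = h @ store[f"{prefix}.w{k}"].data + store[f"{prefix}.b{k}"].data
            if k != n_layers - 1:
                h = h / (1 + np.exp(-h))
        return h

    from celliq.backbone import envelope
    ctx = store["celli.context"].data
    expected = np.zeros_like(out.features.data)
    for e, (i, j) in enumerate(nbrs.edges):
        y = np_mlp("celli.mlp_q",
                   np.concatenate([[q[i], q[j]], ctx[codes[i]], ctx[codes[j]]]))
        xe = np_mlp("celli.mlp_x",
                    np.concatenate([y, x.features.data[e]]))
        expected[e] = xe * envelope(nbrs.distances[e], bb.env)
    assert np.allclose(out.features.data, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# composed forward (through the model)
# ---------------------------------------------------------------------------

def _model(seed=0, **celli_kw):
    return PotentialModel(BackboneConfig(species=(11, 17), seed=seed),
                          CelliConfig(**celli_kw), seed=seed)


def test_homonuclear_symmetric_cluster_has_zero_charges(rng):
    # neutral square of identical atoms: chi equal by symmetry
    s = AtomicSystem(species=[11] * 4,
                     positions=[[0, 0, 0], [2.4, 0, 0], [0, 2.4, 0],
                                [2.4, 2.4, 0]])
    m = _model()
    m.store["celli.mlp_r.w2"].data = rng.normal(
        size=m.store["celli.mlp_r.w2"].data.shape, scale=0.2)
    _, _, q = m.predict(s)
    assert np.max(np.abs(q)) < 1e-10


def test_forward_conserves_charge_for_many_random_structures(rng):
    m = _model()
    m.store["celli.mlp_r.w2"].data = rng.normal(
        size=m.store["celli.mlp_r.w2"].data.shape, scale=0.2)
    for k in range(50):
        qtot = float(rng.choice([0.0, 1.0, -1.0]))
        s = random_open_system(rng, n=int(rng.integers(2, 8)),
                               total_charge=qtot)
        _, _, q = m.predict(s)
        assert abs(q.sum() - qtot) < 1e-10


def test_rotated_structure_gives_identical_charges(rng):
    m = _model()
    m.store["celli.mlp_r.w2"].data = rng.normal(
        size=m.store["celli.mlp_r.w2"].data.shape, scale=0.2)
    s = random_open_system(rng, n=6)
    _, _, q1 = m.predict(s)
    a = rng.normal(size=(3, 3))
    qmat, _ = np.linalg.qr(a)
    s2 = AtomicSystem(species=s.species, positions=s.positions @ qmat.T - 4.0)
    _, _, q2 = m.predict(s2)
    assert np.max(np.abs(q1 - q2)) < 1e-8


def test_charge_state_sensitivity_vs_local_blindness(rng):
    """Changing Q_tot changes a charge-equilibrated model's energy, while a
    purely local backbone returns bit-identical output for both states."""
    s0 = random_open_system(rng, n=6, total_charge=0.0)
    s1 = AtomicSystem(species=s0.species, positions=s0.positions,
                      total_charge=1.0)
    m = _model()
    u0, _, q0 = m.predict(s0)
    u1, _, q1 = m.predict(s1)
    assert u0 != u1
    assert not np.allclose(q0, q1)

    baseline = PotentialModel(BackboneConfig(species=(11, 17)), None, seed=0)
    baseline.store["backbone.readout.w1"].data = rng.normal(
        size=baseline.store["backbone.readout.w1"].data.shape)
    b0 = baseline.predict(s0)
    b1 = baseline.predict(s1)
    assert b0[0] == b1[0]
    assert np.array_equal(b0[1], b1[1])


def test_forward_matches_manual_composition_of_suboperations(rng):
    s = random_open_system(rng, n=6, total_charge=1.0)
    m = _model(placement=1)
    m.store["celli.mlp_r.w2"].data = rng.normal(
        size=m.store["celli.mlp_r.w2"].data.shape, scale=0.2)
    batch = prepare_batch([s], m.backbone_cfg.cutoff,
                          m.backbone.species_codes)
    out = m.forward_batch(batch)

    # manual composition: embed -> layer0 -> celli block -> compare charges
    bb = m.backbone
    nbrs = batch.nbrs
    r = ad.constant(nbrs.distances)
    x = bb.embed_edges(s, nbrs, r)
    pc, pe = edge_environment(nbrs)
    x = bb.interaction_layer(x, pc, pe, layer_index=0)
    pos = ad.constant(batch.positions)
    _, u_coul, q, _ = m.celli.forward(x, pos, batch.codes, nbrs, r,
                                      batch.structure_of_atom,
                                      batch.total_charges, batch.block_mask)
    assert np.allclose(out["charges"].data, q.data, atol=1e-12)
    assert np.allclose(out["u_coul"].data, u_coul.data, atol=1e-12)


def test_multiple_placements_allowed_but_validated():
    with pytest.raises(ValueError):
        CelliConfig(placement=5).resolve_placement(2)
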