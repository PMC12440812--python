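"""Strictly local scalar GNN backbone.

A simplified Allegro-style network: per-directed-edge scalar features,
updated layer by layer through an environment sum over edges sharing the
same source atom, with a weighted residual. A node-feature mode provides the
minimal message-passing backbone used by the adapter that couples the
charge-equilibration block to MPNN architectures.

Only rotation/translation-invariant inputs (species, interatomic distances)
enter the features, so invariance of all outputs is structural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autodiff as ad
from .nn import MLP, ParamStore
from .systems import AtomicSystem, NeighborList

__all__ = [
    "RadialBasis", "EnvelopePolynomial", "EdgeLatents", "NodeLatents",
    "BackboneConfig", "ScalarBackbone",
    "envelope", "envelope_ad", "bessel_ad", "edge_environment",
]


@dataclass
class RadialBasis:
    """Bessel radial basis: sqrt(2/r_c) sin(n pi r / r_c) / r, n = 1..count."""

    count: int = 8
    cutoff: float = 5.0
    kind: str = "bessel"

    def __post_init__(self):
        if self.kind != "bessel":
            raise ValueError("only the bessel radial basis is implemented")
        if self.count < 1 or self.cutoff <= 0:
            raise ValueError("invalid radial basis configuration")


@dataclass
class EnvelopePolynomial:
    """Smooth polynomial cutoff: 1 at r=0, 0 with two vanishing derivatives at r_c."""

    p: int = 6
    cutoff: float = 5.0

    def __post_init__(self):
        if self.p < 2:
            raise ValueError("envelope degree parameter p must be >= 2")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class EdgeLatents:
    """Per-directed-edge scalar feature vectors x_ij^l."""

    features: ad.Tensor
    layer: int = 0


@dataclass
class NodeLatents:
    """Per-node scalar feature vectors h_i^l."""

    features: ad.Tensor
    layer: int = 0


def _env_coeffs(p: int):
    return (-(p + 1) * (p + 2) / 2.0, float(p * (p + 2)), -p * (p + 1) / 2.0)


def envelope(r, env: EnvelopePolynomial):
    """p_env(r): exactly 1 at r=0, exactly 0 for r >= cutoff (numpy)."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    u = r / env.cutoff
    c0, c1, c2 = _env_coeffs(env.p)
    val = 1.0 + c0 * u ** env.p + c1 * u ** (env.p + 1) + c2 * u ** (env.p + 2)
    out = np.where(u < 1.0, val, 0.0)
    return float(out) if out.ndim == 0 else out


def envelope_ad(r: ad.Tensor, env: EnvelopePolynomial) -> ad.Tensor:
    """Differentiable envelope; assumes r < cutoff (guaranteed by the
    neighbor list, which only emits edges inside the cutoff)."""
    u = ad.mul(r, 1.0 / env.cutoff)
    c0, c1, c2 = _env_coeffs(env.p)
    up = ad.power(u, float(env.p))
    return ad.add(1.0, ad.add(ad.mul(c0, up),
                              ad.add(ad.mul(c1, ad.mul(up, u)),
                                     ad.mul(c2, ad.mul(up, ad.mul(u, u))))))


def bessel_ad(r: ad.Tensor, basis: RadialBasis) -> ad.Tensor:
    """(E, count) Bessel features sqrt(2/r_c) sin(n pi r/r_c)/r."""
    rc = basis.cutoff
    n = np.arange(1, basis.count + 1, dtype=np.float64)
    arg = ad.mul(ad.reshape(r, (-1, 1)), ad.constant(n[None, :] * math.pi / rc))
    return ad.mul(ad.div(ad.sin(arg), ad.reshape(r, (-1, 1))),
                  math.sqrt(2.0 / rc))


def edge_environment(nbrs: NeighborList):
    """Index pairs (e, e') of directed edges sharing a source atom.

    Returns (pair_center, pair_env): for each pair, ``pair_center`` is the
    edge being updated and ``pair_env`` runs over all edges leaving the same
    source (including the edge itself). Fixed, deterministic ordering.
    """
    src = nbrs.edges[:, 0]
    order = np.arange(len(src))
    by_src: dict[int, list] = {}
    for e in order:
        by_src.setdefault(int(src[e]), []).append(e)
    centers, envs = [], []
    for e in order:
        for e2 in by_src[int(src[e])]:
            centers.append(e)
            envs.append(e2)
    return np.asarray(centers, dtype=np.int64), np.asarray(envs, dtype=np.int64)


@dataclass
class BackboneConfig:
    n_layers: int = 2
    feature_width: int = 16
    hidden_width: int = 32
    n_bessel: int = 8
    envelope_p: int = 6
    cutoff: float = 5.0
    pair_embed_dim: int = 8
    mode: str = "edge"            # "edge" | "node_adapter"
    species: tuple = (1, 6, 7, 8, 11, 17)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("edge", "node_adapter"):
            raise ValueError(f"unknown backbone mode {self.mode!r}")
        if self.n_layers < 1:
            raise ValueError("need at least one interaction layer")
        self.species = tuple(int(z) for z in self.species)


class ScalarBackbone:
    """Embeddings, interaction layers and readout over a `ParamStore`."""

    def __init__(self, cfg: BackboneConfig, store: ParamStore,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.basis = RadialBasis(cfg.n_bessel, cfg.cutoff)
        self.env = EnvelopePolynomial(cfg.envelope_p, cfg.cutoff)
        self.species_index = {z: k for k, z in enumerate(cfg.species)}
        s = len(cfg.species)
        w = cfg.feature_width
        h = cfg.hidden_width

        self.pair_table = store.add(
            "backbone.pair_embed",
            rng.normal(scale=1.0, size=(s * s, cfg.pair_embed_dim)))
        d0 = cfg.pair_embed_dim + cfg.n_bessel
        self.lift = MLP(store, "backbone.lift", [d0, w], rng)
        self.w_mlps, self.u_mlps, self.betas = [], [], []
        for l in range(cfg.n_layers):
            self.w_mlps.append(MLP(store, f"backbone.layer{l}.W",
                                   [2 * w, h, h, w], rng))
            self.u_mlps.append(MLP(store, f"backbone.layer{l}.U",
                                   [2 * w, h, h, w], rng))
            self.betas.append(store.add(f"backbone.layer{l}.beta", 0.0))
        self.readout_mlp = MLP(store, "backbone.readout", [w, h, 1], rng,
                               zero_init_last=True)
        if cfg.mode == "node_adapter":
            self.node_table = store.add(
                "backbone.node_embed", rng.normal(scale=1.0, size=(s, w)))
            self.msg_mlps = [MLP(store, f"backbone.layer{l}.M",
                                 [2 * w + cfg.n_bessel, h, h, w], rng)
                             for l in range(cfg.n_layers)]
            self.nupd_mlps = [MLP(store, f"backbone.layer{l}.NU",
                                  [2 * w, h, h, w], rng)
                              for l in range(cfg.n_layers)]
            self.node_readout = MLP(store, "backbone.node_readout", [w, 1],
                                    rng, zero_init_last=True)
            self.epsilon = store.add("backbone.epsilon", 0.1)

    # -- species helpers ---------------------------------------------------
    def species_codes(self, species: np.ndarray) -> np.ndarray:
        unknown = [int(z) for z in species if int(z) not in self.species_index]
        if unknown:
            raise ValueError(
                f"species {sorted(set(unknown))} not in configured table "
                f"{self.cfg.species}")
        return np.array([self.species_index[int(z)] for z in species])

    # -- operations --------------------------------------------------------
    def embed_edges(self, system: AtomicSystem, nbrs: NeighborList,
                    r: ad.Tensor) -> EdgeLatents:
        """Layer-0 features from the species pair and envelope-weighted
        Bessel radial features of r_ij."""
        codes = self.species_codes(system.species)
        s = len(self.cfg.species)
        pair_idx = codes[nbrs.edges[:, 0]] * s + codes[nbrs.edges[:, 1]]
        pair = ad.gather(self.pair_table, pair_idx)
        rbf = bessel_ad(r, self.basis)
        p = envelope_ad(r, self.env)
        rbf = ad.mul(rbf, ad.reshape(p, (-1, 1)))
        x0 = ad.concatenate([pair, rbf], axis=1)
        return EdgeLatents(self.lift(x0), layer=0)

    def interaction_layer(self, latents: EdgeLatents, pair_center: np.ndarray,
                          pair_env: np.ndarray,
                          layer_index: Optional[int] = None) -> EdgeLatents:
        """w_ij = sum_k W(x_ij, x_ik); x^{l+1} = x^l (+)_beta U(w_ij, x_ij)."""
        l = latents.layer if layer_index is None else layer_index
        x = latents.features
        e = x.shape[0]
        pc = ad.gather(x, pair_center)
        pe = ad.gather(x, pair_env)
        msgs = self.w_mlps[l](ad.concatenate([pc, pe], axis=1))
        w = ad.scatter_add(msgs, pair_center, (e, x.shape[1]))
        upd = self.u_mlps[l](ad.concatenate([w, x], axis=1))
        beta = self.betas[l]
        scale = ad.power(ad.add(1.0, ad.mul(beta, beta)), -0.5)
        out = ad.mul(ad.add(x, ad.mul(beta, upd)), scale)
        return EdgeLatents(out, layer=l + 1)

    def readout(self, latents: EdgeLatents, r: ad.Tensor,
                structure_of_edge: np.ndarray, n_structures: int) -> ad.Tensor:
        """Per-edge energies, envelope-damped, summed per structure -> dU."""
        per_edge = ad.reshape(self.readout_mlp(latents.features), (-1,))
        per_edge = ad.mul(per_edge, envelope_ad(r, self.env))
        return ad.scatter_add(per_edge, structure_of_edge, (n_structures,))

    # -- node (message-passing) mode ---------------------------------------
    def embed_nodes(self, system: AtomicSystem) -> NodeLatents:
        codes = self.species_codes(system.species)
        return NodeLatents(ad.gather(self.node_table, codes), layer=0)

    def message_passing_layer(self, nodes: NodeLatents, nbrs: NeighborList,
                              r: ad.Tensor) -> NodeLatents:
        """m_i = sum_j M(h_i, h_j, rbf_ij); h^{l+1} = U(m_i, h_i)."""
        l = nodes.layer
        h = nodes.features
        n = h.shape[0]
        src, dst = nbrs.edges[:, 0], nbrs.edges[:, 1]
        rbf = bessel_ad(r, self.basis)
        rbf = ad.mul(rbf, ad.reshape(envelope_ad(r, self.env), (-1, 1)))
        inp = ad.concatenate([ad.gather(h, src), ad.gather(h, dst), rbf], axis=1)
        msgs = self.msg_mlps[l](inp)
        m = ad.scatter_add(msgs, src, (n, h.shape[1]))
        out = self.nupd_mlps[l](ad.concatenate([m, h], axis=1))
        return NodeLatents(out, layer=l + 1)

    def node_mode_update(self, nodes: NodeLatents, edge_out: EdgeLatents,
                         nbrs: NeighborList,
                         epsilon: Optional[ad.Tensor] = None) -> NodeLatents:
        """Residual aggregation h_i^{l+1} = h_i^l + eps sum_{j in N(i)} x_ij."""
        if epsilon is None:
            epsilon = self.epsilon
        h = nodes.features
        if edge_out.features.shape[1] != h.shape[1]:
            raise ValueError(
                f"adapter edge features ({edge_out.features.shape[1]}) do not "
                f"match node width ({h.shape[1]})")
        agg = ad.scatter_add(edge_out.features, nbrs.edges[:, 0],
                             (h.shape[0], h.shape[1]))
        return NodeLatents(ad.add(h, ad.mul(epsilon, agg)), layer=nodes.layer + 1)

    def node_readout_energy(self, nodes: NodeLatents,
                            structure_of_atom: np.ndarray,
                            n_structures: int) -> ad.Tensor:
        per_node = ad.reshape(self.node_readout(nodes.features), (-1,))
        return ad.scatter_add(per_node, structure_of_atom, (n_structures,))
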