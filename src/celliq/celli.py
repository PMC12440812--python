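"""The charge-equilibration layer (CELLI).

Sits between interaction layers of a local GNN. From the incoming edge
latents it predicts per-edge electronegativity contributions (and optionally
environment-dependent hardness contributions), combines them with
species-level hardness and Gaussian-radius embeddings, solves the global
charge-equilibration problem, and embeds the equilibrated charges back into
the edge latents for the remaining layers. The electrostatic energy of the
equilibrated charges is returned alongside.

Positivity of hardnesses and radii is built in through the generalized
softplus sigma_+(x_1..x_k) = log(1 + e^{x_1} + ... + e^{x_k}); radii scale
tabulated single-bond covalent radii by sigma_+(s)/log 2, which is exactly 1
at s = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from . import autodiff as ad
from .backbone import EdgeLatents, EnvelopePolynomial, envelope_ad
from .electrostatics import coulomb_matrix_ad
from .nn import MLP, ParamStore
from .periodic_table import covalent_radius
from .qeq import solve_qeq_ad
from .systems import NeighborList

__all__ = ["SpeciesEmbedding", "CelliConfig", "CelliBlock",
           "generalized_softplus"]

_LOG2 = math.log(2.0)


def generalized_softplus(*values) -> float:
    """sigma_+(x_1, ..., x_k) = log(1 + sum_m e^{x_m}), overflow-safe.

    With no arguments this is log(1) = 0; sigma_+(0) = log 2.
    """
    if not values:
        return 0.0
    return float(logsumexp(np.concatenate([[0.0], np.asarray(values, float).ravel()])))


@dataclass
class CelliConfig:
    """Placement and widths of the charge-equilibration block."""

    placement: Optional[int] = None   # None -> floor(n_layers / 2)
    env_hardness: bool = False
    mlp_r_hidden: int = 32
    mlp_q_hidden: int = 32
    mlp_x_hidden: int = 32
    context_dim: int = 4
    charge_feature_dim: int = 8
    # f = 1 with the zero-initialized MLP_R final layer still gives chi = 0 at
    # cold start, but keeps the electronegativity path trainable (f = 0 and a
    # zero final layer together form a gradient saddle).
    f_init: float = 1.0
    hardness_init: float = 8.0        # raw J^Z; sigma_+(8) ~ 8, a typical atomic hardness [eV/e^2]

    def resolve_placement(self, n_layers: int) -> int:
        p = n_layers // 2 if self.placement is None else int(self.placement)
        if not 0 <= p <= n_layers:
            raise ValueError(
                f"CELLI placement {p} outside 0..{n_layers}")
        return p


@dataclass
class SpeciesEmbedding:
    """Per-species raw hardness, raw radius scale, context vector, and the
    tabulated single-bond covalent radius gamma^exp [A]."""

    hardness_raw: ad.Tensor     # (S,)
    radius_raw: ad.Tensor       # (S,)
    context: ad.Tensor          # (S, context_dim)
    covalent_radii: np.ndarray  # (S,), constant


class CelliBlock:
    """One charge-equilibration block; exactly one per model."""

    def __init__(self, cfg: CelliConfig, species: tuple, edge_dim: int,
                 env: EnvelopePolynomial, store: ParamStore,
                 rng: np.random.Generator, out_dim: int = None):
        self.cfg = cfg
        self.env = env
        self.species = species
        if out_dim is None:
            out_dim = edge_dim
        s = len(species)
        gexp = np.array([covalent_radius(z) for z in species])
        self.embed = SpeciesEmbedding(
            hardness_raw=store.add("celli.hardness_raw",
                                   np.full(s, cfg.hardness_init)),
            radius_raw=store.add("celli.radius_raw", np.zeros(s)),
            context=store.add("celli.context",
                              rng.normal(scale=1.0, size=(s, cfg.context_dim))),
            covalent_radii=gexp,
        )
        self.f = store.add("celli.f", cfg.f_init)
        h = cfg.mlp_r_hidden
        # final layer zero-initialized: cold start has chi = 0, J = species-only
        self.mlp_r = MLP(store, "celli.mlp_r", [edge_dim, h, h, 2], rng,
                         zero_init_last=True)
        self.mlp_q = MLP(store, "celli.mlp_q",
                         [2 + 2 * cfg.context_dim, cfg.mlp_q_hidden,
                          cfg.mlp_q_hidden, cfg.charge_feature_dim], rng)
        self.mlp_x = MLP(store, "celli.mlp_x",
                         [cfg.charge_feature_dim + edge_dim, cfg.mlp_x_hidden,
                          cfg.mlp_x_hidden, out_dim], rng)

    # -- sub-operations ----------------------------------------------------
    def environment_embedding(self, latents: EdgeLatents, nbrs: NeighborList,
                              n_atoms: int):
        """chi_i = f * sum_{k in N(i)} chi~_ik; optionally J~^R sums.

        Atoms with no incident edges get chi_i = 0 (empty sum); the solver
        still assigns them charge through the conservation constraint.
        """
        out = self.mlp_r(latents.features)           # (E, 2)
        chi_edge = out[np.s_[:, 0]]
        jr_edge = out[np.s_[:, 1]]
        src = nbrs.edges[:, 0]
        chi = ad.mul(self.f, ad.scatter_add(chi_edge, src, (n_atoms,)))
        j_env = ad.scatter_add(jr_edge, src, (n_atoms,))
        return chi, j_env

    def species_hardness(self, codes: np.ndarray,
                         j_env_sums: Optional[ad.Tensor]) -> ad.Tensor:
        """J_i = sigma_+(J~^Z_i[, sum_j J~^R_ij]) > 0."""
        jz = ad.gather(self.embed.hardness_raw, codes)
        if not self.cfg.env_hardness or j_env_sums is None:
            return ad.softplus(jz)
        return ad.logaddexp(ad.softplus(jz), j_env_sums)

    def species_radii(self, codes: np.ndarray) -> ad.Tensor:
        """gamma_i = sigma_+(s~_i)/log 2 * gamma_i^exp; equals gamma^exp at s~=0."""
        sraw = ad.gather(self.embed.radius_raw, codes)
        gexp = self.embed.covalent_radii[codes]
        return ad.mul(ad.mul(ad.softplus(sraw), 1.0 / _LOG2), ad.constant(gexp))

    def charge_embedding_update(self, latents: EdgeLatents, charges: ad.Tensor,
                                codes: np.ndarray, nbrs: NeighborList,
                                r: ad.Tensor) -> EdgeLatents:
        """y_ij = MLP_Q(Q_i, Q_j, c_i, c_j);
        x^{l+1} = MLP_x(y_ij, x^l) * p_env(r_ij)."""
        src, dst = nbrs.edges[:, 0], nbrs.edges[:, 1]
        qi = ad.reshape(ad.gather(charges, src), (-1, 1))
        qj = ad.reshape(ad.gather(charges, dst), (-1, 1))
        ci = ad.gather(self.embed.context, codes[src])
        cj = ad.gather(self.embed.context, codes[dst])
        y = self.mlp_q(ad.concatenate([qi, qj, ci, cj], axis=1))
        x_new = self.mlp_x(ad.concatenate([y, latents.features], axis=1))
        x_new = ad.mul(x_new, ad.reshape(envelope_ad(r, self.env), (-1, 1)))
        return EdgeLatents(x_new, layer=latents.layer + 1)

    # -- full block --------------------------------------------------------
    def forward(self, latents: EdgeLatents, positions: ad.Tensor,
                codes: np.ndarray, nbrs: NeighborList, r: ad.Tensor,
                structure_of_atom: np.ndarray, total_charges: np.ndarray,
                block_mask: Optional[np.ndarray] = None):
        """Compose: environment embedding -> hardness/radii -> Qeq solve ->
        charge embedding. Returns (latents^{l+1}, U_Coul per structure,
        charges, multipliers). Fully differentiable."""
        n = positions.shape[0]
        chi, j_env = self.environment_embedding(latents, nbrs, n)
        hardness = self.species_hardness(codes, j_env)
        gamma = self.species_radii(codes)
        matrix = coulomb_matrix_ad(positions, gamma, block_mask)
        charges, lam = solve_qeq_ad(chi, hardness, matrix,
                                    structure_of_atom, total_charges)
        mq = ad.matmul(matrix, charges)
        u_atom = ad.mul(0.5, ad.mul(charges, mq))
        n_struct = len(total_charges)
        u_coul = ad.scatter_add(u_atom, structure_of_atom, (n_struct,))
        out = self.charge_embedding_update(latents, charges, codes, nbrs, r)
        return out, u_coul, charges, lam
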