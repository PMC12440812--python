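"""Full potential assembly and force-matching training.

The potential predicts ``U = U_Coul + dU`` (on the shifted-energy scale),
forces ``F = -dU/dR`` including the sensitivity of the equilibrated charges
to positions, and partial charges ``Q``. Training minimizes the weighted
squared-error loss over energies, forces and charges with Adam, a polynomial
step-size schedule and decoupled weight decay, selecting the checkpoint with
the lowest validation loss.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .backbone import (BackboneConfig, EdgeLatents, ScalarBackbone,
                       edge_environment)
from .celli import CelliBlock, CelliConfig
from .nn import ParamStore
from .systems import AtomicSystem, NeighborList, build_neighbor_list

__all__ = ["PotentialModel", "LossWeights", "TrainSchedule",
           "fit_shifts", "loss", "train", "prepare_batch"]


@dataclass
class LossWeights:
    """gamma_U [eV^-2], gamma_F [(eV/A)^-2], gamma_Q [e^-2] of the
    force-matching loss."""

    gamma_U: float = 1.0
    gamma_F: float = 10.0
    gamma_Q: float = 1.0

    def __post_init__(self):
        if min(self.gamma_U, self.gamma_F, self.gamma_Q) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.gamma_U == self.gamma_F == self.gamma_Q == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class TrainSchedule:
    """Adam + polynomial decay lr(t) = lr0 * (1 - t/T)^kappa, decoupled
    weight decay, gradient clipping by global norm."""

    learning_rate: float = 5e-3
    epochs: int = 40
    batch_size: int = 32
    kappa: float = 1.0
    weight_decay: float = 1e-6
    clip_norm: float = 100.0
    final_lr_fraction: float = 0.02
    #: Polyak averaging decay for the evaluated/selected weights (0 = off)
    ema_decay: float = 0.999


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

class BatchData:
    """Pre-assembled graph of several open structures as one block system."""

    __slots__ = ("systems", "species", "codes", "positions", "nbrs",
                 "pair_center", "pair_env", "structure_of_atom",
                 "structure_of_edge", "total_charges", "block_mask",
                 "n_structures", "n_atoms_per", "labels")

    def __init__(self):
        self.labels = {}


def prepare_batch(systems: Sequence[AtomicSystem], cutoff: float,
                  codes_fn) -> BatchData:
    """Merge structures into one disconnected graph (offsets applied).

    Structures in a batch never interact: the neighbor graph is built per
    structure and the Coulomb matrix is block-masked.
    """
    b = BatchData()
    b.systems = list(systems)
    offs, edges, disp, dist, soa, soe = 0, [], [], [], [], []
    for k, s in enumerate(b.systems):
        if s.is_periodic:
            raise NotImplementedError(
                "the potential model supports open (non-periodic) systems")
        nl = build_neighbor_list(s, cutoff)
        edges.append(nl.edges + offs)
        disp.append(nl.displacements)
        dist.append(nl.distances)
        soa.append(np.full(len(s), k))
        soe.append(np.full(len(nl), k))
        offs += len(s)
    b.species = np.concatenate([s.species for s in b.systems])
    b.codes = codes_fn(b.species)
    b.positions = np.concatenate([s.positions for s in b.systems], axis=0)
    b.nbrs = NeighborList(
        edges=np.concatenate(edges) if edges else np.zeros((0, 2), int),
        displacements=np.concatenate(disp) if disp else np.zeros((0, 3)),
        distances=np.concatenate(dist) if dist else np.zeros(0),
        cutoff=cutoff)
    b.pair_center, b.pair_env = edge_environment(b.nbrs)
    b.structure_of_atom = np.concatenate(soa).astype(np.int64)
    b.structure_of_edge = (np.concatenate(soe).astype(np.int64)
                           if soe else np.zeros(0, np.int64))
    b.total_charges = np.array([s.total_charge for s in b.systems])
    b.n_structures = len(b.systems)
    b.n_atoms_per = np.array([len(s) for s in b.systems])
    b.block_mask = (b.structure_of_atom[:, None]
                    == b.structure_of_atom[None, :]).astype(float)
    return b


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class PotentialModel:
    """Backbone + at most one CELLI block + readout + per-species shifts."""

    def __init__(self, backbone_cfg: BackboneConfig,
                 celli_cfg: Optional[CelliConfig] = None, seed: int = 0):
        self.backbone_cfg = backbone_cfg
        self.celli_cfg = celli_cfg
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.store = ParamStore()
        self.backbone = ScalarBackbone(backbone_cfg, self.store, rng)
        self.celli: Optional[CelliBlock] = None
        self.placement = None
        if celli_cfg is not None:
            self.placement = celli_cfg.resolve_placement(backbone_cfg.n_layers)
            if backbone_cfg.mode == "edge":
                edge_dim = backbone_cfg.feature_width
                out_dim = None
            else:
                edge_dim = backbone_cfg.feature_width + backbone_cfg.n_bessel
                out_dim = backbone_cfg.feature_width
            self.celli = CelliBlock(celli_cfg, backbone_cfg.species, edge_dim,
                                    self.backbone.env, self.store, rng,
                                    out_dim=out_dim)
        self.shifts = np.zeros(len(backbone_cfg.species))  # U_s [eV]

    # -- core forward ------------------------------------------------------
    def forward_batch(self, batch: BatchData, positions: ad.Tensor = None):
        """Returns dict with per-structure 'u' (shifted scale), 'u_coul',
        'charges' (or None), 'positions' tensor for force differentiation."""
        if positions is None:
            positions = ad.parameter(batch.positions.copy())
        src, dst = batch.nbrs.edges[:, 0], batch.nbrs.edges[:, 1]
        d = ad.sub(ad.gather(positions, dst), ad.gather(positions, src))
        r = ad.sqrt(ad.tsum(ad.mul(d, d), axis=1))

        merged = AtomicSystem(species=batch.species,
                              positions=batch.positions)
        bb = self.backbone
        charges = None
        multipliers = None
        u_coul = ad.constant(np.zeros(batch.n_structures))

        if self.backbone_cfg.mode == "edge":
            x = bb.embed_edges(merged, batch.nbrs, r)
            lparam = 0
            for _ in range(self.backbone_cfg.n_layers):
                if self.celli is not None and lparam == self.placement and charges is None:
                    x, u_coul, charges, multipliers = self.celli.forward(
                        x, positions, batch.codes, batch.nbrs, r,
                        batch.structure_of_atom, batch.total_charges,
                        batch.block_mask)
                x = bb.interaction_layer(x, batch.pair_center, batch.pair_env,
                                         layer_index=lparam)
                lparam += 1
            if self.celli is not None and charges is None:  # placement == n_layers
                x, u_coul, charges, multipliers = self.celli.forward(
                    x, positions, batch.codes, batch.nbrs, r,
                    batch.structure_of_atom, batch.total_charges,
                    batch.block_mask)
            du = bb.readout(x, r, batch.structure_of_edge, batch.n_structures)
        else:
            h = bb.embed_nodes(merged)
            lparam = 0
            for _ in range(self.backbone_cfg.n_layers):
                if self.celli is not None and lparam == self.placement and charges is None:
                    h, u_coul, charges, multipliers = self._adapter_step(
                        h, positions, batch, r)
                h = bb.message_passing_layer(h, batch.nbrs, r)
                h.layer = lparam + 1
                lparam += 1
            if self.celli is not None and charges is None:
                h, u_coul, charges, multipliers = self._adapter_step(
                    h, positions, batch, r)
            du = bb.node_readout_energy(h, batch.structure_of_atom,
                                        batch.n_structures)

        u = ad.add(u_coul, du)
        return {"u": u, "u_coul": u_coul, "du": du, "charges": charges,
                "multipliers": multipliers, "positions": positions, "r": r}

    def _adapter_step(self, nodes, positions, batch: BatchData, r):
        """MACE-style coupling: edge features (p_env(r) h_i || rbf) feed the
        block; its output aggregates as a weighted residual on the nodes."""
        from .backbone import bessel_ad, envelope_ad
        bb = self.backbone
        src = batch.nbrs.edges[:, 0]
        p = ad.reshape(envelope_ad(r, bb.env), (-1, 1))
        h_src = ad.mul(ad.gather(nodes.features, src), p)
        rbf = bessel_ad(r, bb.basis)
        x0 = EdgeLatents(ad.concatenate([h_src, rbf], axis=1),
                         layer=nodes.layer)
        x1, u_coul, charges, lam = self.celli.forward(
            x0, positions, batch.codes, batch.nbrs, r,
            batch.structure_of_atom, batch.total_charges, batch.block_mask)
        nodes = bb.node_mode_update(nodes, x1, batch.nbrs)
        return nodes, u_coul, charges, lam

    # -- public prediction -------------------------------------------------
    def predict(self, system: AtomicSystem, add_shifts: bool = False):
        """(U [eV], F [eV/A], Q [e] or None) for one open structure.

        U is on the shifted-energy scale unless ``add_shifts``; F includes
        the charge-position coupling through the Qeq solve.
        """
        batch = prepare_batch([system], self.backbone_cfg.cutoff,
                              self.backbone.species_codes)
        out = self.forward_batch(batch)
        u = float(out["u"].data[0])
        g, = ad.grad(ad.tsum(out["u"]), [out["positions"]])
        forces = -g.data
        q = None if out["charges"] is None else out["charges"].data.copy()
        if add_shifts:
            u += float(self.shifts[batch.codes].sum())
        return u, forces, q

    # -- serialization -----------------------------------------------------
    def config_dict(self) -> dict:
        return {
            "backbone": asdict(self.backbone_cfg),
            "celli": None if self.celli_cfg is None else asdict(self.celli_cfg),
            "seed": self.seed,
        }

    def save(self, path):
        state = self.store.state_dict()
        np.savez(path,
                 __config__=np.frombuffer(
                     json.dumps(self.config_dict()).encode(), dtype=np.uint8),
                 __shifts__=self.shifts,
                 **state)

    @classmethod
    def load(cls, path) -> "PotentialModel":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            bb = BackboneConfig(**{**cfg["backbone"],
                                   "species": tuple(cfg["backbone"]["species"])})
            cc = None if cfg["celli"] is None else CelliConfig(**cfg["celli"])
            model = cls(bb, cc, seed=cfg["seed"])
            state = {k: data[k] for k in data.files
                     if not k.startswith("__")}
            model.store.load_state_dict(state)
            model.shifts = data["__shifts__"].copy()
        return model


# ---------------------------------------------------------------------------
# energy shifts (ridge regression on composition)
# ---------------------------------------------------------------------------

def fit_shifts(dataset: Sequence[AtomicSystem], species: Sequence[int],
               ridge_lambda: float = 1e-8) -> np.ndarray:
    """Per-species shifts U_s minimizing sum_i (U_i - sum_s U_s N_si)^2 +
    ridge_lambda ||U_s||^2, in the ordering of ``species``."""
    species = list(species)
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    rows, y = [], []
    for s in dataset:
        if s.energy is None:
            raise ValueError("every sample needs an energy to fit shifts")
        rows.append([np.sum(s.species == z) for z in species])
        y.append(s.energy)
    n_mat = np.asarray(rows, dtype=np.float64)
    y = np.asarray(y)
    present = n_mat.sum(axis=0) > 0
    shifts = np.zeros(len(species))
    if not present.any():
        return shifts
    a = n_mat[:, present]
    ata = a.T @ a + ridge_lambda * np.eye(present.sum())
    shifts[present] = np.linalg.solve(ata, a.T @ y)
    absent = [species[k] for k in np.nonzero(~present)[0]]
    if absent:
        import warnings
        warnings.warn(f"species {absent} absent from data; shift set to 0")
    return shifts


def apply_shifts(systems: Sequence[AtomicSystem], species: Sequence[int],
                 shifts: np.ndarray, sign: float = -1.0) -> List[AtomicSystem]:
    """Return copies with energies shifted: U_hat = U - sum_s U_s N_si."""
    out = []
    zs = list(species)
    for s in systems:
        c = s.copy()
        if c.energy is not None:
            comp = np.array([np.sum(s.species == z) for z in zs], float)
            c.energy = c.energy + sign * float(comp @ shifts)
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# loss and training
# ---------------------------------------------------------------------------

def _batch_labels(batch: BatchData, weights: LossWeights):
    need_u = weights.gamma_U > 0
    need_f = weights.gamma_F > 0
    need_q = weights.gamma_Q > 0
    for k, s in enumerate(batch.systems):
        if need_u and s.energy is None:
            raise ValueError(f"sample {k} lacks an energy label")
        if need_f and s.forces is None:
            raise ValueError(f"sample {k} lacks force labels")
        if need_q and s.charges is None:
            raise ValueError(f"sample {k} lacks charge labels")
    u_ref = np.array([s.energy if s.energy is not None else 0.0
                      for s in batch.systems])
    f_ref = (np.concatenate([s.forces for s in batch.systems], axis=0)
             if need_f else None)
    q_ref = (np.concatenate([s.charges for s in batch.systems])
             if need_q else None)
    return u_ref, f_ref, q_ref


def loss(model: PotentialModel, batch, weights: LossWeights,
         denominator: Optional[int] = None) -> ad.Tensor:
    """Force-matching loss with per-sample normalizations

    (1/D) sum_i [ g_U |U - U^|^2 + g_F/(3 N_i) |F - F^|^2
                  + g_Q/N_i |Q - Q^|^2 ].
    """
    if not isinstance(batch, BatchData):
        batch = prepare_batch(batch, model.backbone_cfg.cutoff,
                              model.backbone.species_codes)
    u_ref, f_ref, q_ref = _batch_labels(batch, weights)
    d = batch.n_structures if denominator is None else int(denominator)
    out = model.forward_batch(batch)

    total = ad.constant(0.0)
    if weights.gamma_U > 0:
        du = ad.sub(out["u"], ad.constant(u_ref))
        total = ad.add(total, ad.mul(weights.gamma_U / d,
                                     ad.tsum(ad.mul(du, du))))
    if weights.gamma_F > 0:
        g, = ad.grad(ad.tsum(out["u"]), [out["positions"]], create_graph=True)
        df = ad.sub(ad.neg(g), ad.constant(f_ref))
        coeff = (weights.gamma_F / (3.0 * batch.n_atoms_per[batch.structure_of_atom] * d))
        total = ad.add(total, ad.tsum(
            ad.mul(ad.tsum(ad.mul(df, df), axis=1), ad.constant(coeff))))
    if weights.gamma_Q > 0:
        if out["charges"] is None:
            raise ValueError(
                "charge supervision requested but the model predicts no charges")
        dq = ad.sub(out["charges"], ad.constant(q_ref))
        coeff = weights.gamma_Q / (batch.n_atoms_per[batch.structure_of_atom] * d)
        total = ad.add(total, ad.tsum(ad.mul(ad.mul(dq, dq), ad.constant(coeff))))
    return total


class _Adam:
    def __init__(self, params, lr, weight_decay, clip):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.clip = clip
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads, lr):
        gn = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
        scale = min(1.0, self.clip / max(gn, 1e-300))
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g * scale
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= lr * ((m / c1) / (np.sqrt(v / c2) + self.eps)
                            + self.wd * p.data)


def _val_metrics(model: PotentialModel, batches, weights: LossWeights):
    """Validation loss and headline metrics from a single forward per batch."""
    tot_loss, n = 0.0, 0
    ue, qe, fe = [], [], []
    for b in batches:
        out = model.forward_batch(b)
        u_ref, f_ref, q_ref = _batch_labels(b, weights)
        sample_loss = np.zeros(b.n_structures)
        if weights.gamma_U > 0:
            du = out["u"].data - u_ref
            sample_loss += weights.gamma_U * du * du
            ue.extend(np.abs(du) / b.n_atoms_per)
        if weights.gamma_F > 0:
            g, = ad.grad(ad.tsum(out["u"]), [out["positions"]])
            df = -g.data - f_ref
            per_atom = np.sum(df * df, axis=1)
            sums = np.bincount(b.structure_of_atom, weights=per_atom,
                               minlength=b.n_structures)
            sample_loss += weights.gamma_F / (3.0 * b.n_atoms_per) * sums
            fe.extend(df.ravel())
        if weights.gamma_Q > 0 and out["charges"] is not None:
            dq = out["charges"].data - q_ref
            sums = np.bincount(b.structure_of_atom, weights=dq * dq,
                               minlength=b.n_structures)
            sample_loss += weights.gamma_Q / b.n_atoms_per * sums
            qe.extend(dq * dq)
        tot_loss += float(sample_loss.sum())
        n += b.n_structures
    metrics = {"val_loss": tot_loss / max(n, 1)}
    if ue:
        metrics["val_u_mae_mev_atom"] = 1e3 * float(np.mean(ue))
    if fe:
        metrics["val_f_mae_mev_a"] = 1e3 * float(np.mean(np.abs(fe)))
    if qe:
        metrics["val_q_rmse_me"] = 1e3 * float(np.sqrt(np.mean(qe)))
    return metrics


def train(model: PotentialModel, train_set: Sequence[AtomicSystem],
          val_set: Sequence[AtomicSystem], weights: LossWeights,
          schedule: TrainSchedule, seed: int = 0):
    """Minibatch Adam training; returns (model_at_best_val, history).

    Graph topology per batch is prepared once and reused across epochs
    (batch membership is fixed, visiting order is shuffled per epoch).
    """
    rng = np.random.default_rng(seed)
    cutoff = model.backbone_cfg.cutoff
    codes_fn = model.backbone.species_codes
    order = rng.permutation(len(train_set))
    bs = schedule.batch_size
    batches = [prepare_batch([train_set[i] for i in order[k:k + bs]],
                             cutoff, codes_fn)
               for k in range(0, len(order), bs)]
    val_batches = [prepare_batch(val_set[k:k + bs], cutoff, codes_fn)
                   for k in range(0, len(val_set), bs)] if len(val_set) else []

    params = model.store.tensors()
    opt = _Adam(params, schedule.learning_rate, schedule.weight_decay,
                schedule.clip_norm)
    ema = None
    if schedule.ema_decay > 0:
        ema = {k: v.copy() for k, v in model.store.state_dict().items()}
    history = []
    best = {"val_loss": np.inf, "state": model.store.state_dict(), "epoch": -1}
    total_steps = max(schedule.epochs * len(batches), 1)
    step = 0
    names = model.store.names()
    for epoch in range(schedule.epochs):
        ep_loss = 0.0
        for bi in rng.permutation(len(batches)):
            b = batches[bi]
            lv = loss(model, b, weights)
            if not np.isfinite(lv.data):
                raise RuntimeError(f"NaN/Inf loss at step {step}")
            grads = [g.data for g in ad.grad(lv, params)]
            frac = 1.0 - step / total_steps
            lr = schedule.learning_rate * (
                schedule.final_lr_fraction
                + (1 - schedule.final_lr_fraction) * frac ** schedule.kappa)
            opt.step(grads, lr)
            if ema is not None:
                d = schedule.ema_decay
                for name, p in zip(names, params):
                    ema[name] *= d
                    ema[name] += (1 - d) * p.data
            ep_loss += float(lv.data) * b.n_structures
            step += 1
        rec = {"epoch": epoch, "train_loss": ep_loss / max(len(train_set), 1)}
        if val_batches:
            # validate (and select) the averaged weights when EMA is on
            raw = None
            if ema is not None:
                raw = model.store.state_dict()
                model.store.load_state_dict(ema)
            rec.update(_val_metrics(model, val_batches, weights))
            if rec["val_loss"] < best["val_loss"]:
                best = {"val_loss": rec["val_loss"],
                        "state": model.store.state_dict(), "epoch": epoch}
            if raw is not None:
                model.store.load_state_dict(raw)
        history.append(rec)
    if val_batches and best["epoch"] >= 0:
        model.store.load_state_dict(best["state"])
    elif ema is not None:
        model.store.load_state_dict(ema)
    return model, history
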