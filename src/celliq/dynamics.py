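"""Langevin-thermostat molecular dynamics with stability diagnostics.

BAOAB splitting of Langevin dynamics: half-kick, half-drift, exact
Ornstein-Uhlenbeck velocity update, half-drift, half-kick. With zero
friction and zero temperature it reduces exactly to velocity Verlet.
Units: fs, Angstrom, eV, amu; friction is given in 1/ps as is customary.

Several independent systems can be propagated jointly (`simulate_ensemble`),
sharing one batched force evaluation per step — they remain physically
non-interacting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from . import autodiff as ad
from .model import PotentialModel, prepare_batch
from .periodic_table import atomic_mass, covalent_radius
from .systems import AtomicSystem
from .units import FORCE_TO_ACC, K_B

__all__ = ["MDConfig", "StabilityReport", "simulate", "simulate_ensemble",
           "stability_check"]


@dataclass
class MDConfig:
    dt: float = 0.5            # fs
    temperature: float = 300.0  # K
    friction: float = 100.0     # 1/ps
    n_steps: int = 1000
    seed: int = 0
    report_every: int = 100

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature < 0 or self.friction < 0:
            raise ValueError("temperature and friction must be >= 0")


@dataclass
class StabilityReport:
    """Whole-trajectory diagnostics (tracked every step, not only at
    reported frames)."""

    min_distance_seen: float = math.inf     # A
    max_bond_stretch_ratio: float = 0.0     # vs initial bonded distances
    any_nonfinite: bool = False
    nonfinite_step: int = -1
    temperature_trace: list = field(default_factory=list)  # K, per report
    energy_trace: list = field(default_factory=list)       # U + KE [eV], per report


def _initial_bonds(system: AtomicSystem, factor: float = 1.25):
    """Bonded pairs: initial distance within ``factor`` x covalent-radius sum."""
    pos = system.positions
    n = len(system)
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            rc = factor * (covalent_radius(int(system.species[i]))
                           + covalent_radius(int(system.species[j])))
            # ionic A-B contacts sit beyond the covalent sum; widen modestly
            rc = max(rc, 2.6)
            r = np.linalg.norm(pos[j] - pos[i])
            if r < rc:
                bonds.append((i, j, r))
    return bonds


class _ForceProvider:
    """Batched force/energy evaluation for an ensemble of open systems."""

    def __init__(self, model, systems: Sequence[AtomicSystem]):
        self.model = model
        self.template = [s.copy() for s in systems]
        self.n_per = [len(s) for s in systems]

    def __call__(self, positions: np.ndarray):
        if isinstance(self.model, PotentialModel):
            off = 0
            for s in self.template:
                s.positions = positions[off:off + len(s)]
                off += len(s)
            batch = prepare_batch(self.template, self.model.backbone_cfg.cutoff,
                                  self.model.backbone.species_codes)
            out = self.model.forward_batch(batch)
            g, = ad.grad(ad.tsum(out["u"]), [out["positions"]])
            return float(out["u"].data.sum()), -g.data
        # generic object with .predict(system) -> (U, F, ...)
        us, fs = 0.0, []
        off = 0
        for s in self.template:
            s.positions = positions[off:off + len(s)]
            off += len(s)
            res = self.model.predict(s)
            us += res[0]
            fs.append(res[1])
        return us, np.concatenate(fs, axis=0)


def simulate_ensemble(model, systems: Sequence[AtomicSystem], cfg: MDConfig):
    """Joint BAOAB propagation of independent systems.

    Returns (trajectories, reports): per input system, a list of frames
    written every ``report_every`` steps (initial frame included) and a
    `StabilityReport` over every step.
    """
    systems = [s.copy() for s in systems]
    for s in systems:
        if s.is_periodic:
            raise NotImplementedError("MD supports open systems")
    n_per = [len(s) for s in systems]
    offsets = np.cumsum([0] + n_per)
    pos = np.concatenate([s.positions for s in systems], axis=0)
    masses = np.array([atomic_mass(int(z)) for s in systems for z in s.species])
    m = masses[:, None]
    rng = np.random.default_rng(cfg.seed)

    gamma_fs = cfg.friction * 1e-3
    c1 = math.exp(-gamma_fs * cfg.dt)
    sigma_v2 = K_B * cfg.temperature * FORCE_TO_ACC / masses   # (A/fs)^2
    c2 = np.sqrt((1.0 - c1 * c1) * sigma_v2)[:, None]

    vel = np.zeros_like(pos)
    if cfg.temperature > 0:
        vel = rng.normal(size=pos.shape) * np.sqrt(sigma_v2)[:, None]

    force_fn = _ForceProvider(model, systems)
    bonds = [_initial_bonds(s) for s in systems]
    reports = [StabilityReport() for _ in systems]
    trajectories: List[List[AtomicSystem]] = [[] for _ in systems]

    def snapshot(k):
        for si, s in enumerate(systems):
            frame = s.copy()
            frame.positions = pos[offsets[si]:offsets[si + 1]].copy()
            frame.info = {**frame.info, "step": float(k)}
            trajectories[si].append(frame)

    def track(step):
        for si, rep in enumerate(reports):
            p = pos[offsets[si]:offsets[si + 1]]
            if len(p) > 1:
                d = np.linalg.norm(p[None] - p[:, None], axis=-1)
                np.fill_diagonal(d, np.inf)
                rep.min_distance_seen = min(rep.min_distance_seen, float(d.min()))
            for (i, j, r0) in bonds[si]:
                r = float(np.linalg.norm(p[j] - p[i]))
                rep.max_bond_stretch_ratio = max(rep.max_bond_stretch_ratio,
                                                 r / r0)
            if not np.isfinite(p).all() and not rep.any_nonfinite:
                rep.any_nonfinite = True
                rep.nonfinite_step = step

    def record_traces(u_total):
        # per-system potential energy is not separable from a batched total;
        # record the ensemble-total energy on each report and the per-system
        # kinetic temperature
        for si, rep in enumerate(reports):
            sl = slice(offsets[si], offsets[si + 1])
            ke = 0.5 * np.sum(masses[sl] * np.sum(vel[sl] ** 2, axis=1))
            t_kin = 2.0 * ke / (3.0 * n_per[si] * K_B * FORCE_TO_ACC)
            rep.temperature_trace.append(float(t_kin))
        ke_all = 0.5 * np.sum(masses[:, None] * vel ** 2) / FORCE_TO_ACC
        for rep in reports:
            rep.energy_trace.append(float(u_total + ke_all))

    u, forces = force_fn(pos)
    snapshot(0)
    track(0)
    record_traces(u)
    half = 0.5 * cfg.dt
    for step in range(1, cfg.n_steps + 1):
        vel += half * forces / m * FORCE_TO_ACC
        pos += half * vel
        if cfg.friction > 0:
            vel = c1 * vel + c2 * rng.normal(size=vel.shape)
        pos += half * vel
        u, forces = force_fn(pos)
        if not np.isfinite(forces).all() or not math.isfinite(u):
            for rep in reports:
                if not rep.any_nonfinite:
                    rep.any_nonfinite = True
                    rep.nonfinite_step = step
            track(step)
            snapshot(step)
            break
        vel += half * forces / m * FORCE_TO_ACC
        track(step)
        if step % cfg.report_every == 0:
            snapshot(step)
            record_traces(u)
    return trajectories, reports


def simulate(model, system: AtomicSystem, cfg: MDConfig):
    """Single-system wrapper around `simulate_ensemble`."""
    trajs, reports = simulate_ensemble(model, [system], cfg)
    return trajs[0], reports[0]


def stability_check(trajectory: Sequence[AtomicSystem],
                    min_distance: float = 0.5,
                    max_stretch: float = 2.0,
                    report: StabilityReport = None):
    """(passed, reasons): fail on overlap, broken bonds, or non-finite values.

    When a `StabilityReport` is given its whole-trajectory extrema are
    checked; otherwise the provided frames are scanned.
    """
    if not trajectory and report is None:
        raise ValueError("empty trajectory")
    reasons = []
    if report is not None:
        if report.any_nonfinite:
            reasons.append(f"non-finite value at step {report.nonfinite_step}")
        if report.min_distance_seen < min_distance:
            reasons.append(
                f"overlap: min distance {report.min_distance_seen:.3f} A")
        if report.max_bond_stretch_ratio > max_stretch:
            reasons.append(
                f"broken bond: stretch ratio {report.max_bond_stretch_ratio:.2f}")
        return (not reasons), reasons

    bonds = _initial_bonds(trajectory[0])
    for k, frame in enumerate(trajectory):
        p = frame.positions
        if not np.isfinite(p).all():
            reasons.append(f"non-finite positions at frame {k}")
            continue
        if len(p) > 1:
            d = np.linalg.norm(p[None] - p[:, None], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < min_distance:
                reasons.append(f"overlap at frame {k}: {d.min():.3f} A")
        for (i, j, r0) in bonds:
            r = float(np.linalg.norm(p[j] - p[i]))
            if r / r0 > max_stretch:
                reasons.append(
                    f"broken bond {i}-{j} at frame {k}: ratio {r / r0:.2f}")
    return (not reasons), reasons
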