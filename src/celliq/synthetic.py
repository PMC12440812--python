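"""Exact synthetic ground truth for training and benchmarking.

A fixed-parameter charge-equilibration reference model (per-species
electronegativity, hardness and Gaussian radius) plus an envelope-damped
Morse pair potential labels generated structures with energies, forces and
equilibrated partial charges — an analytically differentiable stand-in for
quantum-mechanical reference data. Geometry families mirror classic
charge-transfer benchmarks: two-species chains, rock-salt-like ionic
clusters in two total-charge states (geometry-identical "twins"), and
single-atom displacement scans.

Species are fictitious "A" and "B" mapped to Z = 11 and Z = 17 so that
covalent-radius and mass lookups work without relying on any real element's
chemistry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .backbone import EnvelopePolynomial, envelope
from .electrostatics import GaussianChargeSpec, coulomb_operator
from .extxyz import write_extxyz
from .qeq import QeqError, QeqParameters, solve_qeq
from .systems import AtomicSystem, build_neighbor_list
from .units import K_E, SQRT_PI

__all__ = ["ReferenceModel", "default_reference", "generate_structures",
           "label", "make_benchmark_suite"]

SPECIES_A = 11
SPECIES_B = 17
_MIN_DIST = 0.7  # A; below this a generated geometry is rejected


@dataclass
class ReferenceModel:
    """Ground-truth generator: Qeq parameters + Morse short-range pairs.

    ``morse`` maps unordered species pairs to (D_e [eV], a [1/A], r_e [A]).
    The pair term is damped by the polynomial envelope at ``cutoff`` so the
    reference potential lives exactly inside a finite-cutoff model family.
    """

    chi: dict
    hardness: dict
    radii: dict
    morse: dict
    cutoff: float = 4.5
    envelope_p: int = 6
    noise_sigma_u: float = 0.0
    noise_sigma_f: float = 0.0
    noise_sigma_q: float = 0.0

    def __post_init__(self):
        if any(v <= 0 for v in self.hardness.values()):
            raise ValueError("reference hardnesses must be positive")
        if any(v <= 0 for v in self.radii.values()):
            raise ValueError("reference radii must be positive")
        self.env = EnvelopePolynomial(self.envelope_p, self.cutoff)

    # -- parameter vectors -------------------------------------------------
    def qeq_parameters(self, system: AtomicSystem) -> QeqParameters:
        z = system.species
        return QeqParameters(
            chi=np.array([self.chi[int(s)] for s in z]),
            hardness=np.array([self.hardness[int(s)] for s in z]),
            radii=np.array([self.radii[int(s)] for s in z]),
            total_charge=system.total_charge)

    def _morse_params(self, zi: int, zj: int):
        key = (zi, zj) if (zi, zj) in self.morse else (zj, zi)
        return self.morse[key]

    # -- short-range pair term ---------------------------------------------
    def pair_energy_forces(self, system: AtomicSystem):
        nl = build_neighbor_list(system, self.cutoff)
        u = 0.0
        f = np.zeros_like(system.positions)
        half = nl.edges[:, 0] < nl.edges[:, 1]
        for (i, j), d, r in zip(nl.edges[half], nl.displacements[half],
                                nl.distances[half]):
            de, a, re = self._morse_params(int(system.species[i]),
                                           int(system.species[j]))
            ex = np.exp(-a * (r - re))
            morse = de * (1.0 - ex) ** 2 - de
            dmorse = 2.0 * a * de * (1.0 - ex) * ex
            p = envelope(r, self.env)
            dp = _envelope_derivative(r, self.env)
            u += morse * p
            dv = dmorse * p + morse * dp            # dV/dr
            rhat = d / r
            f[i] += dv * rhat                        # F_i = -dU/dR_i
            f[j] -= dv * rhat
        return u, f

    # -- electrostatic forces at fixed Q ------------------------------------
    @staticmethod
    def _coulomb_forces(system: AtomicSystem, q: np.ndarray,
                        radii: np.ndarray) -> np.ndarray:
        pos = system.positions
        n = len(system)
        d = pos[None, :, :] - pos[:, None, :]
        r = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(r, 1.0)
        g2 = radii ** 2
        a = 1.0 / (np.sqrt(2.0) * np.sqrt(g2[None] + g2[:, None]))
        from scipy.special import erf
        dphi = (2.0 * a / SQRT_PI * np.exp(-(a * r) ** 2) - erf(a * r) / r) / r
        np.fill_diagonal(dphi, 0.0)
        rhat = d / r[:, :, None]
        # dU/dR_j = k_e sum_i Q_i Q_j phi'(r_ij) rhat_ij
        grad = K_E * np.einsum("i,j,ij,ijx->jx", q, q, dphi, rhat)
        return -grad

    def predict(self, system: AtomicSystem):
        """(U [eV], F [eV/A], Q [e]) — exact labels, no noise.

        The charge-response term in dU/dR vanishes at the constrained
        optimum (dU/dQ is constant on the constraint surface and the total
        charge is fixed), so forces are evaluated with Q held at the solve.
        """
        params = self.qeq_parameters(system)
        spec = GaussianChargeSpec(params.radii)
        op = coulomb_operator(system, spec)
        sol = solve_qeq(params, op)
        u_pair, f_pair = self.pair_energy_forces(system)
        u = sol.energy_qeq + u_pair
        f = self._coulomb_forces(system, sol.charges, params.radii) + f_pair
        return u, f, sol.charges


def _envelope_derivative(r: float, env: EnvelopePolynomial) -> float:
    p, rc = env.p, env.cutoff
    u = r / rc
    if u >= 1.0:
        return 0.0
    c0 = -(p + 1) * (p + 2) / 2.0
    c1 = float(p * (p + 2))
    c2 = -p * (p + 1) / 2.0
    return (c0 * p * u ** (p - 1) + c1 * (p + 1) * u ** p
            + c2 * (p + 2) * u ** (p + 1)) / rc


def default_reference() -> ReferenceModel:
    """Shipped reference parameters for the fictitious A/B species.

    chi contrast drives A -> B charge transfer (~0.1-0.2 e per atom);
    hardnesses and radii are typical atomic magnitudes, with radii equal to
    the tabulated covalent radii of the mapped elements.
    """
    return ReferenceModel(
        chi={SPECIES_A: 2.0, SPECIES_B: 6.0},
        hardness={SPECIES_A: 8.0, SPECIES_B: 10.0},
        radii={SPECIES_A: 1.55, SPECIES_B: 0.99},
        morse={
            (SPECIES_A, SPECIES_B): (1.2, 1.7, 2.4),
            (SPECIES_A, SPECIES_A): (0.15, 1.2, 3.4),
            (SPECIES_B, SPECIES_B): (0.15, 1.2, 3.8),
        },
        cutoff=4.5)


# ---------------------------------------------------------------------------
# geometry recipes
# ---------------------------------------------------------------------------

_ROCKSALT_A = 2.4  # A, nearest-neighbor spacing of the cluster lattice


def _min_pair_distance(pos: np.ndarray) -> float:
    if len(pos) < 2:
        return np.inf
    d = np.linalg.norm(pos[None] - pos[:, None], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def _jitter(pos, rng, sigma=0.08):
    return pos + rng.normal(scale=sigma, size=pos.shape)


def _chain(rng, n_atoms: int) -> Tuple[np.ndarray, np.ndarray]:
    bond = 2.3
    x = np.cumsum(np.concatenate([[0.0], bond + rng.normal(0, 0.08, n_atoms - 1)]))
    pos = np.zeros((n_atoms, 3))
    pos[:, 0] = x
    pos[:, 1:] = rng.normal(0, 0.05, (n_atoms, 2))
    species = np.where(np.arange(n_atoms) % 2 == 0, SPECIES_A, SPECIES_B)
    return species, pos


def _rocksalt_cube() -> Tuple[np.ndarray, np.ndarray]:
    frac = np.array([[i, j, k] for i in range(2) for j in range(2)
                     for k in range(2)], float)
    species = np.where(frac.sum(axis=1) % 2 == 0, SPECIES_A, SPECIES_B)
    return species, frac * _ROCKSALT_A


def _cluster(rng, variant: str):
    species, pos = _rocksalt_cube()
    if variant == "vacancy":        # remove one B atom -> A4 B3
        bidx = np.nonzero(species == SPECIES_B)[0]
        drop = bidx[rng.integers(len(bidx))]
        keep = np.arange(len(species)) != drop
        species, pos = species[keep], pos[keep]
    elif variant == "extra_cation":  # add an A atom on a face -> A5 B4
        extra = np.array([[_ROCKSALT_A / 2, _ROCKSALT_A / 2, -_ROCKSALT_A * 0.8]])
        species = np.concatenate([species, [SPECIES_A]])
        pos = np.concatenate([pos, extra], axis=0)
    elif variant != "cube":
        raise ValueError(f"unknown cluster variant {variant!r}")
    return species, pos


def generate_structures(recipe: str, n: int,
                        size_range: Tuple[int, int] = (4, 8),
                        seed: int = 0,
                        charge_states: Sequence[float] = (0.0, 1.0),
                        max_retries: int = 20) -> List[AtomicSystem]:
    """Unlabeled structures from a named geometry family.

    ``chain``: alternating A-B chains with jittered bond lengths, atom count
    uniform in ``size_range``. ``ionic_cluster``: jittered rock-salt
    fragments (cube / B-vacancy / extra-A variants), each geometry emitted
    in the listed total-charge states with matching ``pair`` metadata
    ("twins"). ``dimer_scan``: the extra-A cluster with the extra atom moved
    along its approach axis, all else fixed.
    """
    rng = np.random.default_rng(seed)
    out: List[AtomicSystem] = []

    if recipe == "chain":
        while len(out) < n:
            for _ in range(max_retries):
                n_atoms = int(rng.integers(size_range[0], size_range[1] + 1))
                species, pos = _chain(rng, n_atoms)
                if _min_pair_distance(pos) >= _MIN_DIST:
                    break
            else:
                raise RuntimeError("could not draw a non-overlapping chain")
            qtot = float(rng.choice(charge_states))
            out.append(AtomicSystem(species=species, positions=pos,
                                    total_charge=qtot))
    elif recipe == "ionic_cluster":
        variants = ["cube", "vacancy", "extra_cation"]
        pair_id = 0
        while len(out) < n:
            variant = variants[rng.integers(3)]
            for _ in range(max_retries):
                species, base = _cluster(rng, variant)
                pos = _jitter(base, rng)
                if _min_pair_distance(pos) >= _MIN_DIST:
                    break
            else:
                raise RuntimeError("could not draw a non-overlapping cluster")
            for q in charge_states:
                if len(out) >= n:
                    break
                out.append(AtomicSystem(
                    species=species.copy(), positions=pos.copy(),
                    total_charge=float(q),
                    info={"variant": variant, "pair": float(pair_id)}))
            pair_id += 1
    elif recipe == "dimer_scan":
        species, base = _cluster(rng, "extra_cation")
        dists = np.linspace(1.6, 4.2, max(n // len(charge_states), 1))
        for d in dists:
            pos = base.copy()
            pos[-1, 2] = -d                      # extra atom along its axis
            for q in charge_states:
                out.append(AtomicSystem(
                    species=species.copy(), positions=pos.copy(),
                    total_charge=float(q), info={"scan_d": float(d)}))
        out = out[:n] if n else out
    else:
        raise ValueError(f"unknown recipe {recipe!r}")
    return out


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def label(structures: Sequence[AtomicSystem], ref: ReferenceModel,
          seed: int = 0) -> List[AtomicSystem]:
    """Attach exact (optionally noised) U, F, Q labels; structures on which
    the Qeq solve fails are dropped with a warning."""
    rng = np.random.default_rng(seed)
    out = []
    for k, s in enumerate(structures):
        try:
            u, f, q = ref.predict(s)
        except QeqError as exc:
            warnings.warn(f"dropping structure {k}: Qeq failed ({exc})")
            continue
        c = s.copy()
        noisy = (ref.noise_sigma_u or ref.noise_sigma_f or ref.noise_sigma_q)
        if noisy:
            c.info["exact_energy"] = float(u)
            u = u + rng.normal(0, ref.noise_sigma_u)
            f = f + rng.normal(0, ref.noise_sigma_f, f.shape)
            q = q + rng.normal(0, ref.noise_sigma_q, q.shape)
            q += (c.total_charge - q.sum()) / len(q)  # keep conservation
        c.energy = float(u)
        c.forces = f
        c.charges = q
        out.append(c)
    return out


def make_benchmark_suite(out_dir, seed: int = 0, n_chain: int = 1000,
                         n_cluster: int = 1000, n_twin_pairs: int = 20,
                         ref: Optional[ReferenceModel] = None) -> dict:
    """Deterministic labeled train/val/test splits plus twin and scan sets.

    Splits are 80/10/10 by a seeded shuffle. ``twins_test.extxyz`` holds
    geometry-identical charge-state pairs (pairable by the ``pair`` key);
    ``scan_test.extxyz`` is a single-atom displacement path.
    """
    ref = default_reference() if ref is None else ref
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    pool = (generate_structures("chain", n_chain, seed=int(rng.integers(2**31)))
            + generate_structures("ionic_cluster", n_cluster,
                                  seed=int(rng.integers(2**31))))
    pool = label(pool, ref, seed=int(rng.integers(2**31)))
    order = rng.permutation(len(pool))
    n_train = int(0.8 * len(pool))
    n_val = int(0.1 * len(pool))
    splits = {
        "train": [pool[i] for i in order[:n_train]],
        "val": [pool[i] for i in order[n_train:n_train + n_val]],
        "test": [pool[i] for i in order[n_train + n_val:]],
    }
    paths = {}
    for name, systems in splits.items():
        p = out_dir / f"{name}.extxyz"
        write_extxyz(systems, p)
        paths[name] = p

    twins = label(generate_structures("ionic_cluster", 2 * n_twin_pairs,
                                      seed=seed + 101), ref, seed=0)
    p = out_dir / "twins_test.extxyz"
    write_extxyz(twins, p)
    paths["twins_test"] = p

    scan = label(generate_structures("dimer_scan", 0, seed=seed + 202), ref,
                 seed=0)
    p = out_dir / "scan_test.extxyz"
    write_extxyz(scan, p)
    paths["scan_test"] = p
    return paths
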