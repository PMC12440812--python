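"""Charge equilibration (Qeq).

The charge energy

    U_Qeq(Q) = U_Coul(Q) + sum_i [ chi_i Q_i + J_i/2 Q_i^2 ]

is quadratic; its minimizer under the conservation constraint
``sum_i Q_i = Q_tot`` solves the bordered KKT system

    [ M + diag(J)   1 ] [ Q      ]   [ -chi  ]
    [ 1^T           0 ] [ lambda ] = [ Q_tot ],

where M is the Coulomb charge-space matrix (`CoulombOperator`). A dense
direct solve is the default; `brute_force_qeq` is an independent
constraint-eliminated gradient-descent oracle, and `qeq_jacobians` exposes
the implicit-function sensitivities dQ/dchi, dQ/dJ, dQ/dR needed when
equilibrated charges feed a downstream learned embedding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf as np_erf

from . import autodiff as ad
from .electrostatics import CoulombOperator
from .units import K_E, SQRT_PI

__all__ = [
    "QeqParameters", "QeqSolution", "qeq_energy", "solve_qeq",
    "brute_force_qeq", "qeq_jacobians", "solve_qeq_ad", "QeqError",
]


class QeqError(RuntimeError):
    """Charge-equilibration solve failure (singular or indefinite system)."""


@dataclass
class QeqParameters:
    """Per-atom electronegativity chi [eV/e], hardness J [eV/e^2],
    Gaussian radius gamma [A], and the total charge Q_tot [e]."""

    chi: np.ndarray
    hardness: np.ndarray
    radii: np.ndarray
    total_charge: float = 0.0

    def __post_init__(self):
        self.chi = np.asarray(self.chi, dtype=np.float64).ravel()
        self.hardness = np.asarray(self.hardness, dtype=np.float64).ravel()
        self.radii = np.asarray(self.radii, dtype=np.float64).ravel()
        if not (len(self.chi) == len(self.hardness) == len(self.radii)):
            raise ValueError("chi, hardness and radii must have equal length")
        if np.any(self.hardness <= 0):
            raise ValueError("hardness must be strictly positive")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be strictly positive")
        self.total_charge = float(self.total_charge)

    def __len__(self):
        return len(self.chi)


@dataclass
class QeqSolution:
    """Equilibrated charges plus energies and the KKT multiplier.

    ``multiplier`` is the constraint dual: the negative of the equalized
    electronegativity of the system.
    """

    charges: np.ndarray
    energy_coul: float
    energy_qeq: float
    multiplier: float


def qeq_energy(params: QeqParameters, charges, op: CoulombOperator) -> float:
    """U_Coul + sum_i [chi_i Q_i + J_i/2 Q_i^2]."""
    q = np.asarray(charges, dtype=np.float64).ravel()
    if len(q) != len(params):
        raise ValueError("charge vector length mismatch")
    return op.energy(q) + float(params.chi @ q + 0.5 * params.hardness @ (q * q))


def _kkt(params: QeqParameters, op: CoulombOperator):
    n = len(params)
    if op.matrix.shape != (n, n):
        raise ValueError("operator built for a different atom count")
    a = op.matrix + np.diag(params.hardness)
    k = np.zeros((n + 1, n + 1))
    k[:n, :n] = a
    k[:n, n] = 1.0
    k[n, :n] = 1.0
    rhs = np.concatenate([-params.chi, [params.total_charge]])
    return a, k, rhs


def solve_qeq(params: QeqParameters, op: CoulombOperator) -> QeqSolution:
    """Unique constrained minimizer via the dense bordered KKT solve."""
    if np.any(~np.isfinite(params.chi)) or np.any(~np.isfinite(op.matrix)):
        raise QeqError("non-finite inputs to the Qeq solve")
    n = len(params)
    a, k, rhs = _kkt(params, op)
    try:
        z = np.linalg.solve(k, rhs)
    except np.linalg.LinAlgError as exc:
        ev = float(np.linalg.eigvalsh(a).min())
        raise QeqError(
            f"singular KKT system (smallest eigenvalue of M+diag(J): {ev:.3e})"
        ) from exc
    resid = np.linalg.norm(k @ z - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if not np.isfinite(resid) or resid > 1e-8:
        ev = float(np.linalg.eigvalsh(a).min())
        raise QeqError(
            f"ill-conditioned KKT solve (relative residual {resid:.3e}, "
            f"smallest eigenvalue of M+diag(J): {ev:.3e})")
    q, lam = z[:n], float(z[n])
    u_coul = op.energy(q)
    return QeqSolution(
        charges=q,
        energy_coul=u_coul,
        energy_qeq=u_coul + float(params.chi @ q + 0.5 * params.hardness @ (q * q)),
        multiplier=lam,
    )


def brute_force_qeq(params: QeqParameters, op: CoulombOperator,
                    steps: int = 200_000, tolerance: float = 1e-12) -> np.ndarray:
    """Oracle: eliminate the constraint and run steepest descent.

    Parameterizes ``Q_N = Q_tot - sum_{i<N} Q_i`` and minimizes the reduced
    unconstrained quadratic with exact (Cauchy) step sizes until the reduced
    gradient norm falls below ``tolerance``. Independent of the KKT path.
    """
    n = len(params)
    if n > 50:
        raise ValueError("brute-force oracle is restricted to N <= 50")
    a, _, _ = _kkt(params, op)
    chi, qtot = params.chi, params.total_charge
    if n == 1:
        return np.array([qtot])

    # reduced quadratic: Q = T y + e, T = [I; -1^T], e = (0,...,0,Q_tot)
    t = np.vstack([np.eye(n - 1), -np.ones(n - 1)])
    e = np.zeros(n)
    e[-1] = qtot
    h = t.T @ a @ t                       # reduced Hessian
    b = t.T @ (a @ e + chi)               # reduced linear term
    y = np.zeros(n - 1)
    for _ in range(steps):
        grad = h @ y + b
        gn = np.linalg.norm(grad)
        if gn < tolerance:
            return t @ y + e
        hg = h @ grad
        step = gn * gn / float(grad @ hg)
        y -= step * grad
    raise QeqError(
        f"brute-force descent did not reach tolerance {tolerance} in {steps} steps")


def _dm_dr(positions: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """dM_ij/dR_a for the open-boundary screened-Coulomb matrix.

    Returns an (N, N, N, 3) array; only a in {i, j} is nonzero.
    """
    n = len(radii)
    pos = positions
    d = pos[None, :, :] - pos[:, None, :]
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, 1.0)
    g2 = radii ** 2
    a_ij = 1.0 / (math.sqrt(2.0) * np.sqrt(g2[None] + g2[:, None]))
    # d/dr [erf(ar)/r] = (2a/sqrt(pi) exp(-a^2 r^2) - erf(ar)/r) / r
    dphi = (2.0 * a_ij / SQRT_PI * np.exp(-(a_ij * r) ** 2)
            - np_erf(a_ij * r) / r) / r
    np.fill_diagonal(dphi, 0.0)
    rhat = d / r[:, :, None]
    grad_ij = K_E * dphi[:, :, None] * rhat        # dM_ij/dR_j
    out = np.zeros((n, n, n, 3))
    idx = np.arange(n)
    out[:, idx, idx, :] += grad_ij                 # a == j
    out[idx, :, idx, :] -= grad_ij                 # a == i
    return out


def qeq_jacobians(params: QeqParameters, op: CoulombOperator,
                  positions: np.ndarray = None) -> dict:
    """Implicit-function sensitivities of the equilibrated charges.

    Returns ``dq_dchi`` (N, N), ``dq_dJ`` (N, N) and, when open-boundary
    ``positions`` are given, ``dq_dR`` (N, N, 3) with entry [i, a, :] =
    dQ_i/dR_a. Differentiates the bordered KKT system around the solution.
    """
    n = len(params)
    sol = solve_qeq(params, op)
    _, k, _ = _kkt(params, op)
    kinv = np.linalg.inv(k)
    kq = kinv[:n, :n]

    dq_dchi = -kq                                   # rhs perturbation
    # dA = E_aa  =>  dz = -K^{-1} dK z ; (dK z)_i = delta_ia Q_a
    dq_dJ = -kq * sol.charges[None, :]

    out = {"dq_dchi": dq_dchi, "dq_dJ": dq_dJ, "solution": sol}
    if positions is not None:
        if op.boundary != "open":
            raise NotImplementedError(
                "position sensitivities are implemented for open boundaries")
        dm = _dm_dr(np.asarray(positions, float), params.radii)  # (N,N,N,3)
        # (dK z)[:n] = dM @ Q ; dz = -K^{-1} (dK z)
        rhs = np.einsum("ijax,j->iax", dm, sol.charges)          # (N, N, 3)
        out["dq_dR"] = -np.einsum("pi,iax->pax", kq, rhs)
    return out


# ---------------------------------------------------------------------------
# autodiff route (model path)
# ---------------------------------------------------------------------------

def solve_qeq_ad(chi: ad.Tensor, hardness: ad.Tensor, matrix: ad.Tensor,
                 structure_of_atom: np.ndarray, total_charges: np.ndarray):
    """Batched differentiable Qeq solve.

    ``matrix`` is the (block-masked) Coulomb matrix of all atoms in the
    batch, ``structure_of_atom`` maps each atom to its structure index, and
    ``total_charges`` holds one Q_tot per structure. One constraint row per
    structure borders the system. Returns (charges, multipliers) as Tensors.
    """
    n = matrix.shape[0]
    s = len(total_charges)
    c_blocks = np.zeros((n, s))
    c_blocks[np.arange(n), structure_of_atom] = 1.0

    eye = np.eye(n)
    a = ad.add(matrix, ad.mul(ad.constant(eye), ad.reshape(hardness, (1, n))))
    top = ad.concatenate([a, ad.constant(c_blocks)], axis=1)
    bottom = ad.concatenate(
        [ad.constant(c_blocks.T), ad.constant(np.zeros((s, s)))], axis=1)
    kkt = ad.concatenate([top, bottom], axis=0)
    rhs = ad.concatenate([ad.neg(chi), ad.constant(total_charges)], axis=0)
    z = ad.solve(kkt, rhs)
    return z[np.arange(n)], z[np.arange(n, n + s)]
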