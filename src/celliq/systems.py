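"""Atomic-structure data model and neighbor-list construction.

`AtomicSystem` carries species, Cartesian positions, an optional periodic
cell, the total charge and optional reference labels (energy, forces, partial
charges). `build_neighbor_list` produces directed edges within a cutoff for
open and fully periodic systems (minimum-image convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["AtomicSystem", "NeighborList", "build_neighbor_list"]


@dataclass
class AtomicSystem:
    """One structure: Z_i, R_i [A], optional cell [A], Q_tot [e] and labels."""

    species: np.ndarray
    positions: np.ndarray
    cell: Optional[np.ndarray] = None
    pbc: tuple = (False, False, False)
    total_charge: float = 0.0
    energy: Optional[float] = None
    forces: Optional[np.ndarray] = None
    charges: Optional[np.ndarray] = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.species = np.asarray(self.species, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        if self.species.ndim != 1:
            raise ValueError("species must be a 1-D array of atomic numbers")
        if np.any(self.species < 1):
            raise ValueError("atomic numbers must be >= 1")
        n = len(self.species)
        if len(self.positions) != n:
            raise ValueError(
                f"positions ({len(self.positions)}) and species ({n}) disagree")
        self.pbc = tuple(bool(p) for p in self.pbc)
        if len(self.pbc) != 3:
            raise ValueError("pbc must have three flags")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=np.float64).reshape(3, 3)
        if any(self.pbc):
            if self.cell is None:
                raise ValueError("periodic system requires a cell")
            if abs(np.linalg.det(self.cell)) <= 1e-12:
                raise ValueError("cell is singular (|det| ~ 0)")
        self.total_charge = float(self.total_charge)
        if self.energy is not None:
            self.energy = float(self.energy)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=np.float64).reshape(-1, 3)
            if len(self.forces) != n:
                raise ValueError("forces do not match atom count")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=np.float64).ravel()
            if len(self.charges) != n:
                raise ValueError("charges do not match atom count")
            if abs(self.charges.sum() - self.total_charge) > 1e-6:
                raise ValueError(
                    f"charges sum to {self.charges.sum():.8f} but total_charge "
                    f"is {self.total_charge:.8f}")

    def __len__(self) -> int:
        return len(self.species)

    @property
    def is_periodic(self) -> bool:
        return any(self.pbc)

    def copy(self) -> "AtomicSystem":
        return AtomicSystem(
            species=self.species.copy(),
            positions=self.positions.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            pbc=self.pbc,
            total_charge=self.total_charge,
            energy=self.energy,
            forces=None if self.forces is None else self.forces.copy(),
            charges=None if self.charges is None else self.charges.copy(),
            info=dict(self.info),
        )


@dataclass
class NeighborList:
    """Directed edges (i, j) with displacements R_j - R_i under minimum image."""

    edges: np.ndarray          # (E, 2) int
    displacements: np.ndarray  # (E, 3) float, R_j - R_i (+ image shift)
    distances: np.ndarray      # (E,) float
    cutoff: float
    shifts: np.ndarray = None  # (E, 3) int lattice image of atom j

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.displacements = np.asarray(self.displacements,
                                        dtype=np.float64).reshape(-1, 3)
        self.distances = np.asarray(self.distances, dtype=np.float64).ravel()
        if self.shifts is None:
            self.shifts = np.zeros((len(self.edges), 3), dtype=np.int64)

    def __len__(self) -> int:
        return len(self.edges)


def _min_cell_width(cell: np.ndarray) -> float:
    """Smallest distance between opposite cell faces."""
    vol = abs(np.linalg.det(cell))
    widths = []
    for k in range(3):
        a, b = cell[(k + 1) % 3], cell[(k + 2) % 3]
        widths.append(vol / np.linalg.norm(np.cross(a, b)))
    return min(widths)


def build_neighbor_list(system: AtomicSystem, cutoff: float) -> NeighborList:
    """All directed pairs with (minimum-image) distance strictly below cutoff.

    Edge ordering is lexicographic by (i, j); for a valid periodic cutoff at
    most one image per pair can lie inside the sphere, so (i, j) identifies
    the edge uniquely.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(system)
    pos = system.positions

    if system.is_periodic:
        if not all(system.pbc):
            raise NotImplementedError(
                "partial periodicity is not supported; use all-True pbc")
        width = _min_cell_width(system.cell)
        if cutoff > 0.5 * width:
            raise ValueError(
                f"cutoff {cutoff:.3f} A exceeds half the minimum cell width "
                f"({0.5 * width:.3f} A); replicate the cell to use this cutoff")
        inv = np.linalg.inv(system.cell)
        frac = pos @ inv
        dfrac = frac[None, :, :] - frac[:, None, :]       # (i,j): f_j - f_i
        shift = -np.round(dfrac)
        disp = (dfrac + shift) @ system.cell
        shifts_all = shift.astype(np.int64)
    else:
        disp = pos[None, :, :] - pos[:, None, :]
        shifts_all = np.zeros((n, n, 3), dtype=np.int64)

    dist = np.linalg.norm(disp, axis=-1)
    mask = dist < cutoff
    np.fill_diagonal(mask, False)
    ii, jj = np.nonzero(mask)  # nonzero iterates row-major: lexicographic (i, j)
    edges = np.stack([ii, jj], axis=1)
    return NeighborList(
        edges=edges,
        displacements=disp[ii, jj],
        distances=dist[ii, jj],
        cutoff=float(cutoff),
        shifts=shifts_all[ii, jj],
    )
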