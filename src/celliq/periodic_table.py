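"""Element lookups: symbols, covalent radii, atomic masses.

The radii table (single-bond covalent radii) anchors the Gaussian charge
widths of the charge-equilibration layer; masses feed the MD integrator.
Both ship as plain-text CSVs under ``celliq/data``.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

__all__ = [
    "symbol_to_z", "z_to_symbol", "covalent_radius", "atomic_mass",
    "UnknownElementError",
]


class UnknownElementError(KeyError):
    """Raised when an element is missing from the shipped tables."""


def _load_csv(name: str) -> dict:
    table = {}
    text = resources.files("celliq.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, z, val = line.split(",")
        table[int(z)] = (sym, float(val))
    return table


@lru_cache(maxsize=None)
def _radii() -> dict:
    return _load_csv("covalent_radii.csv")


@lru_cache(maxsize=None)
def _masses() -> dict:
    return _load_csv("atomic_masses.csv")


@lru_cache(maxsize=None)
def _sym_index() -> dict:
    return {sym: z for z, (sym, _) in _masses().items()}


def symbol_to_z(symbol: str) -> int:
    try:
        return _sym_index()[symbol]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol {symbol!r}") from None


def z_to_symbol(z: int) -> str:
    try:
        return _masses()[int(z)][0]
    except KeyError:
        raise UnknownElementError(f"no symbol for atomic number {z}") from None


def covalent_radius(z: int) -> float:
    """Single-bond covalent radius in Angstrom."""
    try:
        return _radii()[int(z)][1]
    except KeyError:
        raise UnknownElementError(
            f"no covalent radius tabulated for element Z={z}") from None


def atomic_mass(z: int) -> float:
    """Standard atomic weight in amu."""
    try:
        return _masses()[int(z)][1]
    except KeyError:
        raise UnknownElementError(
            f"no atomic mass tabulated for element Z={z}") from None
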