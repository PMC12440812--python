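"""Extended XYZ reading and writing.

Dialect (the de-facto community standard):

* frame header line 1: atom count;
* line 2: whitespace-separated ``key=value`` pairs, values possibly quoted —
  ``Lattice="ax ay az bx by bz cx cy cz"`` (row vectors),
  ``Properties=species:S:1:pos:R:3[:forces:R:3][:charge:R:1]``,
  ``energy=<float>``, ``total_charge=<float>``, ``pbc="T T F"``;
* one line per atom with columns as declared by Properties.

Numeric fields are written with 17 significant digits so a write -> read
round trip reproduces every float bit-identically. Labels that are absent
stay absent (never zero-filled).
"""

from __future__ import annotations

import re
from typing import List

import numpy as np

from .periodic_table import symbol_to_z, z_to_symbol
from .systems import AtomicSystem

__all__ = ["read_extxyz", "write_extxyz", "ExtxyzParseError"]


class ExtxyzParseError(ValueError):
    """Malformed extended-XYZ content; message carries the 1-based line number."""


_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str, lineno: int) -> dict:
    out = {}
    for m in _KV_RE.finditer(line):
        key = m.group(1)
        val = m.group(2) if m.group(2) is not None else m.group(3)
        out[key] = val
    if not out and line.strip():
        raise ExtxyzParseError(
            f"line {lineno}: comment line is not key=value formatted: {line!r}")
    return out


def _parse_properties(spec: str, lineno: int) -> List[tuple]:
    fields = spec.split(":")
    if len(fields) % 3 != 0:
        raise ExtxyzParseError(
            f"line {lineno}: malformed Properties string {spec!r}")
    cols = []
    for k in range(0, len(fields), 3):
        name, kind, width = fields[k], fields[k + 1], fields[k + 2]
        try:
            width = int(width)
        except ValueError:
            raise ExtxyzParseError(
                f"line {lineno}: non-integer column width in {spec!r}") from None
        if kind not in ("S", "R", "I"):
            raise ExtxyzParseError(
                f"line {lineno}: unsupported column kind {kind!r}")
        cols.append((name, kind, width))
    return cols


def _maybe_number(s: str):
    try:
        return float(s)
    except ValueError:
        return s


def read_extxyz(path) -> List[AtomicSystem]:
    """Parse every frame of an extended-XYZ file into `AtomicSystem` objects."""
    with open(path) as fh:
        lines = fh.read().splitlines()

    systems = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ExtxyzParseError(
                f"line {i + 1}: expected an atom count, got {lines[i]!r}") from None
        if i + 1 >= len(lines):
            raise ExtxyzParseError(f"line {i + 2}: missing comment line")
        header = _parse_comment(lines[i + 1], i + 2)

        props = header.pop("Properties", "species:S:1:pos:R:3")
        cols = _parse_properties(props, i + 2)
        ncols = sum(w for _, _, w in cols)

        cell = None
        if "Lattice" in header:
            vals = header.pop("Lattice").split()
            if len(vals) != 9:
                raise ExtxyzParseError(
                    f"line {i + 2}: Lattice needs 9 numbers, got {len(vals)}")
            cell = np.array([float(v) for v in vals]).reshape(3, 3)
        pbc = (False, False, False)
        if "pbc" in header:
            flags = header.pop("pbc").split()
            if len(flags) != 3 or any(f not in ("T", "F") for f in flags):
                raise ExtxyzParseError(f"line {i + 2}: malformed pbc flags")
            pbc = tuple(f == "T" for f in flags)
        energy = header.pop("energy", None)
        total_charge = float(header.pop("total_charge", 0.0))
        info = {k: _maybe_number(v) for k, v in header.items()}

        species, positions, forces, charges = [], [], [], []
        has_forces = any(name == "forces" for name, _, _ in cols)
        has_charge = any(name == "charge" for name, _, _ in cols)
        for a in range(natoms):
            ln = i + 2 + a
            if ln >= len(lines):
                raise ExtxyzParseError(f"line {ln + 1}: unexpected end of file")
            toks = lines[ln].split()
            if len(toks) != ncols:
                raise ExtxyzParseError(
                    f"line {ln + 1}: expected {ncols} columns, got {len(toks)}")
            c = 0
            for name, kind, width in cols:
                chunk = toks[c:c + width]
                c += width
                if name == "species":
                    species.append(symbol_to_z(chunk[0]))
                elif name == "pos":
                    positions.append([float(v) for v in chunk])
                elif name == "forces":
                    forces.append([float(v) for v in chunk])
                elif name == "charge":
                    charges.append(float(chunk[0]))
                # unknown per-atom columns are ignored

        try:
            systems.append(AtomicSystem(
                species=np.array(species),
                positions=np.array(positions),
                cell=cell,
                pbc=pbc,
                total_charge=total_charge,
                energy=None if energy is None else float(energy),
                forces=np.array(forces) if has_forces else None,
                charges=np.array(charges) if has_charge else None,
                info=info,
            ))
        except ValueError as exc:
            raise ExtxyzParseError(
                f"frame starting at line {i + 1}: {exc}") from exc
        i += 2 + natoms
    return systems


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_extxyz(systems: List[AtomicSystem], path) -> None:
    """Write frames so that `read_extxyz` recovers them field-identically."""
    with open(path, "w") as fh:
        for sys_ in systems:
            props = "species:S:1:pos:R:3"
            if sys_.forces is not None:
                props += ":forces:R:3"
            if sys_.charges is not None:
                props += ":charge:R:1"
            parts = []
            if sys_.cell is not None:
                parts.append('Lattice="' + " ".join(
                    _fmt(v) for v in sys_.cell.ravel()) + '"')
            parts.append(f"Properties={props}")
            parts.append('pbc="' + " ".join(
                "T" if p else "F" for p in sys_.pbc) + '"')
            parts.append(f"total_charge={_fmt(sys_.total_charge)}")
            if sys_.energy is not None:
                parts.append(f"energy={_fmt(sys_.energy)}")
            for k, v in sys_.info.items():
                sv = _fmt(v) if isinstance(v, float) else str(v)
                if any(ch.isspace() for ch in sv):
                    sv = f'"{sv}"'
                parts.append(f"{k}={sv}")

            fh.write(f"{len(sys_)}\n")
            fh.write(" ".join(parts) + "\n")
            for a in range(len(sys_)):
                row = [z_to_symbol(sys_.species[a])]
                row += [_fmt(v) for v in sys_.positions[a]]
                if sys_.forces is not None:
                    row += [_fmt(v) for v in sys_.forces[a]]
                if sys_.charges is not None:
                    row.append(_fmt(sys_.charges[a]))
                fh.write(" ".join(row) + "\n")
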