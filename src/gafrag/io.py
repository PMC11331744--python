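"""Structure I/O: XYZ and minimal PDB.

XYZ files follow the plain convention (atom count, comment, one
``element x y z`` line per atom, Å).  PDB reading goes through Biopython's
parser with the element column authoritative; writing emits minimal
ATOM/HETATM records sufficient to round-trip coordinates.
"""

from __future__ import annotations

import os
import warnings

import numpy as np

from .geom import Structure


def read_xyz(path: str | os.PathLike) -> Structure:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"empty XYZ file: {path}")
    n = int(lines[0].split()[0])
    comment = lines[1] if len(lines) > 1 else ""
    elements: list[str] = []
    coords = np.empty((n, 3), dtype=float)
    for k in range(n):
        parts = lines[2 + k].split()
        elements.append(parts[0].capitalize())
        coords[k] = [float(v) for v in parts[1:4]]
    return Structure(elements, coords, name=comment.strip())


def write_xyz(structure: Structure | "object", path: str | os.PathLike,
              comment: str = "") -> None:
    """Write a Structure or Geometry-like object (elements/coords) to XYZ."""
    elements = structure.elements
    coords = np.asarray(structure.coords, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(elements)}\n{comment or getattr(structure, 'name', '')}\n")
        for el, (x, y, z) in zip(elements, coords):
            fh.write(f"{el:<3s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def read_pdb(path: str | os.PathLike) -> Structure:
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        model = parser.get_structure("m", str(path))
    elements: list[str] = []
    xyz: list[np.ndarray] = []
    for atom in model.get_atoms():
        el = (atom.element or atom.get_name()[0]).strip().capitalize()
        elements.append(el)
        xyz.append(atom.coord.astype(float))
    if not elements:
        raise ValueError(f"no ATOM/HETATM records found in {path}")
    return Structure(elements, np.asarray(xyz), name=os.path.basename(str(path)))


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, (el, (x, y, z)) in enumerate(
                zip(structure.elements, structure.coords), start=1):
            # unique atom names: identically named atoms in one residue are
            # treated as alternate locations by standard parsers
            name = f"{el.upper()}{i}"[:4]
            fh.write(
                f"HETATM{i:5d} {name:<4s} LIG A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{el.upper():>2s}\n"
            )
        fh.write("END\n")


def read_structure(path: str | os.PathLike) -> Structure:
    """Dispatch on file extension (.xyz or .pdb)."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".xyz":
        return read_xyz(path)
    if ext in (".pdb", ".ent"):
        return read_pdb(path)
    raise ValueError(f"unsupported structure format: {ext!r}")
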