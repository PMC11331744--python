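"""Bundled element data: covalent radii, van der Waals radii, atomic masses
and reference covalent bond lengths used for bond perception.

Covalent radii follow the Cordero et al. compilation (single-bond radii, Å);
van der Waals radii follow Bondi with Alvarez values for elements Bondi did
not cover.  Reference bond lengths are typical experimental equilibrium
distances for each element pair and bond order.
"""

from __future__ import annotations

# Cordero single-bond covalent radii, Å.  C is the sp3 value.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Zn": 1.22, "Br": 1.20, "Kr": 1.16,
    "I": 1.39, "Xe": 1.40,
}

# Bondi/Alvarez van der Waals radii, Å (sigma_i of the volume model).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "Li": 1.81, "Be": 1.53, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Zn": 1.39, "Br": 1.85, "Kr": 2.02,
    "I": 1.98, "Xe": 2.16,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Zn": 30, "Br": 35,
    "Kr": 36, "I": 53, "Xe": 54,
}

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.003, "Li": 6.94, "Be": 9.012, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Zn": 65.38, "Br": 79.904, "Kr": 83.798, "I": 126.904, "Xe": 131.293,
}

# Reference bond lengths, Å, keyed by an alphabetically sorted element pair,
# mapping bond order -> typical equilibrium length.
_REF: dict[tuple[str, str], dict[int, float]] = {
    ("H", "H"): {1: 0.74},
    ("C", "H"): {1: 1.09},
    ("H", "N"): {1: 1.01},
    ("H", "O"): {1: 0.96},
    ("H", "S"): {1: 1.34},
    ("H", "P"): {1: 1.42},
    ("C", "C"): {1: 1.54, 2: 1.34, 3: 1.20},
    ("C", "N"): {1: 1.47, 2: 1.28, 3: 1.16},
    ("C", "O"): {1: 1.43, 2: 1.21},
    ("C", "S"): {1: 1.82, 2: 1.60},
    ("C", "P"): {1: 1.84},
    ("C", "F"): {1: 1.35},
    ("C", "Cl"): {1: 1.77},
    ("Br", "C"): {1: 1.94},
    ("C", "I"): {1: 2.14},
    ("N", "N"): {1: 1.45, 2: 1.25, 3: 1.10},
    ("N", "O"): {1: 1.40, 2: 1.21},
    ("O", "O"): {1: 1.48, 2: 1.21},
    ("S", "S"): {1: 2.05},
    ("O", "S"): {1: 1.57, 2: 1.43},
    ("O", "P"): {1: 1.63, 2: 1.50},
    ("N", "P"): {1: 1.70},
}

#: Slack added to the longest reference length when deciding bond existence, Å.
BOND_TOLERANCE = 0.25

#: Interatomic distances below this are treated as overlapping atoms, Å.
OVERLAP_DISTANCE = 0.30


def reference_lengths(el_a: str, el_b: str) -> dict[int, float]:
    """Reference bond lengths for an element pair.

    Falls back to the sum of covalent radii (order 1) for pairs absent from
    the curated table, so uncommon but chemically sensible bonds are still
    perceived.  Returns an empty dict when either element has no covalent
    radius entry.
    """
    key = tuple(sorted((el_a, el_b)))
    if key in _REF:
        return _REF[key]  # type: ignore[index]
    ra = COVALENT_RADII.get(el_a)
    rb = COVALENT_RADII.get(el_b)
    if ra is None or rb is None:
        return {}
    # Noble gases do not form covalent bonds in this model.
    noble = {"He", "Ne", "Ar", "Kr", "Xe"}
    if el_a in noble or el_b in noble:
        return {}
    return {1: ra + rb}


HALOGENS = frozenset({"F", "Cl", "Br", "I"})
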