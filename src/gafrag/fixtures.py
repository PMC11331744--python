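"""Deterministic molecular fixtures.

Small worked-example molecules (pyrrole, methanol, 3-chloroprop-1-ene,
alkenes, a stearic-acid-like chain) built from idealised bond lengths and
angles, plus seeded synthetic chains (alkanes and peptide-like backbones)
standing in for protein-scale systems.  Geometries are idealised: only the
bonded topology and approximate distances matter for perception and
scoring, not spectroscopic accuracy.  Bond lengths are chosen so the
geometric bond-perception table recovers the intended orders (e.g. the
amide C–N is drawn at a single-bond length).
"""

from __future__ import annotations

import math

import numpy as np

from .geom import Structure

_D120 = math.radians(120.0)
#: half-angle of the tetrahedral zig-zag (backbone angle 109.47°)
_PHI = math.radians(35.26439)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(d: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(d, ref))


def _sp3_dirs(existing: list[np.ndarray], n: int) -> list[np.ndarray]:
    """Unit vectors completing an approximately tetrahedral centre."""
    existing = [_unit(e) for e in existing]
    if len(existing) == 0:
        base = [np.array(v) / math.sqrt(3.0)
                for v in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))]
        return base[:n]
    if len(existing) == 1:
        d = existing[0]
        u = _perp(d)
        v = np.cross(d, u)
        cos_t, sin_t = math.cos(math.radians(109.47)), math.sin(math.radians(109.47))
        out = []
        for k in range(n):
            az = 2.0 * math.pi * k / max(n, 1)
            out.append(cos_t * d + sin_t * (math.cos(az) * u + math.sin(az) * v))
        return out
    if len(existing) == 2:
        b = -_unit(existing[0] + existing[1])
        w = _unit(np.cross(existing[0], existing[1]))
        half = math.radians(54.735)
        dirs = [math.cos(half) * b + math.sin(half) * w,
                math.cos(half) * b - math.sin(half) * w]
        return dirs[:n]
    return [-_unit(sum(existing))][:n]


class _Builder:
    def __init__(self) -> None:
        self.elements: list[str] = []
        self.coords: list[np.ndarray] = []

    def add(self, element: str, xyz) -> int:
        self.elements.append(element)
        self.coords.append(np.asarray(xyz, dtype=float))
        return len(self.elements) - 1

    def hydrogens(self, centre: int, neighbour_ids: list[int], n: int,
                  length: float = 1.09) -> list[int]:
        c = self.coords[centre]
        dirs = _sp3_dirs([self.coords[i] - c for i in neighbour_ids], n)
        return [self.add("H", c + length * d) for d in dirs]

    def structure(self, name: str) -> Structure:
        return Structure(self.elements, np.asarray(self.coords), name=name)


def _zigzag(n: int, lengths) -> list[np.ndarray]:
    """Backbone positions with alternating directions (109.47° angles)."""
    up = np.array([math.cos(_PHI), math.sin(_PHI), 0.0])
    down = np.array([math.cos(_PHI), -math.sin(_PHI), 0.0])
    pos = [np.zeros(3)]
    for k in range(n - 1):
        d = up if k % 2 == 0 else down
        pos.append(pos[-1] + lengths[k] * d)
    return pos


def build_methane() -> Structure:
    b = _Builder()
    c = b.add("C", (0.0, 0.0, 0.0))
    b.hydrogens(c, [], 4)
    return b.structure("methane")


def build_ethene() -> Structure:
    b = _Builder()
    c1 = b.add("C", (0.0, 0.0, 0.0))
    c2 = b.add("C", (1.34, 0.0, 0.0))
    for c, sign in ((c1, -1.0), (c2, 1.0)):
        x0 = b.coords[c]
        for dy in (1.0, -1.0):
            d = np.array([sign * 0.5, dy * math.sin(_D120), 0.0])
            b.add("H", x0 + 1.09 * _unit(d))
    return b.structure("ethene")


def _sp2_h(b: _Builder, centre: int, neighbours: list[int],
           length: float = 1.08) -> int:
    c = b.coords[centre]
    bis = -_unit(sum(_unit(b.coords[i] - c) for i in neighbours))
    return b.add("H", c + length * bis)


def build_propene() -> Structure:
    b = _Builder()
    c1 = b.add("C", (0.0, 0.0, 0.0))
    c2 = b.add("C", (1.34, 0.0, 0.0))
    c3 = b.add("C", np.array([1.34, 0.0, 0.0])
               + 1.50 * np.array([math.cos(math.radians(60)),
                                  math.sin(math.radians(60)), 0.0]))
    _sp2_h(b, c2, [c1, c3])
    x1 = b.coords[c1]
    for ang in (120.0, -120.0):
        d = np.array([math.cos(math.radians(ang)),
                      math.sin(math.radians(ang)), 0.0])
        b.add("H", x1 + 1.09 * d)
    b.hydrogens(c3, [c2], 3)
    return b.structure("propene")


def build_chloropropene() -> Structure:
    """3-chloroprop-1-ene with atoms 1,2 = C=C, 3 = CH2 carbon, 4 = Cl."""
    b = _Builder()
    c1 = b.add("C", (0.0, 0.0, 0.0))
    c2 = b.add("C", (1.34, 0.0, 0.0))
    c3 = b.add("C", np.array([1.34, 0.0, 0.0])
               + 1.50 * np.array([math.cos(math.radians(60)),
                                  math.sin(math.radians(60)), 0.0]))
    cl_dir = _sp3_dirs([b.coords[c2] - b.coords[c3]], 3)
    b.add("Cl", b.coords[c3] + 1.77 * cl_dir[0])
    x1 = b.coords[c1]
    for ang in (120.0, -120.0):
        d = np.array([math.cos(math.radians(ang)),
                      math.sin(math.radians(ang)), 0.0])
        b.add("H", x1 + 1.09 * d)
    _sp2_h(b, c2, [c1, c3])
    for d in cl_dir[1:]:
        b.add("H", b.coords[c3] + 1.09 * d)
    return b.structure("3-chloroprop-1-ene")


def build_butadiene() -> Structure:
    b = _Builder()
    c1 = b.add("C", (0.0, 0.0, 0.0))
    c2 = b.add("C", (1.34, 0.0, 0.0))
    u = np.array([math.cos(math.radians(60)), math.sin(math.radians(60)), 0.0])
    c3 = b.add("C", b.coords[c2] + 1.46 * u)
    c4 = b.add("C", b.coords[c3] + 1.34 * np.array([1.0, 0.0, 0.0]))
    x1 = b.coords[c1]
    for ang in (120.0, -120.0):
        b.add("H", x1 + 1.09 * np.array([math.cos(math.radians(ang)),
                                         math.sin(math.radians(ang)), 0.0]))
    _sp2_h(b, c2, [c1, c3])
    _sp2_h(b, c3, [c2, c4])
    x4 = b.coords[c4]
    for ang in (60.0, -60.0):
        b.add("H", x4 + 1.09 * np.array([math.cos(math.radians(ang)),
                                         math.sin(math.radians(ang)), 0.0]))
    return b.structure("1,3-butadiene")


# hand-solved planar ring with N–C 1.40, C=C 1.36, C–C 1.46 Å
_PYRROLE_RING = {
    "N": (0.0, 1.15), "C2": (1.148913, 0.35), "C3": (0.73, -0.943875),
    "C4": (-0.73, -0.943875), "C5": (-1.148913, 0.35),
}


def build_pyrrole() -> Structure:
    b = _Builder()
    ring_ids = {}
    for name, (x, y) in _PYRROLE_RING.items():
        ring_ids[name] = b.add(name[0], (x, y, 0.0))
    centre = np.mean([b.coords[i] for i in ring_ids.values()], axis=0)
    for name, i in ring_ids.items():
        length = 1.01 if name == "N" else 1.08
        u = _unit(b.coords[i] - centre)
        b.add("H", b.coords[i] + length * u)
    return b.structure("pyrrole")


def build_methanol() -> Structure:
    b = _Builder()
    c = b.add("C", (0.0, 0.0, 0.0))
    o = b.add("O", (1.43, 0.0, 0.0))
    ho_dir = np.array([math.cos(math.radians(180 - 108.5)),
                       math.sin(math.radians(180 - 108.5)), 0.0])
    b.add("H", b.coords[o] + 0.96 * ho_dir)
    b.hydrogens(c, [o], 3)
    return b.structure("methanol")


def build_alkane(n_carbons: int) -> Structure:
    if n_carbons < 1:
        raise ValueError("need at least one carbon")
    b = _Builder()
    pos = _zigzag(n_carbons, [1.54] * (n_carbons - 1))
    carbons = [b.add("C", p) for p in pos]
    for k, c in enumerate(carbons):
        nbs = [carbons[k - 1]] if k > 0 else []
        if k < n_carbons - 1:
            nbs.append(carbons[k + 1])
        b.hydrogens(c, nbs, 4 - len(nbs))
    return b.structure(f"n-{'CH4' if n_carbons == 1 else f'C{n_carbons}'}-alkane")


def build_fatty_acid(n_carbons: int = 18) -> Structure:
    """Saturated fatty-acid-like chain (default: stearic-acid-like, 56 atoms)."""
    b = _Builder()
    pos = _zigzag(n_carbons, [1.54] * (n_carbons - 1))
    carbons = [b.add("C", p) for p in pos]
    for k in range(n_carbons - 1):
        nbs = [carbons[k - 1]] if k > 0 else []
        nbs.append(carbons[k + 1])
        b.hydrogens(carbons[k], nbs, 4 - len(nbs))
    # carboxyl head on the last carbon (sp2: =O and –OH at ±120°)
    c_last = carbons[-1]
    x = b.coords[c_last]
    d_ca = _unit(b.coords[carbons[-2]] - x)

    # rotate d_ca by ±120° in the xy-plane
    def rot(v, deg):
        a = math.radians(deg)
        return np.array([v[0] * math.cos(a) - v[1] * math.sin(a),
                         v[0] * math.sin(a) + v[1] * math.cos(a), v[2]])
    o_double = b.add("O", x + 1.22 * rot(d_ca, 120.0))
    o_single = b.add("O", x + 1.40 * rot(d_ca, -120.0))
    oh_dir = _unit(rot(d_ca, -120.0) + np.array([0.6, 0.0, 0.0]))
    b.add("H", b.coords[o_single] + 0.96 * oh_dir)
    return b.structure(f"fatty-acid-C{n_carbons}")


def build_chain(n_residues: int, kind: str = "peptide", seed: int = 0,
                sequence: str | None = None) -> Structure:
    """Synthetic chain fixture.

    ``kind='alkane'`` gives CnH2n+2; ``kind='peptide'`` gives an extended
    glycine/alanine/serine chain (``sequence`` of G/A/S per residue, default
    alanine at every third position) with an N-terminal NH2 and C-terminal
    COOH.  A seeded uniform jitter of at most 0.02 Å decorrelates repeated
    builds with different seeds without perturbing bond perception.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    if kind == "alkane":
        s = build_alkane(n_residues)
    elif kind == "peptide":
        if sequence is None:
            sequence = "".join("A" if (k + 1) % 3 == 0 else "G"
                               for k in range(n_residues))
        if len(sequence) != n_residues:
            raise ValueError("sequence length must equal n_residues")
        s = _build_peptide(sequence)
    else:
        raise ValueError(f"unknown chain kind {kind!r}")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.02, 0.02, size=s.coords.shape)
    return Structure(s.elements, s.coords + jitter, name=s.name)


def _build_peptide(sequence: str) -> Structure:
    b = _Builder()
    n_res = len(sequence)
    lengths = []
    for _k in range(n_res):
        lengths.extend([1.46, 1.52, 1.45])  # N–CA, CA–C, C–N(next)
    pos = _zigzag(3 * n_res, lengths[:3 * n_res - 1])
    backbone = []
    for r in range(n_res):
        n_i = b.add("N", pos[3 * r])
        ca_i = b.add("C", pos[3 * r + 1])
        c_i = b.add("C", pos[3 * r + 2])
        backbone.append((n_i, ca_i, c_i))
    for r, aa in enumerate(sequence.upper()):
        n_i, ca_i, c_i = backbone[r]
        # amide N: H on the in-plane bisector; N-terminus gets a second H
        n_nbs = [ca_i] + ([backbone[r - 1][2]] if r > 0 else [])
        if r == 0:
            b.hydrogens(n_i, n_nbs, 2, length=1.01)
        else:
            b.hydrogens(n_i, n_nbs, 1, length=1.01)
        # carbonyl / C-terminal carboxyl
        x = b.coords[c_i]
        d_ca = _unit(b.coords[ca_i] - x)

        def rot(v, deg):
            a = math.radians(deg)
            return np.array([v[0] * math.cos(a) - v[1] * math.sin(a),
                             v[0] * math.sin(a) + v[1] * math.cos(a), v[2]])

        if r < n_res - 1:
            d_next = _unit(b.coords[backbone[r + 1][0]] - x)
            bis = -_unit(d_ca + d_next)
            b.add("O", x + 1.22 * bis)
        else:
            b.add("O", x + 1.22 * rot(d_ca, 120.0))
            o_s = b.add("O", x + 1.40 * rot(d_ca, -120.0))
            oh = _unit(rot(d_ca, -120.0) + 0.6 * np.array([1.0, 0.0, 0.0]))
            b.add("H", b.coords[o_s] + 0.96 * oh)
        # CA substituents
        ca_nbs = [n_i, c_i]
        if aa == "G":
            b.hydrogens(ca_i, ca_nbs, 2)
        elif aa == "A":
            ha = b.hydrogens(ca_i, ca_nbs, 1)
            dirs = _sp3_dirs([b.coords[i] - b.coords[ca_i]
                              for i in ca_nbs + ha], 1)
            cb = b.add("C", b.coords[ca_i] + 1.53 * dirs[0])
            b.hydrogens(cb, [ca_i], 3)
        elif aa == "S":
            ha = b.hydrogens(ca_i, ca_nbs, 1)
            dirs = _sp3_dirs([b.coords[i] - b.coords[ca_i]
                              for i in ca_nbs + ha], 1)
            cb = b.add("C", b.coords[ca_i] + 1.53 * dirs[0])
            og_dirs = _sp3_dirs([b.coords[ca_i] - b.coords[cb]], 3)
            og = b.add("O", b.coords[cb] + 1.43 * og_dirs[0])
            for d in og_dirs[1:]:
                b.add("H", b.coords[cb] + 1.09 * d)
            oh_dirs = _sp3_dirs([b.coords[cb] - b.coords[og]], 1)
            b.add("H", b.coords[og] + 0.96 * oh_dirs[0])
        else:
            raise ValueError(f"unsupported residue {aa!r} (use G, A or S)")
    return b.structure(f"peptide-{sequence}")


_REGISTRY = {
    "methane": build_methane,
    "ethene": build_ethene,
    "propene": build_propene,
    "3-chloroprop-1-ene": build_chloropropene,
    "1,3-butadiene": build_butadiene,
    "pyrrole": build_pyrrole,
    "methanol": build_methanol,
    "n-butane": lambda: build_alkane(4),
    "stearic-like": lambda: build_fatty_acid(18),
    # 24 residues, one alanine: 174 atoms, the protein-fixture scale
    "peptide174": lambda: build_chain(
        24, "peptide", seed=0,
        sequence="".join("A" if k == 11 else "G" for k in range(24))),
}


def build_named_molecule(name: str) -> Structure:
    """Build a registry fixture; geometries are bit-identical across calls."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown molecule {name!r}; registry: {sorted(_REGISTRY)}")
    return factory()


def registry_names() -> list[str]:
    return sorted(_REGISTRY)
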