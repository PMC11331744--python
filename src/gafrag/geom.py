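"""Light containers for atomic structures and bonded geometries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Structure:
    """A bare atomic structure: element symbols + Cartesian coordinates (Å).

    ``formal_charges`` is trusted from input metadata when provided and
    defaults to all-zero.
    """

    elements: list[str]
    coords: np.ndarray
    formal_charges: list[int] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.formal_charges is None:
            self.formal_charges = [0] * len(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """Return a rigidly moved copy (used by invariance checks)."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return Structure(list(self.elements), xyz,
                         list(self.formal_charges), self.name)


@dataclass
class Geometry:
    """A structure together with its bonded topology.

    This is the unit that energy backends consume.  ``bonds`` holds
    ``(i, j, order)`` triples over local indices; ``cap_indices`` flags which
    atoms are hydrogen caps appended to restore valence at severed bonds.
    """

    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int, int]]
    cap_indices: list[int] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def n_real_atoms(self) -> int:
        return len(self.elements) - len(self.cap_indices)
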