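"""In-memory molecular container shared by the real-dataset and synthetic branches.

A :class:`Molecule3D` is deliberately minimal: elements, Cartesian
coordinates, partial charges, van der Waals radii and the five per-atom
similarity-index properties (steric, electrostatic, hydrophobic, H-bond
donor, H-bond acceptor).  Everything downstream — alignment, grid fields,
PLS — operates on this container and never needs chemistry toolkit objects,
which is what lets synthetic point-atom molecules flow through the same
pipeline as real structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

#: similarity-index property keys: steric, electrostatic, hydrophobic,
#: hydrogen-bond donor, hydrogen-bond acceptor
COMSIA_PROPS = ("S", "E", "H", "D", "A")


@dataclass
class Molecule3D:
    """A charged 3D conformation with per-atom field properties.

    Parameters
    ----------
    compound_id:
        Identifier of the compound this conformation belongs to.
    elements:
        Element symbol per atom.
    coords:
        ``(n_atoms, 3)`` Cartesian coordinates in Angstrom.
    charges:
        Partial atomic charges in elementary-charge units.
    vdw_radii:
        Van der Waals radius per atom in Angstrom.
    props:
        Map from similarity-index property key (``S``, ``E``, ``H``, ``D``,
        ``A``) to a per-atom value array.
    core_atom_indices:
        Ordered indices of the invariant-scaffold atoms used for rigid
        alignment; identical length and ordering convention across a series.
    anchors:
        Optional map from a substituent position label (e.g. ``"4'"``,
        ``"N1-R1"``) to the index of the substituent's attachment atom;
        used by the contour-map region reports.
    """

    compound_id: int
    elements: List[str]
    coords: np.ndarray
    charges: np.ndarray
    vdw_radii: np.ndarray
    props: Dict[str, np.ndarray] = field(default_factory=dict)
    core_atom_indices: Optional[List[int]] = None
    anchors: Dict[str, int] = field(default_factory=dict)
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{n} atoms (compound {self.compound_id})"
            )
        if self.charges.shape != (n,) or self.vdw_radii.shape != (n,):
            raise ValueError(f"per-atom array length mismatch (compound {self.compound_id})")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates (compound {self.compound_id})")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def validate(self) -> None:
        """Raise if coordinates, radii or similarity properties are unusable."""
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates (compound {self.compound_id})")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError(f"non-finite charges (compound {self.compound_id})")
        if not np.all(self.vdw_radii > 0):
            raise ValueError(f"non-positive vdW radius (compound {self.compound_id})")
        for key in COMSIA_PROPS:
            if key not in self.props:
                raise ValueError(
                    f"missing similarity property {key!r} (compound {self.compound_id})"
                )
            arr = np.asarray(self.props[key])
            if arr.shape != (self.n_atoms,) or not np.all(np.isfinite(arr)):
                raise ValueError(
                    f"bad similarity property array {key!r} (compound {self.compound_id})"
                )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule3D":
        """Return a copy with coordinates mapped through ``x @ R.T + t``."""
        new_coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return replace(
            self,
            coords=new_coords,
            charges=self.charges.copy(),
            vdw_radii=self.vdw_radii.copy(),
            props={k: np.asarray(v).copy() for k, v in self.props.items()},
            anchors=dict(self.anchors),
            core_atom_indices=None
            if self.core_atom_indices is None
            else list(self.core_atom_indices),
        )
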