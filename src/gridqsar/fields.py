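"""Molecular interaction fields on a shared rectangular lattice.

Two families of descriptors are computed for an aligned congeneric series:

* probe-interaction fields: a +1 e, 1 Angstrom probe atom's Lennard-Jones
  6-12 (steric) and Coulomb (electrostatic, distance-dependent dielectric
  eps = r) energies at every lattice point, truncated at 30 kcal/mol;
* similarity-index fields: for each property k (steric, electrostatic,
  hydrophobic, H-bond donor, H-bond acceptor) the Gaussian-attenuated sum

      A_k(q) = - sum_i  w_probe,k * w_ik * exp(-alpha * r_iq^2)

  with attenuation alpha = 0.3, evaluated over all atoms i of the molecule
  for each lattice point q.  The Gaussian is bounded, so no truncation is
  applied.

The lattice has a default 2 Angstrom spacing and extends 4 Angstrom beyond
the union bounding box of the aligned series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .molecule import COMSIA_PROPS, Molecule3D

__all__ = [
    "GridSpec",
    "ProbeSpec",
    "FieldBlock",
    "VDW_PARAMS",
    "COULOMB_CONSTANT",
    "COMFA_FIELD_KINDS",
    "COMSIA_FIELD_KINDS",
    "make_grid",
    "comfa_values",
    "comfa_fields",
    "comsia_values",
    "comsia_fields",
    "assemble_block",
    "assemble_comfa_blocks",
    "assemble_comsia_blocks",
]

#: kcal * Angstrom / (mol * e^2)
COULOMB_CONSTANT = 332.0637

COMFA_FIELD_KINDS = ("comfa_steric", "comfa_electrostatic")
COMSIA_FIELD_KINDS = tuple(f"comsia_{k}" for k in COMSIA_PROPS)

# General-purpose element Lennard-Jones parameters (rmin/2 in Angstrom,
# well depth in kcal/mol), AMBER-style values.
VDW_PARAMS: Dict[str, Tuple[float, float]] = {
    "H": (1.20, 0.0157),
    "C": (1.908, 0.1094),
    "N": (1.824, 0.17),
    "O": (1.6612, 0.21),
    "F": (1.75, 0.061),
    "P": (2.10, 0.20),
    "S": (2.00, 0.25),
    "Cl": (1.948, 0.265),
    "Br": (2.22, 0.32),
    "I": (2.35, 0.40),
    "X": (1.70, 0.10),  # synthetic point atoms
}


class FieldConfigError(ValueError):
    """Missing per-atom parameter or property required by a field kind."""


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned rectangular lattice: points at origin + spacing*(i,j,k)."""

    origin: Tuple[float, float, float]
    spacing: float
    dims: Tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be positive")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def points(self) -> np.ndarray:
        """All lattice points, C-ordered over (i, j, k), shape (n_points, 3)."""
        idx = np.indices(self.dims).reshape(3, -1).T
        return np.asarray(self.origin) + self.spacing * idx

    def flat_to_ijk(self, flat: np.ndarray) -> np.ndarray:
        return np.stack(np.unravel_index(np.asarray(flat), self.dims), axis=-1)


@dataclass(frozen=True)
class ProbeSpec:
    """Probe-atom settings: +1 e charge, 1 Angstrom radius, unit similarity
    property weights, attenuation 0.3, truncation 30 kcal/mol."""

    charge: float = 1.0
    radius: float = 1.0
    epsilon: float = 0.107  # sp3-carbon-like well depth, kcal/mol
    alpha: float = 0.3
    truncation: float = 30.0
    comsia_weights: Dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in COMSIA_PROPS}
    )


@dataclass
class FieldBlock:
    """compounds x lattice-points descriptor matrix for one field kind."""

    field_kind: str
    matrix: np.ndarray
    grid: GridSpec
    compound_ids: List[int]
    probe: ProbeSpec = field(default_factory=ProbeSpec)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (len(self.compound_ids), self.grid.n_points):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.compound_ids)} compounds x {self.grid.n_points} points"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"non-finite entries in {self.field_kind} block")

    def subset(self, ids: Sequence[int]) -> "FieldBlock":
        """Row subset in the given compound-id order."""
        pos = {cid: i for i, cid in enumerate(self.compound_ids)}
        rows = [pos[i] for i in ids]
        return replace(self, matrix=self.matrix[rows], compound_ids=list(ids))


def make_grid(
    mols: Sequence[Molecule3D], spacing: float = 2.0, margin: float = 4.0
) -> GridSpec:
    """Lattice covering the union bounding box of the series plus a margin."""
    if not mols:
        raise ValueError("cannot build a grid from an empty molecule list")
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    coords = np.vstack([m.coords for m in mols])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = tuple(int(np.ceil((h - l) / spacing - 1e-9)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(float(x) for x in lo), spacing=float(spacing), dims=dims)


def _lj_params(elements: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    try:
        pairs = [VDW_PARAMS[e] for e in elements]
    except KeyError as exc:
        raise FieldConfigError(
            f"no Lennard-Jones parameters for element {exc.args[0]!r}"
        ) from None
    arr = np.array(pairs)
    return arr[:, 0], arr[:, 1]


def comfa_values(
    mol: Molecule3D, points: np.ndarray, probe: ProbeSpec = ProbeSpec()
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Probe-interaction steric and electrostatic energies at arbitrary points.

    Returns ``(steric, electrostatic, excluded)``.  ``excluded`` marks
    points where the unclamped steric energy reached the truncation value
    (points inside the molecular envelope); the electrostatic values there
    are still the clamped raw sums — cross-compound replacement by the
    column mean happens at block assembly.
    """
    r = cdist(np.atleast_2d(points), mol.coords)
    r = np.maximum(r, 1e-6)

    rmin_half, eps_atom = _lj_params(mol.elements)
    rmin = rmin_half + probe.radius
    eps = np.sqrt(eps_atom * probe.epsilon)
    with np.errstate(over="ignore"):
        frac6 = (rmin / r) ** 6
        steric_raw = np.sum(eps * (frac6 ** 2 - 2.0 * frac6), axis=1)
    excluded = steric_raw >= probe.truncation
    steric = np.minimum(steric_raw, probe.truncation)

    elec_raw = COULOMB_CONSTANT * probe.charge * np.sum(mol.charges / r ** 2, axis=1)
    electrostatic = np.clip(elec_raw, -probe.truncation, probe.truncation)
    return steric, electrostatic, excluded


def comfa_fields(
    mol: Molecule3D, grid: GridSpec, probe: ProbeSpec = ProbeSpec()
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """:func:`comfa_values` evaluated on every lattice point of ``grid``."""
    return comfa_values(mol, grid.points(), probe)


def comsia_values(
    mol: Molecule3D, points: np.ndarray, probe: ProbeSpec = ProbeSpec()
) -> Dict[str, np.ndarray]:
    """Similarity-index values for all five properties at arbitrary points."""
    for key in COMSIA_PROPS:
        if key not in mol.props:
            raise FieldConfigError(
                f"compound {mol.compound_id}: missing similarity property "
                f"{key!r} for its atoms"
            )
    r2 = cdist(np.atleast_2d(points), mol.coords, metric="sqeuclidean")
    g = np.exp(-probe.alpha * r2)
    out = {}
    for key in COMSIA_PROPS:
        w = np.asarray(mol.props[key], float)
        out[key] = -probe.comsia_weights.get(key, 1.0) * (g @ w)
    return out


def comsia_fields(
    mol: Molecule3D, grid: GridSpec, probe: ProbeSpec = ProbeSpec()
) -> Dict[str, np.ndarray]:
    """:func:`comsia_values` evaluated on every lattice point of ``grid``."""
    return comsia_values(mol, grid.points(), probe)


def _as_ensembles(mols) -> Dict[int, List[Molecule3D]]:
    """Normalise a flat series or an id -> conformer-list mapping.

    A compound may be represented by several conformers; its descriptor row
    is then the ensemble mean of the per-conformer field vectors.
    """
    if hasattr(mols, "items"):
        ens = {int(cid): list(group) for cid, group in mols.items()}
    else:
        ens = {}
        for m in mols:
            ens.setdefault(m.compound_id, []).append(m)
    if not ens:
        raise ValueError("no molecules given")
    for cid, group in ens.items():
        if not group:
            raise ValueError(f"empty conformer list for compound {cid}")
    return dict(sorted(ens.items()))


def assemble_comfa_blocks(
    mols,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    electrostatic_exclusion: str = "column_mean",
) -> Dict[str, FieldBlock]:
    """Steric and electrostatic blocks for a series, rows ordered by id.

    ``mols`` may be a flat molecule sequence or an id -> conformer-list
    mapping (rows are then ensemble means; a point counts as sterically
    excluded when most conformers exclude it).  ``electrostatic_exclusion``
    controls values at sterically excluded points: ``"column_mean"``
    replaces them with the mean over non-excluded compounds at that lattice
    point (conventional treatment), ``"raw"`` keeps the clamped Coulomb sums.
    """
    if electrostatic_exclusion not in ("column_mean", "raw"):
        raise ValueError(f"unknown exclusion rule {electrostatic_exclusion!r}")
    ens = _as_ensembles(mols)
    ids = list(ens)
    steric = np.empty((len(ids), grid.n_points))
    elec = np.empty_like(steric)
    excl = np.empty((len(ids), grid.n_points), dtype=bool)
    for i, cid in enumerate(ids):
        rows = [comfa_fields(m, grid, probe) for m in ens[cid]]
        steric[i] = np.mean([r[0] for r in rows], axis=0)
        elec[i] = np.mean([r[1] for r in rows], axis=0)
        excl[i] = np.mean([r[2] for r in rows], axis=0) >= 0.5
    if electrostatic_exclusion == "column_mean":
        n_ok = np.sum(~excl, axis=0)
        col_sum = np.sum(np.where(excl, 0.0, elec), axis=0)
        col_mean = np.where(n_ok > 0, col_sum / np.maximum(n_ok, 1), np.mean(elec, axis=0))
        elec = np.where(excl, col_mean[None, :], elec)
    return {
        "comfa_steric": FieldBlock("comfa_steric", steric, grid, ids, probe),
        "comfa_electrostatic": FieldBlock("comfa_electrostatic", elec, grid, ids, probe),
    }


def assemble_comsia_blocks(
    mols, grid: GridSpec, probe: ProbeSpec = ProbeSpec()
) -> Dict[str, FieldBlock]:
    """All five similarity-index blocks for a series, rows ordered by id.

    Accepts a flat molecule sequence or an id -> conformer-list mapping
    (ensemble-mean rows).
    """
    ens = _as_ensembles(mols)
    ids = list(ens)
    mats = {k: np.empty((len(ids), grid.n_points)) for k in COMSIA_PROPS}
    for i, cid in enumerate(ids):
        per_conf = [comsia_fields(m, grid, probe) for m in ens[cid]]
        for k in COMSIA_PROPS:
            mats[k][i] = np.mean([v[k] for v in per_conf], axis=0)
    return {
        f"comsia_{k}": FieldBlock(f"comsia_{k}", mats[k], grid, ids, probe)
        for k in COMSIA_PROPS
    }


def assemble_block(
    mols,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    field_kind: str = "comsia_S",
    **kwargs,
) -> FieldBlock:
    """One named descriptor block (rows ordered by compound id)."""
    if field_kind in COMFA_FIELD_KINDS:
        return assemble_comfa_blocks(mols, grid, probe, **kwargs)[field_kind]
    if field_kind in COMSIA_FIELD_KINDS:
        return assemble_comsia_blocks(mols, grid, probe)[field_kind]
    raise ValueError(f"unknown field kind {field_kind!r}")
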