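"""Volumetric and tabular exports.

Grids and contour maps go out as OpenDX (via gridData) or Gaussian cube
text files for external viewers; statistics as deterministic JSON;
predictions as CSV."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fields import GridSpec
from .molecule import Molecule3D

__all__ = ["write_dx", "write_cube", "read_dx", "save_json", "predictions_to_csv"]

_BOHR_PER_ANGSTROM = 1.0 / 0.52917721092

_ELEMENT_Z = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
    "Cl": 17, "Br": 35, "I": 53, "X": 6,
}


def write_dx(values: np.ndarray, grid: GridSpec, path: Union[str, Path]) -> None:
    """Export a lattice of values as an OpenDX volumetric file."""
    from gridData import Grid

    g = Grid(
        np.asarray(values, float).reshape(grid.dims),
        origin=np.asarray(grid.origin, float),
        delta=grid.spacing,
    )
    g.export(str(path), file_format="dx")


def read_dx(path: Union[str, Path]):
    from gridData import Grid

    return Grid(str(path))


def write_cube(
    values: np.ndarray,
    grid: GridSpec,
    path: Union[str, Path],
    mol: Optional[Molecule3D] = None,
    comment: str = "grid field",
) -> None:
    """Export a lattice of values as a Gaussian cube file.

    Cube files are in atomic units; coordinates and spacing are converted
    from Angstrom to bohr.  When no molecule is supplied a single dummy
    atom at the grid origin is written (some readers reject zero atoms).
    """
    vals = np.asarray(values, float).reshape(grid.dims)
    origin = np.asarray(grid.origin, float) * _BOHR_PER_ANGSTROM
    step = grid.spacing * _BOHR_PER_ANGSTROM
    atoms = (
        [(_ELEMENT_Z.get(e, 6), xyz) for e, xyz in zip(mol.elements, mol.coords)]
        if mol is not None
        else [(1, np.asarray(grid.origin, float))]
    )
    nx, ny, nz = grid.dims
    with open(path, "w") as fh:
        fh.write(f"{comment}\nvolumetric data on a regular lattice\n")
        fh.write(f"{len(atoms):5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}\n")
        fh.write(f"{nx:5d} {step:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {step:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {step:12.6f}\n")
        for z, xyz in atoms:
            b = np.asarray(xyz, float) * _BOHR_PER_ANGSTROM
            fh.write(f"{z:5d} {float(z):12.6f} {b[0]:12.6f} {b[1]:12.6f} {b[2]:12.6f}\n")
        for ix in range(nx):
            for iy in range(ny):
                row = vals[ix, iy]
                for start in range(0, nz, 6):
                    chunk = row[start : start + 6]
                    fh.write("".join(f"{v:13.5E}" for v in chunk) + "\n")


def save_json(obj: Dict, path: Union[str, Path]) -> None:
    """Deterministic JSON dump (sorted keys, fixed float formatting)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def predictions_to_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
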