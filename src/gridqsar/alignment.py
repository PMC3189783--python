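"""Rigid superposition of a congeneric series onto a reference compound.

Every molecule is least-squares fitted onto the reference over the ordered
heavy atoms of the shared scaffold (uracil ring A with both carbonyl
oxygens plus the N3-aryl ipso ring, 14 atoms).  The fit is a proper
rotation + translation (Kabsch, no scaling, no reflection); mappings that
are equivalent under the two-fold symmetry of the aryl ring are resolved by
the lower post-fit RMSD, then by lexicographic atom order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .molecule import Molecule3D

__all__ = [
    "AlignmentError",
    "CoreMap",
    "find_core",
    "core_candidates",
    "kabsch",
    "align_to_reference",
    "align_series",
    "core_rmsd",
]


class AlignmentError(RuntimeError):
    """Scaffold matching or rigid fitting failed."""


@dataclass
class CoreMap:
    """Resolved scaffold atom indices for a series, all of equal length."""

    reference_id: int
    core_atoms: Dict[int, List[int]]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.core_atoms.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"core atom lists differ in length: {lengths}")


def core_candidates(mol: Molecule3D) -> List[List[int]]:
    """All symmetry-distinct scaffold matches in canonical scaffold order."""
    if mol.smiles is not None:
        from rdkit import Chem

        from .dataset import CORE_SMARTS, _SMARTS_TO_CANONICAL

        rdmol = Chem.AddHs(Chem.MolFromSmiles(mol.smiles))
        if rdmol.GetNumAtoms() != mol.n_atoms:
            raise AlignmentError(
                f"structure string does not describe compound {mol.compound_id}'s atoms"
            )
        patt = Chem.MolFromSmarts(CORE_SMARTS)
        matches = rdmol.GetSubstructMatches(patt, uniquify=False)
        if not matches:
            raise AlignmentError(
                f"scaffold substructure absent from compound {mol.compound_id}"
            )
        ordered = sorted(
            set(tuple(m[i] for i in _SMARTS_TO_CANONICAL) for m in matches)
        )
        return [list(m) for m in ordered]
    if mol.core_atom_indices is not None:
        return [list(mol.core_atom_indices)]
    raise AlignmentError(
        f"compound {mol.compound_id} carries neither a structure string nor "
        "precomputed core atom indices"
    )


def find_core(mol: Molecule3D) -> List[int]:
    """Canonical ordered scaffold match (lexicographically smallest among
    symmetry-equivalent matches)."""
    return core_candidates(mol)[0]


def kabsch(
    moving: np.ndarray, target: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Proper-rotation least-squares fit of ``moving`` onto ``target``.

    Returns ``(R, t, rmsd)`` such that ``moving @ R.T + t`` best matches
    ``target``.  Raises :class:`AlignmentError` for degenerate (collinear)
    point sets, where the rotation about the axis is undetermined.
    """
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    if moving.shape != target.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise AlignmentError("point sets must both be (n, 3) and conformable")
    cm = moving.mean(axis=0)
    ct = target.mean(axis=0)
    a = moving - cm
    b = target - ct
    sv = np.linalg.svd(a, compute_uv=False)
    if sv.size < 2 or sv[1] < 1e-8 * max(sv[0], 1.0):
        raise AlignmentError("degenerate (collinear) core geometry")
    rot, _ = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    t = ct - cm @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((a @ R.T - b) ** 2, axis=1))))
    return R, t, rmsd


def core_rmsd(mol: Molecule3D, ref: Molecule3D, mol_core: Sequence[int], ref_core: Sequence[int]) -> float:
    d = mol.coords[list(mol_core)] - ref.coords[list(ref_core)]
    return float(np.sqrt(np.mean(np.sum(d ** 2, axis=1))))


def align_to_reference(
    mol: Molecule3D,
    ref: Molecule3D,
    core_map: Optional[CoreMap] = None,
) -> Molecule3D:
    """Rigidly superpose ``mol`` onto ``ref`` over the shared scaffold.

    When no :class:`CoreMap` is supplied, the scaffold is matched on the
    fly; among symmetry-equivalent aryl mappings the one with the smallest
    post-fit RMSD wins (ties resolved lexicographically by the candidate
    ordering, which is already sorted).
    """
    ref_core = (
        core_map.core_atoms[ref.compound_id]
        if core_map is not None and ref.compound_id in core_map.core_atoms
        else find_core(ref)
    )
    if core_map is not None and mol.compound_id in core_map.core_atoms:
        candidates = [core_map.core_atoms[mol.compound_id]]
    else:
        candidates = core_candidates(mol)

    best: Optional[Tuple[float, np.ndarray, np.ndarray, List[int]]] = None
    for cand in candidates:
        R, t, rmsd = kabsch(mol.coords[list(cand)], ref.coords[list(ref_core)])
        if best is None or rmsd < best[0] - 1e-12:
            best = (rmsd, R, t, list(cand))
    assert best is not None
    _, R, t, chosen = best
    out = mol.transformed(R, t)
    out.core_atom_indices = chosen
    return out


def align_series(
    mols: Sequence[Molecule3D], reference_id: int = 58
) -> Tuple[List[Molecule3D], CoreMap]:
    """Align every molecule (including the reference) onto the reference.

    The reference itself is centred at its core centroid orientation as-is;
    all other molecules are fitted onto it.  Returns the aligned series in
    the input order together with the resolved :class:`CoreMap`.
    """
    by_id = {m.compound_id: m for m in mols}
    if reference_id not in by_id:
        raise AlignmentError(f"reference compound {reference_id} not in the series")
    ref = by_id[reference_id]
    aligned: List[Molecule3D] = []
    core_atoms: Dict[int, List[int]] = {}
    for m in mols:
        out = align_to_reference(m, ref)
        aligned.append(out)
        core_atoms[m.compound_id] = list(out.core_atom_indices)
    return aligned, CoreMap(reference_id=reference_id, core_atoms=core_atoms)
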