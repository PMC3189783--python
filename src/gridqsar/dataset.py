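"""Encode the 60-compound arylpyrimidinedione (APD) series.

The compounds are 3-aryl-pyrimidine-2,4-diones: a uracil ring (ring A)
carrying a substituent R1 on N1, an aryl ring on N3 and a substituent R2 on
C6, assayed as non-competitive antagonists of the housefly GABA-gated
chloride channel (pKi from a [3H]-EBOB displacement assay).  This module
turns the tabulated substitution patterns into SMILES, embeds a single
low-energy 3D conformer per compound (ETKDG + MMFF94 minimisation), assigns
Gasteiger partial charges and populates the five per-atom similarity-index
properties used by the field engine.

Two transcription corrections are applied at load time and logged: the
printed pKi of compound 28 ("42", far outside the stated 3.8-9.3 activity
range) is read as 4.2, and compound 49's bare "5" as 5.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Lipinski, rdMolDescriptors

from .molecule import COMSIA_PROPS, Molecule3D

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "UnsupportedGroupError",
    "load_table",
    "build_structure",
    "embed_molecule",
    "embed_constrained_ensemble",
    "build_series",
    "build_series_ensembles",
    "to_rdkit",
    "export_sdf",
    "records_to_dataframe",
    "SUBSTITUENT_SMILES",
    "CORE_SMARTS",
    "CORE_ATOM_LABELS",
]


class UnsupportedGroupError(ValueError):
    """A substituent code outside the supported vocabulary."""


#: pKi transcription corrections (printed value -> value used), logged at load
PKI_CORRECTIONS = {28: 4.2}

#: test-set compound ids (asterisked rows of the source table)
TEST_IDS = frozenset({4, 5, 6, 7, 14, 21, 38, 39, 40, 41, 43, 45, 53, 56, 60})

#: test-set compounds whose prediction residual exceeded one log unit
OUTLIER_IDS = frozenset({14, 21})

# Substituent vocabulary.  Fragments are SMILES written attachment-atom
# first, suitable for insertion as a branch; ring-bearing fragments use ring
# bond number 9 (the scaffold uses 1, the N3-aryl ring uses 2).
SUBSTITUENT_SMILES: Dict[str, str] = {
    "H": "",
    "F": "F",
    "Cl": "Cl",
    "Br": "Br",
    "I": "I",
    "CH3": "C",
    "NH2": "N",
    "CN": "C#N",
    "COOH": "C(=O)O",
    "CF3": "C(F)(F)F",
    "CF2CF3": "C(F)(F)C(F)(F)F",
    "CF2CF2CF3": "C(F)(F)C(F)(F)C(F)(F)F",
    "CF2CF2CF2CF3": "C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",
    "CH(CH3)2": "C(C)C",
    "C(CH3)3": "C(C)(C)C",
    "CH2C(CH3)3": "CC(C)(C)C",
    "CH2CF3": "CC(F)(F)F",
    "CH2CN": "CC#N",
    "CH2COCH3": "CC(C)=O",
    "CH2OCH3": "COC",
    "CH2SCH3": "CSC",
    "CH2SO2CH3": "CS(C)(=O)=O",
    "CH2CH2CF3": "CCC(F)(F)F",
    "CH2CH2CH3": "CCC",
    "CH2CH2OCH3": "CCOC",
    "CH2CH2CH2CH3": "CCCC",
    "CH2Ph": "Cc9ccccc9",
    "NHCOCH3": "NC(C)=O",
    "OCH3": "OC",
    "OCH(CH3)2": "OC(C)C",
    "SCH3": "SC",
    "SOCH3": "S(=O)C",
    "N(CH3)2": "N(C)C",
    "Ph": "c9ccccc9",
    "2-thienyl": "c9cccs9",
    "2-F-phenyl": "c9ccccc9F",
    "4-F-phenyl": "c9ccc(F)cc9",
}

# Invariant scaffold (ring A + N3-aryl ipso ring) as a SMARTS whose atom
# order is N1, C2, O2, N3, ipso, 2', 3', 4', 5', 6', C4, O4, C5, C6.
CORE_SMARTS = (
    "[#7]1[#6](=[#8X1])[#7](-[#6]2:[#6]:[#6]:[#6]:[#6]:[#6]:2)"
    "[#6](=[#8X1])[#6][#6]1"
)

# Reordering of a SMARTS match into the canonical scaffold numbering
# N1, C2, O2, N3, C4, O4, C5, C6, ipso, 2', 3', 4', 5', 6'.
_SMARTS_TO_CANONICAL = (0, 1, 2, 3, 10, 11, 12, 13, 4, 5, 6, 7, 8, 9)

CORE_ATOM_LABELS = (
    "N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6",
    "ipso", "2'", "3'", "4'", "5'", "6'",
)


@dataclass
class CompoundRecord:
    """One row of the compound table."""

    id: int
    aryl_subs: Dict[int, str]  # benzene ring position (2-6) -> code
    r1: str
    r2: str
    pki: float
    is_test: bool
    is_outlier: bool = False
    note: str = ""

    @property
    def is_train(self) -> bool:
        return not self.is_test


def _parse_aryl_pattern(pattern: str) -> Dict[int, str]:
    """Parse ``"3-Cl,4-(2-thienyl),5-Cl"`` into ``{3: "Cl", 4: "2-thienyl", 5: "Cl"}``."""
    pattern = pattern.strip()
    if pattern in ("H", "-H", ""):
        return {}
    subs: Dict[int, str] = {}
    for token in pattern.split(","):
        token = token.strip()
        pos_str, _, code = token.partition("-")
        try:
            pos = int(pos_str)
        except ValueError as exc:
            raise ValueError(f"malformed aryl substituent token {token!r}") from exc
        if pos not in (2, 3, 4, 5, 6):
            raise ValueError(f"aryl position {pos} outside 2-6 in token {token!r}")
        code = code.strip()
        if code.startswith("(") and code.endswith(")"):
            code = code[1:-1]
        subs[pos] = code
    return subs


def load_table(path: Optional[str] = None) -> List[CompoundRecord]:
    """Load the packaged compound table (or a user CSV in the same layout).

    Returns the 60 records with the split and outlier flags set and the
    documented pKi transcription corrections applied.
    """
    if path is None:
        src = resources.files("gridqsar.data").joinpath("apd_table.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, dtype={"corrected": str})
    else:
        df = pd.read_csv(path, dtype={"corrected": str})

    records: List[CompoundRecord] = []
    for _, row in df.iterrows():
        try:
            cid = int(row["id"])
            pki = float(row["pKi"])
            if cid in PKI_CORRECTIONS:
                logger.warning(
                    "compound %d: pKi %s corrected to %s (%s)",
                    cid, row["pKi"], PKI_CORRECTIONS[cid], row.get("corrected", ""),
                )
                pki = PKI_CORRECTIONS[cid]
            elif isinstance(row.get("corrected"), str) and row["corrected"].strip():
                logger.info("compound %d: %s", cid, row["corrected"])
            rec = CompoundRecord(
                id=cid,
                aryl_subs=_parse_aryl_pattern(str(row["X"])),
                r1=str(row["R1"]).strip(),
                r2=str(row["R2"]).strip(),
                pki=pki,
                is_test=bool(int(row["test"])),
                is_outlier=cid in OUTLIER_IDS,
                note=str(row["corrected"]) if isinstance(row.get("corrected"), str) else "",
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed compound-table row {dict(row)!r}: {exc}") from exc
        records.append(rec)

    _validate_records(records)
    return records


def _validate_records(records: List[CompoundRecord]) -> None:
    ids = [r.id for r in records]
    if sorted(ids) != list(range(1, 61)):
        raise ValueError(f"expected ids 1-60, got {len(ids)} records")
    n_test = sum(r.is_test for r in records)
    if n_test != 15:
        raise ValueError(f"expected 15 test compounds, found {n_test}")
    for r in records:
        if r.is_outlier and not r.is_test:
            raise ValueError(f"outlier {r.id} not in the test set")
    pkis = [r.pki for r in records]
    if not (min(pkis) == 3.8 and max(pkis) == 9.3):
        raise ValueError(
            f"pKi range [{min(pkis)}, {max(pkis)}] does not match the expected [3.8, 9.3]"
        )


def _fragment(code: str) -> str:
    try:
        return SUBSTITUENT_SMILES[code]
    except KeyError:
        raise UnsupportedGroupError(
            f"substituent code {code!r} not in the supported vocabulary "
            f"({sorted(SUBSTITUENT_SMILES)})"
        ) from None


def build_structure(record: CompoundRecord) -> str:
    """Assemble the compound's SMILES from the uracil scaffold and return it
    in canonical form."""
    aryl_atoms = []
    for pos in (2, 3, 4, 5):
        frag = _fragment(record.aryl_subs.get(pos, "H"))
        aryl_atoms.append(f"c({frag})" if frag else "c")
    frag6 = _fragment(record.aryl_subs.get(6, "H"))
    aryl_atoms.append(f"c2({frag6})" if frag6 else "c2")
    aryl = "c2" + "".join(aryl_atoms)

    r1 = _fragment(record.r1)
    n1 = f"N1({r1})" if r1 else "N1"
    r2 = _fragment(record.r2)
    if not r2:
        raise UnsupportedGroupError("R2 = H is not part of the series")
    smiles = f"{n1}C(=O)N({aryl})C(=O)C=C1{r2}"

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"assembled SMILES for compound {record.id} failed to parse: {smiles}")
    return Chem.MolToSmiles(mol)


def _donor_acceptor_flags(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
    n = mol.GetNumAtoms()
    donors = np.zeros(n)
    acceptors = np.zeros(n)
    for (idx,) in mol.GetSubstructMatches(Lipinski.HDonorSmarts):
        donors[idx] = 1.0
    for (idx,) in mol.GetSubstructMatches(Lipinski.HAcceptorSmarts):
        acceptors[idx] = 1.0
    return donors, acceptors


def _core_match(mol: Chem.Mol) -> List[int]:
    """Unique canonical scaffold match in scaffold numbering (see find_core)."""
    patt = Chem.MolFromSmarts(CORE_SMARTS)
    matches = mol.GetSubstructMatches(patt, uniquify=False)
    if not matches:
        raise ValueError("scaffold substructure absent")
    ordered = sorted(tuple(m[i] for i in _SMARTS_TO_CANONICAL) for m in matches)
    return list(ordered[0])


#: conformers per compound whose fields are averaged in the real pipeline
N_FIELD_CONFORMERS = 6


def _finish_molecule(molh: Chem.Mol, structure: str, compound_id: int) -> Molecule3D:
    """Charge, type and wrap an embedded RDKit molecule as a Molecule3D."""
    # MMFF setup switches the molecule to MMFF aromaticity; restore the
    # default perception so scaffold matching and typing behave normally
    Chem.SanitizeMol(molh)
    AllChem.ComputeGasteigerCharges(molh)
    pt = Chem.GetPeriodicTable()
    charges = np.array([float(a.GetProp("_GasteigerCharge")) for a in molh.GetAtoms()])
    if not np.all(np.isfinite(charges)):
        raise ValueError(f"Gasteiger charges undefined for compound {compound_id}")
    radii = np.array([pt.GetRvdw(a.GetAtomicNum()) for a in molh.GetAtoms()])
    crippen = rdMolDescriptors._CalcCrippenContribs(molh)
    hydrophobic = np.array([c[0] for c in crippen])
    donors, acceptors = _donor_acceptor_flags(molh)
    core = _core_match(molh)
    m3d = Molecule3D(
        compound_id=compound_id,
        elements=[a.GetSymbol() for a in molh.GetAtoms()],
        coords=molh.GetConformer().GetPositions(),
        charges=charges,
        vdw_radii=radii,
        props={
            "S": radii ** 3,
            "E": charges,
            "H": hydrophobic,
            "D": donors,
            "A": acceptors,
        },
        core_atom_indices=core,
        anchors=_substituent_anchors(molh, core),
        smiles=structure,
    )
    m3d.validate()
    return m3d


def embed_molecule(structure: str, seed: int, compound_id: int = 0) -> Molecule3D:
    """Embed one energy-minimised 3D conformer and populate atom properties.

    A single ETKDG conformer is generated with the given random seed and
    relaxed with MMFF94; Gasteiger charges are then assigned.  The result is
    deterministic for a given (structure, seed) pair.  Heavy atoms keep the
    ordering of the parsed SMILES, so scaffold atom indices remain valid.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure for compound {compound_id}: {structure}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise RuntimeError(f"3D embedding failed for compound {compound_id}")
    AllChem.MMFFOptimizeMolecule(molh, maxIters=5000, nonBondedThresh=100.0)
    return _finish_molecule(molh, structure, compound_id)


def embed_constrained_ensemble(
    structure: str,
    reference: Molecule3D,
    seed: int,
    compound_id: int = 0,
    n_conformers: int = N_FIELD_CONFORMERS,
) -> List[Molecule3D]:
    """Embed conformers that inherit the reference's shared-substructure
    geometry.

    The maximum common substructure (element-matched, whole rings only)
    between the compound and the reference is located and its atoms are
    constrained to the reference coordinates during distance-geometry
    embedding; the remaining (differing) substituent atoms are then relaxed
    with MMFF94 while the template atoms stay fixed.  This emulates the
    analog-by-modification workflow used for congeneric series: compounds
    differ from the template only where their substituents actually differ,
    so descriptor noise from irrelevant torsions is minimal.

    Conformers come out in an arbitrary overall frame (distance geometry is
    frame-free) and must still be rigidly aligned onto the reference.
    """
    from rdkit.Chem import rdFMCS
    from rdkit.Geometry import Point3D

    refh = to_rdkit(reference)
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure for compound {compound_id}: {structure}")
    molh0 = Chem.AddHs(mol)
    mcs = rdFMCS.FindMCS(
        [Chem.RemoveHs(molh0), Chem.RemoveHs(refh)],
        ringMatchesRingOnly=True,
        completeRingsOnly=True,
        timeout=10,
    )
    query = Chem.MolFromSmarts(mcs.smartsString) if mcs.numAtoms else None
    coord_map = {}
    if query is not None:
        mol_idx = molh0.GetSubstructMatch(query)
        ref_idx = refh.GetSubstructMatch(query)
        conf = refh.GetConformer()
        coord_map = {
            int(m): Point3D(*[float(x) for x in conf.GetAtomPosition(int(r))])
            for m, r in zip(mol_idx, ref_idx)
        }
    if len(coord_map) < 10:
        raise RuntimeError(
            f"common substructure with the reference too small for compound "
            f"{compound_id} ({len(coord_map)} atoms)"
        )

    out: List[Molecule3D] = []
    tries = 0
    while len(out) < n_conformers and tries < 3 * n_conformers:
        m = Chem.Mol(molh0)
        sub_seed = (int(seed) + 7919 * tries) & 0x7FFFFFFF
        tries += 1
        ok = AllChem.EmbedMolecule(
            m,
            coordMap=coord_map,
            randomSeed=sub_seed,
            useExpTorsionAnglePrefs=True,
            useBasicKnowledge=True,
        )
        if ok != 0:
            continue
        props = AllChem.MMFFGetMoleculeProperties(m)
        ff = AllChem.MMFFGetMoleculeForceField(m, props, nonBondedThresh=100.0)
        for idx in coord_map:
            ff.AddFixedPoint(int(idx))
        ff.Minimize(maxIts=2000)
        out.append(_finish_molecule(m, structure, compound_id))
    if not out:
        raise RuntimeError(f"constrained embedding failed for compound {compound_id}")
    return out


def _substituent_anchors(mol: Chem.Mol, core: List[int]) -> Dict[str, int]:
    """Label each substitution site with the first atom of its substituent.

    Ring positions keep the ring atom itself as a fallback when
    unsubstituted, so every site always has a coordinate to report against.
    """
    core_set = set(core)
    anchors: Dict[str, int] = {}
    site_atoms = {"N1-R1": core[0], "C6-R2": core[7]}
    for lbl, idx in zip(CORE_ATOM_LABELS[9:], core[9:]):
        site_atoms[lbl] = idx
    for label, atom_idx in site_atoms.items():
        atom = mol.GetAtomWithIdx(int(atom_idx))
        sub = [
            nb.GetIdx()
            for nb in atom.GetNeighbors()
            if nb.GetIdx() not in core_set and nb.GetSymbol() != "H"
        ]
        anchors[label] = min(sub) if sub else int(atom_idx)
    return anchors


def build_series(
    records: List[CompoundRecord], seed: int = 20110923
) -> List[Molecule3D]:
    """Build, embed and annotate every record; per-compound seeds are derived
    from the global seed so the whole series is reproducible."""
    mols = []
    for rec in records:
        smiles = build_structure(rec)
        mols.append(embed_molecule(smiles, seed=(seed + rec.id) & 0x7FFFFFFF, compound_id=rec.id))
    return mols


def build_series_ensembles(
    records: List[CompoundRecord],
    seed: int = 20110923,
    reference_id: int = 58,
    n_conformers: int = N_FIELD_CONFORMERS,
) -> Dict[int, List[Molecule3D]]:
    """Template-based conformer ensembles for the whole series.

    The reference compound is embedded and minimised once; every other
    compound inherits the reference geometry over their common substructure
    (:func:`embed_constrained_ensemble`) and contributes ``n_conformers``
    conformers whose fields downstream code averages.  The reference's
    ensemble is the single template conformation itself.
    """
    by_id = {r.id: r for r in records}
    if reference_id not in by_id:
        raise ValueError(f"reference compound {reference_id} not among the records")
    ref_smiles = build_structure(by_id[reference_id])
    reference = embed_molecule(
        ref_smiles, seed=(seed + reference_id) & 0x7FFFFFFF, compound_id=reference_id
    )
    ensembles: Dict[int, List[Molecule3D]] = {}
    for rec in records:
        if rec.id == reference_id:
            ensembles[rec.id] = [reference]
            continue
        smiles = build_structure(rec)
        ensembles[rec.id] = embed_constrained_ensemble(
            smiles,
            reference,
            seed=(seed + rec.id) & 0x7FFFFFFF,
            compound_id=rec.id,
            n_conformers=n_conformers,
        )
    return ensembles


def to_rdkit(mol3d: Molecule3D) -> Chem.Mol:
    """Rebuild an RDKit molecule carrying this conformation (for SDF export)."""
    smiles = getattr(mol3d, "smiles", None)
    if smiles is None:
        raise ValueError("molecule does not carry a structure string")
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    if mol.GetNumAtoms() != mol3d.n_atoms:
        raise ValueError("atom count mismatch between structure string and coordinates")
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(mol3d.coords):
        conf.SetAtomPosition(i, [float(x) for x in xyz])
    mol.AddConformer(conf, assignId=True)
    return mol


def export_sdf(mols: List[Molecule3D], path: str) -> None:
    """Write the series to a multi-record SDF (V2000)."""
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            rd = to_rdkit(m)
            rd.SetProp("_Name", f"compound_{m.compound_id}")
            rd.SetIntProp("compound_id", m.compound_id)
            writer.write(rd)
    finally:
        writer.close()


def records_to_dataframe(records: List[CompoundRecord]) -> pd.DataFrame:
    """Corrected record table as a DataFrame (CSV-exportable)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "X": [
                ",".join(f"{p}-{c}" for p, c in sorted(r.aryl_subs.items())) or "H"
                for r in records
            ],
            "R1": [r.r1 for r in records],
            "R2": [r.r2 for r in records],
            "pKi": [r.pki for r in records],
            "test": [int(r.is_test) for r in records],
            "outlier": [int(r.is_outlier) for r in records],
        }
    )
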