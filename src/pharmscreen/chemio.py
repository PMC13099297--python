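"""Readers, writers and molecular descriptors for the screening pipeline.

Handles the three structural formats the pipeline touches — PDB for
receptor–ligand complexes, SDF V2000 for compound libraries — and the
drug-likeness descriptors (MW, H-bond donor/acceptor counts, Crippen logP)
used by the Lipinski filter.  RDKit does the chemistry; Biopython parses
PDB.  All coordinates are Ångström in a right-handed frame.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors

logger = logging.getLogger(__name__)

# RDKit reports skipped records through our logger, not stderr spam.
RDLogger.DisableLog("rdApp.error")

_BOND_ORDERS = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}
_BOND_ORDERS_INV = {v: k for k, v in _BOND_ORDERS.items()}


class ReceptorAtom(NamedTuple):
    element: str
    position: np.ndarray  # (3,) Å
    res_name: str
    res_seq: int
    chain: str
    atom_name: str


class LigandAtom(NamedTuple):
    element: str
    position: np.ndarray  # (3,) Å
    atom_name: str


@dataclass
class ComplexStructure:
    """A receptor–ligand complex: polymer atoms plus one selected HETATM residue.

    Waters are never present; they are dropped at parse time (bound or not,
    crystallographic waters are removed before feature perception).
    """

    receptor_atoms: list[ReceptorAtom]
    ligand_atoms: list[LigandAtom]

    def __post_init__(self) -> None:
        for a in self.receptor_atoms:
            if not np.all(np.isfinite(a.position)):
                raise ValueError(f"non-finite receptor coordinate on {a.atom_name}")
        for a in self.ligand_atoms:
            if not np.all(np.isfinite(a.position)):
                raise ValueError(f"non-finite ligand coordinate on {a.atom_name}")


@dataclass
class MoleculeRecord:
    """One library compound (one conformer): identity, coordinates, bonds.

    ``atoms`` is a list of ``(element_symbol, xyz)`` with xyz in Å; ``bonds``
    is ``((i, j), order)`` with 0-based atom indices.  ``source_line`` is the
    1-based line in the source SDF where the record's block started (-1 if
    built programmatically).
    """

    id: str
    atoms: list[tuple[str, np.ndarray]]
    bonds: list[tuple[tuple[int, int], int]]
    conformer_id: int = 0
    source_line: int = -1
    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        n = len(self.atoms)
        for (i, j), order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"molecule {self.id!r}: invalid bond ({i}, {j})")
        for sym, pos in self.atoms:
            if not np.all(np.isfinite(np.asarray(pos, dtype=float))):
                raise ValueError(f"molecule {self.id!r}: non-finite coordinate on {sym}")

    # -- RDKit bridge -------------------------------------------------------

    def to_rdkit(self) -> Chem.Mol:
        """Return a sanitized RDKit molecule with a 3D conformer attached."""
        if self._mol is not None:
            return self._mol
        rw = Chem.RWMol()
        for sym, _ in self.atoms:
            try:
                rw.AddAtom(Chem.Atom(sym))
            except Exception as exc:  # pragma: no cover - rdkit raises RuntimeError
                raise ValueError(f"unknown element symbol {sym!r}") from exc
        for (i, j), order in self.bonds:
            rw.AddBond(i, j, _BOND_ORDERS.get(order, Chem.BondType.SINGLE))
        conf = Chem.Conformer(len(self.atoms))
        for idx, (_, pos) in enumerate(self.atoms):
            x, y, z = (float(v) for v in pos)
            conf.SetAtomPosition(idx, (x, y, z))
        mol = rw.GetMol()
        mol.AddConformer(conf, assignId=True)
        Chem.SanitizeMol(mol)
        mol.SetProp("_Name", self.id)
        self._mol = mol
        return mol

    @classmethod
    def from_rdkit(
        cls,
        mol: Chem.Mol,
        mol_id: str | None = None,
        conformer_id: int = 0,
        source_line: int = -1,
    ) -> "MoleculeRecord":
        if mol.GetNumConformers() == 0:
            raise ValueError("molecule has no 3D coordinates")
        positions = mol.GetConformer().GetPositions()
        atoms = [
            (a.GetSymbol(), positions[a.GetIdx()].astype(float))
            for a in mol.GetAtoms()
        ]
        bonds = [
            (
                (b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                _BOND_ORDERS_INV.get(b.GetBondType(), 1),
            )
            for b in mol.GetBonds()
        ]
        name = mol_id
        if name is None:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        rec = cls(
            id=name,
            atoms=atoms,
            bonds=bonds,
            conformer_id=conformer_id,
            source_line=source_line,
        )
        mol.SetProp("_Name", rec.id)
        rec._mol = mol
        return rec


@dataclass(frozen=True)
class DescriptorSet:
    """Rule-of-five descriptors: MW (Da), donor/acceptor counts, Crippen logP."""

    mw: float
    hbd: int
    hba: int
    logp: float

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError("molecular weight must be positive")
        if self.hbd < 0 or self.hba < 0:
            raise ValueError("H-bond counts must be non-negative")


# ---------------------------------------------------------------------------
# PDB complexes
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pdb_complex(path: str | Path, ligand_selector: str) -> ComplexStructure:
    """Read a receptor–ligand complex from a PDB file.

    The receptor is every polymer (ATOM-record) atom; the ligand is the
    HETATM residue(s) whose residue name equals ``ligand_selector``.  Waters
    are discarded.  Alternate locations other than blank/'A' are dropped.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` when
    no residue matches the selector.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("complex", str(path))

    receptor: list[ReceptorAtom] = []
    ligand: list[LigandAtom] = []
    sel = ligand_selector.strip().upper()
    for model in structure:
        for chain in model:
            for residue in chain:
                hetflag, resseq, _ = residue.id
                resname = residue.get_resname().strip().upper()
                if hetflag == "W" or resname in _WATER_NAMES:
                    continue
                for atom in residue.get_unpacked_list():
                    if atom.get_altloc() not in (" ", "A"):
                        continue
                    pos = np.asarray(atom.get_coord(), dtype=float)
                    elem = (atom.element or atom.get_name()[:1]).strip().capitalize()
                    if hetflag == " ":
                        receptor.append(
                            ReceptorAtom(
                                elem, pos, resname, int(resseq), chain.id, atom.get_name()
                            )
                        )
                    elif resname == sel:
                        ligand.append(LigandAtom(elem, pos, atom.get_name()))
        break  # first model only
    if not ligand:
        raise ValueError(f"ligand not found: no HETATM residue named {ligand_selector!r}")
    return ComplexStructure(receptor_atoms=receptor, ligand_atoms=ligand)


# ---------------------------------------------------------------------------
# SDF V2000 libraries
# ---------------------------------------------------------------------------


def _iter_sdf_blocks(text: str):
    """Yield (start_line, block_text) for each $$$$-delimited record."""
    lines = text.split("\n")
    start = 0
    block: list[str] = []
    for lineno, line in enumerate(lines):
        if line.strip() == "$$$$":
            if any(s.strip() for s in block):
                yield start + 1, "\n".join(block) + "\n"
            block = []
            start = lineno + 1
        else:
            block.append(line)
    if any(s.strip() for s in block):
        yield start + 1, "\n".join(block) + "\n"


def parse_sdf_text(text: str) -> list[MoleculeRecord]:
    """Parse SDF text into records; unparseable blocks are skipped and logged.

    Consecutive records sharing the same (non-empty) title are treated as
    conformers of one compound and numbered with increasing ``conformer_id``.
    V3000 blocks are rejected outright.
    """
    records: list[MoleculeRecord] = []
    conf_counts: dict[str, int] = {}
    for start_line, block in _iter_sdf_blocks(text):
        if "V3000" in block:
            raise ValueError(
                f"V3000 connection table at line {start_line}: only V2000 is supported"
            )
        mol = Chem.MolFromMolBlock(block, sanitize=True, removeHs=False)
        if mol is None:
            logger.warning("skipping unparseable SDF block starting at line %d", start_line)
            continue
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        mol_id = title if title else f"mol{len(records) + 1}"
        cid = conf_counts.get(mol_id, 0)
        conf_counts[mol_id] = cid + 1
        records.append(
            MoleculeRecord.from_rdkit(mol, mol_id=mol_id, conformer_id=cid, source_line=start_line)
        )
    return records


def read_sdf_library(path: str | Path) -> list[MoleculeRecord]:
    """Read an SDF V2000 library; one MoleculeRecord per molecule block."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("empty SDF file: %s", path)
        return []
    return parse_sdf_text(text)


def records_to_sdf_text(records: Sequence[MoleculeRecord]) -> str:
    out = []
    for rec in records:
        out.append(Chem.MolToMolBlock(rec.to_rdkit(), kekulize=True))
        out.append("$$$$\n")
    return "".join(out)


def write_sdf_library(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    Path(path).write_text(records_to_sdf_text(records))


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------


def _is_donor_atom(atom: Chem.Atom) -> bool:
    # Lipinski's original OH + NH count, per heavy atom: an N or O bearing
    # at least one hydrogen counts once however many hydrogens it carries.
    return atom.GetAtomicNum() in (7, 8) and atom.GetTotalNumHs(includeNeighbors=True) > 0


def _is_acceptor_atom(atom: Chem.Atom) -> bool:
    # All N and O except pyrrole-type aromatic NH, whose lone pair is in the
    # ring π system (the same atoms the Crippen scheme treats as non-acceptor).
    z = atom.GetAtomicNum()
    if z not in (7, 8):
        return False
    if z == 7 and atom.GetIsAromatic() and atom.GetTotalNumHs(includeNeighbors=True) > 0:
        return False
    return True


def compute_descriptors(mol: MoleculeRecord) -> DescriptorSet:
    """Compute MW / HBD / HBA / logP for a library compound.

    MW is the sum of standard atomic weights over all atoms (implicit
    hydrogens included); logP is the Crippen atom-contribution estimate.
    """
    m = mol.to_rdkit()
    mw = Descriptors.MolWt(m)
    hbd = sum(1 for a in m.GetAtoms() if _is_donor_atom(a))
    hba = sum(1 for a in m.GetAtoms() if _is_acceptor_atom(a))
    logp = Crippen.MolLogP(m)
    if math.isnan(mw) or mw <= 0:
        raise ValueError(f"could not compute molecular weight for {mol.id!r}")
    return DescriptorSet(mw=mw, hbd=hbd, hba=hba, logp=logp)
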