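"""Shared fixtures: a planted galactose-like complex, its model, and helpers."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from pharmscreen import (
    MoleculeRecord,
    build_model,
    detect_hbonds,
    galactose_like_spec,
    generate_complex,
    read_pdb_complex,
)


def record_from_smiles(smiles: str, name: str, seed: int = 42) -> MoleculeRecord:
    """Deterministically embedded 3D record for a small molecule."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    return MoleculeRecord.from_rdkit(mol, mol_id=name)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


@pytest.fixture(scope="session")
def planted_complex(tmp_path_factory):
    """(ComplexStructure, ground-truth contacts) for the 4-donor/1-acceptor fixture."""
    text, truth = generate_complex(galactose_like_spec(seed=1))
    path = tmp_path_factory.mktemp("complex") / "complex.pdb"
    path.write_text(text)
    return read_pdb_complex(path, "LIG"), truth


@pytest.fixture(scope="session")
def galactose_model(planted_complex):
    """The canonical 4-donor + 1-acceptor pharmacophore model."""
    cx, _ = planted_complex
    return build_model(detect_hbonds(cx), cx)
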