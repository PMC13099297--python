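"""Synthetic fixtures with ground truth for every pipeline stage.

Real inputs of this kind — a crystal complex of a sugar transporter, a
proprietary screening library, a curated active/decoy validation set, raw
uptake counts — are either unavailable or unpublishable, so each generator
emulates one of them with planted, verifiable structure:

* ``generate_complex``: a minimal receptor (capped polar residues) around a
  polyol-like ligand, with hydrogen-bond contacts planted strictly inside
  (or outside) the detection criteria.  The returned contact list is the
  oracle for H-bond perception.
* ``generate_library``: an SDF library of actives whose perceived feature
  points are a rigid transform of a pharmacophore model plus Gaussian
  jitter, mixed with random-geometry decoys.  Labels are the oracle for
  enrichment statistics.
* ``generate_assay``: replicated 4PL dose–response data with known IC50,
  Hill slope and Gaussian noise — the oracle for curve fitting.

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .activity import STANDARD_DOSE_LADDER_NM, DoseResponseDataset, Target, four_pl
from .chemio import MoleculeRecord
from .pharmacophore import (
    DEFAULT_CRITERIA,
    Direction,
    FeatureKind,
    HBondCriteria,
    PharmacophoreModel,
)

# residue identities cycled through for planted receptor contacts
_RESIDUE_CYCLE = [
    ("LYS", 294, "NZ", "N"),
    ("GLU", 88, "OE1", "O"),
    ("GLN", 69, "OE1", "O"),
    ("SER", 91, "OG", "O"),
    ("GLN", 428, "NE2", "N"),
    ("ASN", 260, "OD1", "O"),
    ("THR", 431, "OG1", "O"),
    ("TYR", 263, "OH", "O"),
]

_LIGAND_RING_RADIUS = 4.0  # Å
_OH_BOND = 0.97  # Å
_CO_BOND = 1.4  # Å
_NONPLANTED_BUFFER = 0.2  # Å clearance outside criteria for every other polar pair


@dataclass(frozen=True)
class PlantedContact:
    """Ground truth for one planted hydrogen bond."""

    ligand_atom_index: int  # index into the parsed ligand atom list
    residue_label: str
    direction: Direction
    distance: float


@dataclass(frozen=True)
class ComplexSpec:
    """Recipe for a toy receptor–ligand complex with planted H-bonds.

    ``geometry_margin`` > 0 plants every contact that far inside the default
    criteria (distance = cutoff − margin, angle 180°); < 0 plants them
    outside.  ``n_waters`` adds far-away crystallographic waters that parsers
    must discard.
    """

    n_planted_contacts: int
    directions: tuple[Direction, ...]
    geometry_margin: float = 0.3
    seed: int = 0
    n_waters: int = 0

    def __post_init__(self) -> None:
        if self.geometry_margin == 0:
            raise ValueError("geometry_margin must be non-zero")
        if len(self.directions) != self.n_planted_contacts:
            raise ValueError("directions must have one entry per planted contact")
        if self.n_planted_contacts < 1:
            raise ValueError("need at least one planted contact")
        if self.n_planted_contacts > len(_RESIDUE_CYCLE):
            raise ValueError(
                f"cannot place more than {len(_RESIDUE_CYCLE)} contacts without collisions"
            )


def galactose_like_spec(seed: int = 0, margin: float = 0.3, n_waters: int = 0) -> ComplexSpec:
    """The canonical fixture: four ligand-donor and one ligand-acceptor contacts,
    mimicking a pyranose's four donating hydroxyls plus one accepting oxygen."""
    return ComplexSpec(
        n_planted_contacts=5,
        directions=(
            Direction.LIGAND_DONOR,
            Direction.LIGAND_DONOR,
            Direction.LIGAND_DONOR,
            Direction.LIGAND_DONOR,
            Direction.LIGAND_ACCEPTOR,
        ),
        geometry_margin=margin,
        seed=seed,
        n_waters=n_waters,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det +1)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def _pdb_atom_line(
    record: str,
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    pos: np.ndarray,
    element: str,
) -> str:
    pname = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:5d} {pname:<4s} {resname:>3s} {chain:1s}{resseq:4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{element:>2s}\n"
    )


def generate_complex(
    spec: ComplexSpec, criteria: HBondCriteria = DEFAULT_CRITERIA
) -> tuple[str, list[PlantedContact]]:
    """Build PDB text for a planted complex plus its ground-truth contacts.

    The ligand's hydroxyl/ether oxygens sit on a ring; each planted receptor
    polar atom lies radially outward at ``cutoff − margin`` (donor hydrogens
    collinear, so the D–H···A angle is 180°).  All non-planted polar pairs
    are strictly outside the criteria, which is asserted before returning.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_planted_contacts
    d_planted = criteria.max_da_distance - spec.geometry_margin

    theta0 = rng.uniform(0, 2 * np.pi)
    frame_R = _random_rotation(rng)
    frame_t = rng.uniform(-5, 5, size=3)

    def world(p: np.ndarray) -> np.ndarray:
        return frame_R @ p + frame_t

    # ligand: central carbon, one C/O (and H for donors) unit per contact
    lig_atoms: list[tuple[str, str, np.ndarray]] = [("C1", "C", np.zeros(3))]
    truth: list[PlantedContact] = []
    rec_atoms: list[tuple[str, str, int, str, str, np.ndarray]] = []
    # (atom name, resname, resseq, chain, element, pos)

    planted_pairs: list[tuple[int, int]] = []  # (ligand polar idx, receptor polar idx)
    for i in range(n):
        ang = theta0 + 2 * np.pi * i / n
        radial = np.array([np.cos(ang), np.sin(ang), 0.0])
        c_pos = 2.0 * radial
        o_pos = _LIGAND_RING_RADIUS * radial
        lig_atoms.append((f"C{i + 2}", "C", c_pos))
        o_index = len(lig_atoms)
        lig_atoms.append((f"O{i + 1}", "O", o_pos))
        direction = spec.directions[i]
        resname, resseq, polar_name, polar_elem = _RESIDUE_CYCLE[i]
        r_polar = (_LIGAND_RING_RADIUS + d_planted) * radial
        if direction == Direction.LIGAND_DONOR:
            lig_atoms.append((f"HO{i + 1}", "H", o_pos + _OH_BOND * radial))
        else:
            # receptor donates: put the receptor hydrogen between, collinear
            rec_atoms.append(
                (
                    f"H{polar_name}",
                    resname,
                    resseq,
                    "A",
                    "H",
                    r_polar - _OH_BOND * radial,
                )
            )
        rec_polar_index = len(rec_atoms)
        rec_atoms.append((polar_name, resname, resseq, "A", polar_elem, r_polar))
        # capping carbons, radially further out (never within criteria)
        rec_atoms.append(
            (
                "CB",
                resname,
                resseq,
                "A",
                "C",
                (_LIGAND_RING_RADIUS + d_planted + 1.5) * radial,
            )
        )
        rec_atoms.append(
            (
                "CA",
                resname,
                resseq,
                "A",
                "C",
                (_LIGAND_RING_RADIUS + d_planted + 3.0) * radial,
            )
        )
        truth.append(
            PlantedContact(
                ligand_atom_index=o_index,  # 0-based; C1 is index 0
                residue_label=f"{resname.capitalize()}{resseq}",
                direction=direction,
                distance=float(d_planted),
            )
        )
        planted_pairs.append((o_index, rec_polar_index))

    # --- generation-time guarantee check (strict, in the local frame) -----
    lig_polar = [(idx, a[2]) for idx, a in enumerate(lig_atoms) if a[1] in ("N", "O")]
    rec_polar = [(idx, a[5]) for idx, a in enumerate(rec_atoms) if a[4] in ("N", "O")]
    for li, lp in lig_polar:
        for ri, rp in rec_polar:
            d = float(np.linalg.norm(lp - rp))
            if (li, ri) in planted_pairs:
                if spec.geometry_margin > 0:
                    assert d <= criteria.max_da_distance - spec.geometry_margin + 1e-9
                else:
                    assert d >= criteria.max_da_distance - spec.geometry_margin - 1e-9
            else:
                assert d >= criteria.max_da_distance + _NONPLANTED_BUFFER, (
                    f"non-planted polar pair within criteria: {d:.2f} Å"
                )

    # --- emit PDB text ----------------------------------------------------
    lines = [
        f"REMARK   1 SYNTHETIC COMPLEX SEED {spec.seed} MARGIN {spec.geometry_margin}\n"
    ]
    serial = 1
    for name, resname, resseq, chain, elem, pos in rec_atoms:
        lines.append(
            _pdb_atom_line("ATOM", serial, name, resname, chain, resseq, world(pos), elem)
        )
        serial += 1
    for name, elem, pos in lig_atoms:
        lines.append(_pdb_atom_line("HETATM", serial, name, "LIG", "L", 1, world(pos), elem))
        serial += 1
    for w in range(spec.n_waters):
        pos = np.array([25.0 + 3.0 * w, 25.0, 25.0])
        lines.append(_pdb_atom_line("HETATM", serial, "O", "HOH", "W", 1000 + w, world(pos), "O"))
        serial += 1
    lines.append("END\n")
    return "".join(lines), truth


# ---------------------------------------------------------------------------
# Screening libraries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibrarySpec:
    """Recipe for a screening library with planted actives and random decoys.

    Actives carry hydroxyl/ether oxygens whose perceived feature points are a
    random rigid transform of the model's feature positions plus per-
    coordinate Gaussian jitter of ``jitter_sd`` Å.  Decoys carry 2–6 donor
    and 0–2 extra ether oxygens at random positions in the model's inflated
    bounding box.  ``mw_range``, when set, pads molecules with a carbon tail
    into the requested molecular-weight window.
    """

    n_actives: int
    n_decoys: int
    jitter_sd: float = 0.1
    seed: int = 0
    mw_range: tuple[float, float] | None = None
    decoy_box_pad: float = 2.0
    decoy_min_separation: float = 2.0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.n_actives < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _build_feature_molecule(
    name: str,
    donor_positions: np.ndarray,
    ether_positions: np.ndarray,
    rng: np.random.Generator,
    extra_carbons: int = 0,
) -> Chem.Mol:
    """Assemble a connected molecule realizing the requested feature points.

    Each donor position becomes a hydroxyl oxygen (O with explicit H); each
    ether position an oxygen bonded to two carbons (acceptor only).  A carbon
    backbone strings the units together; geometry is synthetic and not
    energy-minimized — only the oxygen positions matter downstream.
    """
    rw = Chem.RWMol()
    conf_pos: list[np.ndarray] = []

    def add(symbol: str, pos: np.ndarray) -> int:
        idx = rw.AddAtom(Chem.Atom(symbol))
        conf_pos.append(np.asarray(pos, dtype=float))
        return idx

    backbone: list[int] = []
    for p in donor_positions:
        c = add("C", p + _CO_BOND * _unit(rng))
        o = add("O", p)
        h = add("H", p + _OH_BOND * _unit(rng))
        rw.AddBond(c, o, Chem.BondType.SINGLE)
        rw.AddBond(o, h, Chem.BondType.SINGLE)
        backbone.append(c)
    for q in ether_positions:
        c1 = add("C", q + _CO_BOND * _unit(rng))
        o = add("O", q)
        c2 = add("C", q + _CO_BOND * _unit(rng))
        rw.AddBond(c1, o, Chem.BondType.SINGLE)
        rw.AddBond(o, c2, Chem.BondType.SINGLE)
        backbone.append(c1)
    for a, b in zip(backbone, backbone[1:]):
        rw.AddBond(a, b, Chem.BondType.SINGLE)
    tail_anchor = backbone[-1]
    tail_dir = _unit(rng)
    base = conf_pos[tail_anchor]
    for k in range(extra_carbons):
        c = add("C", base + (k + 1) * 1.5 * tail_dir)
        rw.AddBond(tail_anchor, c, Chem.BondType.SINGLE)
        tail_anchor = c

    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, p in enumerate(conf_pos):
        conf.SetAtomPosition(i, tuple(float(v) for v in p))
    mol.AddConformer(conf, assignId=True)
    Chem.SanitizeMol(mol)
    mol.SetProp("_Name", name)
    return mol


def _mw_padding_carbons(mol: Chem.Mol, mw_range: tuple[float, float] | None) -> int:
    if mw_range is None:
        return 0
    from rdkit.Chem import Descriptors

    current = Descriptors.MolWt(mol)
    lo, hi = mw_range
    if current >= lo:
        return 0
    # each CH2 adds ~14.03 Da
    return max(0, int(np.ceil((lo - current) / 14.03)))


def generate_library(
    model: PharmacophoreModel, spec: LibrarySpec
) -> tuple[list[MoleculeRecord], dict[str, str]]:
    """Generate a labelled library of planted actives and random decoys.

    Returns ``(records, labels)`` with labels mapping molecule id to
    ``"active"`` / ``"decoy"``.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    donors = np.array(
        [f.position for f in model.features if f.kind == FeatureKind.DONOR], dtype=float
    )
    acceptors = np.array(
        [f.position for f in model.features if f.kind == FeatureKind.ACCEPTOR], dtype=float
    )
    if spec.n_actives > 0 and len(donors) + len(acceptors) == 0:
        raise ValueError("model has no features to plant actives from")

    all_pos = model.positions
    box_lo = all_pos.min(axis=0) - spec.decoy_box_pad
    box_hi = all_pos.max(axis=0) + spec.decoy_box_pad

    records: list[MoleculeRecord] = []
    labels: dict[str, str] = {}

    for i in range(spec.n_actives):
        name = f"ACT{i + 1:04d}"
        R = _random_rotation(rng)
        t = rng.uniform(-10, 10, size=3)
        d_pts = (donors @ R.T + t) if len(donors) else np.zeros((0, 3))
        a_pts = (acceptors @ R.T + t) if len(acceptors) else np.zeros((0, 3))
        if spec.jitter_sd > 0:
            d_pts = d_pts + rng.normal(scale=spec.jitter_sd, size=d_pts.shape)
            a_pts = a_pts + rng.normal(scale=spec.jitter_sd, size=a_pts.shape)
        # an acceptor coinciding with a donor is realized by the hydroxyl itself
        keep = [
            q for q in a_pts
            if len(d_pts) == 0 or np.min(np.linalg.norm(d_pts - q, axis=1)) > 0.5
        ]
        a_keep = np.array(keep) if keep else np.zeros((0, 3))
        mol = _build_feature_molecule(name, d_pts, a_keep, rng)
        pad = _mw_padding_carbons(mol, spec.mw_range)
        if pad:
            mol = _build_feature_molecule(name, d_pts, a_keep, rng, extra_carbons=pad)
        records.append(MoleculeRecord.from_rdkit(mol, mol_id=name))
        labels[name] = "active"

    for i in range(spec.n_decoys):
        name = f"DEC{i + 1:04d}"
        n_donor = int(rng.integers(2, 7))
        n_ether = int(rng.integers(0, 3))
        pts: list[np.ndarray] = []
        attempts = 0
        while len(pts) < n_donor + n_ether and attempts < 500:
            cand = rng.uniform(box_lo, box_hi)
            attempts += 1
            if all(np.linalg.norm(cand - p) >= spec.decoy_min_separation for p in pts):
                pts.append(cand)
        arr = np.array(pts)
        mol = _build_feature_molecule(name, arr[:n_donor], arr[n_donor:], rng)
        pad = _mw_padding_carbons(mol, spec.mw_range)
        if pad:
            mol = _build_feature_molecule(name, arr[:n_donor], arr[n_donor:], rng, extra_carbons=pad)
        records.append(MoleculeRecord.from_rdkit(mol, mol_id=name))
        labels[name] = "decoy"

    return records, labels


def labels_to_csv(labels: dict[str, str]) -> str:
    lines = ["id,label\n"]
    for k in labels:
        lines.append(f"{k},{labels[k]}\n")
    return "".join(lines)


# ---------------------------------------------------------------------------
# Dose–response assays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssaySpec:
    """Recipe for a simulated uptake-inhibition assay.

    Responses are 4PL(dose) + iid Gaussian(0, ``noise_sd``) per replicate on
    the standard 15-level half-log dose ladder (0.001–10,000 nM) unless
    other doses are given.
    """

    true_ic50: float  # nM
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    noise_sd: float = 5.0
    replicates: int = 3
    doses: tuple[float, ...] = STANDARD_DOSE_LADDER_NM
    seed: int = 0
    compound_id: str = "SIM"
    target: Target = Target.SGLT2

    def __post_init__(self) -> None:
        if self.true_ic50 <= 0:
            raise ValueError("true_ic50 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def generate_assay(spec: AssaySpec) -> DoseResponseDataset:
    """Simulate one replicated dose–response dataset; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    doses = np.asarray(spec.doses, dtype=float)
    clean = four_pl(doses, spec.top, spec.bottom, spec.true_ic50, spec.hill)
    responses = []
    for mean in clean:
        noise = rng.normal(scale=spec.noise_sd, size=spec.replicates) if spec.noise_sd else np.zeros(spec.replicates)
        responses.append([float(mean + e) for e in noise])
    return DoseResponseDataset(
        compound_id=spec.compound_id,
        target=spec.target,
        doses=[float(d) for d in doses],
        responses=responses,
        replicates=spec.replicates,
    )
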