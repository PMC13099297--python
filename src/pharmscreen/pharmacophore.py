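"""Structure-based pharmacophore generation from receptor–ligand H-bonds.

Given a receptor–ligand complex, ``detect_hbonds`` perceives hydrogen bonds
between ligand N/O atoms and receptor N/O atoms under geometric criteria
(donor–acceptor distance, D–H···A angle).  ``build_model`` turns those
contacts into a pharmacophore model: one DONOR feature per ligand atom that
donates, one ACCEPTOR feature per ligand atom that accepts, positioned at
the ligand heavy atom.  For a sugar bound in a polar site this yields the
classic hydroxyl-donor / ring-oxygen-acceptor arrangement.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .chemio import ComplexStructure

MODEL_SCHEMA_VERSION = 1

#: covalent X–H cutoff used to decide which heavy atom a hydrogen belongs to
_H_COVALENT_CUTOFF = 1.25  # Å

_POLAR_ELEMENTS = {"N", "O"}


class FeatureKind(str, enum.Enum):
    DONOR = "DONOR"
    ACCEPTOR = "ACCEPTOR"


class Direction(str, enum.Enum):
    LIGAND_DONOR = "LIGAND_DONOR"
    LIGAND_ACCEPTOR = "LIGAND_ACCEPTOR"


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    ``max_da_distance`` is the donor–acceptor heavy-atom distance cutoff;
    ``min_dha_angle`` the D–H···A angle cutoff, applied only when the donor
    hydrogen is present in the structure.  Defaults (3.5 Å, 120°) are
    standard crystallographic practice.
    """

    max_da_distance: float = 3.5
    min_dha_angle: float = 120.0

    def __post_init__(self) -> None:
        if not 0 < self.max_da_distance < 10:
            raise ValueError("max_da_distance must be in (0, 10) Å")
        if not 0 <= self.min_dha_angle <= 180:
            raise ValueError("min_dha_angle must be in [0, 180] degrees")


DEFAULT_CRITERIA = HBondCriteria()


@dataclass(frozen=True)
class HBondContact:
    """One receptor–ligand hydrogen bond.

    ``direction`` is LIGAND_DONOR when the bridging hydrogen belongs to the
    ligand atom, LIGAND_ACCEPTOR when it belongs to the receptor atom.
    ``angle`` is None in distance-only mode (no hydrogens in the structure).
    """

    ligand_atom_index: int
    receptor_atom_index: int
    residue_label: str
    distance: float
    angle: float | None
    direction: Direction

    def __post_init__(self) -> None:
        if not self.residue_label:
            raise ValueError("residue_label must be non-empty")


@dataclass
class PharmacophoreFeature:
    label: str
    kind: FeatureKind
    position: np.ndarray  # (3,) Å
    tolerance: float
    provenance: list[str]

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.tolerance <= 0:
            raise ValueError("feature tolerance must be positive")


@dataclass
class PharmacophoreModel:
    features: list[PharmacophoreFeature]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("a pharmacophore model needs at least one feature")
        labels = [f.label for f in self.features]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate feature labels: {labels}")

    @property
    def positions(self) -> np.ndarray:
        return np.vstack([f.position for f in self.features])

    def features_of(self, kind: FeatureKind) -> list[PharmacophoreFeature]:
        return [f for f in self.features if f.kind == kind]


# ---------------------------------------------------------------------------
# Hydrogen-bond perception
# ---------------------------------------------------------------------------


def _attached_hydrogens(elements, positions):
    """Map heavy-atom index -> list of H positions bonded to it (by distance)."""
    h_idx = [i for i, e in enumerate(elements) if e == "H"]
    heavy_idx = [i for i, e in enumerate(elements) if e != "H"]
    attach: dict[int, list[np.ndarray]] = {}
    for hi in h_idx:
        best, best_d = None, _H_COVALENT_CUTOFF
        for ai in heavy_idx:
            d = float(np.linalg.norm(positions[hi] - positions[ai]))
            if d < best_d:
                best, best_d = ai, d
        if best is not None:
            attach.setdefault(best, []).append(positions[hi])
    return attach


def _dha_angle(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray) -> float:
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def residue_label(res_name: str, res_seq: int) -> str:
    return f"{res_name.capitalize()}{res_seq}"


def detect_hbonds(
    complex_: ComplexStructure, criteria: HBondCriteria = DEFAULT_CRITERIA
) -> list[HBondContact]:
    """Perceive receptor–ligand hydrogen bonds.

    Every contact pairs a ligand N/O with a receptor N/O within
    ``criteria.max_da_distance``; when the donor hydrogen is present, the
    D–H···A angle must also clear ``criteria.min_dha_angle``.  If the
    structure carries no hydrogens at all, perception falls back to a
    distance-only mode: donor and acceptor roles cannot be told apart, so
    each qualifying pair is reported once per direction with ``angle=None``.
    Contacts are sorted by ligand atom index, then distance.
    """
    lig_elems = [a.element for a in complex_.ligand_atoms]
    lig_pos = [np.asarray(a.position, dtype=float) for a in complex_.ligand_atoms]
    rec_elems = [a.element for a in complex_.receptor_atoms]
    rec_pos = [np.asarray(a.position, dtype=float) for a in complex_.receptor_atoms]

    lig_h = _attached_hydrogens(lig_elems, lig_pos)
    rec_h = _attached_hydrogens(rec_elems, rec_pos)
    structure_has_h = any(e == "H" for e in lig_elems) or any(e == "H" for e in rec_elems)

    contacts: list[HBondContact] = []
    for li, (le, lp) in enumerate(zip(lig_elems, lig_pos)):
        if le not in _POLAR_ELEMENTS:
            continue
        for ri, (re_, rp) in enumerate(zip(rec_elems, rec_pos)):
            if re_ not in _POLAR_ELEMENTS:
                continue
            d = float(np.linalg.norm(lp - rp))
            if d > criteria.max_da_distance:
                continue
            label = residue_label(
                complex_.receptor_atoms[ri].res_name, complex_.receptor_atoms[ri].res_seq
            )
            if not structure_has_h:
                for direction in (Direction.LIGAND_DONOR, Direction.LIGAND_ACCEPTOR):
                    contacts.append(
                        HBondContact(li, ri, label, d, None, direction)
                    )
                continue
            # ligand donates: a ligand H on this atom points at the receptor atom
            for hpos in lig_h.get(li, []):
                ang = _dha_angle(lp, hpos, rp)
                if ang >= criteria.min_dha_angle:
                    contacts.append(
                        HBondContact(li, ri, label, d, ang, Direction.LIGAND_DONOR)
                    )
                    break
            # receptor donates: a receptor H on that atom points at the ligand atom
            for hpos in rec_h.get(ri, []):
                ang = _dha_angle(rp, hpos, lp)
                if ang >= criteria.min_dha_angle:
                    contacts.append(
                        HBondContact(li, ri, label, d, ang, Direction.LIGAND_ACCEPTOR)
                    )
                    break
    contacts.sort(key=lambda c: (c.ligand_atom_index, c.distance))
    return contacts


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------


def build_model(
    contacts: Sequence[HBondContact],
    complex_: ComplexStructure,
    tolerance: float = 1.0,
    source: str = "",
) -> PharmacophoreModel:
    """Build the pharmacophore model from detected contacts.

    One feature per distinct (ligand atom, direction) pair, positioned at the
    ligand heavy atom; a hydroxyl that both donates and accepts yields two
    co-located features.  Labels run F1… with donors first, each group in
    ligand-atom-index order; provenance collects the residue labels of all
    contacts merged into the feature.
    """
    if not contacts:
        raise ValueError("cannot build a model from an empty contact list")
    groups: dict[tuple[int, Direction], list[HBondContact]] = {}
    for c in contacts:
        groups.setdefault((c.ligand_atom_index, c.direction), []).append(c)

    def _mk(key, n):
        li, direction = key
        kind = (
            FeatureKind.DONOR if direction == Direction.LIGAND_DONOR else FeatureKind.ACCEPTOR
        )
        prov: list[str] = []
        for c in groups[key]:
            if c.residue_label not in prov:
                prov.append(c.residue_label)
        return PharmacophoreFeature(
            label=f"F{n}",
            kind=kind,
            position=np.array(complex_.ligand_atoms[li].position, dtype=float),
            tolerance=tolerance,
            provenance=prov,
        )

    donor_keys = sorted(k for k in groups if k[1] == Direction.LIGAND_DONOR)
    acceptor_keys = sorted(k for k in groups if k[1] == Direction.LIGAND_ACCEPTOR)
    features = [_mk(k, i + 1) for i, k in enumerate(donor_keys + acceptor_keys)]
    return PharmacophoreModel(features=features, source=source)


# ---------------------------------------------------------------------------
# JSON (de)serialization
# ---------------------------------------------------------------------------


def model_to_dict(model: PharmacophoreModel) -> dict:
    return {
        "version": MODEL_SCHEMA_VERSION,
        "source": model.source,
        "features": [
            {
                "label": f.label,
                "kind": f.kind.value,
                "position": [float(v) for v in f.position],
                "tolerance": float(f.tolerance),
                "provenance": list(f.provenance),
            }
            for f in model.features
        ],
    }


def model_from_dict(data: dict) -> PharmacophoreModel:
    version = data.get("version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {version!r} (expected {MODEL_SCHEMA_VERSION})"
        )
    features = [
        PharmacophoreFeature(
            label=f["label"],
            kind=FeatureKind(f["kind"]),
            position=np.asarray(f["position"], dtype=float),
            tolerance=float(f["tolerance"]),
            provenance=list(f.get("provenance", [])),
        )
        for f in data["features"]
    ]
    return PharmacophoreModel(features=features, source=data.get("source", ""))


def save_model(model: PharmacophoreModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


def load_model(path: str | Path) -> PharmacophoreModel:
    data = json.loads(Path(path).read_text())
    return model_from_dict(data)
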