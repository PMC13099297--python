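"""Drug-likeness filtering and pharmacophore matching (the screening funnel).

The funnel mirrors hierarchical virtual screening practice: descriptors →
Lipinski rule-of-five filter → pharmacophore feature perception → all-feature
matching.  Matching enumerates every injective, kind-respecting assignment of
model features to molecule feature points, superposes each assigned point set
onto the model by the Kabsch least-squares rotation, and keeps the minimum
RMSD; a compound is a hit when that minimum is at or below the cutoff
(0.6 Å by default) with every model feature assigned.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .chemio import DescriptorSet, MoleculeRecord, compute_descriptors
from .pharmacophore import FeatureKind, PharmacophoreModel

#: hard cap on enumerated correspondences per molecule
MAX_ASSIGNMENTS = 1_000_000

DEFAULT_RMSD_CUTOFF = 0.6  # Å

#: collinearity threshold on the second singular value of the covariance
_DEGENERATE_TOL = 1e-8


class TooManyAssignmentsError(RuntimeError):
    pass


@dataclass(frozen=True)
class FeaturePoint:
    kind: FeatureKind
    position: np.ndarray  # (3,) Å
    atom_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not np.all(np.isfinite(self.position)):
            raise ValueError("feature point position must be finite")


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    rmsd: float | None
    correspondence: tuple[tuple[str, int], ...] | None  # (feature label, atom index)
    conformer_id: int = 0


@dataclass
class CompoundOutcome:
    """Per-compound funnel bookkeeping (best conformer where relevant)."""

    id: str
    stage: str  # "input" | "druglike" | "hit"
    descriptors: DescriptorSet
    lipinski: bool
    best_rmsd: float | None
    matched: bool
    conformer_id: int | None


@dataclass
class FunnelReport:
    n_input: int
    n_druglike: int
    n_pharm_hits: int
    per_compound: list[CompoundOutcome]
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF

    def __post_init__(self) -> None:
        if not self.n_input >= self.n_druglike >= self.n_pharm_hits:
            raise ValueError("funnel counts must be non-increasing")

    @property
    def hits(self) -> list[CompoundOutcome]:
        """Hit compounds ranked by ascending best RMSD."""
        return sorted(
            (c for c in self.per_compound if c.stage == "hit"),
            key=lambda c: (c.best_rmsd, c.id),
        )

    def to_csv(self, path: str | Path | None = None) -> str:
        """Render the report as CSV (deterministic formatting); hits first."""
        buf = io.StringIO()
        buf.write("id,stage,mw,hbd,hba,logp,lipinski,best_rmsd,matched,conformer_id\n")
        ranked = self.hits + sorted(
            (c for c in self.per_compound if c.stage != "hit"), key=lambda c: c.id
        )
        for c in ranked:
            rmsd = "" if c.best_rmsd is None else f"{c.best_rmsd:.6f}"
            conf = "" if c.conformer_id is None else str(c.conformer_id)
            buf.write(
                f"{c.id},{c.stage},{c.descriptors.mw:.3f},{c.descriptors.hbd},"
                f"{c.descriptors.hba},{c.descriptors.logp:.3f},"
                f"{str(c.lipinski).lower()},{rmsd},{str(c.matched).lower()},{conf}\n"
            )
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Lipinski rule of five
# ---------------------------------------------------------------------------


def lipinski_pass(d: DescriptorSet) -> bool:
    """MW ≤ 500, HBD ≤ 5, HBA ≤ 10, logP ≤ 5 — all inclusive."""
    return d.mw <= 500 and d.hbd <= 5 and d.hba <= 10 and d.logp <= 5


# ---------------------------------------------------------------------------
# Feature perception
# ---------------------------------------------------------------------------


def perceive_features(mol: MoleculeRecord) -> list[FeaturePoint]:
    """Donor/acceptor feature points of a compound, at heavy-atom positions.

    One DONOR per N/O bearing at least one hydrogen; one ACCEPTOR per
    acceptor-qualified N/O (pyrrole-type aromatic NH excluded).  A hydroxyl
    oxygen therefore contributes both a donor and an acceptor point.
    """
    from .chemio import _is_acceptor_atom, _is_donor_atom

    m = mol.to_rdkit()
    if m.GetNumConformers() == 0:
        raise ValueError(f"molecule {mol.id!r} has no 3D coordinates")
    positions = m.GetConformer().GetPositions()
    points: list[FeaturePoint] = []
    for atom in m.GetAtoms():
        if atom.GetAtomicNum() not in (7, 8):
            continue
        idx = atom.GetIdx()
        if _is_donor_atom(atom):
            points.append(FeaturePoint(FeatureKind.DONOR, positions[idx], idx))
        if _is_acceptor_atom(atom):
            points.append(FeaturePoint(FeatureKind.ACCEPTOR, positions[idx], idx))
    return points


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def _kabsch_rmsd_batch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Minimum RMSD over proper rotations for each point set in a batch.

    P: (k, 3) reference points; Q: (m, k, 3) candidate point sets.
    Returns (m,) RMSDs after optimal rigid (rotation+translation)
    superposition of each Q[i] onto P.
    """
    k = P.shape[0]
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=1, keepdims=True)
    # covariance per batch: H[i] = Qc[i]^T @ Pc
    H = np.einsum("mki,kj->mij", Qc, Pc)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(U) * np.linalg.det(Vt)
    S_eff = S.copy()
    S_eff[:, -1] *= np.sign(det)
    sq = (Pc**2).sum() + (Qc**2).sum(axis=(1, 2)) - 2.0 * S_eff.sum(axis=1)
    return np.sqrt(np.maximum(sq, 0.0) / k)


def superpose_rmsd(
    P: Sequence[Sequence[float]] | np.ndarray, Q: Sequence[Sequence[float]] | np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, bool]:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Points are ordered as corresponding pairs; at least 3 pairs required.
    Returns ``(rmsd, R, t, degenerate)`` with ``R`` a proper rotation
    (det +1) and ``t`` a translation such that ``R @ q + t`` best matches
    ``p``.  ``degenerate`` is True for (near-)collinear point sets, where the
    best proper rotation is still returned but is not unique.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must both be (n, 3) arrays of corresponding points")
    if P.shape[0] < 3:
        raise ValueError("at least 3 point pairs are required")
    Pm, Qm = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - Pm, Q - Qm
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    degenerate = bool(S[1] < _DEGENERATE_TOL * max(S[0], 1.0))
    t = Pm - R @ Qm
    diff = (Qc @ R.T) - Pc
    rmsd = float(np.sqrt((diff**2).sum() / P.shape[0]))
    return rmsd, R, t, degenerate


# ---------------------------------------------------------------------------
# Correspondence search
# ---------------------------------------------------------------------------


_PERM_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _permutation_index(n: int, k: int) -> np.ndarray:
    """All ordered k-selections from range(n), lexicographic, as an (m, k) array."""
    key = (n, k)
    if key not in _PERM_CACHE:
        if k == 0:
            _PERM_CACHE[key] = np.zeros((1, 0), dtype=int)
        else:
            _PERM_CACHE[key] = np.array(
                list(itertools.permutations(range(n), k)), dtype=int
            )
    return _PERM_CACHE[key]


def _count_assignments(n_points: dict[FeatureKind, int], n_model: dict[FeatureKind, int]) -> int:
    total = 1
    for kind, need in n_model.items():
        have = n_points.get(kind, 0)
        if have < need:
            return 0
        perms = 1
        for i in range(need):
            perms *= have - i
        total *= perms
    return total


def match_pharmacophore(
    features: Sequence[FeaturePoint],
    model: PharmacophoreModel,
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
    conformer_id: int = 0,
) -> MatchResult:
    """Best all-feature match of a compound against a pharmacophore model.

    Enumerates every injective, kind-respecting assignment of model features
    to the compound's feature points, computes the Kabsch superposition RMSD
    of each, and returns the minimum-RMSD assignment; ties resolve to the
    lexicographically smallest correspondence.  A compound lacking enough
    points of some kind is unmatched (``rmsd=None``), not an error.
    """
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be positive")
    model_feats = model.features
    kinds = [FeatureKind.DONOR, FeatureKind.ACCEPTOR]
    model_by_kind = {k: [f for f in model_feats if f.kind == k] for k in kinds}
    # candidate point indices per kind, sorted by atom index for the tie-break
    pts = list(features)
    cand = {
        k: sorted(
            (i for i, p in enumerate(pts) if p.kind == k),
            key=lambda i: pts[i].atom_index,
        )
        for k in kinds
    }
    n_assign = _count_assignments(
        {k: len(v) for k, v in cand.items()}, {k: len(v) for k, v in model_by_kind.items()}
    )
    if n_assign == 0:
        return MatchResult(False, None, None, conformer_id)
    if n_assign > MAX_ASSIGNMENTS:
        raise TooManyAssignmentsError(
            f"{n_assign} candidate correspondences exceed the cap of {MAX_ASSIGNMENTS}"
        )

    # model feature order: donors then acceptors, in model order
    ordered_model = model_by_kind[FeatureKind.DONOR] + model_by_kind[FeatureKind.ACCEPTOR]
    P = np.vstack([f.position for f in ordered_model])

    cand_d = np.array(cand[FeatureKind.DONOR], dtype=int)
    cand_a = np.array(cand[FeatureKind.ACCEPTOR], dtype=int)
    perm_d = cand_d[_permutation_index(len(cand_d), len(model_by_kind[FeatureKind.DONOR]))]
    perm_a = cand_a[_permutation_index(len(cand_a), len(model_by_kind[FeatureKind.ACCEPTOR]))]
    md, ma = perm_d.shape[0], perm_a.shape[0]
    # donor-major cartesian product keeps assignments in lexicographic order
    idx = np.hstack([np.repeat(perm_d, ma, axis=0), np.tile(perm_a, (md, 1))])  # (m, k)
    coords = np.array([p.position for p in pts])  # (n, 3)
    Q = coords[idx]  # (m, k, 3)
    rmsds = _kabsch_rmsd_batch(P, Q)
    # first argmin = lexicographically smallest correspondence among ties,
    # because assignments are enumerated in sorted-candidate order
    best = int(np.argmin(rmsds))
    best_rmsd = float(rmsds[best])
    if P.shape[0] >= 3:
        # the trace formula loses ~sqrt(eps) near zero; recompute the winner
        # from the explicit rotated residual
        best_rmsd = superpose_rmsd(P, Q[best])[0]
    correspondence = tuple(
        (f.label, pts[i].atom_index) for f, i in zip(ordered_model, idx[best])
    )
    matched = best_rmsd <= rmsd_cutoff
    return MatchResult(matched, best_rmsd, correspondence, conformer_id)


# ---------------------------------------------------------------------------
# The funnel
# ---------------------------------------------------------------------------


def match_record(
    mol: MoleculeRecord, model: PharmacophoreModel, rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF
) -> MatchResult:
    """Perceive a single record's features and match them against the model."""
    return match_pharmacophore(
        perceive_features(mol), model, rmsd_cutoff, conformer_id=mol.conformer_id
    )


def run_funnel(
    library: Sequence[MoleculeRecord],
    model: PharmacophoreModel,
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
    apply_lipinski: bool = True,
) -> FunnelReport:
    """Run the hierarchical screen: descriptors → Lipinski → feature match.

    Records sharing an id are conformers of one compound: each is matched
    independently and the best (lowest-RMSD) conformer is reported.  Counts
    are monotone non-increasing through the stages and the whole run is
    deterministic given its inputs.
    """
    groups: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in library:
        if rec.id not in groups:
            groups[rec.id] = []
            order.append(rec.id)
        groups[rec.id].append(rec)

    per_compound: list[CompoundOutcome] = []
    n_druglike = 0
    n_hits = 0
    for cid in order:
        recs = groups[cid]
        desc = compute_descriptors(recs[0])
        ok = lipinski_pass(desc) if apply_lipinski else True
        if not ok:
            per_compound.append(
                CompoundOutcome(cid, "input", desc, False, None, False, None)
            )
            continue
        n_druglike += 1
        best: MatchResult | None = None
        for rec in recs:
            res = match_record(rec, model, rmsd_cutoff)
            if res.rmsd is None:
                continue
            if best is None or best.rmsd is None or res.rmsd < best.rmsd:
                best = res
        if best is not None and best.matched:
            n_hits += 1
            per_compound.append(
                CompoundOutcome(
                    cid, "hit", desc, True, best.rmsd, True, best.conformer_id
                )
            )
        else:
            rmsd = None if best is None else best.rmsd
            conf = None if best is None else best.conformer_id
            per_compound.append(
                CompoundOutcome(cid, "druglike", desc, True, rmsd, False, conf)
            )
    return FunnelReport(
        n_input=len(order),
        n_druglike=n_druglike,
        n_pharm_hits=n_hits,
        per_compound=per_compound,
        rmsd_cutoff=rmsd_cutoff,
    )
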