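"""Lipinski filtering, Kabsch superposition, and pharmacophore matching."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pharmscreen import (
    DescriptorSet,
    FeatureKind,
    FeaturePoint,
    generate_library,
    lipinski_pass,
    match_pharmacophore,
    perceive_features,
    run_funnel,
    superpose_rmsd,
)
from pharmscreen.screening import TooManyAssignmentsError
from pharmscreen.synthetic_data import LibrarySpec

from conftest import random_rotation, record_from_smiles


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def scipy_pair_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Superposition RMSD via scipy's align_vectors (independent of our Kabsch)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    _, rssd = Rotation.align_vectors(Pc, Qc)
    return float(rssd / np.sqrt(len(P)))


def grid_search_rmsd(P: np.ndarray, Q: np.ndarray, levels: int = 6, n: int = 14) -> float:
    """Brute-force minimum RMSD over rotations by refined Euler-angle search."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    center = np.zeros(3)
    width = np.pi
    best = np.inf
    for _ in range(levels):
        grids = [np.linspace(c - w, c + w, n) for c, w in zip(center, [width] * 3)]
        angles = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
        mats = Rotation.from_euler("zyx", angles).as_matrix()
        rot = np.einsum("mij,kj->mki", mats, Qc)
        rmsds = np.sqrt(((rot - Pc) ** 2).sum(axis=(1, 2)) / len(P))
        i = int(np.argmin(rmsds))
        if rmsds[i] < best:
            best = float(rmsds[i])
            center = angles[i]
        width /= n / 2.5
    return best


def brute_force_min_rmsd(points, model) -> float | None:
    """Exhaustive enumeration over kind-respecting correspondences (oracle)."""
    by_kind = {k: [p for p in points if p.kind == k] for k in FeatureKind}
    model_by_kind = {k: [f for f in model.features if f.kind == k] for k in FeatureKind}
    P = np.vstack(
        [f.position for k in (FeatureKind.DONOR, FeatureKind.ACCEPTOR) for f in model_by_kind[k]]
    )
    best = None
    d_perms = itertools.permutations(by_kind[FeatureKind.DONOR], len(model_by_kind[FeatureKind.DONOR]))
    for dsel in d_perms:
        for asel in itertools.permutations(
            by_kind[FeatureKind.ACCEPTOR], len(model_by_kind[FeatureKind.ACCEPTOR])
        ):
            Q = np.vstack([p.position for p in dsel + asel])
            r = scipy_pair_rmsd(P, Q)
            if best is None or r < best:
                best = r
    return best


def random_instance(rng, n_donor_pts, n_acceptor_pts):
    pts = [
        FeaturePoint(FeatureKind.DONOR, rng.uniform(-4, 4, 3), i)
        for i in range(n_donor_pts)
    ] + [
        FeaturePoint(FeatureKind.ACCEPTOR, rng.uniform(-4, 4, 3), 100 + i)
        for i in range(n_acceptor_pts)
    ]
    return pts


# ---------------------------------------------------------------------------
# Lipinski
# ---------------------------------------------------------------------------


class TestLipinski:
    def test_passing_profile(self):
        assert lipinski_pass(DescriptorSet(mw=475, hbd=4, hba=6, logp=3.8))

    @pytest.mark.parametrize(
        "d",
        [
            DescriptorSet(mw=501, hbd=4, hba=6, logp=3.8),
            DescriptorSet(mw=475, hbd=6, hba=6, logp=3.8),
            DescriptorSet(mw=475, hbd=4, hba=11, logp=3.8),
            DescriptorSet(mw=475, hbd=4, hba=6, logp=5.1),
        ],
    )
    def test_single_violation_fails(self, d):
        assert not lipinski_pass(d)

    def test_boundaries_are_inclusive(self):
        assert lipinski_pass(DescriptorSet(mw=500, hbd=5, hba=10, logp=5.0))


# ---------------------------------------------------------------------------
# Feature perception
# ---------------------------------------------------------------------------


class TestPerceiveFeatures:
    def test_ethanol_has_donor_and_acceptor_on_hydroxyl_oxygen(self):
        pts = perceive_features(record_from_smiles("CCO", "ethanol"))
        assert sorted(p.kind.value for p in pts) == ["ACCEPTOR", "DONOR"]
        assert pts[0].atom_index == pts[1].atom_index

    def test_benzene_has_no_features(self):
        assert perceive_features(record_from_smiles("c1ccccc1", "benzene")) == []

    def test_galactopyranose_five_donors_six_acceptors(self):
        pts = perceive_features(
            record_from_smiles("OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@H]1O", "galactose")
        )
        donors = [p for p in pts if p.kind == FeatureKind.DONOR]
        acceptors = [p for p in pts if p.kind == FeatureKind.ACCEPTOR]
        assert len(donors) == 5
        assert len(acceptors) == 6


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


class TestSuperposeRmsd:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(5, 3))
        rmsd, R, t, degenerate = superpose_rmsd(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert not degenerate

    def test_rigid_transform_gives_zero_rmsd(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(6, 3))
        R0, t0 = random_rotation(rng), rng.uniform(-3, 3, 3)
        Q = P @ R0.T + t0
        rmsd, R, t, _ = superpose_rmsd(P, Q)
        assert rmsd < 1e-9
        assert np.allclose(Q @ R.T + t, P, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_rotation_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        P, Q = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        rmsd, *_ = superpose_rmsd(P, Q)
        assert rmsd == pytest.approx(grid_search_rmsd(P, Q), abs=1e-3)
        assert rmsd == pytest.approx(scipy_pair_rmsd(P, Q), abs=1e-9)

    def test_collinear_points_flagged_degenerate(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        rmsd, R, t, degenerate = superpose_rmsd(P, P)
        assert degenerate
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError, match="3 point pairs"):
            superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


class TestMatchPharmacophore:
    def test_exact_rigid_copy_matches_at_zero(self, galactose_model):
        rng = np.random.default_rng(2)
        R, t = random_rotation(rng), rng.uniform(-8, 8, 3)
        pts = [
            FeaturePoint(f.kind, R @ f.position + t, i)
            for i, f in enumerate(galactose_model.features)
        ]
        res = match_pharmacophore(pts, galactose_model, 0.6)
        assert res.matched
        assert res.rmsd < 1e-9
        assert len(res.correspondence) == len(galactose_model.features)

    def test_jittered_copy_equals_brute_force(self, galactose_model):
        rng = np.random.default_rng(3)
        R, t = random_rotation(rng), rng.uniform(-8, 8, 3)
        pts = [
            FeaturePoint(f.kind, R @ f.position + t + rng.normal(scale=0.2, size=3), i)
            for i, f in enumerate(galactose_model.features)
        ]
        # surplus acceptors to force a real correspondence search
        pts += [FeaturePoint(FeatureKind.ACCEPTOR, rng.uniform(-4, 4, 3), 50 + i) for i in range(2)]
        res = match_pharmacophore(pts, galactose_model, 0.6)
        assert res.rmsd == pytest.approx(brute_force_min_rmsd(pts, galactose_model), abs=1e-9)

    def test_insufficient_features_is_unmatched_not_error(self, galactose_model):
        pts = random_instance(np.random.default_rng(4), n_donor_pts=3, n_acceptor_pts=2)
        res = match_pharmacophore(pts, galactose_model, 0.6)
        assert not res.matched
        assert res.rmsd is None
        assert res.correspondence is None

    def test_invariant_to_rigid_motion_and_point_permutation(self, galactose_model):
        rng = np.random.default_rng(6)
        pts = random_instance(rng, 5, 3)
        base = match_pharmacophore(pts, galactose_model, 0.6).rmsd
        R, t = random_rotation(rng), rng.uniform(-5, 5, 3)
        moved = [FeaturePoint(p.kind, R @ p.position + t, p.atom_index) for p in pts]
        rng.shuffle(moved)
        assert match_pharmacophore(moved, galactose_model, 0.6).rmsd == pytest.approx(
            base, abs=1e-9
        )

    def test_assignment_cap_guard(self, galactose_model):
        pts = random_instance(np.random.default_rng(7), 40, 20)
        with pytest.raises(TooManyAssignmentsError):
            match_pharmacophore(pts, galactose_model, 0.6)


# ---------------------------------------------------------------------------
# The funnel
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_library(galactose_model):
    recs, labels = generate_library(
        galactose_model, LibrarySpec(n_actives=10, n_decoys=40, jitter_sd=0.05, seed=21)
    )
    return recs, labels


class TestRunFunnel:
    def test_planted_actives_are_recovered(self, galactose_model, small_library):
        recs, labels = small_library
        report = run_funnel(recs, galactose_model, 0.6)
        hit_ids = {c.id for c in report.hits}
        active_ids = {i for i, l in labels.items() if l == "active"}
        assert active_ids <= hit_ids
        assert report.n_input >= report.n_druglike >= report.n_pharm_hits

    def test_empty_library(self, galactose_model):
        report = run_funnel([], galactose_model, 0.6)
        assert (report.n_input, report.n_druglike, report.n_pharm_hits) == (0, 0, 0)

    def test_mw_violations_stop_at_stage_one(self, galactose_model):
        recs, _ = generate_library(
            galactose_model,
            LibrarySpec(n_actives=3, n_decoys=3, jitter_sd=0.0, seed=8, mw_range=(600.0, 700.0)),
        )
        report = run_funnel(recs, galactose_model, 0.6)
        assert report.n_druglike == 0
        assert report.n_pharm_hits == 0

    def test_lowering_cutoff_never_increases_hits(self, galactose_model, small_library):
        recs, _ = small_library
        hits = [
            run_funnel(recs, galactose_model, cutoff).n_pharm_hits
            for cutoff in (0.8, 0.6, 0.3, 0.1)
        ]
        assert hits == sorted(hits, reverse=True)

    def test_per_compound_independence(self, galactose_model, small_library):
        recs, _ = small_library
        extra, _ = generate_library(
            galactose_model, LibrarySpec(n_actives=0, n_decoys=1, jitter_sd=0.0, seed=99)
        )
        extra[0].id = "EXTRA0001"  # avoid colliding with the library's decoy ids
        base = run_funnel(recs, galactose_model, 0.6)
        augmented = run_funnel(recs + extra, galactose_model, 0.6)
        base_rows = {c.id: (c.stage, c.best_rmsd) for c in base.per_compound}
        aug_rows = {c.id: (c.stage, c.best_rmsd) for c in augmented.per_compound}
        for cid, row in base_rows.items():
            assert aug_rows[cid] == row

    def test_best_conformer_is_reported(self, galactose_model):
        rng = np.random.default_rng(13)
        recs, _ = generate_library(
            galactose_model, LibrarySpec(n_actives=1, n_decoys=0, jitter_sd=0.3, seed=31)
        )
        good, _ = generate_library(
            galactose_model, LibrarySpec(n_actives=1, n_decoys=0, jitter_sd=0.0, seed=32)
        )
        worse = recs[0]
        better = good[0]
        worse.conformer_id = 0
        better.conformer_id = 1
        better.id = worse.id = "MULTI"
        report = run_funnel([worse, better], galactose_model, 0.6)
        row = report.per_compound[0]
        assert row.conformer_id == 1
        assert row.best_rmsd < 1e-6
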