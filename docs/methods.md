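# Methods

This note documents the models and procedures implemented in `pharmscreen`,
the parameter choices that matter, the numerical details, and the known
limitations — in particular what the synthetic fixtures do and do not show
about real screening data.

## Hydrogen-bond perception and pharmacophore construction

A hydrogen bond is accepted between a ligand N/O and a receptor N/O when the
donor–acceptor heavy-atom distance is ≤ `max_da_distance` (default 3.5 Å)
and, when the donor hydrogen is present in the structure, the D–H···A angle
is ≥ `min_dha_angle` (default 120°).  These defaults are standard
crystallographic practice for moderate-resolution structures; both are
configurable through `HBondCriteria`.  Hydrogens are assigned to heavy atoms
by covalent distance (< 1.25 Å).  Directionality follows the hydrogen: a
contact is LIGAND_DONOR when the bridging hydrogen belongs to the ligand
atom, LIGAND_ACCEPTOR when it belongs to the receptor.

**Degenerate input — structures without hydrogens.**  X-ray structures are
commonly deposited without protons.  If the complex contains no hydrogens at
all, perception falls back to a distance-only mode: the angle criterion is
waived (`angle=None` on the contact) and, because donor and acceptor roles
cannot be distinguished without protons, each qualifying pair is reported
once per direction.  This is deliberate: the model builder already allows
both roles to coexist on one atom (a hydroxyl oxygen donates and accepts),
so the ambiguous case degrades to "both", never to a silent guess.  Users
who know the protonation should protonate the input instead.

The model places one feature per distinct (ligand atom, direction) pair at
the **ligand heavy atom** — not at the hydrogen or the midpoint — which is
where feature-mapping of sugar hydroxyls is conventionally drawn.  Labels
run F1… with donors before acceptors, each group ordered by ligand atom
index, so the canonical sugar-site model reads F1–F4 (donors), F5
(acceptor).  Feature tolerance radii default to 1.0 Å; they annotate the
model (and steer the library generator) but acceptance in matching is by the
global RMSD cutoff alone.

## Feature matching

Molecule feature points are perceived per heavy atom: a DONOR point on every
N/O bearing at least one hydrogen (explicit or implicit), an ACCEPTOR point
on every N/O except pyrrole-type aromatic NH (whose lone pair sits in the
ring π system).  Matching enumerates every injective, kind-respecting
assignment of model features to molecule points — surplus molecule features
are ignored, but *every* model feature must be assigned; there is no partial
credit.  Each assignment is scored by the RMSD after optimal rigid
superposition (Kabsch: SVD of the 3×3 covariance with the determinant
correction that forbids reflections), and the minimum over assignments is
reported.  Ties resolve to the lexicographically smallest correspondence.
A compound matches when the minimum RMSD is ≤ the cutoff (default 0.6 Å,
the conventional threshold for all-feature matches).

Numerics: assignments are evaluated in a single batched SVD; because the
trace formula `rmsd² = (|P|² + |Q|² − 2Σσ)/k` loses ~√ε of precision near
zero, the winning assignment's RMSD is recomputed from the explicit rotated
residual, which is exact to machine precision.  Near-collinear point sets
(second singular value ≈ 0) still return the best proper rotation but are
flagged degenerate.  Enumeration is capped at 10⁶ assignments and aborts
with a clear error beyond that; realistic drug-like feature counts stay
orders of magnitude below the cap.

Multi-conformer SDF records (consecutive blocks with the same title) are
matched independently and the best conformer is reported.

## Drug-likeness descriptors

MW is the standard atomic-weight sum (implicit hydrogens included).  HBD
counts N/O atoms bearing at least one hydrogen (the classic OH+NH heavy-atom
count — water scores 1, not 2).  HBA counts N and O excluding pyrrole-type
aromatic NH, consistent with the acceptor definition used in matching.
logP is the Crippen atom-contribution estimate.  The rule-of-five filter is
all-inclusive: MW ≤ 500, HBD ≤ 5, HBA ≤ 10, logP ≤ 5.  Published descriptor
tables computed with other software will differ slightly in logP; the filter
decisions, not the third decimal, are the contract.

## Güner–Henry validation

`compute_enrichment` requires consistent confusion counts: D > A > 0,
Ha ≤ min(Ht, A), and Ht − Ha ≤ D − A (decoy hits cannot outnumber decoys —
without this last constraint GH can leave [0, 1], so it is validated, not
assumed).  Within that domain GH ∈ [0, 1], equals 1 exactly for perfect
retrieval (Ht = Ha = A) and 0 for a null screen (Ha = 0), and is strictly
increasing in Ha.  When Ht = 0 the yield and E are undefined and flagged
rather than zero-filled; GH is 0.  Raw values are always retained; rounded
views (yield/ratio to whole percent, E to integer, GH to two decimals,
half-away-from-zero) match how such tables are printed.

## Dose–response fitting

The 4PL is fitted in log10-dose space by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective) with
top ∈ [80, 120] %, bottom ∈ [−10, 20] %, hill ∈ [0.3, 5], and log10 IC50
within the tested dose span ± 2 decades.  The fit is seeded from nine
equally spaced log-IC50 starting points across the dose span and keeps the
lowest-RSS solution, making it deterministic with no random restarts — the
GraphPad-style "sigmoidal dose–response" convention.  A 3-parameter variant
(`fix_bottom=`) pins the floor.  Replicates are pooled with equal weights;
per-replicate fits can be assembled into a mean ± SD table with
`summarize_activity`.  Data whose total response range is below 10 % are
flagged `no_inhibition` instead of being force-fitted; a converged IC50
outside the tested dose span is flagged `extrapolated`.  The standard error
of log10 IC50 comes from the Jacobian at the solution.

Selectivity is the raw ratio IC50(SGLT1)/IC50(SGLT2) with an integer view
rounded half away from zero, the convention used for printed fold-ratios.

## Synthetic data: what it emulates and what it does not

The generators stand in for four unavailable inputs and exist to make every
stage testable against planted ground truth.

* **Complexes** — a polyol-like ligand whose ring oxygens point at capped
  polar side chains.  Planted contacts sit strictly inside the detection
  criteria by `geometry_margin` (default 0.3 Å, angle 180°), all other polar
  pairs strictly outside with ≥ 0.2 Å clearance; this guarantee is asserted
  at generation time, which is what makes contact-recovery tests sound
  oracles rather than regression snapshots.  The default layout (4 donors +
  1 acceptor, residues named after a sugar transporter's binding site)
  mirrors how a pyranose binds a polar pocket.
* **Libraries** — actives realize a random rigid transform of the model's
  feature points plus per-coordinate Gaussian jitter (default σ = 0.1 Å, a
  realistic conformational slop well inside the 0.6 Å acceptance); decoys
  carry 2–6 hydroxyls and 0–2 ethers at random positions (≥ 2 Å apart) in
  the model's 2 Å-inflated bounding box, so they present plausible feature
  counts in implausible geometry.  The default validation set size, 25
  actives vs 1975 decoys, is the conventional 80:1 decoy ratio for
  enrichment studies.  Because jitter is applied in feature space, the
  expected matching RMSD has a known relation to σ, enabling quantitative
  recall tests.  Molecular geometry outside the oxygen positions is
  synthetic (bond lengths are not minimized); descriptors are computed, not
  planted — only a molecular-weight window can be requested, realized by
  carbon-chain padding.
* **Assays** — responses are 4PL(dose) + iid Gaussian noise (default 5 %,
  3 replicates) on the standard 15-level half-log ladder from 0.001 to
  10,000 nM.

What passing tests on these fixtures show: the perception, matching,
enrichment and fitting machinery is correct, deterministic, and meets its
quantitative bars under controlled noise.  What they do not show: behavior
on real chemistry — tautomers, protonation states, conformer strain,
property-matched (DUD-E-style) decoys that defeat trivial discrimination, or
assay artifacts beyond homoscedastic Gaussian noise.  GH scores near 1 on
random-geometry decoys are expected and say nothing about enrichment against
property-matched decoys.

## Problem sizes and scope choices

The shipped validation study uses 2000-molecule libraries (25/1975) over 20
seeds and 200 simulated assays per IC50 level — sizes chosen so the full
suite and the reproduction script each run in minutes on a single core while
keeping the Monte-Carlo error of the checked medians well below their
tolerances.  Docking, molecular dynamics, and any wet-lab-derived numbers
are out of scope: the funnel ranks by feature-matching RMSD, and
docking-score columns are accepted only as pass-through annotations.
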