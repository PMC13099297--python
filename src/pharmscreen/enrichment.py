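"""Güner–Henry (GH) goodness-of-hit statistics for decoy-set validation.

A pharmacophore model is validated by screening a test set of D molecules
containing A known actives; the screen retrieves Ht hits of which Ha are
active.  The derived statistics are

    yield  = 100 · Ha / Ht          (% of hits that are active)
    ratio  = 100 · Ha / A           (% of actives recovered)
    E      = (Ha · D) / (Ht · A)    (enrichment factor)
    GH     = [Ha(3A + Ht) / (4·Ht·A)] · [1 − (Ht − Ha)/(D − A)]

GH lies in [0, 1]; 0 is the null model, 1 the ideal model, and values above
0.7 conventionally indicate a reliable model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .chemio import MoleculeRecord
from .pharmacophore import PharmacophoreModel
from .screening import DEFAULT_RMSD_CUTOFF, match_record

GH_RELIABILITY_THRESHOLD = 0.7


def _round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention printed reports use)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class EnrichmentStats:
    """Confusion counts and GH-family statistics of one validation screen.

    Raw (unrounded) values are stored; ``*_rounded`` properties give the
    display precision: yield/ratio to whole percent, E to the nearest
    integer, GH to two decimals.  With ``Ht == 0`` the yield and E are
    undefined (flagged) and GH is 0.
    """

    D: int
    A: int
    Ht: int
    Ha: int
    yield_pct: float  # nan when undefined
    ratio_pct: float
    E: float  # nan when undefined
    false_negatives: int
    false_positives: int
    GH: float

    @property
    def yield_undefined(self) -> bool:
        return math.isnan(self.yield_pct)

    @property
    def e_undefined(self) -> bool:
        return math.isnan(self.E)

    @property
    def yield_pct_rounded(self) -> int | None:
        return None if self.yield_undefined else int(_round_half_up(self.yield_pct))

    @property
    def ratio_pct_rounded(self) -> int:
        return int(_round_half_up(self.ratio_pct))

    @property
    def E_rounded(self) -> int | None:
        return None if self.e_undefined else int(_round_half_up(self.E))

    @property
    def GH_rounded(self) -> float:
        return _round_half_up(self.GH, 2)

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "A": self.A,
            "Ht": self.Ht,
            "Ha": self.Ha,
            "yield_pct": None if self.yield_undefined else self.yield_pct,
            "ratio_pct": self.ratio_pct,
            "E": None if self.e_undefined else self.E,
            "false_negatives": self.false_negatives,
            "false_positives": self.false_positives,
            "GH": self.GH,
            "rounded": {
                "yield_pct": self.yield_pct_rounded,
                "ratio_pct": self.ratio_pct_rounded,
                "E": self.E_rounded,
                "GH": self.GH_rounded,
            },
        }


def compute_enrichment(D: int, A: int, Ht: int, Ha: int) -> EnrichmentStats:
    """GH-family statistics from the four confusion counts.

    Requires D > A > 0, 0 ≤ Ht ≤ D and 0 ≤ Ha ≤ min(Ht, A).
    """
    if A <= 0:
        raise ValueError("A (number of actives) must be positive")
    if D <= A:
        raise ValueError("D must exceed A (the set must contain decoys)")
    if not 0 <= Ht <= D:
        raise ValueError("Ht must lie in [0, D]")
    if Ha > Ht:
        raise ValueError("Ha cannot exceed Ht")
    if Ha > A:
        raise ValueError("Ha cannot exceed A")
    if Ha < 0:
        raise ValueError("Ha must be non-negative")
    if Ht - Ha > D - A:
        raise ValueError("inconsistent counts: decoy hits (Ht - Ha) exceed decoys (D - A)")

    ratio = 100.0 * Ha / A
    if Ht == 0:
        yield_pct = float("nan")
        E = float("nan")
        GH = 0.0
    else:
        yield_pct = 100.0 * Ha / Ht
        E = (Ha * D) / (Ht * A)
        GH = (Ha * (3 * A + Ht) / (4.0 * Ht * A)) * (1.0 - (Ht - Ha) / float(D - A))
    return EnrichmentStats(
        D=D,
        A=A,
        Ht=Ht,
        Ha=Ha,
        yield_pct=yield_pct,
        ratio_pct=ratio,
        E=E,
        false_negatives=A - Ha,
        false_positives=Ht - Ha,
        GH=GH,
    )


def evaluate_model(
    model: PharmacophoreModel,
    actives: Sequence[MoleculeRecord],
    decoys: Sequence[MoleculeRecord],
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
) -> EnrichmentStats:
    """Screen an active/decoy test set against a model and score it by GH.

    Every molecule is matched with ``match_record``; Ht counts all matches,
    Ha the matched actives.  Actives and decoys must be disjoint by id.
    """
    if not actives:
        raise ValueError("the test set must contain at least one active")
    overlap = {m.id for m in actives} & {m.id for m in decoys}
    if overlap:
        raise ValueError(f"actives and decoys share ids: {sorted(overlap)[:5]}")
    Ha = sum(1 for m in actives if match_record(m, model, rmsd_cutoff).matched)
    hit_decoys = sum(1 for m in decoys if match_record(m, model, rmsd_cutoff).matched)
    D = len(actives) + len(decoys)
    return compute_enrichment(D=D, A=len(actives), Ht=Ha + hit_decoys, Ha=Ha)
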