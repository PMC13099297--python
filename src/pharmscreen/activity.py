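"""Dose–response analysis: 4PL IC50 fitting and SGLT1/SGLT2 selectivity.

Uptake-inhibition data (% substrate uptake vs inhibitor dose in nM) are
fitted with the four-parameter logistic

    response = bottom + (top − bottom) / (1 + (dose / IC50)^hill)

by least squares in log10-dose space, seeded from a coarse log-IC50 grid so
the fit is deterministic.  Selectivity is the ratio IC50(SGLT1)/IC50(SGLT2);
large values mean preferential SGLT2 inhibition.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

#: the 15-level half-log dose ladder used for uptake-inhibition assays (nM)
STANDARD_DOSE_LADDER_NM = (
    0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0,
    1000.0, 3000.0, 10000.0,
)

#: below this response range (%) data are flagged as showing no inhibition
NO_INHIBITION_RANGE = 10.0

_BOUNDS_TOP = (80.0, 120.0)
_BOUNDS_BOTTOM = (-10.0, 20.0)
_BOUNDS_HILL = (0.3, 5.0)


class Target(str, enum.Enum):
    SGLT1 = "SGLT1"
    SGLT2 = "SGLT2"


@dataclass
class DoseResponseDataset:
    """Replicated uptake measurements for one compound on one transporter.

    ``responses[i]`` holds the replicate responses (% uptake) at
    ``doses[i]`` (nM).
    """

    compound_id: str
    target: Target
    doses: list[float]
    responses: list[list[float]]
    replicates: int

    def __post_init__(self) -> None:
        self.target = Target(self.target)
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be strictly positive (nM)")
        if len(set(self.doses)) < 4:
            raise ValueError("at least 4 distinct doses are required")
        if len(self.responses) != len(self.doses):
            raise ValueError("responses must parallel doses")
        for r in self.responses:
            if len(r) != self.replicates:
                raise ValueError("each dose needs `replicates` responses")

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(dose, response) arrays with replicates pooled."""
        x = np.repeat(np.asarray(self.doses, dtype=float), self.replicates)
        y = np.asarray(self.responses, dtype=float).ravel()
        return x, y


@dataclass(frozen=True)
class DoseResponseFit:
    ic50: float  # nM
    hill: float
    top: float  # %
    bottom: float  # %
    se_log_ic50: float  # log10-nM
    converged: bool
    rss: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SelectivityResult:
    ic50_sglt1: float
    ic50_sglt2: float
    selectivity: float  # raw ratio

    @property
    def selectivity_rounded(self) -> int:
        return int(math.floor(self.selectivity + 0.5))


def four_pl(dose: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    """The 4PL inhibition curve; decreasing in dose for hill > 0."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def _residuals(params: np.ndarray, logx: np.ndarray, y: np.ndarray) -> np.ndarray:
    top, bottom, logic50, hill = params
    pred = bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - logic50)))
    return pred - y


def fit_ic50(
    data: DoseResponseDataset,
    fix_bottom: float | None = None,
    n_grid: int = 9,
) -> DoseResponseFit:
    """Fit the 4PL to a dataset and return the IC50 with diagnostics.

    The fit is pooled over replicates, parameterized in log10-dose, bounded
    (top 80–120 %, bottom −10–20 %, hill 0.3–5) and seeded from ``n_grid``
    log-IC50 starting points spanning the dose range — fully deterministic.
    ``fix_bottom`` switches to a 3-parameter fit with the floor pinned.
    Flat data (range below ``NO_INHIBITION_RANGE``) are flagged
    ``no_inhibition`` and reported unconverged.
    """
    x, y = data.flat()
    logx = np.log10(x)
    span = (logx.min(), logx.max())

    if float(y.max() - y.min()) < NO_INHIBITION_RANGE:
        return DoseResponseFit(
            ic50=float("nan"),
            hill=float("nan"),
            top=float(y.mean()),
            bottom=float(y.mean()),
            se_log_ic50=float("nan"),
            converged=False,
            rss=float(((y - y.mean()) ** 2).sum()),
            flags=("no_inhibition",),
        )

    lo = [_BOUNDS_TOP[0], _BOUNDS_BOTTOM[0], span[0] - 2.0, _BOUNDS_HILL[0]]
    hi = [_BOUNDS_TOP[1], _BOUNDS_BOTTOM[1], span[1] + 2.0, _BOUNDS_HILL[1]]
    if fix_bottom is not None:
        lo[1] = fix_bottom - 1e-9
        hi[1] = fix_bottom + 1e-9

    top0 = float(np.clip(y.max(), *_BOUNDS_TOP))
    bot0 = float(np.clip(y.min(), *_BOUNDS_BOTTOM)) if fix_bottom is None else fix_bottom

    best = None
    for logic50_0 in np.linspace(span[0], span[1], n_grid):
        p0 = np.clip([top0, bot0, logic50_0, 1.0], lo, hi)
        try:
            sol = least_squares(
                _residuals, p0, bounds=(lo, hi), args=(logx, y), method="trf"
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        return DoseResponseFit(
            ic50=float("nan"), hill=float("nan"), top=float("nan"), bottom=float("nan"),
            se_log_ic50=float("nan"), converged=False,
            rss=float("inf") if best is None else float(2 * best.cost), flags=("no_convergence",),
        )

    top, bottom, logic50, hill = best.x
    rss = float(2.0 * best.cost)
    dof = max(len(y) - len(best.x), 1)
    # standard error of log10 IC50 from the Jacobian at the solution
    try:
        JTJ = best.jac.T @ best.jac
        cov = np.linalg.pinv(JTJ) * (rss / dof)
        se_log = float(np.sqrt(max(cov[2, 2], 0.0)))
    except Exception:
        se_log = float("nan")
    flags: list[str] = []
    if not span[0] <= logic50 <= span[1]:
        flags.append("extrapolated")
    return DoseResponseFit(
        ic50=float(10.0**logic50),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        se_log_ic50=se_log,
        converged=True,
        rss=rss,
        flags=tuple(flags),
    )


def selectivity_ratio(ic50_sglt1: float, ic50_sglt2: float) -> SelectivityResult:
    """SGLT1/SGLT2 selectivity: IC50(SGLT1) / IC50(SGLT2).

    The integer view rounds half away from zero, matching how selectivity
    fold-ratios are conventionally printed.
    """
    if ic50_sglt1 <= 0 or ic50_sglt2 <= 0:
        raise ValueError("IC50 values must be positive")
    return SelectivityResult(
        ic50_sglt1=float(ic50_sglt1),
        ic50_sglt2=float(ic50_sglt2),
        selectivity=float(ic50_sglt1) / float(ic50_sglt2),
    )


# ---------------------------------------------------------------------------
# Activity-table assembly
# ---------------------------------------------------------------------------


def _ic50_values(entries) -> list[float]:
    vals = []
    for e in entries:
        vals.append(float(e.ic50) if isinstance(e, DoseResponseFit) else float(e))
    return vals


@dataclass
class ActivityRecord:
    """One compound's fits (or raw IC50s, nM) per transporter.

    ``sglt2`` is required; ``sglt1`` may be empty, in which case no
    selectivity is reported.
    """

    compound_id: str
    sglt2: Sequence  # DoseResponseFit or float, one per replicate fit
    sglt1: Sequence = ()


def summarize_activity(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    """Assemble the activity table: IC50 mean ± SD per target plus selectivity.

    Selectivity uses the mean IC50s and is blank for compounds without
    SGLT1 data.  Input ordering is preserved.
    """
    rows = []
    for rec in records:
        sglt2 = _ic50_values(rec.sglt2)
        if not sglt2:
            raise ValueError(f"compound {rec.compound_id!r} lacks an SGLT2 fit")
        sglt1 = _ic50_values(rec.sglt1)
        row = {
            "compound_id": rec.compound_id,
            "ic50_sglt2_nM": float(np.mean(sglt2)),
            "ic50_sglt2_sd": float(np.std(sglt2, ddof=1)) if len(sglt2) > 1 else float("nan"),
            "ic50_sglt1_nM": float(np.mean(sglt1)) if sglt1 else float("nan"),
            "ic50_sglt1_sd": float(np.std(sglt1, ddof=1)) if len(sglt1) > 1 else float("nan"),
        }
        if sglt1:
            sel = selectivity_ratio(row["ic50_sglt1_nM"], row["ic50_sglt2_nM"])
            row["selectivity"] = sel.selectivity_rounded
        else:
            row["selectivity"] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV I/O (columns: compound_id, target, dose_nM, response_pct, replicate)
# ---------------------------------------------------------------------------


def write_dose_response_csv(datasets: Sequence[DoseResponseDataset], path: str | Path) -> None:
    rows = []
    for ds in datasets:
        for dose, reps in zip(ds.doses, ds.responses):
            for r, resp in enumerate(reps, start=1):
                rows.append(
                    {
                        "compound_id": ds.compound_id,
                        "target": ds.target.value,
                        "dose_nM": dose,
                        "response_pct": resp,
                        "replicate": r,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dose_response_csv(path: str | Path) -> list[DoseResponseDataset]:
    df = pd.read_csv(path)
    required = {"compound_id", "target", "dose_nM", "response_pct", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dose–response CSV missing columns: {sorted(missing)}")
    datasets = []
    for (cid, tgt), grp in df.groupby(["compound_id", "target"], sort=False):
        doses = sorted(grp["dose_nM"].unique())
        n_rep = int(grp["replicate"].max())
        responses = []
        for d in doses:
            sub = grp[grp["dose_nM"] == d].sort_values("replicate")
            responses.append([float(v) for v in sub["response_pct"]])
        datasets.append(
            DoseResponseDataset(
                compound_id=str(cid),
                target=Target(tgt),
                doses=[float(d) for d in doses],
                responses=responses,
                replicates=n_rep,
            )
        )
    return datasets
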