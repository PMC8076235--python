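"""Back-dating tumor initiation and the first BAP1-mutant cell.

Under exponential growth with a constant doubling time T (days), a tumor of
N cells grew from one cell log2(N) doublings ago, i.e. ``log2(N) * T`` days
before diagnosis. Applying the same doubling time to the subpopulation of
cells with lost BAP1 expression dates the first mutant cell, and the
difference between the two doubling counts gives both the tumor's age when
the mutation arose and the size of the whole tumor at that moment
(``2**(x_total - x_mutant)`` cells).

Reported median doubling times for primary uveal melanoma span 128 to 511
days with a median of 292; results are always reported per scenario, never
averaged across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .geometry import doublings

DAYS_PER_YEAR = 365.25

#: Literature-derived doubling-time scenarios (days): fastest and slowest
#: reported medians plus their overall median.
DEFAULT_SCENARIO_DAYS = (128.0, 292.0, 511.0)


@dataclass(frozen=True)
class DoublingTimeScenario:
    """One assumed doubling time, in days per doubling."""

    days_per_doubling: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.days_per_doubling > 0):
            raise InvalidInputError(
                f"days_per_doubling must be > 0, got {self.days_per_doubling}"
            )
        if not self.label:
            object.__setattr__(self, "label", f"{self.days_per_doubling:g}d")


def default_scenarios() -> list[DoublingTimeScenario]:
    return [DoublingTimeScenario(d) for d in DEFAULT_SCENARIO_DAYS]


@dataclass(frozen=True)
class TimingEstimate:
    """Back-dated initiation and mutation times under one scenario.

    All day offsets are before diagnosis; ``tumor_age_at_mutation`` is the
    tumor's age (days since initiation) when the first mutant cell appeared;
    ``clone_size_at_mutation`` is the whole-tumor cell count at that moment.
    """

    scenario: DoublingTimeScenario
    doublings_total: float
    doublings_mutant: float
    initiation_days_before_dx: float
    mutation_days_before_dx: float
    tumor_age_at_mutation: float
    clone_size_at_mutation: float


@dataclass(frozen=True)
class NoMutantClone:
    """Typed result for a tumor with no BAP1-lost cells.

    Wild-type tumors flow through cohort summaries via this sentinel instead
    of raising; only the initiation side is defined.
    """

    scenario: DoublingTimeScenario
    doublings_total: float
    initiation_days_before_dx: float


def time_before_diagnosis(n_doublings: float, scenario: DoublingTimeScenario) -> float:
    """Days before diagnosis at which the population was a single cell."""
    if n_doublings < 0:
        raise InvalidInputError(f"doubling count must be >= 0, got {n_doublings}")
    return n_doublings * scenario.days_per_doubling


def years(days: float, days_per_year: float = DAYS_PER_YEAR) -> float:
    """Convert a day count to years."""
    if days < 0:
        raise InvalidInputError(f"days must be >= 0, got {days}")
    return days / days_per_year


def mutation_timing(
    total_cells: float,
    mutant_cells: float,
    scenario: DoublingTimeScenario,
    doubling_decimals: int | None = None,
) -> TimingEstimate | NoMutantClone:
    """Date tumor initiation and the first BAP1-lost cell before diagnosis.

    Both populations are assumed to share the scenario's doubling time (the
    estimator deliberately ignores any growth advantage of the mutant clone;
    the forward simulator, not this function, quantifies that bias).

    Parameters
    ----------
    total_cells, mutant_cells
        Cell counts; ``1 <= mutant_cells <= total_cells``. ``mutant_cells=0``
        returns :class:`NoMutantClone` rather than raising.
    doubling_decimals
        If given, round both doubling counts to this many decimals before
        converting to days — the display convention used when reproducing
        printed worked examples (1 d.p.). Default: full precision.
    """
    if total_cells < 1:
        raise InvalidInputError(f"total_cells must be >= 1, got {total_cells}")
    if mutant_cells > total_cells:
        raise InvalidInputError(
            f"mutant_cells ({mutant_cells}) exceeds total_cells ({total_cells})"
        )
    d_total = doublings(total_cells)
    if doubling_decimals is not None:
        d_total = round(d_total, doubling_decimals)
    if mutant_cells == 0:
        return NoMutantClone(
            scenario=scenario,
            doublings_total=d_total,
            initiation_days_before_dx=time_before_diagnosis(d_total, scenario),
        )
    if mutant_cells < 1:
        raise InvalidInputError(
            f"mutant_cells must be 0 or >= 1, got {mutant_cells}"
        )
    d_mut = doublings(mutant_cells)
    if doubling_decimals is not None:
        d_mut = round(d_mut, doubling_decimals)
    initiation = time_before_diagnosis(d_total, scenario)
    mutation = time_before_diagnosis(d_mut, scenario)
    return TimingEstimate(
        scenario=scenario,
        doublings_total=d_total,
        doublings_mutant=d_mut,
        initiation_days_before_dx=initiation,
        mutation_days_before_dx=mutation,
        tumor_age_at_mutation=initiation - mutation,
        clone_size_at_mutation=2.0 ** (d_total - d_mut),
    )


_SUMMARY_FIELDS = (
    "doublings_total",
    "doublings_mutant",
    "initiation_days_before_dx",
    "mutation_days_before_dx",
    "tumor_age_at_mutation",
    "clone_size_at_mutation",
)


def cohort_timing_summary(estimates: list[TimingEstimate]) -> pd.DataFrame:
    """Mean / sample SD / min / max of every timing field over a cohort.

    ``NoMutantClone`` results contribute only to the initiation fields.
    """
    if not estimates:
        raise InvalidInputError("no timing estimates to summarize")
    rows = {}
    for f in _SUMMARY_FIELDS:
        vals = np.array(
            [getattr(e, f) for e in estimates if hasattr(e, f)], dtype=float
        )
        if len(vals) == 0:
            continue
        rows[f] = {
            "n": len(vals),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    out = pd.DataFrame(rows).T
    out["n"] = out["n"].astype(int)
    return out


def estimate_to_dict(patient_id, est: TimingEstimate | NoMutantClone) -> dict:
    """Serialize one per-tumor timing result (JSON-friendly)."""
    d = {
        "patient_id": patient_id,
        "scenario": est.scenario.label,
        "doublings_total": est.doublings_total,
        "initiation_days_before_dx": est.initiation_days_before_dx,
    }
    if isinstance(est, TimingEstimate):
        d.update(
            doublings_mutant=est.doublings_mutant,
            mutation_days_before_dx=est.mutation_days_before_dx,
            tumor_age_at_mutation_days=est.tumor_age_at_mutation,
            clone_size_at_mutation=est.clone_size_at_mutation,
        )
    else:
        d.update(
            doublings_mutant=None,
            mutation_days_before_dx=None,
            tumor_age_at_mutation_days=None,
            clone_size_at_mutation=None,
        )
    return d
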