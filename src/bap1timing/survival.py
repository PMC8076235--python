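"""Metastasis-free survival, optionally anchored before diagnosis.

Standard Kaplan-Meier product-limit estimation (Greenwood variance, log-log
confidence band, median with a Brookmeyer-Crowley-style 95% CI obtained from
where the band crosses 0.5) and the two-group log-rank test, both via
lifelines.

The anchored variants shift each patient's time origin backwards from
diagnosis to the estimated tumor initiation or first BAP1-lost cell: each
patient's follow-up time is incremented by their OWN back-dated offset under
a chosen doubling-time scenario (per-patient offsets, not a cohort mean —
the spread of the offsets is part of the estimate). Patients whose tumors
retain BAP1 expression in 100% of cells have no mutant clone to date and are
excluded from mutation-anchored analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times

from .errors import InvalidInputError
from .timing import DAYS_PER_YEAR, NoMutantClone, TimingEstimate

MONTHS_PER_YEAR = 12.0

Z_95 = 1.959963984540054


@dataclass
class SurvivalCurve:
    """Product-limit estimate with median summaries (times in years).

    ``median`` is the smallest time with S(t) <= 0.5; NaN (with
    ``median_defined=False``) when the curve never reaches 0.5.
    ``median_se`` is derived from the 95% CI half-width under a normal
    approximation — the convention of mainstream statistics packages; set
    ``median_se`` aside and report the CI alone where that convention is
    not wanted.
    """

    times: np.ndarray
    survival: np.ndarray
    n: int
    events: int
    median: float
    median_defined: bool
    median_ci95: tuple[float, float]
    median_se: float
    all_censored: bool = False


def km_fit(durations, event_observed, label: str = "KM") -> SurvivalCurve:
    """Kaplan-Meier metastasis-free survival from durations (years) + events."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(event_observed, dtype=int)
    if len(durations) == 0:
        raise InvalidInputError("no follow-up records")
    if np.any(durations < 0):
        raise InvalidInputError("negative follow-up time")
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(durations, events)
    median = float(kmf.median_survival_time_)
    defined = np.isfinite(median)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    se = (hi - lo) / (2 * Z_95) if np.isfinite(lo) and np.isfinite(hi) else float("nan")
    sf = kmf.survival_function_
    return SurvivalCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        n=int(len(durations)),
        events=int(events.sum()),
        median=median if defined else float("nan"),
        median_defined=bool(defined),
        median_ci95=(lo, hi),
        median_se=se,
        all_censored=bool(events.sum() == 0),
    )


def logrank(durations_a, events_a, durations_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    if len(durations_a) == 0 or len(durations_b) == 0:
        raise InvalidInputError("both groups must be non-empty")
    res = _ll_logrank(durations_a, durations_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def anchor_records(
    records: pd.DataFrame,
    timings: dict,
    anchor: str,
    days_per_year: float = DAYS_PER_YEAR,
) -> pd.DataFrame:
    """Shift follow-up origins back to estimated initiation or mutation.

    Parameters
    ----------
    records
        DataFrame with columns ``patient_id``, ``follow_up_months``,
        ``metastasis_event`` and optionally ``percent_bap1_expression``.
    timings
        Mapping patient_id -> :class:`TimingEstimate` (or
        :class:`NoMutantClone`) under the chosen doubling-time scenario.
    anchor
        ``"initiation"`` or ``"mutation"``.

    Returns a copy with ``time_years`` = follow-up (months/12) plus the
    per-patient offset (days/``days_per_year``). Event flags are unchanged.
    For ``anchor="mutation"``, tumors with 100% BAP1 expression (no lost
    cells) are excluded; any other included patient without a timing raises.
    """
    if anchor not in ("initiation", "mutation"):
        raise InvalidInputError(f"anchor must be 'initiation' or 'mutation', got {anchor!r}")
    df = records.copy()
    if anchor == "mutation" and "percent_bap1_expression" in df.columns:
        df = df[df["percent_bap1_expression"] < 100.0].copy()

    offsets = []
    keep = []
    for pid in df["patient_id"]:
        est = timings.get(pid)
        if est is None:
            raise InvalidInputError(f"no timing estimate for patient {pid!r}")
        if anchor == "initiation":
            offsets.append(est.initiation_days_before_dx)
            keep.append(True)
        else:
            if isinstance(est, NoMutantClone):
                # wild-type tumor: nothing to anchor on
                keep.append(False)
                offsets.append(np.nan)
            else:
                offsets.append(est.mutation_days_before_dx)
                keep.append(True)
    df["offset_days"] = offsets
    df = df[np.array(keep, dtype=bool)].copy()
    df["time_years"] = (
        df["follow_up_months"] / MONTHS_PER_YEAR + df["offset_days"] / days_per_year
    )
    return df


def survival_report(curve: SurvivalCurve) -> dict:
    """JSON-friendly summary of a fitted curve."""
    return {
        "n": curve.n,
        "events": curve.events,
        "median_years": curve.median if curve.median_defined else None,
        "median_se": None if np.isnan(curve.median_se) else curve.median_se,
        "median_ci95": [
            None if not np.isfinite(v) else v for v in curve.median_ci95
        ],
        "all_censored": curve.all_censored,
    }
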