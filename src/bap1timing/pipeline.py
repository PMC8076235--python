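"""End-to-end orchestration: cohort table in, report bundle out.

Stages (each consuming only prior-stage artifacts):

1. schema validation of the per-tumor table (itemized errors);
2. tumor volumes from thickness/LBD where not supplied;
3. cell counts and doubling counts from a mean cell volume — pooled from
   per-cell measurements when provided, otherwise a configurable constant
   (default 2105 um^3, the published pooled mean for uveal melanoma);
4. back-dating of initiation and first BAP1-lost cell per doubling-time
   scenario;
5. percent-lost-vs-volume curve fitting across all families, with
   zero-crossing volumes;
6. volume-based low/high expression classification scored against
   pathologist labels when present;
7. Kaplan-Meier metastasis-free survival by BAP1 group with log-rank, plus
   initiation- and mutation-anchored curves per scenario.

Tumors without a percent-lost measurement are excluded from curve fitting
but retained in survival analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import curves as curves_mod
from . import geometry, survival as survival_mod, timing as timing_mod, validation
from .errors import InvalidInputError, SchemaError

logger = logging.getLogger(__name__)

MIN_CURVE_N = 6  # cubic needs k+2 = 5; require one extra for any signal


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    cohort_csv: str | Path | None = None
    cells_tsv: str | Path | None = None
    output_dir: str | Path = "bap1timing_out"
    doubling_times_days: tuple = timing_mod.DEFAULT_SCENARIO_DAYS
    cutoff_percent: float = validation.DEFAULT_CUTOFF_PERCENT
    days_per_year: float = timing_mod.DAYS_PER_YEAR
    mean_cell_volume_um3: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.doubling_times_days:
            raise InvalidInputError("at least one doubling-time scenario required")
        if not (0.0 < self.cutoff_percent < 100.0):
            raise InvalidInputError("cutoff must be in (0, 100)")

    @property
    def scenarios(self) -> list[timing_mod.DoublingTimeScenario]:
        return [timing_mod.DoublingTimeScenario(d) for d in self.doubling_times_days]


def validate_cohort(tumors: pd.DataFrame) -> pd.DataFrame:
    """Schema-check the per-tumor table; returns a copy with volume_mm3 set.

    Requires ``patient_id`` plus either ``volume_mm3`` or both
    ``thickness_mm`` and ``lbd_mm``. Violations are collected and raised
    together as :class:`SchemaError`.
    """
    problems: list[str] = []
    if len(tumors) == 0:
        raise SchemaError(["cohort table is empty"])
    if "patient_id" not in tumors.columns:
        problems.append("missing column patient_id")
    has_volume = "volume_mm3" in tumors.columns
    has_dims = {"thickness_mm", "lbd_mm"} <= set(tumors.columns)
    if not (has_volume or has_dims):
        problems.append("need volume_mm3 or thickness_mm+lbd_mm")
    if problems:
        raise SchemaError(problems)

    df = tumors.copy()
    if not has_volume:
        df["volume_mm3"] = np.nan
    for i, row in df.iterrows():
        if has_dims and not np.isfinite(row.get("volume_mm3", np.nan)):
            t, d = row["thickness_mm"], row["lbd_mm"]
            if not (t > 0 and d > 0):
                problems.append(f"row {i} ({row.get('patient_id')}): non-positive dimensions")
                continue
            df.loc[i, "volume_mm3"] = geometry.tumor_volume(
                geometry.TumorDimensions(t, d)
            )
        elif not (row.get("volume_mm3", np.nan) > 0):
            problems.append(f"row {i} ({row.get('patient_id')}): non-positive volume")
    if "percent_bap1_loss" in df.columns:
        bad = df["percent_bap1_loss"].dropna()
        bad = bad[(bad < 0) | (bad > 100)]
        for i in bad.index:
            problems.append(f"row {i}: percent_bap1_loss outside [0, 100]")
    if problems:
        raise SchemaError(problems)
    if df["patient_id"].duplicated().any():
        raise SchemaError(["duplicate patient_id values"])
    return df


def analyze_cohort(
    tumors: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Run every applicable stage on in-memory tables; returns the bundle."""
    cfg = config or RunConfig()
    df = validate_cohort(tumors)
    bundle: dict = {}

    # --- mean cell volume & per-cell summary ---
    if cells is not None and len(cells):
        cell_summary = geometry.summarize_cell_population(cells)
        mean_cell_volume = float(cell_summary.loc["all", "mean_volume_um3"])
        bundle["cell_summary"] = cell_summary
    else:
        mean_cell_volume = (
            cfg.mean_cell_volume_um3
            if cfg.mean_cell_volume_um3 is not None
            else geometry.DEFAULT_MEAN_CELL_VOLUME_UM3
        )
    bundle["mean_cell_volume_um3"] = mean_cell_volume

    # --- counts and doublings ---
    df["total_cells"] = [
        geometry.cells_from_volume(v, mean_cell_volume) for v in df["volume_mm3"]
    ]
    df["doublings_total"] = [geometry.doublings(n) for n in df["total_cells"]]
    has_loss = "percent_bap1_loss" in df.columns
    if has_loss:
        df["mutant_cells"] = [
            int(round(n * p / 100.0)) if np.isfinite(p) else 0
            for n, p in zip(df["total_cells"], df["percent_bap1_loss"])
        ]
    bundle["per_tumor"] = df

    # --- timing per scenario ---
    timing_tables = {}
    timings_by_scenario: dict[str, dict] = {}
    for sc in cfg.scenarios:
        per_patient = {}
        rows = []
        for _, row in df.iterrows():
            mut = int(row["mutant_cells"]) if has_loss else 0
            est = timing_mod.mutation_timing(row["total_cells"], mut, sc)
            per_patient[row["patient_id"]] = est
            rows.append(timing_mod.estimate_to_dict(row["patient_id"], est))
        timings_by_scenario[sc.label] = per_patient
        timing_tables[sc.label] = pd.DataFrame(rows)
    bundle["timing"] = timing_tables
    bundle["timing_summary"] = {
        label: timing_mod.cohort_timing_summary(
            [e for e in per.values()]
        )
        for label, per in timings_by_scenario.items()
    }

    # --- curve fitting ---
    if has_loss:
        fit_df = df.dropna(subset=["percent_bap1_loss"])
        if len(fit_df) >= MIN_CURVE_N:
            fits = curves_mod.fit_all_families(
                fit_df["volume_mm3"].to_numpy(), fit_df["percent_bap1_loss"].to_numpy()
            )
            search_max = float(fit_df["volume_mm3"].max())
            table = curves_mod.model_summary_table(fits)
            table["zero_crossing_mm3"] = [
                curves_mod.zero_crossing_volume(f, search_max) if f.fitted else np.nan
                for f in fits
            ]
            bundle["curve_fits"] = fits
            bundle["curve_table"] = table
        else:
            logger.info(
                "curve fitting skipped: only %d tumors with percent loss (< %d)",
                len(fit_df), MIN_CURVE_N,
            )
            bundle["curve_table"] = None

    # --- classification validation ---
    if has_loss and "pathologist_class" in df.columns and bundle.get("curve_fits"):
        val = {}
        labeled = df.dropna(subset=["pathologist_class"])
        for f in bundle["curve_fits"]:
            if f.fitted:
                val[f.family] = validation.validate_curve(
                    f, labeled["volume_mm3"], labeled["pathologist_class"],
                    cfg.cutoff_percent,
                )
        bundle["validation"] = val

    # --- survival ---
    if {"follow_up_months", "metastasis_event"} <= set(df.columns):
        surv: dict = {}
        yrs = df["follow_up_months"].to_numpy() / survival_mod.MONTHS_PER_YEAR
        ev = df["metastasis_event"].to_numpy(dtype=int)
        surv["after_diagnosis"] = {"all": survival_mod.km_fit(yrs, ev, "all")}
        if "group" in df.columns and df["group"].nunique() == 2:
            g1, g2 = sorted(df["group"].unique())
            m1, m2 = df["group"] == g1, df["group"] == g2
            surv["after_diagnosis"][g1] = survival_mod.km_fit(yrs[m1.to_numpy()], ev[m1.to_numpy()], g1)
            surv["after_diagnosis"][g2] = survival_mod.km_fit(yrs[m2.to_numpy()], ev[m2.to_numpy()], g2)
            stat, p = survival_mod.logrank(
                yrs[m1.to_numpy()], ev[m1.to_numpy()], yrs[m2.to_numpy()], ev[m2.to_numpy()]
            )
            surv["logrank"] = {"statistic": stat, "p_value": p, "groups": [g1, g2]}
        for sc in cfg.scenarios:
            per = timings_by_scenario[sc.label]
            for anchor in ("initiation", "mutation"):
                shifted = survival_mod.anchor_records(
                    df, per, anchor, cfg.days_per_year
                )
                if len(shifted):
                    surv[f"after_{anchor}_{sc.label}"] = survival_mod.km_fit(
                        shifted["time_years"], shifted["metastasis_event"],
                        f"after {anchor} ({sc.label})",
                    )
        bundle["survival"] = surv

    return bundle


def write_report(bundle: dict, output_dir: str | Path) -> Path:
    """Write the bundle as CSV/JSON files; returns the output directory."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["per_tumor"].to_csv(out / "per_tumor.csv", index=False)
    if "cell_summary" in bundle:
        bundle["cell_summary"].to_csv(out / "cell_summary.csv")
    for label, table in bundle.get("timing", {}).items():
        table.to_csv(out / f"timing_{label}.csv", index=False)
    for label, table in bundle.get("timing_summary", {}).items():
        table.to_csv(out / f"timing_summary_{label}.csv")
    if bundle.get("curve_table") is not None:
        bundle["curve_table"].to_csv(out / "curve_fits.csv", index=False)
    if "validation" in bundle:
        payload = {
            fam: {
                "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                "accuracy": c.accuracy, "sensitivity": c.sensitivity,
                "specificity": c.specificity, "kappa": c.kappa, "band": c.band,
            }
            for fam, c in bundle["validation"].items()
        }
        (out / "validation.json").write_text(json.dumps(payload, indent=2))
    if "survival" in bundle:
        payload = {}
        for key, val in bundle["survival"].items():
            if key == "logrank":
                payload[key] = val
            elif isinstance(val, dict):
                payload[key] = {k: survival_mod.survival_report(c) for k, c in val.items()}
            else:
                payload[key] = survival_mod.survival_report(val)
                pd.DataFrame(
                    {"time_years": val.times, "survival": val.survival}
                ).to_csv(out / f"survival_{key}.csv", index=False)
        (out / "survival.json").write_text(json.dumps(payload, indent=2))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Load inputs per config, analyze, and write the report bundle."""
    if config.cohort_csv is None:
        raise InvalidInputError("cohort_csv is required")
    tumors = pd.read_csv(config.cohort_csv)
    cells = None
    if config.cells_tsv is not None:
        cells = geometry.read_qupath_cells(config.cells_tsv)
    bundle = analyze_cohort(tumors, cells, config)
    write_report(bundle, config.output_dir)
    return bundle


def two_sample_t(a, b) -> tuple[float, float]:
    """Pooled-variance (Student's) two-sided t-test.

    Returns (t, p); (nan, nan) when both samples are constant and equal so
    the statistic is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each sample needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            logger.warning("degenerate t-test: both samples constant and equal")
            return float("nan"), float("nan")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
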