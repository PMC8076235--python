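"""Synthetic cohorts and a two-clone forward growth simulator.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage is testable without patient data:

* Tumor dimensions: truncated bivariate-independent normals (thickness
  mean 7.2 SD 4.0 mm, >= 1 mm; LBD mean 13.8 SD 4.8 mm, >= 3 mm; thickness
  <= LBD enforced by rejection) — the size distribution of enucleated uveal
  melanomas.
* BAP1 mutation status: Bernoulli with prevalence 0.34 (the fraction of
  sequenced tumors carrying a mutation).
* Percent of cells with lost BAP1 expression: for mutant tumors, a linear
  trend in tumor volume (slope 0.017 %/mm^3, intercept 29.03%) plus Gaussian
  noise, clamped to [0, 100]; wild-type tumors get a small half-normal
  percentage (IHC label noise), so the mutant/wild-type dichotomy is not
  artificially sharp.
* Per-cell calipers: cell volumes drawn from two log-normal populations
  moment-matched to lost 2657 (SD 1283) um^3 and retained 1593 (SD 602)
  um^3, mixed per tumor according to its percent lost; calipers recovered
  from volume and a log-normal aspect ratio (>= 1).
* Metastasis-free survival: exponential event times with medians 2.4 y
  (mutant/low-expression) and 16.0 y (wild-type), uniform censoring on
  [0, horizon].

``simulate_growth`` is the deterministic forward model the timing estimator
inverts: a founding cell doubles every ``doubling_time_wt`` days; at
generation ``mutation_generation`` one existing cell converts to the mutant
clone, which thereafter doubles every ``doubling_time_mut`` days. Under
equal doubling times the total population stays exactly 2^(t/T), so
inverting the final counts recovers the mutation generation exactly;
``recovery_experiment`` tabulates the bias when the clone grows faster or
slower than the bulk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InvalidInputError
from .geometry import MM3_TO_UM3
from .timing import DoublingTimeScenario, mutation_timing

# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_tumors: int = 101
    seed: int = 0
    thickness_mean_mm: float = 7.2
    thickness_sd_mm: float = 4.0
    thickness_min_mm: float = 1.0
    lbd_mean_mm: float = 13.8
    lbd_sd_mm: float = 4.8
    lbd_min_mm: float = 3.0
    mutation_prevalence: float = 0.34
    loss_intercept: float = 29.03   # percent at zero volume
    loss_slope: float = 0.017       # percent per mm^3
    loss_noise_sd: float = 36.0     # percent; calibrated, see docs/methods.md
    wildtype_loss_sd: float = 5.0   # half-normal width for wild-type tumors
    cells_per_tumor: int = 2000
    lost_cell_volume_mean_um3: float = 2657.0
    lost_cell_volume_sd_um3: float = 1283.0
    retained_cell_volume_mean_um3: float = 1593.0
    retained_cell_volume_sd_um3: float = 602.0
    aspect_ratio_median: float = 1.4
    aspect_ratio_log_sd: float = 0.2
    survival_median_mutant_years: float = 2.4
    survival_median_wildtype_years: float = 16.0
    censoring_horizon_years: float = 25.0

    def __post_init__(self) -> None:
        if self.n_tumors < 0:
            raise InvalidInputError("n_tumors must be >= 0")
        for name in (
            "thickness_sd_mm", "lbd_sd_mm", "loss_noise_sd", "cells_per_tumor",
            "lost_cell_volume_mean_um3", "retained_cell_volume_mean_um3",
            "survival_median_mutant_years", "survival_median_wildtype_years",
            "censoring_horizon_years",
        ):
            if not (getattr(self, name) > 0):
                raise InvalidInputError(f"{name} must be > 0")
        if not 0.0 <= self.mutation_prevalence <= 1.0:
            raise InvalidInputError("mutation_prevalence must be in [0, 1]")
        if self.thickness_min_mm > self.lbd_min_mm + 6 * self.lbd_sd_mm:
            raise InvalidInputError("infeasible truncation bounds")


def _sample_dimensions(cfg: CohortConfig, rng: np.random.Generator, n: int):
    """Rejection-sample (thickness, lbd) pairs under the truncation rules."""
    t_out = np.empty(n)
    d_out = np.empty(n)
    filled = 0
    for _ in range(1000):
        if filled >= n:
            break
        m = max(2 * (n - filled), 16)
        t = rng.normal(cfg.thickness_mean_mm, cfg.thickness_sd_mm, m)
        d = rng.normal(cfg.lbd_mean_mm, cfg.lbd_sd_mm, m)
        ok = (t >= cfg.thickness_min_mm) & (d >= cfg.lbd_min_mm) & (t <= d)
        k = min(int(ok.sum()), n - filled)
        t_out[filled:filled + k] = t[ok][:k]
        d_out[filled:filled + k] = d[ok][:k]
        filled += k
    if filled < n:
        raise InvalidInputError("infeasible truncation bounds: acceptance rate ~ 0")
    return t_out, d_out


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD (exact)."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _calipers_from_volume(vol_um3, rng: np.random.Generator, cfg: CohortConfig):
    """Draw an aspect ratio >= 1 and convert volume to (long, short) calipers.

    V = (pi/6) * a * b^2 with a = r*b  =>  b = (6V / (pi r))^(1/3).
    """
    r = np.exp(rng.normal(math.log(cfg.aspect_ratio_median),
                          cfg.aspect_ratio_log_sd, len(vol_um3)))
    r = np.maximum(r, 1.0)
    b = np.cbrt(6.0 * np.asarray(vol_um3) / (math.pi * r))
    return r * b, b


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort: per-tumor table and per-cell caliper table.

    Returns
    -------
    tumors
        Columns: patient_id, thickness_mm, lbd_mm, volume_mm3, bap1_mutant,
        percent_bap1_loss, percent_bap1_expression, follow_up_months,
        metastasis_event, group.
    cells
        Columns: patient_id, long_caliper_um, short_caliper_um, bap1_lost.

    Fully reproducible: identical config (including seed) gives identical
    output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_tumors
    if n == 0:
        return (
            pd.DataFrame(columns=[
                "patient_id", "thickness_mm", "lbd_mm", "volume_mm3",
                "bap1_mutant", "percent_bap1_loss", "percent_bap1_expression",
                "follow_up_months", "metastasis_event", "group",
            ]),
            pd.DataFrame(columns=[
                "patient_id", "long_caliper_um", "short_caliper_um", "bap1_lost",
            ]),
        )
    thick, lbd = _sample_dimensions(cfg, rng, n)
    volume = math.pi / 6.0 * thick * lbd**2

    mutant = rng.random(n) < cfg.mutation_prevalence
    loss = np.where(
        mutant,
        cfg.loss_intercept + cfg.loss_slope * volume + rng.normal(0.0, cfg.loss_noise_sd, n),
        np.abs(rng.normal(0.0, cfg.wildtype_loss_sd, n)),
    )
    loss = np.clip(loss, 0.0, 100.0)

    # exponential metastasis times (median-matched), uniform censoring
    median = np.where(mutant, cfg.survival_median_mutant_years,
                      cfg.survival_median_wildtype_years)
    t_event = rng.exponential(median / math.log(2.0))
    t_censor = rng.uniform(0.0, cfg.censoring_horizon_years, n)
    follow_up = np.minimum(t_event, t_censor)
    event = t_event <= t_censor

    pid = np.array([f"SYN-{i:04d}" for i in range(n)])
    tumors = pd.DataFrame(
        {
            "patient_id": pid,
            "thickness_mm": thick,
            "lbd_mm": lbd,
            "volume_mm3": volume,
            "bap1_mutant": mutant,
            "percent_bap1_loss": loss,
            "percent_bap1_expression": 100.0 - loss,
            "follow_up_months": follow_up * 12.0,
            "metastasis_event": event.astype(int),
            "group": np.where(mutant, "mutant", "wild-type"),
        }
    )

    # per-cell calipers: two moment-matched log-normal volume populations
    m = cfg.cells_per_tumor
    lost_flags = rng.random((n, m)) < (loss[:, None] / 100.0)
    lost_flags = lost_flags.ravel()
    total = n * m
    mu_l, sg_l = _lognormal_params(cfg.lost_cell_volume_mean_um3,
                                   cfg.lost_cell_volume_sd_um3)
    mu_r, sg_r = _lognormal_params(cfg.retained_cell_volume_mean_um3,
                                   cfg.retained_cell_volume_sd_um3)
    z = rng.normal(0.0, 1.0, total)
    vol_cell = np.where(lost_flags, np.exp(mu_l + sg_l * z), np.exp(mu_r + sg_r * z))
    a, b = _calipers_from_volume(vol_cell, rng, cfg)
    cells = pd.DataFrame(
        {
            "patient_id": np.repeat(pid, m),
            "long_caliper_um": a,
            "short_caliper_um": b,
            "bap1_lost": lost_flags,
        }
    )
    return tumors, cells


def cells_to_qupath(cells: pd.DataFrame) -> pd.DataFrame:
    """Render the internal cell table in QuPath detection-export columns."""
    return pd.DataFrame(
        {
            "Image": cells["patient_id"],
            "Class": np.where(cells["bap1_lost"], "BAP1 lost", "BAP1 retained"),
            "Nucleus: Max caliper": cells["long_caliper_um"],
            "Nucleus: Min caliper": cells["short_caliper_um"],
        }
    )


# ---------------------------------------------------------------------------
# forward growth model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthParams:
    """Two-clone deterministic exponential growth scenario."""

    doubling_time_wt: float
    doubling_time_mut: float
    mutation_generation: float
    end_volume_mm3: float
    mean_cell_volume_um3: float = 2105.0

    def __post_init__(self) -> None:
        if not (self.doubling_time_wt > 0 and self.doubling_time_mut > 0):
            raise InvalidInputError("doubling times must be > 0")
        if self.mutation_generation < 0:
            raise InvalidInputError("mutation_generation must be >= 0")
        if not (self.end_volume_mm3 > 0 and self.mean_cell_volume_um3 > 0):
            raise InvalidInputError("volumes must be > 0")


@dataclass(frozen=True)
class GrowthResult:
    """Final state of a forward simulation."""

    params: GrowthParams
    duration_days: float
    mutation_day: float
    total_cells: float
    mutant_cells: float
    mutant_fraction: float
    trajectory: pd.DataFrame


def _populations(t: float, p: GrowthParams) -> tuple[float, float]:
    """(wt, mutant) cell counts at time t (days).

    One of the 2^g cells present at the mutation time converts to the mutant
    clone; both compartments then grow exponentially at their own rates.
    Counts are real-valued (deterministic mean-field model).
    """
    t_m = p.mutation_generation * p.doubling_time_wt
    if t < t_m:
        return 2.0 ** (t / p.doubling_time_wt), 0.0
    n_tm = 2.0 ** p.mutation_generation
    wt = (n_tm - 1.0) * 2.0 ** ((t - t_m) / p.doubling_time_wt)
    mut = 2.0 ** ((t - t_m) / p.doubling_time_mut)
    return wt, mut


def simulate_growth(params: GrowthParams, n_trajectory_points: int = 64) -> GrowthResult:
    """Grow a tumor to its end volume and report final clone sizes.

    Stops when (wt + mutant) cells x mean cell volume reaches
    ``end_volume_mm3``. Raises if the end volume is reached before the
    mutation occurs (nothing to time) — lower ``mutation_generation`` or
    raise ``end_volume_mm3``.
    """
    p = params
    n_end = p.end_volume_mm3 * MM3_TO_UM3 / p.mean_cell_volume_um3
    if n_end < 1.0:
        raise InvalidInputError("end volume smaller than one cell")
    t_m = p.mutation_generation * p.doubling_time_wt
    if 2.0 ** p.mutation_generation > n_end:
        raise InvalidInputError(
            "end volume reached before the mutation generation; "
            "nothing to time"
        )

    def total_minus_target(t: float) -> float:
        wt, mut = _populations(t, p)
        return wt + mut - n_end

    # bracket: total is nondecreasing in t; find an upper bound
    hi = t_m + max(p.doubling_time_wt, p.doubling_time_mut)
    while total_minus_target(hi) < 0:
        hi *= 2.0
    t_end = float(brentq(total_minus_target, t_m, hi, xtol=1e-9, rtol=1e-14))
    wt, mut = _populations(t_end, p)

    ts = np.linspace(0.0, t_end, n_trajectory_points)
    traj = pd.DataFrame(
        [(t, *_populations(t, p)) for t in ts],
        columns=["time_days", "wt_cells", "mutant_cells"],
    )
    total = wt + mut
    return GrowthResult(
        params=p,
        duration_days=t_end,
        mutation_day=t_m,
        total_cells=total,
        mutant_cells=mut,
        mutant_fraction=mut / total,
        trajectory=traj,
    )


def recovery_experiment(
    grid: list[GrowthParams],
    scenarios: list[DoublingTimeScenario],
) -> pd.DataFrame:
    """Bias of the back-dating estimator across a forward-simulation grid.

    For every (params, scenario) pair: simulate growth, invert the final
    counts with :func:`bap1timing.timing.mutation_timing`, and compare the
    estimated to the true time since mutation. Bias is reported in days and
    in doublings (days / scenario doubling time).
    """
    if not grid:
        raise InvalidInputError("empty parameter grid")
    rows = []
    for p in grid:
        res = simulate_growth(p)
        true_since_mutation = res.duration_days - res.mutation_day
        for sc in scenarios:
            est = mutation_timing(res.total_cells, res.mutant_cells, sc)
            bias_days = est.mutation_days_before_dx - true_since_mutation
            rows.append(
                {
                    "doubling_time_wt": p.doubling_time_wt,
                    "doubling_time_mut": p.doubling_time_mut,
                    "mutation_generation": p.mutation_generation,
                    "end_volume_mm3": p.end_volume_mm3,
                    "scenario": sc.label,
                    "true_days_since_mutation": true_since_mutation,
                    "estimated_days_since_mutation": est.mutation_days_before_dx,
                    "bias_days": bias_days,
                    "bias_doublings": bias_days / sc.days_per_doubling,
                    "estimated_tumor_age_at_mutation": est.tumor_age_at_mutation,
                    "true_tumor_age_at_mutation": res.mutation_day,
                }
            )
    return pd.DataFrame(rows)
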