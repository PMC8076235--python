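"""Percent-of-BAP1-lost-cells as a function of tumor volume.

Eleven classical curve families (the SPSS CURVEFIT set) are fitted by
ordinary least squares on each family's linearizing transformation:

=============  ==============================  =========================
family         model (percent y, volume x)     fitted as
=============  ==============================  =========================
linear         y = b0 + b1*x                   y ~ x
logarithmic    y = b0 + b1*ln(x)               y ~ ln x
inverse        y = b0 + b1/x                   y ~ 1/x
quadratic      y = b0 + b1*x + b2*x^2          y ~ x + x^2
cubic          y = b0 + ... + b3*x^3           y ~ x + x^2 + x^3
compound       y = b0 * b1^x                   ln y ~ x
power          y = b0 * x^b1                   ln y ~ ln x
S              y = exp(b0 + b1/x)              ln y ~ 1/x
growth         y = exp(b0 + b1*x)              ln y ~ x
exponential    y = b0 * exp(b1*x)              ln y ~ x
logistic       y = 1/(1/u + b0*b1^x), u=100    ln(1/y - 1/u) ~ x
=============  ==============================  =========================

A family "could not be fitted" when its transformation is undefined for any
observation (e.g. ln y with a zero percent) or the design matrix is singular
— the deterministic criterion that reproduces the exclusion of every ln-y
family as soon as one tumor has 0% lost cells. R2, F and p are reported on
the transformed scale, F = (R2/k) / ((1-R2)/(n-k-1)).

The zero-crossing volume — the tumor size at which the fitted percent of
mutant cells reaches zero — is found analytically where possible and by real
polynomial root enumeration otherwise, bounded by the observed volume range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidInputError, UnfittedCurveError

FAMILIES = (
    "linear",
    "logarithmic",
    "inverse",
    "quadratic",
    "cubic",
    "compound",
    "power",
    "S",
    "growth",
    "exponential",
    "logistic",
)

#: families estimated through a log transform of y (strictly positive fits)
_LN_Y = {"compound", "power", "S", "growth", "exponential"}
_NEEDS_POSITIVE_X = {"logarithmic", "inverse", "power", "S"}

#: number of slope parameters per family (on the transformed scale)
_K = {f: 1 for f in FAMILIES}
_K["quadratic"] = 2
_K["cubic"] = 3

DEFAULT_LOGISTIC_UPPER = 100.0


@dataclass(frozen=True)
class CurveFit:
    """One fitted (or excluded) curve family.

    ``coefficients`` are in the family's natural parameterization (b0..bk,
    intercept first); empty when ``fitted`` is False, with ``reason`` set.
    """

    family: str
    coefficients: tuple = ()
    r_squared: float = float("nan")
    f_statistic: float = float("nan")
    p_value: float = float("nan")
    n: int = 0
    fitted: bool = False
    reason: str = ""
    logistic_upper: float = DEFAULT_LOGISTIC_UPPER


def _design(x: np.ndarray, family: str) -> np.ndarray:
    if family in ("linear", "compound", "growth", "exponential", "logistic"):
        cols = [x]
    elif family in ("logarithmic", "power"):
        cols = [np.log(x)]
    elif family in ("inverse", "S"):
        cols = [1.0 / x]
    elif family == "quadratic":
        cols = [x, x**2]
    elif family == "cubic":
        cols = [x, x**2, x**3]
    else:
        raise InvalidInputError(f"unknown curve family {family!r}")
    return sm.add_constant(np.column_stack(cols))


def _back_transform(family: str, params: np.ndarray) -> tuple:
    """Transformed-scale OLS coefficients -> natural parameterization."""
    if family in ("compound", "logistic"):
        return (float(np.exp(params[0])), float(np.exp(params[1])))
    if family == "power":
        return (float(np.exp(params[0])), float(params[1]))
    if family == "exponential":
        return (float(np.exp(params[0])), float(params[1]))
    # S and growth keep the linear predictor inside exp(); polynomials are direct
    return tuple(float(p) for p in params)


def fit_curve(
    volumes,
    proportions,
    family: str,
    logistic_upper: float = DEFAULT_LOGISTIC_UPPER,
) -> CurveFit:
    """Fit one family of percent-lost vs tumor volume by transformed OLS.

    Parameters
    ----------
    volumes
        Tumor volumes, mm^3.
    proportions
        Percent of cells with lost BAP1 expression, 0-100 scale.
    family
        One of :data:`FAMILIES`.
    """
    if family not in FAMILIES:
        raise InvalidInputError(f"unknown curve family {family!r}")
    x = np.asarray(volumes, dtype=float)
    y = np.asarray(proportions, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("volumes and proportions must be equal-length 1-d")
    k = _K[family]
    n = len(x)
    if n < k + 2:
        return CurveFit(family=family, n=n, reason=f"needs at least {k + 2} points")

    def _excluded(why: str) -> CurveFit:
        return CurveFit(family=family, n=n, reason=f"could not be fitted: {why}")

    if family in _NEEDS_POSITIVE_X and not np.all(x > 0):
        return _excluded("non-positive volume under log/inverse transform")
    if family in _LN_Y and not np.all(y > 0):
        return _excluded("zero or negative proportion under log transform")
    if family == "logistic":
        if not np.all((y > 0) & (y < logistic_upper)):
            return _excluded(
                f"proportion outside (0, {logistic_upper:g}) under logistic transform"
            )
        yt = np.log(1.0 / y - 1.0 / logistic_upper)
    elif family in _LN_Y:
        yt = np.log(y)
    else:
        yt = y

    X = _design(x, family)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return _excluded("singular design matrix")
    res = sm.OLS(yt, X).fit()
    return CurveFit(
        family=family,
        coefficients=_back_transform(family, res.params),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        p_value=float(res.f_pvalue),
        n=n,
        fitted=True,
        logistic_upper=logistic_upper,
    )


def fit_all_families(volumes, proportions, **kw) -> list[CurveFit]:
    """Fit every family in :data:`FAMILIES`, in canonical order."""
    return [fit_curve(volumes, proportions, f, **kw) for f in FAMILIES]


def evaluate(fit: CurveFit, volume):
    """Evaluate a fitted curve at a volume (mm^3); returns percent.

    No clamping to [0, 100] — presentation-side clamping is a separate step
    (:func:`bap1timing.validation.predict_class` clamps).
    """
    if not fit.fitted:
        raise UnfittedCurveError(f"{fit.family} curve was not fitted: {fit.reason}")
    x = np.asarray(volume, dtype=float)
    b = fit.coefficients
    fam = fit.family
    if fam in ("logarithmic", "inverse", "power", "S") and np.any(x <= 0):
        raise InvalidInputError(f"{fam} curve requires volume > 0")
    if fam == "linear":
        out = b[0] + b[1] * x
    elif fam == "logarithmic":
        out = b[0] + b[1] * np.log(x)
    elif fam == "inverse":
        out = b[0] + b[1] / x
    elif fam == "quadratic":
        out = b[0] + b[1] * x + b[2] * x**2
    elif fam == "cubic":
        out = b[0] + b[1] * x + b[2] * x**2 + b[3] * x**3
    elif fam == "compound":
        out = b[0] * b[1] ** x
    elif fam == "power":
        out = b[0] * x ** b[1]
    elif fam == "S":
        out = np.exp(b[0] + b[1] / x)
    elif fam == "growth":
        out = np.exp(b[0] + b[1] * x)
    elif fam == "exponential":
        out = b[0] * np.exp(b[1] * x)
    elif fam == "logistic":
        out = 1.0 / (1.0 / fit.logistic_upper + b[0] * b[1] ** x)
    else:  # pragma: no cover
        raise InvalidInputError(f"unknown family {fam!r}")
    return float(out) if np.isscalar(volume) else out


def table2_curve(family: str, coefficients, n: int = 61) -> CurveFit:
    """Build a :class:`CurveFit` from published coefficients.

    Convenience for evaluating externally reported fits (e.g. a published
    model-summary table) without refitting.
    """
    return CurveFit(
        family=family, coefficients=tuple(coefficients), n=n, fitted=True
    )


def zero_crossing_volume(fit: CurveFit, search_max: float) -> float:
    """Smallest volume in (0, search_max] where the fitted percent hits 0.

    Returns 0.0 when no such root exists — either the analytic root falls at
    a non-positive volume (linear curves with positive intercept and slope)
    or the family is strictly positive (all ln-y families, logistic). The
    search is bounded by the observed volume range so polynomial roots far
    outside the data cannot override the in-range answer.
    """
    if not fit.fitted:
        raise UnfittedCurveError(f"{fit.family} curve was not fitted: {fit.reason}")
    if not (search_max > 0):
        raise InvalidInputError(f"search_max must be > 0, got {search_max}")
    b = fit.coefficients
    fam = fit.family
    roots: list[float] = []
    if fam == "linear":
        if b[1] != 0:
            roots = [-b[0] / b[1]]
    elif fam == "logarithmic":
        if b[1] != 0:
            roots = [float(np.exp(-b[0] / b[1]))]
    elif fam == "inverse":
        if b[0] != 0:
            roots = [-b[1] / b[0]]
    elif fam in ("quadratic", "cubic"):
        coefs = list(b[::-1])  # highest power first for np.roots
        while coefs and coefs[0] == 0:
            coefs = coefs[1:]
        if len(coefs) > 1:
            rr = np.roots(coefs)
            roots = [float(r.real) for r in rr if abs(r.imag) < 1e-9]
    # compound/power/S/growth/exponential/logistic are strictly positive: no root
    in_range = [r for r in roots if 0 < r <= search_max]
    return min(in_range) if in_range else 0.0


def model_summary_table(fits: list[CurveFit], decimals: int | None = None) -> pd.DataFrame:
    """Per-family function string, R2, F, p, n; unfitted families keep their
    exclusion reason, mirroring a published model-summary table."""
    rows = []
    for f in fits:
        rows.append(
            {
                "family": f.family,
                "function": function_string(f) if f.fitted else "",
                "r_squared": round(f.r_squared, decimals) if decimals and f.fitted else f.r_squared,
                "f_statistic": f.f_statistic,
                "p_value": f.p_value,
                "n": f.n,
                "fitted": f.fitted,
                "reason": f.reason,
            }
        )
    return pd.DataFrame(rows)


def function_string(fit: CurveFit) -> str:
    """Human-readable equation for a fitted family."""
    if not fit.fitted:
        return f"({fit.reason})"
    b = fit.coefficients
    fam = fit.family
    if fam == "linear":
        return f"y = {b[0]:.4g} + {b[1]:.4g}x"
    if fam == "logarithmic":
        return f"y = {b[0]:.4g} + {b[1]:.4g}ln(x)"
    if fam == "inverse":
        return f"y = {b[0]:.4g} + {b[1]:.4g}/x"
    if fam == "quadratic":
        return f"y = {b[0]:.4g} + {b[1]:.4g}x + {b[2]:.4g}x^2"
    if fam == "cubic":
        return f"y = {b[0]:.4g} + {b[1]:.4g}x + {b[2]:.4g}x^2 + {b[3]:.4g}x^3"
    if fam == "compound":
        return f"y = {b[0]:.4g} * {b[1]:.4g}^x"
    if fam == "power":
        return f"y = {b[0]:.4g} * x^{b[1]:.4g}"
    if fam == "S":
        return f"y = exp({b[0]:.4g} + {b[1]:.4g}/x)"
    if fam == "growth":
        return f"y = exp({b[0]:.4g} + {b[1]:.4g}x)"
    if fam == "exponential":
        return f"y = {b[0]:.4g} * exp({b[1]:.4g}x)"
    if fam == "logistic":
        return f"y = 1/(1/{fit.logistic_upper:g} + {b[0]:.4g} * {b[1]:.4g}^x)"
    raise InvalidInputError(f"unknown family {fam!r}")  # pragma: no cover
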