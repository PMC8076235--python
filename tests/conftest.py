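import pytest

from bap1timing import CohortConfig, generate_cohort, table2_curve

# published model-summary coefficients (percent lost vs volume in mm^3)
TABLE2 = {
    "linear": (29.03, 0.017),
    "logarithmic": (-18.28, 10.02),
    "quadratic": (29.62, 0.015, 5.73e-7),
    "cubic": (32.24, 0.003, 1.07e-5, -2.00e-9),
}


@pytest.fixture(scope="session")
def published_fits():
    """CurveFit objects built from the published model-summary table."""
    return {fam: table2_curve(fam, coefs) for fam, coefs in TABLE2.items()}


@pytest.fixture(scope="session")
def trend_cohort():
    """61-tumor cohort in which every tumor carries the loss-vs-volume trend."""
    cfg = CohortConfig(n_tumors=61, seed=42, mutation_prevalence=1.0,
                       cells_per_tumor=50)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def mixed_cohort():
    """Default-prevalence cohort with per-cell table."""
    cfg = CohortConfig(n_tumors=101, seed=7, cells_per_tumor=100)
    return generate_cohort(cfg)
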