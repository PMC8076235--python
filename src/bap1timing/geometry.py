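"""Tumor and cell volume estimation, cell counting, doubling arithmetic.

Tumors are modelled as semi-ellipsoids sitting on the eye wall, the standard
ophthalmic-oncology convention:

    V_tumor = (pi/6) * thickness * LBD**2        [mm^3]

where LBD is the largest basal diameter. Individual tumor cells are modelled
as prolate spheroids whose long/short axes are the maximum/minimum calipers
reported by digital-pathology detection (QuPath-style exports):

    V_cell = (pi/6) * long_caliper * short_caliper**2    [um^3]

Calipers are full diameters; with semi-axes a = A/2, b = B/2 this is the
familiar (4/3)*pi*a*b**2 rotating-ellipsoid volume.

Cell counts follow by dividing tumor volume by a mean cell volume
(1 mm^3 = 1e9 um^3), and the number of doublings needed to grow a tumor from
a single cell is log2 of its cell count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: 1 mm^3 in um^3; exact.
MM3_TO_UM3 = 1e9

#: Pooled mean tumor-cell volume (um^3) reported for uveal melanoma cells
#: measured by nuclear morphometry; used as the default when no per-cell
#: measurements accompany a cohort.
DEFAULT_MEAN_CELL_VOLUME_UM3 = 2105.0


@dataclass(frozen=True)
class TumorDimensions:
    """Clinical tumor dimensions in mm.

    thickness
        Apical tumor thickness.
    lbd
        Largest basal diameter.

    Thickness exceeding the basal diameter is geometrically unusual
    (mushroom-shaped tumors) but not impossible; it is flagged with a
    warning rather than rejected.
    """

    thickness: float
    lbd: float

    def __post_init__(self) -> None:
        if not (self.thickness > 0 and self.lbd > 0):
            raise InvalidInputError(
                f"tumor dimensions must be positive, got thickness={self.thickness}, "
                f"lbd={self.lbd}"
            )
        if self.thickness > self.lbd:
            logger.warning(
                "thickness %.2f mm exceeds largest basal diameter %.2f mm "
                "(mushroom-shaped tumor?)",
                self.thickness,
                self.lbd,
            )


@dataclass(frozen=True)
class CellCalipers:
    """One cell's maximum/minimum caliper (um) and its BAP1 IHC label."""

    long_caliper: float
    short_caliper: float
    bap1_lost: bool = False

    def __post_init__(self) -> None:
        if not (self.short_caliper > 0):
            raise InvalidInputError(
                f"calipers must be positive, got short={self.short_caliper}"
            )
        if self.long_caliper < self.short_caliper:
            raise InvalidInputError(
                f"long caliper ({self.long_caliper}) must be >= short caliper "
                f"({self.short_caliper})"
            )


def tumor_volume(dims: TumorDimensions) -> float:
    """Semi-ellipsoid tumor volume in mm^3: (pi/6) * t * lbd^2."""
    return math.pi / 6.0 * dims.thickness * dims.lbd**2


def cell_volume(cell: CellCalipers) -> float:
    """Prolate-spheroid cell volume in um^3: (pi/6) * long * short^2."""
    return math.pi / 6.0 * cell.long_caliper * cell.short_caliper**2


def cells_from_volume(tumor_volume_mm3: float, mean_cell_volume_um3: float) -> int:
    """Number of cells in a tumor: volume divided by mean cell volume.

    Rounded to the nearest whole cell.
    """
    if not (tumor_volume_mm3 > 0):
        raise InvalidInputError(f"tumor volume must be > 0, got {tumor_volume_mm3}")
    if not (mean_cell_volume_um3 > 0):
        raise InvalidInputError(
            f"mean cell volume must be > 0, got {mean_cell_volume_um3}"
        )
    return int(round(tumor_volume_mm3 * MM3_TO_UM3 / mean_cell_volume_um3))


def doublings(n_cells: float) -> float:
    """Doubling count x with 2**x = n_cells, i.e. log2 of the cell count."""
    if n_cells < 1:
        raise InvalidInputError(f"cell count must be >= 1, got {n_cells}")
    return math.log2(n_cells)


def summarize_cell_population(cells: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD cell volume and counts, per BAP1 label and pooled.

    Parameters
    ----------
    cells
        DataFrame with columns ``long_caliper_um``, ``short_caliper_um``,
        ``bap1_lost`` (boolean). See :func:`read_qupath_cells`.

    Returns
    -------
    DataFrame indexed by ``{"lost", "retained", "all"}`` with columns
    ``n``, ``mean_volume_um3``, ``sd_volume_um3`` (sample SD).
    """
    if len(cells) == 0:
        raise InvalidInputError("cell table is empty")
    bad = cells["long_caliper_um"] < cells["short_caliper_um"]
    if bad.any():
        raise InvalidInputError(
            f"{int(bad.sum())} cells have long caliper < short caliper"
        )
    vol = (
        math.pi / 6.0 * cells["long_caliper_um"] * cells["short_caliper_um"] ** 2
    ).to_numpy()
    lost = cells["bap1_lost"].to_numpy(dtype=bool)

    def _row(v: np.ndarray) -> dict:
        return {
            "n": len(v),
            "mean_volume_um3": float(np.mean(v)) if len(v) else float("nan"),
            "sd_volume_um3": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        }

    out = pd.DataFrame(
        {
            "lost": _row(vol[lost]),
            "retained": _row(vol[~lost]),
            "all": _row(vol),
        }
    ).T
    out["n"] = out["n"].astype(int)
    return out


# ---------------------------------------------------------------------------
# I/O: QuPath-style per-cell TSV and per-tumor CSV
# ---------------------------------------------------------------------------

QUPATH_LONG_COL = "Nucleus: Max caliper"
QUPATH_SHORT_COL = "Nucleus: Min caliper"
QUPATH_CLASS_COL = "Class"


def read_qupath_cells(
    path,
    long_col: str = QUPATH_LONG_COL,
    short_col: str = QUPATH_SHORT_COL,
    class_col: str = QUPATH_CLASS_COL,
    lost_pattern: str = "lost",
) -> pd.DataFrame:
    """Read a QuPath detection-measurements TSV into the internal cell table.

    Column names are configurable because QuPath exports vary with the
    detection settings; calipers are assumed to be in um. A cell is labelled
    BAP1-lost when its classification matches ``lost_pattern``
    (case-insensitive substring).
    """
    raw = pd.read_csv(path, sep="\t")
    for col in (long_col, short_col, class_col):
        if col not in raw.columns:
            raise InvalidInputError(f"column {col!r} missing from {path}")
    out = pd.DataFrame(
        {
            "long_caliper_um": raw[long_col].astype(float),
            "short_caliper_um": raw[short_col].astype(float),
            "bap1_lost": raw[class_col]
            .astype(str)
            .str.contains(lost_pattern, case=False, regex=False),
        }
    )
    if "Image" in raw.columns:
        out["image"] = raw["Image"]
    return out


def read_tumor_dimensions(path) -> pd.DataFrame:
    """Read a per-tumor CSV (patient_id, thickness_mm, lbd_mm), add volume.

    Rows with non-positive dimensions raise; thickness > LBD is only warned
    about, matching :class:`TumorDimensions`.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "thickness_mm", "lbd_mm"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    df = df.copy()
    df["volume_mm3"] = [
        tumor_volume(TumorDimensions(t, d))
        for t, d in zip(df["thickness_mm"], df["lbd_mm"])
    ]
    return df
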