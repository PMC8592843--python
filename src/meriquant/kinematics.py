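"""Root growth kinematics: displacement rates, residence times and
production-rate bookkeeping.

Cells in the meristem are displaced away from the quiescent centre (QC)
by the cumulative elongation of the cells below them, so the displacement
velocity rises roughly linearly with distance from the QC. Time-lapse
tracks give a per-cell displacement rate over the imaging window; a
linear regression of rate on position yields the velocity field
v(x) = a + b·x, from which the residence time between two positions
follows by integrating 1/v. For genotypes without live imaging, relative
displacement rates are derived from daily root elongation and cell-length
bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd
from scipy import integrate, stats

MERISTEM_START_UM = 8.0
MERISTEM_END_UM = 100.0


@dataclass
class KinematicsFit:
    """Linear velocity field v(x) = intercept + slope·x for one condition."""

    condition: str
    intercept: float  # µm/h
    slope: float  # 1/h
    r_squared: float
    n_cells: int
    relative_rate: float = np.nan  # fold vs the reference condition


def _per_cell_rates(tracks: pd.DataFrame, position: str) -> pd.DataFrame:
    """Endpoint displacement rate and regression position per cell.

    The rate is the full-window endpoint difference divided by elapsed
    time; the position covariate is either the start distance or the
    track's time-averaged distance (default in :func:`fit_displacement`).
    """
    rows = []
    for cell_id, g in tracks.groupby("cell_id"):
        g = g.sort_values("time_h")
        t = g["time_h"].to_numpy(dtype=float)
        x = g["distance_qc"].to_numpy(dtype=float)
        if t.size < 2 or t[-1] == t[0]:
            continue
        rate = (x[-1] - x[0]) / (t[-1] - t[0])
        pos = x[0] if position == "start" else float(np.mean(x))
        rows.append((cell_id, g["condition"].iloc[0], pos, rate))
    return pd.DataFrame(rows, columns=["cell_id", "condition", "position", "rate"])


def fit_displacement(
    tracks: pd.DataFrame,
    reference: str = "WT",
    position: str = "mean",
    force_zero_intercept: bool = False,
    r2_warn: float = 0.9,
) -> Dict[str, KinematicsFit]:
    """Fit the displacement-velocity field per condition.

    Each cell contributes one rate (endpoint difference over the full
    imaging window). Rates are regressed linearly on position — by
    default the cell's time-averaged distance from the QC, which keeps
    the fitted slope unbiased when displacement is near-exponential over
    the window; ``position="start"`` regresses on the initial distance
    instead. Relative rates are slope ratios versus the reference
    condition. A warning is raised when R² ≤ 0.9, the quality bar used
    for accepting a linear velocity field.
    """
    per_cell = _per_cell_rates(tracks, position)
    fits: Dict[str, KinematicsFit] = {}
    for cond, g in per_cell.groupby("condition"):
        xs = g["position"].to_numpy()
        ys = g["rate"].to_numpy()
        if np.unique(xs).size < 2:
            raise ValueError(f"condition {cond!r} needs ≥ 2 distinct positions")
        if xs.size < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 cells")
        if np.ptp(xs) < 30.0:
            warnings.warn(
                f"condition {cond!r} spans only {np.ptp(xs):.1f} µm of positions",
                stacklevel=2,
            )
        if force_zero_intercept:
            slope = float(xs @ ys / (xs @ xs))
            intercept = 0.0
            resid = ys - slope * xs
            ss_tot = float(np.sum(ys**2))
        else:
            res = stats.linregress(xs, ys)
            slope, intercept = float(res.slope), float(res.intercept)
            resid = ys - (intercept + slope * xs)
            ss_tot = float(np.sum((ys - ys.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        if r2 <= r2_warn:
            warnings.warn(
                f"condition {cond!r}: R² = {r2:.3f} ≤ {r2_warn}", stacklevel=2
            )
        fits[cond] = KinematicsFit(cond, intercept, slope, r2, int(xs.size))
    if reference in fits and fits[reference].slope != 0:
        for f in fits.values():
            f.relative_rate = f.slope / fits[reference].slope
    return fits


def residence_time(
    fit: KinematicsFit,
    x0: float = MERISTEM_START_UM,
    x1: float = MERISTEM_END_UM,
) -> float:
    """Hours a cell spends travelling from ``x0`` to ``x1`` µm from the QC.

    Closed-form integral of dx/v(x) for the linear field v = a + b·x:
    (1/b)·ln((a + b·x1)/(a + b·x0)), with the uniform-motion limit
    (x1 − x0)/a at b = 0. Raises ``ValueError`` if the velocity is not
    strictly positive on the interval.
    """
    a, b = fit.intercept, fit.slope
    if min(a + b * x0, a + b * x1) <= 0:
        raise ValueError("velocity must be positive on the whole interval")
    if b == 0:
        return (x1 - x0) / a
    return float(np.log((a + b * x1) / (a + b * x0)) / b)


def residence_time_quadrature(fit: KinematicsFit, x0: float, x1: float) -> float:
    """Numerical-quadrature cross-check of :func:`residence_time`."""
    val, _ = integrate.quad(lambda x: 1.0 / (fit.intercept + fit.slope * x), x0, x1)
    return float(val)


@dataclass
class ProductionInputs:
    """Daily whole-root bookkeeping for one genotype.

    ``root_elongation_day`` is the root length gained between days 6 and
    7 (µm/day); ``mature_cell_length`` the average fully elongated cell
    length (µm); ``mean_meristem_cell_length`` and
    ``meristem_cell_number`` describe the meristematic cell file.
    """

    root_elongation_day: float  # µm/day
    mature_cell_length: float  # µm
    mean_meristem_cell_length: float  # µm
    meristem_cell_number: int

    def validate(self) -> None:
        vals = (
            self.root_elongation_day,
            self.mature_cell_length,
            self.mean_meristem_cell_length,
            self.meristem_cell_number,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all production inputs must be positive")

    def residence_proxy(self) -> float:
        """Meristem length divided by the length leaving it per day."""
        self.validate()
        cells_per_day = self.root_elongation_day / self.mature_cell_length
        flux = cells_per_day * self.mean_meristem_cell_length  # µm/day
        if flux <= 0:
            raise ValueError("zero cell flux")
        meristem_length = self.meristem_cell_number * self.mean_meristem_cell_length
        return meristem_length / flux  # days


def relative_rate_from_production(
    genotype: ProductionInputs, wt: ProductionInputs
) -> float:
    """Displacement rate of a genotype relative to the WT from production
    bookkeeping: the ratio of WT to genotype meristem residence proxies."""
    return wt.residence_proxy() / genotype.residence_proxy()
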