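"""Shoot-area trajectories: calibration, leaf area duration, phenology.

Leaf area duration (LAD, cm2 d) is the time integral of the (projected)
shoot area over a growth window — the integrative measure of the
transpiring surface. Projected areas from side-view imaging track true
leaf area tightly at early vegetative stages; a simple OLS calibration
against destructive measurements converts between the two where a
per-unit-leaf-area quantity is needed.
"""

from __future__ import annotations

import numpy as np

from .stats import FitResult, ols
from .types import AreaTrajectory, ValidationError, _require


def calibrate_projected_area(projected_final, destructive_final) -> FitResult:
    """OLS of destructive leaf area on final projected area (paired by pot)."""
    x = np.asarray(projected_final, dtype=float)
    y = np.asarray(destructive_final, dtype=float)
    _require(len(x) == len(y), "calibration inputs must be paired")
    _require(len(x) >= 3, "calibration needs n >= 3 pairs")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in projected areas; cannot calibrate")
    return ols(y, x, names=["projected_area"])


def lad(traj: AreaTrajectory, das_start: float | None = None,
        das_end: float | None = None) -> float:
    """Leaf area duration: trapezoidal integral of area over DAS, cm2 d.

    The window defaults to the full trajectory span. Window endpoints
    inside the span are handled by linear interpolation; endpoints
    outside it raise (no extrapolation).
    """
    das = np.asarray(traj.das, dtype=float)
    area = np.asarray(traj.area, dtype=float)
    if das_start is None:
        das_start = das[0]
    if das_end is None:
        das_end = das[-1]
    _require(das_start < das_end, "das_start < das_end required")
    if das_start < das[0] or das_end > das[-1]:
        raise ValidationError(
            f"window [{das_start}, {das_end}] outside trajectory span "
            f"[{das[0]}, {das[-1]}] (pot {traj.pot_id})")
    inside = (das > das_start) & (das < das_end)
    grid = np.concatenate(([das_start], das[inside], [das_end]))
    vals = np.interp(grid, das, area)
    return float(np.trapezoid(vals, grid))


def phyllochron(leaf_counts) -> float:
    """Phyllochron (d per leaf): inverse slope of leaf count on DAS.

    ``leaf_counts`` is a sequence of (das, n_leaves) pairs with
    non-decreasing counts. A zero slope (no leaf appearance) has no
    finite phyllochron and raises.
    """
    pts = sorted((float(d), float(c)) for d, c in leaf_counts)
    _require(len(pts) >= 2, "phyllochron needs >= 2 observations")
    das = np.array([p[0] for p in pts])
    counts = np.array([p[1] for p in pts])
    _require(np.all(np.diff(counts) >= 0), "leaf counts must be non-decreasing")
    if counts[-1] == counts[0]:
        raise ValidationError("zero leaf-appearance rate: phyllochron undefined")
    fit = ols(counts, das, names=["das"])
    if fit.slope <= 0:
        raise ValidationError("zero leaf-appearance rate: phyllochron undefined")
    return 1.0 / fit.slope


def trajectory_from_frame(pot_df, pot_id: str) -> AreaTrajectory:
    """Build an AreaTrajectory from pot observations with projected areas."""
    sub = pot_df[(pot_df["pot_id"] == pot_id)
                 & pot_df["projected_area"].notna()].sort_values("das")
    first = sub.iloc[0]
    return AreaTrajectory(
        pot_id=pot_id, genotype_id=str(first["genotype_id"]),
        treatment=str(first["treatment"]),
        points=list(zip(sub["das"].astype(float), sub["projected_area"].astype(float))))
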