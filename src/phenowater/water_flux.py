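"""Gravimetric water fluxes: ET rates, evaporation/transpiration split.

Each pot is weighed on a fixed cadence and re-irrigated to a target
weight; between consecutive weighings the evapotranspiration rate is

    ET = (weight_prev + irrigation - weight_now) / d(DAS)   [1 g = 1 ml]

assigned to the interval midpoint. Regressing ET rate on leaf area
across pots separates the two loss pathways: the intercept is soil
evaporation (the leaf-area -> 0 limit, a property of the watering
regime), the slope is transpiration per unit canopy area. Transpiration
of any point is then ET minus the treatment's evaporation intercept,
floored at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .stats import FitResult, SlopeComparison
from .types import PartitionResult, ValidationError, _require

log = logging.getLogger(__name__)

#: Default first DAS entering regressions; earlier data are dominated by
#: evaporation during establishment and dry-down to the target moisture.
DEFAULT_ANALYSIS_START_DAS = 18

#: Pot surface footprint (23 cm x 17 cm rectangle), m2; converts ml of
#: transpired water to mm depth. Configurable because the printed pot
#: dimensions do not fix the geometry.
DEFAULT_POT_AREA_M2 = 0.23 * 0.17

#: Negative ET rates larger than this magnitude are flagged as probable
#: weighing errors (the point is retained).
NEGATIVE_ET_TOLERANCE = 2.0  # ml d-1

FLUX_COLUMNS = ["pot_id", "genotype_id", "treatment", "das", "d_das",
                "et_rate", "leaf_area"]


def et_rate_series(pots: pd.DataFrame) -> pd.DataFrame:
    """Per-interval ET rates with leaf area interpolated to midpoints.

    ``pots`` columns: pot_id, genotype_id, treatment, das, weight,
    irrigation_since_prev, projected_area (NaN on weighing-only days).
    Returns a frame with FLUX_COLUMNS; ``d_das`` is the interval length
    the rate integrates over.
    """
    rows = []
    n_negative = 0
    for pot_id, g in pots.groupby("pot_id", sort=False):
        g = g.sort_values("das")
        if g["das"].duplicated().any():
            raise ValidationError(f"duplicate (pot_id, das) for pot {pot_id}")
        weighed = g[g["weight"].notna()]
        if len(weighed) < 2:
            raise ValidationError(f"pot {pot_id}: need >= 2 weighings")
        imaged = g[g["projected_area"].notna()]
        das_w = weighed["das"].to_numpy(dtype=float)
        w = weighed["weight"].to_numpy(dtype=float)
        irr = weighed["irrigation_since_prev"].to_numpy(dtype=float)
        d_das = np.diff(das_w)
        et = (w[:-1] + irr[1:] - w[1:]) / d_das
        mid = (das_w[:-1] + das_w[1:]) / 2.0
        bad = et < -NEGATIVE_ET_TOLERANCE
        if bad.any():
            n_negative += int(bad.sum())
            log.warning("pot %s: %d ET rates below -%.1f ml d-1 (weighing "
                        "error?); points retained", pot_id, int(bad.sum()),
                        NEGATIVE_ET_TOLERANCE)
        if len(imaged):
            la = np.interp(mid, imaged["das"].to_numpy(dtype=float),
                           imaged["projected_area"].to_numpy(dtype=float))
        else:
            la = np.zeros_like(mid)
        first = g.iloc[0]
        for m, d, e, a in zip(mid, d_das, et, la):
            rows.append((pot_id, first["genotype_id"], first["treatment"],
                         m, d, e, max(a, 0.0)))
    if n_negative:
        log.info("flagged %d strongly negative ET rates in total", n_negative)
    return pd.DataFrame(rows, columns=FLUX_COLUMNS)


def partition_evapotranspiration(
        flux: pd.DataFrame, treatment: str, *,
        das_start: float = DEFAULT_ANALYSIS_START_DAS,
        genotype_means: bool = False) -> PartitionResult:
    """Split ET into evaporation (intercept) and transpiration (slope).

    OLS of ET rate on leaf area over all pot x interval points of one
    treatment from ``das_start`` onward. ``genotype_means=True`` fits
    genotype-mean points instead (sensitivity variant).
    """
    sub = flux[(flux["treatment"] == treatment) & (flux["das"] >= das_start)]
    if genotype_means:
        sub = (sub.groupby("genotype_id", observed=True)
               [["leaf_area", "et_rate"]].mean().reset_index())
    if len(sub) < 3:
        raise ValidationError(
            f"partition needs >= 3 points (treatment={treatment})")
    if np.ptp(sub["leaf_area"].to_numpy()) == 0:
        raise ValidationError("zero leaf-area variance; cannot partition")
    fit = stats.ols(sub["et_rate"].to_numpy(), sub["leaf_area"].to_numpy(),
                    names=["leaf_area"])
    log.info("partition %s: evaporation %.2f ml d-1, slope %.4f, R2 %.3f, n=%d",
             treatment, fit.intercept, fit.slope, fit.r2, fit.n)
    return PartitionResult(treatment=treatment, evaporation=fit.intercept,
                           slope=fit.slope, r2=fit.r2, n=fit.n, fit=fit)


def transpiration_of(flux: pd.DataFrame,
                     partitions: dict[str, PartitionResult]) -> pd.Series:
    """Per-point transpiration: ET minus the treatment's evaporation, >= 0."""
    evap = flux["treatment"].map({t: p.evaporation for t, p in partitions.items()})
    if evap.isna().any():
        missing = sorted(flux.loc[evap.isna(), "treatment"].unique())
        raise ValidationError(f"no partition available for treatments {missing}")
    tr = flux["et_rate"] - evap
    n_floor = int((tr < 0).sum())
    if n_floor:
        log.info("floored %d negative transpiration points to 0", n_floor)
    return tr.clip(lower=0.0)


def transpiration_traits(flux: pd.DataFrame,
                         partitions: dict[str, PartitionResult], *,
                         das_start: float = DEFAULT_ANALYSIS_START_DAS,
                         das_end: float | None = None,
                         pot_area: float = DEFAULT_POT_AREA_M2) -> pd.DataFrame:
    """Genotype x treatment transpiration rate and cumulative transpiration.

    tr_rate (ml d-1) is the window mean of per-point transpiration;
    cum_transp (mm) integrates transpiration over the window intervals
    and divides by pot surface area (1 mm over 1 m2 = 1000 ml).
    Per-pot values are averaged over replicates.
    """
    win = flux[flux["das"] >= das_start]
    if das_end is not None:
        win = win[win["das"] <= das_end]
    win = win.copy()
    win["tr"] = transpiration_of(win, partitions)
    per_pot = win.groupby(["genotype_id", "treatment", "pot_id"],
                          observed=True).apply(
        lambda g: pd.Series({
            "tr_rate": g["tr"].mean(),
            "cum_transp": float((g["tr"] * g["d_das"]).sum())
                          / (pot_area * 1000.0),
        }), include_groups=False)
    out = (per_pot.groupby(["genotype_id", "treatment"], observed=True)
           .mean().reset_index())
    return out


@dataclass
class ResidualAnalysis:
    """Genotype x treatment structure left after the leaf-area regression."""

    means: pd.DataFrame  # genotype_id, treatment, mean_residual, n
    anova: stats.AnovaResult
    letters: dict[tuple[str, str], str]  # (genotype, treatment) -> letters


def residual_analysis(flux: pd.DataFrame,
                      partitions: dict[str, PartitionResult], *,
                      das_start: float = DEFAULT_ANALYSIS_START_DAS,
                      alpha: float = 0.05) -> ResidualAnalysis:
    """Residuals of transpiration ~ leaf area, tested for genotype structure.

    Per treatment, transpiration is regressed on leaf area; residuals
    pooled over treatments enter a two-way genotype x treatment ANOVA,
    and Tukey-Kramer letters are computed on the cell means.
    """
    win = flux[flux["das"] >= das_start].copy()
    win["tr"] = transpiration_of(win, partitions)
    resid = np.empty(len(win))
    for trt, sub in win.groupby("treatment", observed=True):
        fit = stats.ols(sub["tr"].to_numpy(), sub["leaf_area"].to_numpy(),
                        names=["leaf_area"])
        resid[win.index.get_indexer(sub.index)] = fit.residuals
    win["residual"] = resid
    means = (win.groupby(["genotype_id", "treatment"], observed=True)["residual"]
             .agg(mean_residual="mean", n="size").reset_index())
    aov = stats.anova_two_way(win["residual"], win["genotype_id"],
                              win["treatment"])
    mse = float(aov.table.loc["residual", "sum_sq"]
                / aov.table.loc["residual", "df"])
    df_resid = int(aov.table.loc["residual", "df"])
    cell_means = {(r.genotype_id, r.treatment): r.mean_residual
                  for r in means.itertuples()}
    cell_n = {(r.genotype_id, r.treatment): r.n for r in means.itertuples()}
    letters = stats.tukey_letters(cell_means, mse, df_resid, cell_n,
                                  alpha=alpha)
    return ResidualAnalysis(means=means, anova=aov, letters=letters)


@dataclass
class SlopeStudy:
    """Per-treatment fits of transpiration per leaf area on conductance."""

    fits: dict[str, FitResult]
    comparison: SlopeComparison
    excluded: list[str]
    fits_all: dict[str, FitResult]  # without exclusions
    comparison_all: SlopeComparison


def transp_per_leaf_area_vs_sc(traits: pd.DataFrame, *,
                               exclusions: list[str] | None = None) -> SlopeStudy:
    """Transpiration per unit leaf area against stomatal conductance.

    ``traits`` needs genotype_id, treatment, tr_rate (ml d-1),
    leaf_area_final (cm2) and sc columns. Fits per-treatment OLS of
    tr_rate/leaf_area_final on sc and tests slope equality between the
    two treatments, both with and without the exclusion list.
    """
    exclusions = list(exclusions or [])
    treatments = sorted(traits["treatment"].unique())

    def fit_set(df: pd.DataFrame) -> dict[str, FitResult]:
        fits = {}
        for trt in treatments:
            sub = df[df["treatment"] == trt]
            if len(sub) < 3:
                raise ValidationError(
                    f"treatment {trt}: fewer than 3 points after exclusions")
            y = (sub["tr_rate"] / sub["leaf_area_final"]).to_numpy()
            fits[trt] = stats.ols(y, sub["sc"].to_numpy(), names=["sc"])
        return fits

    fits_all = fit_set(traits)
    trts = sorted(fits_all)
    comp_all = stats.compare_slopes(fits_all[trts[0]], fits_all[trts[1]])
    kept = traits[~traits["genotype_id"].isin(exclusions)]
    if exclusions:
        log.warning("excluding genotypes from conductance regression: %s",
                    ", ".join(exclusions))
    fits = fit_set(kept)
    comp = stats.compare_slopes(fits[trts[0]], fits[trts[1]])
    return SlopeStudy(fits=fits, comparison=comp, excluded=exclusions,
                      fits_all=fits_all, comparison_all=comp_all)
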