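"""End-to-end analysis: raw experiment tables -> trait table -> typology.

The stages mirror how a gravimetric pot experiment is evaluated:

1. gravimetric ET rates per pot interval, leaf areas interpolated to
   interval midpoints (water_flux.et_rate_series);
2. evaporation/transpiration partition per water regime from the
   ET ~ leaf area regression intercept;
3. genotype x treatment trait table: LAD (trapezoid over the imaging
   trajectory), mean ET rate, transpiration rate, cumulative
   transpiration, gas-exchange and harvest means;
4. typology: standardize LAD and SC, classify into the four water-use
   types, summarize, transpiration efficiency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import canopy, typology, water_flux
from .io import PipelineConfig
from .types import PartitionResult

log = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    flux: pd.DataFrame
    partitions: dict[str, PartitionResult]
    traits: pd.DataFrame  # genotype x treatment trait table
    types: pd.DataFrame  # genotype, lad_rel, sc_rel, type
    type_summary: pd.DataFrame
    te: typology.TranspirationEfficiency
    residuals: water_flux.ResidualAnalysis | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)


def build_trait_table(pots: pd.DataFrame, gas: pd.DataFrame,
                      harvest: pd.DataFrame, flux: pd.DataFrame,
                      partitions: dict[str, PartitionResult],
                      cfg: PipelineConfig) -> pd.DataFrame:
    """Assemble the genotype x treatment trait table from raw tables."""
    # per-pot LAD over the full imaging span, averaged over replicates
    lad_rows = []
    for pot_id in pots["pot_id"].unique():
        traj = canopy.trajectory_from_frame(pots, pot_id)
        lad_rows.append({"genotype_id": traj.genotype_id,
                         "treatment": traj.treatment,
                         "lad": canopy.lad(traj)})
    lad_df = (pd.DataFrame(lad_rows)
              .groupby(["genotype_id", "treatment"], observed=True)
              .mean().reset_index())

    win = flux[flux["das"] >= cfg.das_start]
    et_df = (win.groupby(["genotype_id", "treatment"], observed=True)["et_rate"]
             .mean().reset_index())
    tr_df = water_flux.transpiration_traits(
        flux, partitions, das_start=cfg.das_start, pot_area=cfg.pot_area)
    gas_df = (gas.groupby(["genotype_id", "treatment"], observed=True)
              [["sc", "pr"]].mean().reset_index())
    harvest_df = (harvest.groupby(["genotype_id", "treatment"], observed=True)
                  [["dm", "leaf_area_final", "tiller_n", "bbch", "phyllochron"]]
                  .mean().reset_index())
    traits = (lad_df.merge(et_df, on=["genotype_id", "treatment"])
              .merge(tr_df, on=["genotype_id", "treatment"])
              .merge(gas_df, on=["genotype_id", "treatment"])
              .merge(harvest_df, on=["genotype_id", "treatment"]))
    return traits


def run_analysis(pots: pd.DataFrame, gas: pd.DataFrame,
                 harvest: pd.DataFrame,
                 cfg: PipelineConfig | None = None, *,
                 with_residuals: bool = False) -> AnalysisResult:
    """Full pipeline on raw experiment frames."""
    cfg = cfg or PipelineConfig()
    flux = water_flux.et_rate_series(pots)
    partitions = {
        trt: water_flux.partition_evapotranspiration(
            flux, trt, das_start=cfg.das_start)
        for trt in sorted(flux["treatment"].unique())}
    traits = build_trait_table(pots, gas, harvest, flux, partitions, cfg)
    types = typology.classify_table(traits)
    summary = typology.type_summary(
        traits, {t: p.evaporation for t, p in partitions.items()}, types)
    te = typology.transpiration_efficiency(traits, cfg.pot_area)
    residuals = (water_flux.residual_analysis(flux, partitions,
                                              das_start=cfg.das_start,
                                              alpha=cfg.alpha)
                 if with_residuals else None)
    return AnalysisResult(flux=flux, partitions=partitions, traits=traits,
                          types=types, type_summary=summary, te=te,
                          residuals=residuals, config=cfg)


def et0_residual_regression(flux: pd.DataFrame, climate: pd.DataFrame, *,
                            das_start: float | None = None):
    """Atmospheric-demand check: residuals of ET rate ~ DAS against ET0.

    Treatment-mean ET rates are regressed on time; the residual scatter
    is regressed on reference evapotranspiration averaged over each
    weighing interval (the gravimetric rates are interval means, so the
    demand covariate must be too). Returns that second fit (its R2
    measures how much of the day-to-day ET scatter evaporative demand
    explains).
    """
    from . import stats

    if das_start is None:
        das_start = water_flux.DEFAULT_ANALYSIS_START_DAS
    win = flux[flux["das"] >= das_start]
    mean_et = (win.groupby("das", observed=True)
               .agg(et_rate=("et_rate", "mean"), d_das=("d_das", "first"))
               .reset_index())
    trend = stats.ols(mean_et["et_rate"].to_numpy(),
                      mean_et["das"].to_numpy(), names=["das"])
    cdas = climate["das"].to_numpy()
    cet0 = climate["et0"].to_numpy()
    et0 = np.array([
        cet0[(cdas >= mid - dd / 2) & (cdas < mid + dd / 2)].mean()
        for mid, dd in zip(mean_et["das"], mean_et["d_das"])])
    return stats.ols(trend.residuals, et0, names=["et0"])
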