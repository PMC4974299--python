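"""Water-use typology: the quadrant classification on standardized traits.

Transpiration is regulated morphologically (transpiring surface, taken
as leaf area duration LAD) and physiologically (stomatal conductance
SC). Standardizing both traits by their within-treatment genotype means
and averaging the two ratios per genotype places every genotype on a
dimensionless LAD x SC plane centred at (1, 1); the four quadrants are
the water-use strategies:

    lad_rel >= 1, sc_rel >= 1  -> spender      (big canopy, open stomata)
    lad_rel >= 1, sc_rel <  1  -> area         (big canopy, closed stomata)
    lad_rel <  1, sc_rel <  1  -> saver        (small canopy, closed stomata)
    lad_rel <  1, sc_rel >= 1  -> conductance  (small canopy, open stomata)

Ties at exactly 1.0 go to the "high" side — a measure-zero case that
must be deterministic. Transpiration efficiency (TE, g m-2 mm-1) is the
slope of area-normalized dry matter on cumulative transpiration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .types import (StandardizedTraits, ValidationError, WaterUseType,
                    _require)

log = logging.getLogger(__name__)


def standardize(traits: pd.DataFrame, *, lad_col: str = "lad",
                sc_col: str = "sc",
                pooled_means: bool = False) -> list[StandardizedTraits]:
    """Mean-standardized LAD and SC per genotype.

    Default: x_rel(g) = mean over treatments of x(g, t) / mean_G x(., t)
    (the average of the two within-treatment ratios). With
    ``pooled_means=True`` the ratio of cross-treatment means is used
    instead (sensitivity variant).
    """
    for trt, sub in traits.groupby("treatment", observed=True):
        dup = sub["genotype_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate genotype records in treatment {trt}: "
                f"{sorted(sub.loc[dup, 'genotype_id'])}")
    counts = traits.groupby("genotype_id", observed=True)["treatment"].nunique()
    n_trt = traits["treatment"].nunique()
    missing = counts[counts < n_trt]
    if len(missing):
        raise ValidationError(
            f"genotypes missing a treatment record: {sorted(missing.index)}")
    out = []
    t = traits.copy()
    for col in (lad_col, sc_col):
        t[f"_{col}_ratio"] = t[col] / t.groupby("treatment", observed=True)[col].transform("mean")
    if pooled_means:
        g = t.groupby("genotype_id", observed=True)[[lad_col, sc_col]].mean()
        rel = g / g.mean(axis=0)
        for gid, row in rel.iterrows():
            out.append(StandardizedTraits(genotype_id=str(gid),
                                          lad_rel=float(row[lad_col]),
                                          sc_rel=float(row[sc_col])))
    else:
        g = t.groupby("genotype_id", observed=True)[
            [f"_{lad_col}_ratio", f"_{sc_col}_ratio"]].mean()
        for gid, row in g.iterrows():
            out.append(StandardizedTraits(genotype_id=str(gid),
                                          lad_rel=float(row.iloc[0]),
                                          sc_rel=float(row.iloc[1])))
    return out


def classify(std: StandardizedTraits) -> WaterUseType:
    """Quadrant label for one genotype's standardized traits."""
    high_lad = std.lad_rel >= 1.0
    high_sc = std.sc_rel >= 1.0
    if high_lad and high_sc:
        label = "spender"
    elif high_lad:
        label = "area"
    elif high_sc:
        label = "conductance"
    else:
        label = "saver"
    return WaterUseType(genotype_id=std.genotype_id, label=label,
                        lad_rel=std.lad_rel, sc_rel=std.sc_rel)


def classify_table(traits: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """standardize + classify, as a frame (genotype, lad_rel, sc_rel, type)."""
    types = [classify(s) for s in standardize(traits, **kwargs)]
    return pd.DataFrame({
        "genotype_id": [t.genotype_id for t in types],
        "lad_rel": [t.lad_rel for t in types],
        "sc_rel": [t.sc_rel for t in types],
        "type": [t.label for t in types],
    })


def type_summary(traits: pd.DataFrame, evaporation: dict[str, float],
                 types: pd.DataFrame) -> pd.DataFrame:
    """Per-type means of standardized traits, transpiration rate and DM.

    Transpiration rate per genotype x treatment record is the ET rate
    minus the treatment's evaporation intercept; type means pool the
    records of both treatments with equal weight. Empty types appear
    with n = 0 and NaN means.
    """
    merged = traits.merge(types, on="genotype_id", how="left")
    if merged["type"].isna().any():
        miss = sorted(merged.loc[merged["type"].isna(), "genotype_id"].unique())
        raise ValidationError(f"genotypes without type label: {miss}")
    evap = merged["treatment"].map(evaporation)
    if evap.isna().any():
        raise ValidationError("evaporation intercept missing for a treatment")
    merged["tr_rate"] = merged["et_rate"] - evap
    rows = []
    for label in ("saver", "area", "conductance", "spender"):
        sub = merged[merged["type"] == label]
        rows.append({
            "type": label,
            "n_genotypes": sub["genotype_id"].nunique(),
            "lad_rel": sub["lad_rel"].mean() if len(sub) else np.nan,
            "sc_rel": sub["sc_rel"].mean() if len(sub) else np.nan,
            "tr_rate": sub["tr_rate"].mean() if len(sub) else np.nan,
            "dm": sub["dm"].mean() if len(sub) else np.nan,
        })
    return pd.DataFrame(rows)


def type_contrasts(std_long: pd.DataFrame) -> stats.AnovaResult:
    """Factorial ANOVA of standardized trait values.

    ``std_long`` is replicate- or genotype-level long data with columns
    value (the standardized trait ratio), type, trait (lad/sc) and
    treatment. Tests TYPE, TRAIT, TRT main effects and interactions.
    """
    if std_long["type"].nunique() < 2:
        raise ValidationError("type_contrasts needs >= 2 types present")
    return stats.anova_n_way(
        std_long["value"],
        {"type": std_long["type"], "trait": std_long["trait"],
         "treatment": std_long["treatment"]})


@dataclass
class TranspirationEfficiency:
    records: pd.DataFrame  # per record: te = (dm/pot_area)/cum_transp
    slope: float  # pooled regression slope, g m-2 mm-1
    intercept: float
    r2: float
    n: int


def transpiration_efficiency(traits: pd.DataFrame,
                             pot_area: float) -> TranspirationEfficiency:
    """Dry matter produced per unit water transpired.

    Per genotype x treatment record TE = (dm / pot_area) / cum_transp
    (g m-2 per mm); the pooled estimate is the OLS slope (with
    intercept) of area-normalized dry matter on cumulative
    transpiration across all records. Records with non-positive
    cumulative transpiration are skipped with a warning.
    """
    _require(pot_area > 0, "pot_area > 0 required")
    t = traits.copy()
    bad = t["cum_transp"] <= 0
    if bad.any():
        log.warning("skipping %d records with non-positive cumulative "
                    "transpiration", int(bad.sum()))
        t = t[~bad]
    t["dm_per_area"] = t["dm"] / pot_area
    t["te"] = t["dm_per_area"] / t["cum_transp"]
    fit = stats.ols(t["dm_per_area"].to_numpy(), t["cum_transp"].to_numpy(),
                    names=["cum_transp"])
    return TranspirationEfficiency(
        records=t[["genotype_id", "treatment", "te"]].reset_index(drop=True),
        slope=fit.slope, intercept=fit.intercept, r2=fit.r2, n=fit.n)
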