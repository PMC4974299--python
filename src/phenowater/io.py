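"""CSV schemas, typed reading/writing, experiment-level validation, config.

All files are UTF-8 CSV with a mandatory header and dot decimal
separator. Missing optional values (e.g. projected_area on weighing-only
days) are empty fields, never 0. Calendar dates are not stored; DAS is
the single time axis (conversion from dates happens upstream, once).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import environment, water_flux
from .environment import RetentionParams, SubstrateSpec
from .types import (ClimateDay, GasExchangeRecord, GenotypeTraitRecord,
                    HarvestRecord, PotObservation, ValidationError,
                    ValidationIssue, ValidationReport)

log = logging.getLogger(__name__)

#: Trait-table column order (fixed; mirrors the published trait table).
TRAIT_COLUMNS = ["genotype_id", "treatment", "dm", "lad", "bbch",
                 "phyllochron", "tiller_n", "et_rate", "cum_transp",
                 "sc", "pr", "is_cultivar"]

SCHEMAS: dict[str, tuple[type, list[str]]] = {
    "climate": (ClimateDay, ["das", "t_mean", "t_min", "t_max",
                             "rh_mean", "radiation"]),
    "pots": (PotObservation, ["pot_id", "genotype_id", "treatment", "das",
                              "weight", "irrigation_since_prev",
                              "projected_area"]),
    "gas_exchange": (GasExchangeRecord, ["genotype_id", "treatment",
                                         "replicate", "sc", "pr", "tr_leaf"]),
    "harvest": (HarvestRecord, ["genotype_id", "treatment", "replicate",
                                "dm", "leaf_area_final", "tiller_n",
                                "bbch", "phyllochron"]),
    "traits": (GenotypeTraitRecord, TRAIT_COLUMNS),
}

_STR_FIELDS = {"pot_id", "genotype_id", "treatment"}
_INT_FIELDS = {"das", "replicate", "bbch"}
_BOOL_FIELDS = {"is_cultivar"}


def _coerce(name: str, value):
    if pd.isna(value):
        return None
    if name in _STR_FIELDS:
        return str(value)
    if name in _INT_FIELDS:
        return int(value)
    if name in _BOOL_FIELDS:
        if isinstance(value, str):
            return value.strip().lower() in ("true", "1", "yes")
        return bool(value)
    return float(value)


def read_table(path: str | Path, schema_name: str) -> list:
    """Read a CSV into validated typed records, preserving row order."""
    if schema_name not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema_name!r}; "
                              f"known: {sorted(SCHEMAS)}")
    cls, columns = SCHEMAS[schema_name]
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path.name}: schema {schema_name!r} missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        kwargs = {c: _coerce(c, getattr(row, c)) for c in columns}
        try:
            records.append(cls(**kwargs))
        except (ValidationError, TypeError) as exc:
            raise ValidationError(f"{path.name} row {i + 2}: {exc}") from exc
    log.info("read %d %s records from %s", len(records), schema_name, path)
    return records


def records_to_frame(records: list) -> pd.DataFrame:
    """Typed records to a DataFrame (None -> NaN)."""
    if not records:
        return pd.DataFrame()
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def frame_to_records(df: pd.DataFrame, schema_name: str) -> list:
    cls, columns = SCHEMAS[schema_name]
    out = []
    for row in df[columns].itertuples(index=False):
        out.append(cls(**{c: _coerce(c, getattr(row, c)) for c in columns}))
    return out


def write_table(records_or_frame, path: str | Path,
                schema_name: str) -> None:
    """Write records (or an equivalent frame) as schema-ordered CSV."""
    _, columns = SCHEMAS[schema_name]
    if isinstance(records_or_frame, pd.DataFrame):
        df = records_or_frame
    else:
        df = records_to_frame(list(records_or_frame))
    extra = [c for c in columns if c not in df.columns]
    if extra:
        raise ValidationError(f"cannot write {schema_name}: missing {extra}")
    df[columns].to_csv(path, index=False)
    log.info("wrote %d %s rows to %s", len(df), schema_name, path)


def write_trait_table(records: list[GenotypeTraitRecord],
                      path: str | Path) -> None:
    """Write the genotype x treatment trait table (fixed column order).

    Raises on empty input or duplicate (genotype, treatment) keys; a
    round-trip read returns equal values (full stored precision).
    """
    if not records:
        raise ValidationError("write_trait_table: no records")
    keys = [(r.genotype_id, r.treatment) for r in records]
    dupes = sorted({k for k in keys if keys.count(k) > 1})
    if dupes:
        raise ValidationError(f"duplicate (genotype, treatment) rows: {dupes}")
    write_table(records, path, "traits")


def validate_experiment(pots: list[PotObservation],
                        climate: list[ClimateDay],
                        gas: list[GasExchangeRecord],
                        harvest: list[HarvestRecord],
                        *, max_weighing_gap: float = 4.0) -> ValidationReport:
    """Cross-record consistency checks; never raises, returns a report."""
    report = ValidationReport()

    def err(msg):
        report.issues.append(ValidationIssue("error", msg))

    def warn(msg):
        report.issues.append(ValidationIssue("warning", msg))

    climate_das = sorted({c.das for c in climate})
    if len(climate_das) != len(climate):
        err("duplicate das in climate series")
    pot_genotypes = {p.genotype_id for p in pots}
    harvest_genotypes = {h.genotype_id for h in harvest}
    for g in sorted(pot_genotypes - harvest_genotypes):
        err(f"genotype {g} present in pots but absent in harvest")
    for g in sorted({r.genotype_id for r in gas} - pot_genotypes):
        warn(f"genotype {g} has gas exchange but no pots")
    if pots:
        pot_das = [p.das for p in pots]
        if climate_das:
            if min(pot_das) < climate_das[0] or max(pot_das) > climate_das[-1]:
                err("climate coverage: climate series does not span the pot "
                    f"DAS range [{min(pot_das)}, {max(pot_das)}]")
        else:
            err("climate coverage: climate series is empty")
        seen = set()
        by_pot: dict[str, list[int]] = {}
        for p in pots:
            if (p.pot_id, p.das) in seen:
                err(f"duplicate observation (pot {p.pot_id}, das {p.das})")
            seen.add((p.pot_id, p.das))
            if p.weight is not None:
                by_pot.setdefault(p.pot_id, []).append(p.das)
        for pot_id, das in by_pot.items():
            das = sorted(das)
            gaps = [b - a for a, b in zip(das, das[1:]) if b - a > max_weighing_gap]
            if gaps:
                warn(f"pot {pot_id}: weighing gap(s) > {max_weighing_gap} d: "
                     f"{gaps}")
    return report


# ---------------------------------------------------------------------------
# Configuration (YAML with [substrate], [irrigation], [penman], [analysis],
# [simulation] sections)
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    substrate: SubstrateSpec = field(default_factory=lambda: SubstrateSpec(
        retention=environment.DEFAULT_RETENTION))
    paw_levels: dict = field(default_factory=lambda: {"control": 0.75,
                                                      "stress": 0.25})
    u2: float = environment.DEFAULT_U2
    elevation: float = 0.0
    rn_factor: float = environment.DEFAULT_RN_FACTOR
    das_start: float = water_flux.DEFAULT_ANALYSIS_START_DAS
    pot_area: float = water_flux.DEFAULT_POT_AREA_M2
    alpha: float = 0.05
    exclusions: list = field(default_factory=list)
    simulation: dict = field(default_factory=dict)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (missing sections -> defaults)."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sub = raw.get("substrate", {})
    if sub:
        ret = sub.get("retention", {})
        retention = RetentionParams(
            theta_r=ret.get("theta_r", environment.DEFAULT_RETENTION.theta_r),
            theta_s=ret.get("theta_s", environment.DEFAULT_RETENTION.theta_s),
            alpha=ret.get("alpha", environment.DEFAULT_RETENTION.alpha),
            n=ret.get("n", environment.DEFAULT_RETENTION.n))
        cfg.substrate = SubstrateSpec(
            retention=retention,
            volume=sub.get("volume", 5.0),
            dry_mass=sub.get("dry_mass", 1200.0),
            tare=sub.get("tare", 250.0),
            fc_potential=sub.get("fc_potential", -0.01),
            pwp_potential=sub.get("pwp_potential", -1.5))
    irr = raw.get("irrigation", {})
    if "paw_levels" in irr:
        cfg.paw_levels = dict(irr["paw_levels"])
    pen = raw.get("penman", {})
    cfg.u2 = pen.get("u2", cfg.u2)
    cfg.elevation = pen.get("elevation", cfg.elevation)
    cfg.rn_factor = pen.get("rn_factor", cfg.rn_factor)
    ana = raw.get("analysis", {})
    cfg.das_start = ana.get("das_start", cfg.das_start)
    cfg.pot_area = ana.get("pot_area_m2", cfg.pot_area)
    cfg.alpha = ana.get("alpha", cfg.alpha)
    cfg.exclusions = list(ana.get("exclusions", []))
    cfg.simulation = dict(raw.get("simulation", {}))
    return cfg
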