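"""Domain types for the pot-experiment water-use pipeline.

All records are plain dataclasses with eager invariant checks in
``__post_init__``; a violated invariant raises :class:`ValidationError`
naming the offending field and, where available, the pot or genotype id.
The single time axis everywhere is DAS (days after sowing, sowing = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Sequence

TREATMENTS = ("control", "stress")

#: Gas-exchange cuvette conditions (photon flux density and CO2 mole
#: fraction the conductance/assimilation readings refer to).
GAS_EXCHANGE_PPFD = 1500.0  # umol m-2 s-1
GAS_EXCHANGE_CO2 = 400.0  # umol mol-1


class ValidationError(ValueError):
    """An input record violates a declared invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _finite(value: float, name: str, ctx: str = "") -> None:
    if value is None or not math.isfinite(value):
        raise ValidationError(f"{name} must be finite{ctx}")


@dataclass
class ClimateDay:
    """One day of greenhouse atmosphere feeding reference ET."""

    das: int
    t_mean: float  # degC
    t_min: float
    t_max: float
    rh_mean: float  # %, 0-100
    radiation: float  # global shortwave, MJ m-2 d-1

    def __post_init__(self) -> None:
        ctx = f" (climate das={self.das})"
        for f in fields(self):
            if f.name != "das":
                _finite(getattr(self, f.name), f.name, ctx)
        _require(self.t_min <= self.t_mean <= self.t_max,
                 f"t_min <= t_mean <= t_max violated{ctx}")
        _require(0.0 <= self.rh_mean <= 100.0, f"0 <= rh_mean <= 100 violated{ctx}")
        _require(self.radiation >= 0.0, f"radiation >= 0 violated{ctx}")


@dataclass
class PotObservation:
    """One pot on one weighing/imaging day.

    The imaging and weighing cadences differ: ``projected_area`` is None
    on weighing-only days (never encoded as 0) and ``weight`` is None on
    imaging-only days. Every row carries at least one of the two.
    """

    pot_id: str
    genotype_id: str
    treatment: str
    das: int
    weight: float | None  # g, pot + substrate + water + plant
    irrigation_since_prev: float | None = None  # ml since previous weighing
    projected_area: float | None = None  # cm2

    def __post_init__(self) -> None:
        ctx = f" (pot {self.pot_id}, das={self.das})"
        _require(self.treatment in TREATMENTS,
                 f"treatment must be one of {TREATMENTS}{ctx}")
        _require(self.weight is not None or self.projected_area is not None,
                 f"row carries neither weight nor projected_area{ctx}")
        if self.weight is not None:
            _finite(self.weight, "weight", ctx)
            _require(self.weight > 0, f"weight > 0 violated{ctx}")
            _finite(self.irrigation_since_prev, "irrigation_since_prev", ctx)
            _require(self.irrigation_since_prev >= 0,
                     f"irrigation_since_prev >= 0 violated{ctx}")
        if self.projected_area is not None:
            _finite(self.projected_area, "projected_area", ctx)
            _require(self.projected_area >= 0,
                     f"projected_area >= 0 violated{ctx}")


@dataclass
class GasExchangeRecord:
    """Single-time-point leaf gas exchange (IRGA cuvette)."""

    genotype_id: str
    treatment: str
    replicate: int
    sc: float  # stomatal conductance, mmol m-2 s-1
    pr: float  # net assimilation, umol m-2 s-1
    tr_leaf: float  # leaf transpiration, mmol m-2 s-1

    def __post_init__(self) -> None:
        ctx = f" (gas exchange {self.genotype_id}/{self.treatment} rep {self.replicate})"
        _require(self.treatment in TREATMENTS,
                 f"treatment must be one of {TREATMENTS}{ctx}")
        for name in ("sc", "pr", "tr_leaf"):
            _finite(getattr(self, name), name, ctx)
        _require(self.sc > 0, f"sc > 0 violated{ctx}")


@dataclass
class HarvestRecord:
    """Destructive end-of-experiment measurements for one plant."""

    genotype_id: str
    treatment: str
    replicate: int
    dm: float  # shoot dry matter, g
    leaf_area_final: float  # destructively measured leaf area, cm2
    tiller_n: float
    bbch: int
    phyllochron: float  # d leaf-1

    def __post_init__(self) -> None:
        ctx = f" (harvest {self.genotype_id}/{self.treatment} rep {self.replicate})"
        _require(self.treatment in TREATMENTS,
                 f"treatment must be one of {TREATMENTS}{ctx}")
        for name in ("dm", "leaf_area_final", "tiller_n", "phyllochron"):
            _finite(getattr(self, name), name, ctx)
        _require(self.dm > 0, f"dm > 0 violated{ctx}")
        _require(self.leaf_area_final > 0, f"leaf_area_final > 0 violated{ctx}")
        _require(self.tiller_n >= 0, f"tiller_n >= 0 violated{ctx}")


@dataclass
class GenotypeTraitRecord:
    """One genotype x treatment row of derived traits (trait-table shape)."""

    genotype_id: str
    treatment: str
    dm: float  # g
    lad: float  # projected leaf area duration, cm2 d
    bbch: float
    phyllochron: float  # d leaf-1
    tiller_n: float
    et_rate: float  # ml d-1
    cum_transp: float  # mm
    sc: float  # mmol m-2 s-1
    pr: float  # umol m-2 s-1
    is_cultivar: bool = False

    def __post_init__(self) -> None:
        ctx = f" (traits {self.genotype_id}/{self.treatment})"
        _require(self.treatment in TREATMENTS,
                 f"treatment must be one of {TREATMENTS}{ctx}")
        for name in ("dm", "lad", "bbch", "phyllochron", "tiller_n",
                     "et_rate", "cum_transp", "sc", "pr"):
            _finite(getattr(self, name), name, ctx)


@dataclass
class AreaTrajectory:
    """Ordered projected-area time series for one pot."""

    pot_id: str
    genotype_id: str
    treatment: str
    points: Sequence[tuple[float, float]]  # (das, area cm2), das increasing

    def __post_init__(self) -> None:
        ctx = f" (trajectory pot {self.pot_id})"
        _require(len(self.points) >= 2, f"need >= 2 points for integration{ctx}")
        das = [p[0] for p in self.points]
        _require(all(b > a for a, b in zip(das, das[1:])),
                 f"das must be strictly increasing{ctx}")
        _require(all(p[1] >= 0 for p in self.points), f"area >= 0 violated{ctx}")

    @property
    def das(self) -> list[float]:
        return [p[0] for p in self.points]

    @property
    def area(self) -> list[float]:
        return [p[1] for p in self.points]


@dataclass
class FluxPoint:
    """Gravimetric ET rate for one inter-weighing interval of one pot."""

    pot_id: str
    genotype_id: str
    treatment: str
    das: float  # interval midpoint
    et_rate: float  # ml d-1
    leaf_area: float  # cm2, interpolated to das

    def __post_init__(self) -> None:
        ctx = f" (flux pot {self.pot_id}, das={self.das})"
        _finite(self.et_rate, "et_rate", ctx)
        _require(self.leaf_area >= 0, f"leaf_area >= 0 violated{ctx}")


@dataclass
class PartitionResult:
    """Evaporation/transpiration split for one treatment.

    The regression of ET rate on leaf area attributes its intercept to
    soil evaporation (leaf area -> 0 limit) and its slope to canopy
    transpiration per unit area.
    """

    treatment: str
    evaporation: float  # ml d-1 (intercept)
    slope: float  # ml d-1 cm-2
    r2: float
    n: int
    fit: "FitResult | None" = None

    def __post_init__(self) -> None:
        _require(self.n >= 3, "partition requires n >= 3 points")


WATER_USE_TYPES = ("saver", "area", "conductance", "spender")


@dataclass
class StandardizedTraits:
    """Mean-standardized leaf area duration and stomatal conductance.

    Each value is the average over treatments of the genotype's trait
    divided by the within-treatment genotype mean, so 1.0 marks the
    population average.
    """

    genotype_id: str
    lad_rel: float
    sc_rel: float

    def __post_init__(self) -> None:
        _finite(self.lad_rel, "lad_rel", f" ({self.genotype_id})")
        _finite(self.sc_rel, "sc_rel", f" ({self.genotype_id})")


@dataclass
class WaterUseType:
    """Quadrant label of the standardized LAD x SC plane."""

    genotype_id: str
    label: str
    lad_rel: float
    sc_rel: float

    def __post_init__(self) -> None:
        _require(self.label in WATER_USE_TYPES,
                 f"label must be one of {WATER_USE_TYPES}")


@dataclass
class GenotypeArchetype:
    """Generating parameters for one synthetic genotype."""

    genotype_id: str
    type_label: str
    leaf_area_max: float  # logistic asymptote under control, cm2
    sc_base: float  # control stomatal conductance, mmol m-2 s-1
    phyllochron_true: float  # d leaf-1
    is_cultivar: bool = False

    def __post_init__(self) -> None:
        _require(self.type_label in WATER_USE_TYPES,
                 f"type_label must be one of {WATER_USE_TYPES}")
        _require(self.leaf_area_max > 0 and self.sc_base > 0
                 and self.phyllochron_true > 0,
                 f"archetype rates must be positive ({self.genotype_id})")


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors
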