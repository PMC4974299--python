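"""Atmospheric demand and substrate hydrology.

Reference evapotranspiration (ET0) follows the FAO-56 daily
Penman-Monteith standard (Allen et al. formulation):

    ET0 = (0.408 * Delta * (Rn - G) + gamma * 900/(T+273) * u2 * (es - ea))
          / (Delta + gamma * (1 + 0.34 * u2))

with the saturation vapour pressure ``es`` averaged over the daily
minimum and maximum temperature and the actual vapour pressure ``ea``
taken from mean relative humidity. Greenhouse wind speed is not
measured, so ``u2`` defaults to 0.5 m s-1 (still-air greenhouse).

Substrate water retention uses the van Genuchten closed form

    theta(h) = theta_r + (theta_s - theta_r) * (1 + (alpha*h)^n)^(-m),
    m = 1 - 1/n

with suction head h in cm. Plant-available water (PAW) is the water
content difference between field capacity (-0.01 MPa) and permanent
wilting point (-1.5 MPa).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .types import ClimateDay, ValidationError, _require

log = logging.getLogger(__name__)

#: 1 MPa of matric potential expressed as cm of water column. This is
#: the single place the MPa -> suction-head conversion lives.
MPA_TO_CM_HEAD = 10197.16

#: Fraction of global radiation reaching plant level that acts as net
#: radiation in the daily energy balance (greenhouse transmission).
DEFAULT_RN_FACTOR = 0.77

DEFAULT_U2 = 0.5  # m s-1, still-air greenhouse

UNEP_CLASSES = (
    (0.05, "hyperarid"),
    (0.20, "arid"),
    (0.50, "semi-arid"),
    (0.65, "dry subhumid"),
)


# ---------------------------------------------------------------------------
# Penman-Monteith reference evapotranspiration
# ---------------------------------------------------------------------------

@dataclass
class PenmanInputs:
    """Daily inputs to the FAO-56 Penman-Monteith equation."""

    t_mean: float  # degC
    t_min: float
    t_max: float
    rh_mean: float  # %
    rn: float  # net radiation, MJ m-2 d-1
    g_flux: float = 0.0  # soil heat flux, MJ m-2 d-1 (daily convention: 0)
    u2: float = DEFAULT_U2  # wind at 2 m, m s-1
    elevation: float = 0.0  # m, for atmospheric pressure / gamma

    def __post_init__(self) -> None:
        _require(self.u2 >= 0, "u2 >= 0 violated")
        _require(self.t_min <= self.t_mean <= self.t_max,
                 "t_min <= t_mean <= t_max violated")
        _require(0 <= self.rh_mean <= 100, "0 <= rh_mean <= 100 violated")


def saturation_vapor_pressure(t: float) -> float:
    """Saturation vapour pressure e0(T) in kPa (FAO-56 eq. form)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def et0_penman_monteith(day: PenmanInputs) -> float:
    """Daily reference evapotranspiration, mm d-1.

    A (numerically possible) negative result is clamped to 0 with a
    warning; under the input invariants es >= ea so this only occurs
    with strongly negative net radiation.
    """
    es = (saturation_vapor_pressure(day.t_max)
          + saturation_vapor_pressure(day.t_min)) / 2.0
    ea = day.rh_mean / 100.0 * es
    e0_mean = saturation_vapor_pressure(day.t_mean)
    delta = 4098.0 * e0_mean / (day.t_mean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * day.elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    num = (0.408 * delta * (day.rn - day.g_flux)
           + gamma * 900.0 / (day.t_mean + 273.0) * day.u2 * (es - ea))
    den = delta + gamma * (1.0 + 0.34 * day.u2)
    et0 = num / den
    if et0 < 0:
        log.warning("negative ET0 (%.3f mm d-1) clamped to 0", et0)
        return 0.0
    return et0


def et0_from_climate(day: ClimateDay, *, u2: float = DEFAULT_U2,
                     elevation: float = 0.0,
                     rn_factor: float = DEFAULT_RN_FACTOR) -> float:
    """ET0 from a greenhouse climate record.

    Net radiation is approximated as ``rn_factor`` times global
    radiation unless the caller supplies PenmanInputs directly.
    """
    return et0_penman_monteith(PenmanInputs(
        t_mean=day.t_mean, t_min=day.t_min, t_max=day.t_max,
        rh_mean=day.rh_mean, rn=rn_factor * day.radiation,
        u2=u2, elevation=elevation))


def aridity_index(p_annual: float, et0_annual: float) -> tuple[float, str]:
    """UNEP aridity index AI = P/ET0 and its climate class.

    Bins: AI < 0.05 hyperarid, < 0.20 arid, < 0.50 semi-arid,
    < 0.65 dry subhumid, otherwise humid.
    """
    if et0_annual <= 0:
        raise ValidationError("et0_annual must be > 0")
    _require(p_annual >= 0, "p_annual >= 0 violated")
    ai = p_annual / et0_annual
    for upper, label in UNEP_CLASSES:
        if ai < upper:
            return ai, label
    return ai, "humid"


# ---------------------------------------------------------------------------
# Substrate hydrology
# ---------------------------------------------------------------------------

@dataclass
class RetentionParams:
    """van Genuchten water-retention parameters."""

    theta_r: float  # residual water content, cm3 cm-3
    theta_s: float  # saturated water content, cm3 cm-3
    alpha: float  # cm-1
    n: float  # shape, > 1

    def __post_init__(self) -> None:
        _require(0 <= self.theta_r < self.theta_s <= 1,
                 "0 <= theta_r < theta_s <= 1 violated")
        _require(self.alpha > 0, "alpha > 0 violated")
        _require(self.n > 1, "n > 1 violated")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n


#: Default retention parameters for a peat-sand-pumice potting substrate.
#: These are assumed typical values for such a mix (high porosity, easily
#: drained coarse fraction), not a laboratory fit.
DEFAULT_RETENTION = RetentionParams(theta_r=0.05, theta_s=0.55,
                                    alpha=0.02, n=1.6)


@dataclass
class SubstrateSpec:
    """A potted substrate plus the bookkeeping masses around it."""

    retention: RetentionParams
    volume: float = 5.0  # L
    dry_mass: float = 1200.0  # g oven-dry substrate per pot
    tare: float = 250.0  # g pot + cover
    fc_potential: float = -0.01  # MPa, field capacity
    pwp_potential: float = -1.5  # MPa, permanent wilting point

    def __post_init__(self) -> None:
        _require(self.volume > 0, "volume > 0 violated")
        _require(self.fc_potential > self.pwp_potential,
                 "fc_potential must be less negative than pwp_potential")


def suction_head_cm(potential_mpa: float) -> float:
    """Matric potential in MPa (negative) to suction head in cm (>= 0)."""
    return abs(potential_mpa) * MPA_TO_CM_HEAD


def theta_at(h: float, retention: RetentionParams) -> float:
    """Water content at suction head ``h`` (cm, >= 0), cm3 cm-3."""
    _require(h >= 0, "suction head h must be >= 0 (cm of water)")
    r = retention
    return r.theta_r + (r.theta_s - r.theta_r) * (1.0 + (r.alpha * h) ** r.n) ** (-r.m)


def paw(substrate: SubstrateSpec) -> tuple[float, float]:
    """Plant-available water: (volumetric fraction, ml per pot)."""
    theta_fc = theta_at(suction_head_cm(substrate.fc_potential), substrate.retention)
    theta_pwp = theta_at(suction_head_cm(substrate.pwp_potential), substrate.retention)
    frac = theta_fc - theta_pwp
    if frac <= 0:
        raise ValidationError(
            "non-positive PAW: retention curve degenerate between "
            f"{substrate.fc_potential} and {substrate.pwp_potential} MPa")
    return frac, frac * substrate.volume * 1000.0


def target_weight(substrate: SubstrateSpec, paw_level: float,
                  plant_fw: float = 0.0) -> float:
    """Pot target weight (g) holding the moisture at ``paw_level`` of PAW.

    Water mass is theta(pwp) plus paw_level of the available range,
    over the pot volume (1 g per ml).
    """
    _require(0 <= paw_level <= 1, "0 <= paw_level <= 1 violated")
    theta_pwp = theta_at(suction_head_cm(substrate.pwp_potential), substrate.retention)
    frac, _ = paw(substrate)
    water_ml = (theta_pwp + paw_level * frac) * substrate.volume * 1000.0
    return substrate.tare + substrate.dry_mass + water_ml + plant_fw
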