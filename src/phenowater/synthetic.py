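"""Synthetic pot-experiment generator.

Emulates a greenhouse phenotyping experiment: 15 durum wheat genotypes
(12 landraces, 3 modern cultivars) x 2 water regimes (75% / 25% of
plant-available water) x 5 replicate pots, grown for 47 days after
sowing, with

* daily greenhouse climate (temperature, humidity, global radiation)
  with weather-like oscillations, feeding Penman-Monteith ET0;
* per-pot logistic leaf-area growth, scaled down under drought;
* daily canopy transpiration k * area * (ET0 / mean ET0) * (SC_g /
  SC_ref) plus a constant per-treatment soil evaporation; pot weights
  follow the water balance exactly, with automated re-irrigation to the
  treatment's target weight every third day and weighing noise only on
  the recorded values;
* shoot imaging three times a week with multiplicative area noise;
* single-time-point gas exchange (3 replicates) at DAS 36, with the
  drought SC reduction and an SC-saturating assimilation so drought
  lowers conductance much more than assimilation;
* destructive harvest: dry matter built from a true transpiration
  efficiency applied to window cumulative transpiration, plus genotype
  effect and noise.

The genotype archetypes mirror the four water-use strategies (2 savers,
5 area types, 5 conductance types, 3 spenders; the cultivars are
conductance types). Drought acts on canopy water loss through leaf
area; the leaf-level conductance reduction appears in the gas-exchange
readings while the ET-vs-leaf-area relation keeps a common slope across
regimes, matching the structure the partition analysis assumes.

Every generating parameter is recorded in a truth ledger so recovery
tests can compare estimates against it. Randomness is organised as one
seed-derived stream per concern (climate, genotypes, each pot, each
gas-exchange unit), so adding pots never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .environment import SubstrateSpec, DEFAULT_RETENTION, et0_from_climate, target_weight
from .types import ClimateDay, GenotypeArchetype, ValidationError, _require

#: Archetype counts and trait levels. Leaf-area asymptotes (cm2, control)
#: and stomatal conductance (mmol m-2 s-1, control) are "high"/"low"
#: levels that place the four types in their quadrants at magnitudes
#: matching an early-vegetative-stage durum experiment.
ARCHETYPES: dict[str, tuple[int, float, float]] = {
    # label: (n genotypes, leaf_area_max, sc_base)
    "saver": (2, 325.0, 400.0),
    "area": (5, 435.0, 400.0),
    "conductance": (5, 325.0, 650.0),
    "spender": (3, 435.0, 650.0),
}


@dataclass
class SimConfig:
    """Generator configuration; the defaults are the study conditions."""

    seed: int = 0
    n_replicates: int = 5
    duration: int = 47  # DAS of harvest
    paw_levels: dict = field(default_factory=lambda: {"control": 0.75,
                                                      "stress": 0.25})
    evaporation_true: dict = field(default_factory=lambda: {"control": 39.4,
                                                            "stress": 18.6})
    te_true: float = 3.8  # g m-2 mm-1
    dm_offset: float = 30.0  # g m-2, biomass not explained by window transp.
    k_transp: float = 0.185  # ml d-1 per cm2 at reference demand/conductance
    stress_area_factor: float = 0.68  # drought multiplier on leaf area
    sc_stress_factor: float = 0.84  # drought multiplier on leaf-level SC
    pot_area: float = 0.0391  # m2
    substrate: SubstrateSpec = field(default_factory=lambda: SubstrateSpec(
        retention=DEFAULT_RETENTION))
    weigh_interval: int = 3  # d
    # noise scales
    weighing_sd: float = 5.0  # g, on recorded weights
    area_noise: float = 0.05  # multiplicative SD on imaged areas
    gas_noise: float = 0.08  # multiplicative SD on gas-exchange readings
    genotype_area_jitter: float = 0.04  # SD of genotype leaf-area deviation
    genotype_sc_jitter: float = 0.06  # SD of genotype conductance deviation
    dm_genotype_sd: float = 0.25  # g, genotype effect on dry matter
    dm_noise_sd: float = 0.3  # g, replicate noise on dry matter
    # reference modes for identifiability studies
    constant_climate: bool = False  # deterministic climate, flat demand
    uniform_conductance: bool = False  # canopy flux ignores genotype SC

    def __post_init__(self) -> None:
        for name in ("weighing_sd", "area_noise", "gas_noise",
                     "genotype_area_jitter", "genotype_sc_jitter",
                     "dm_genotype_sd", "dm_noise_sd"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.duration > self.weigh_interval, "duration too short")

    def noise_free(self) -> "SimConfig":
        """Copy with every noise scale set to zero (identifiability runs)."""
        return replace(self, weighing_sd=0.0, area_noise=0.0, gas_noise=0.0,
                       genotype_area_jitter=0.0, genotype_sc_jitter=0.0,
                       dm_genotype_sd=0.0, dm_noise_sd=0.0)


@dataclass
class SimulatedExperiment:
    climate: pd.DataFrame
    pots: pd.DataFrame
    gas_exchange: pd.DataFrame
    harvest: pd.DataFrame
    truth: dict


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def make_archetypes(cfg: SimConfig) -> list[GenotypeArchetype]:
    """The 15 default genotypes with fixed per-genotype trait jitter."""
    rng = _rng(cfg.seed, 1)
    out = []
    idx = 0
    for label, (count, area_mu, sc_mu) in ARCHETYPES.items():
        for j in range(count):
            idx += 1
            gid = f"G{idx:02d}-{label[:4]}"
            area = area_mu * (1.0 + cfg.genotype_area_jitter * rng.standard_normal())
            sc = sc_mu * (1.0 + cfg.genotype_sc_jitter * rng.standard_normal())
            phyllo = rng.uniform(2.8, 5.5)
            # the three modern cultivars sit in the conductance quadrant
            out.append(GenotypeArchetype(
                genotype_id=gid, type_label=label,
                leaf_area_max=max(area, 50.0), sc_base=max(sc, 100.0),
                phyllochron_true=phyllo,
                is_cultivar=(label == "conductance" and j < 3)))
    return out


def simulate_climate(cfg: SimConfig) -> pd.DataFrame:
    """Daily greenhouse climate, DAS 0..duration."""
    rng = _rng(cfg.seed, 0)
    rows = []
    if cfg.constant_climate:
        return pd.DataFrame([ClimateDay(das=das, t_mean=19.0, t_min=14.0,
                                        t_max=24.0, rh_mean=65.0,
                                        radiation=13.0).__dict__
                             for das in range(cfg.duration + 1)])
    for das in range(cfg.duration + 1):
        # day-to-day weather noise dominates inside a greenhouse over a
        # four-week run; the deterministic cycles are kept mild so
        # evaporative demand is not confounded with the growth trend
        t_mean = 19.0 + 1.5 * np.sin(2 * np.pi * das / 11.0) \
            + 2.0 * rng.standard_normal()
        spread_lo = 4.0 + rng.uniform(0, 2)
        spread_hi = 4.0 + rng.uniform(0, 2)
        rh = float(np.clip(65.0 + 5.0 * np.sin(2 * np.pi * das / 17.0 + 1.0)
                           + 5.0 * rng.standard_normal(), 35.0, 95.0))
        rad = float(np.clip(13.0 + 2.0 * np.sin(2 * np.pi * das / 9.0 + 0.7)
                            + 4.0 * rng.standard_normal(), 2.0, 30.0))
        rows.append(ClimateDay(das=das, t_mean=round(t_mean, 2),
                               t_min=round(t_mean - spread_lo, 2),
                               t_max=round(t_mean + spread_hi, 2),
                               rh_mean=round(rh, 1), radiation=round(rad, 2)))
    return pd.DataFrame([r.__dict__ for r in rows])


def _logistic_area(das: np.ndarray, a_max: float, rate: float,
                   midpoint: float) -> np.ndarray:
    return a_max / (1.0 + np.exp(-rate * (das - midpoint)))


def simulate_experiment(cfg: SimConfig) -> SimulatedExperiment:
    """Run the full generator; see the module docstring for the model."""
    climate = simulate_climate(cfg)
    days = [ClimateDay(**row) for row in climate.to_dict("records")]
    et0 = np.array([et0_from_climate(d) for d in days])
    et0_rel = et0 / et0.mean()
    climate = climate.assign(et0=et0)

    archetypes = make_archetypes(cfg)
    sc_ref = float(np.mean([g.sc_base for g in archetypes]))

    weigh_days = list(range(0, cfg.duration + 1, cfg.weigh_interval))
    if weigh_days[-1] != cfg.duration:
        weigh_days.append(cfg.duration)
    image_days = [d for d in range(cfg.duration + 1) if d % 7 in (1, 3, 5)]

    gas_das = min(36, cfg.duration)
    pot_rows, gas_rows, harvest_rows = [], [], []
    truth_pots = {}
    for gi, geno in enumerate(archetypes):
        for ti, (trt, paw_level) in enumerate(sorted(cfg.paw_levels.items())):
            evap = cfg.evaporation_true[trt]
            area_factor = 1.0 if trt == "control" else cfg.stress_area_factor
            for rep in range(1, cfg.n_replicates + 1):
                rng = _rng(cfg.seed, 2, gi, ti, rep)
                pot_id = f"{geno.genotype_id}_{trt[:4]}_{rep}"
                a_max = geno.leaf_area_max * area_factor \
                    * np.exp(0.05 * rng.standard_normal() if cfg.area_noise else 0.0)
                midpoint = 30.0 + (rng.uniform(-1, 1) if cfg.area_noise else 0.0)
                das_grid = np.arange(cfg.duration + 1, dtype=float)
                area_true = _logistic_area(das_grid, a_max, 0.15, midpoint)
                # day das covers [das, das+1): its flux uses the mid-day
                # canopy, not the start-of-day snapshot the camera sees
                area_midday = _logistic_area(das_grid + 0.5, a_max, 0.15,
                                             midpoint)
                # canopy flux scales sublinearly with leaf-level
                # conductance (boundary-layer decoupling): sqrt dependence
                sc_factor = (1.0 if cfg.uniform_conductance
                             else np.sqrt(geno.sc_base / sc_ref))
                tr_daily = cfg.k_transp * area_midday * et0_rel * sc_factor
                outflux = tr_daily + evap  # ml d-1, per calendar day

                target = target_weight(cfg.substrate, paw_level)
                w_true = target
                irr_since_prev = 0.0
                obs = {}
                for das in range(cfg.duration + 1):
                    if das in weigh_days:
                        noise = (cfg.weighing_sd * rng.standard_normal()
                                 if cfg.weighing_sd else 0.0)
                        obs[das] = {"weight": w_true + noise,
                                    "irrigation_since_prev": irr_since_prev}
                        irr = target - w_true  # re-irrigate to target
                        w_true = target
                        irr_since_prev = irr
                    # the day's water loss (evaluated at day's end)
                    w_true -= outflux[das]
                for das in image_days:
                    mult = (np.exp(cfg.area_noise * rng.standard_normal()
                                   - cfg.area_noise ** 2 / 2)
                            if cfg.area_noise else 1.0)
                    obs.setdefault(das, {})["projected_area"] = \
                        max(area_true[das] * mult, 0.0)
                for das in sorted(obs):
                    rec = obs[das]
                    pot_rows.append({
                        "pot_id": pot_id, "genotype_id": geno.genotype_id,
                        "treatment": trt, "das": das,
                        "weight": rec.get("weight", np.nan),
                        "irrigation_since_prev": rec.get(
                            "irrigation_since_prev", np.nan),
                        "projected_area": rec.get("projected_area", np.nan),
                    })

                # harvest: dry matter from window cumulative transpiration.
                # The window matches what the flux analysis can see: whole
                # days from the analysis start up to the last weighing.
                window = (das_grid >= 18) & (das_grid < cfg.duration)
                cum_tr_ml = float(tr_daily[window].sum())
                cum_tr_mm = cum_tr_ml / (cfg.pot_area * 1000.0)
                g_eff = (cfg.dm_genotype_sd
                         * _rng(cfg.seed, 4, gi).standard_normal())
                dm = ((cfg.te_true * cum_tr_mm + cfg.dm_offset) * cfg.pot_area
                      + g_eff + cfg.dm_noise_sd * rng.standard_normal())
                la_mult = (np.exp(cfg.area_noise * rng.standard_normal())
                           if cfg.area_noise else 1.0)
                tiller_base = 2.4 if trt == "control" else 1.5
                tiller = max(0.0, round(tiller_base + (
                    0.7 * rng.standard_normal() if cfg.area_noise else 0.0)))
                harvest_rows.append({
                    "genotype_id": geno.genotype_id, "treatment": trt,
                    "replicate": rep, "dm": max(dm, 0.1),
                    "leaf_area_final": 1.1 * area_true[-1] * la_mult,
                    "tiller_n": tiller,
                    "bbch": int(np.clip(round(30 + (
                        3 * rng.standard_normal() if cfg.area_noise else 0.0)),
                        19, 46)),
                    "phyllochron": geno.phyllochron_true * (
                        1.0 + (0.08 * rng.standard_normal()
                               if cfg.area_noise else 0.0)),
                })
                truth_pots[pot_id] = {
                    "genotype_id": geno.genotype_id, "treatment": trt,
                    "a_max": float(a_max),
                    "cum_transp_mm_window": cum_tr_mm,
                    "cum_transp_ml_total": float(tr_daily.sum()),
                    "cum_evaporation_ml": float(evap * (cfg.duration + 1)),
                    "outflux_daily": [float(v) for v in outflux],
                }

            # gas exchange: 3 replicate leaves per genotype x treatment
            sc_level = geno.sc_base * (1.0 if trt == "control"
                                       else cfg.sc_stress_factor)
            for rep in range(1, 4):
                rng = _rng(cfg.seed, 3, gi, ti, rep)
                mult = (np.exp(cfg.gas_noise * rng.standard_normal()
                               - cfg.gas_noise ** 2 / 2)
                        if cfg.gas_noise else 1.0)
                sc_obs = sc_level * mult
                pr_obs = 40.0 * sc_obs / (sc_obs + 200.0) * (
                    np.exp(0.04 * rng.standard_normal())
                    if cfg.gas_noise else 1.0)
                gas_rows.append({
                    "genotype_id": geno.genotype_id, "treatment": trt,
                    "replicate": rep, "sc": sc_obs, "pr": pr_obs,
                    "tr_leaf": 0.012 * sc_obs,
                })

    truth = {
        "seed": cfg.seed,
        "evaporation_true": dict(cfg.evaporation_true),
        "te_true": cfg.te_true,
        "dm_offset": cfg.dm_offset,
        "k_transp": cfg.k_transp,
        "sc_ref": sc_ref,
        "stress_area_factor": cfg.stress_area_factor,
        "sc_stress_factor": cfg.sc_stress_factor,
        "pot_area": cfg.pot_area,
        "gas_exchange_das": gas_das,
        "genotypes": {g.genotype_id: {
            "type": g.type_label, "leaf_area_max": g.leaf_area_max,
            "sc_base": g.sc_base, "phyllochron_true": g.phyllochron_true,
            "is_cultivar": g.is_cultivar} for g in archetypes},
        "pots": truth_pots,
    }
    return SimulatedExperiment(
        climate=climate,
        pots=pd.DataFrame(pot_rows),
        gas_exchange=pd.DataFrame(gas_rows),
        harvest=pd.DataFrame(harvest_rows),
        truth=truth,
    )


def leaf_count_series(phyllochron_true: float, das: np.ndarray,
                      rng: np.random.Generator | None = None,
                      noise_sd: float = 0.0) -> list[tuple[float, float]]:
    """Leaf-appearance observations for phyllochron recovery tests.

    Counts follow das / phyllochron (+1 for the first leaf), optionally
    with rounded Gaussian noise, kept non-decreasing.
    """
    _require(phyllochron_true > 0, "phyllochron_true must be positive")
    counts = 1.0 + np.asarray(das, dtype=float) / phyllochron_true
    if noise_sd and rng is not None:
        counts = counts + noise_sd * rng.standard_normal(len(counts))
        counts = np.maximum.accumulate(counts)
    return list(zip(np.asarray(das, dtype=float), counts))


def reference_trait_table() -> list:
    """The packaged genotype x treatment trait table (printed values).

    15 genotypes x 2 water regimes of derived traits (dry matter, LAD,
    phenology, ET rate, cumulative transpiration, gas exchange), stored
    verbatim at the precision they were reported.
    """
    from importlib.resources import files

    from .io import read_table
    return read_table(files("phenowater.data").joinpath("reference_traits.csv"),
                      "traits")
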