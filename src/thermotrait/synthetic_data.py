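"""Synthetic plate-reader and community-count data with known ground truth.

This module emulates a two-stage thermal-gradient experiment on a pool of
bacterial isolates with diverse thermal tolerance traits:

1.  *Monoculture thermal tolerance*: each taxon grows logistically in
    replicate wells at a ladder of assay temperatures (defaults: 0, 15, 20,
    25, 30, 35, 40, 45, 50 degC; 6 technical replicates), with its true
    exponential rate given by a Sharpe-Schoolfield curve and additive
    Gaussian measurement noise on OD600 (truncated at 0).  Four blank wells
    per temperature carry the medium baseline.
2.  *Community assembly under thermal selection*: the same taxa are pooled
    and incubated at community temperatures (defaults: 10, 15, 20, 25, 30,
    35 degC; 20 replicate communities).  The expected share of taxon *i* at
    temperature *T* is proportional to ``max(r_i(T), eps)**q`` where ``q``
    is the selection exponent: q = 0 gives neutral (uniform) assembly, large
    q lets the fastest grower dominate.  Colony counts are multinomial draws
    with a fixed total per replicate plate.

Because every dataset carries its generating parameters, the downstream
fitting chain can be tested for parameter recovery end-to-end.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .growth_fitting import PLATE_COLUMNS, logistic_od
from .thermal_traits import (
    BOLTZMANN_EV_PER_K,
    ZERO_C_IN_K,
    compute_topt,
    sharpe_schoolfield_ln_rate,
    to_celsius,
)

logger = logging.getLogger(__name__)

#: Floor applied to rates in the selection weighting (avoids zero weights).
RATE_FLOOR = 1e-6

#: Column order of a tidy community-count table.
COUNT_COLUMNS = ["temp_c", "replicate", "taxon", "count"]

#: Column order of the per-replicate asymptotic-biomass summary.
BIOMASS_COLUMNS = ["temp_c", "replicate", "biomass_od"]


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclasses.dataclass(frozen=True)
class TrueTaxonParams:
    """Ground-truth Sharpe-Schoolfield parameters for one simulated taxon."""

    taxon_id: str
    ea_ev: float        # activation energy (eV)
    eh_ev: float        # deactivation energy (eV)
    th_k: float         # half-inactivation temperature (K)
    ln_r_tc: float      # ln growth rate at the reference temperature
    tc_k: float = 291.15  # reference temperature (K; 18 degC)

    def __post_init__(self):
        if not (self.eh_ev > self.ea_ev > 0.0):
            raise ConfigError(
                f"{self.taxon_id}: need Eh > Ea > 0 "
                f"(Ea={self.ea_ev}, Eh={self.eh_ev})"
            )
        if not (self.th_k > ZERO_C_IN_K):
            raise ConfigError(f"{self.taxon_id}: Th must exceed 273.15 K")
        topt = compute_topt(self.ea_ev, self.eh_ev, self.th_k)
        if not math.isfinite(topt):
            raise ConfigError(f"{self.taxon_id}: implied T_opt not finite")

    @property
    def topt_c(self) -> float:
        """Implied optimum growth temperature, degC."""
        return float(to_celsius(compute_topt(self.ea_ev, self.eh_ev, self.th_k)))


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for the generator.

    Defaults mirror the experimental design being emulated: 8 taxa, nine
    monoculture assay temperatures spanning 0-50 degC with 6 technical
    replicates sampled every 2 h, and six community temperatures (10-35
    degC) with 20 replicate communities each.
    """

    n_taxa: int = 8
    assay_temps_c: tuple = (0.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)
    community_temps_c: tuple = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0)
    n_tech_reps: int = 6
    n_community_reps: int = 20
    noise_sd_od: float = 0.005
    selection_exponent: float = 3.0
    total_colonies: int = 200
    seed: int = 0
    # well-scale constants (typical plate-reader magnitudes)
    carrying_k_od: float = 1.0
    n0_od: float = 0.01
    blank_baseline_od: float = 0.05
    n_blanks: int = 4
    sample_interval_h: float = 2.0
    max_duration_h: float = 240.0
    # trait-pool ranges the taxa are drawn from
    topt_range_c: tuple = (18.7, 35.3)
    ea_range_ev: tuple = (0.23, 1.06)
    ln_r_tc_range: tuple = (math.log(0.1), math.log(0.5))
    eh_over_ea_range: tuple = (2.0, 8.0)
    tref_c: float = 18.0
    biomass_noise_sd: float = 0.05

    def __post_init__(self):
        # accept lists (e.g. from YAML) but store hashable tuples
        for field in ("assay_temps_c", "community_temps_c", "topt_range_c",
                      "ea_range_ev", "ln_r_tc_range", "eh_over_ea_range"):
            object.__setattr__(self, field,
                               tuple(float(v) for v in getattr(self, field)))

    def validate(self) -> None:
        counts = {
            "n_taxa": self.n_taxa, "n_tech_reps": self.n_tech_reps,
            "n_community_reps": self.n_community_reps,
            "total_colonies": self.total_colonies, "n_blanks": self.n_blanks,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        if self.noise_sd_od < 0:
            raise ConfigError("noise_sd_od must be >= 0")
        if self.selection_exponent < 0:
            raise ConfigError("selection_exponent must be >= 0")
        for name, (lo, hi) in (
            ("topt_range_c", self.topt_range_c),
            ("ea_range_ev", self.ea_range_ev),
            ("ln_r_tc_range", self.ln_r_tc_range),
            ("eh_over_ea_range", self.eh_over_ea_range),
        ):
            if not (hi >= lo):
                raise ConfigError(f"{name} is empty: ({lo}, {hi})")
        if self.ea_range_ev[0] <= 0:
            raise ConfigError("activation energies must be positive")
        if self.eh_over_ea_range[0] <= 1.0:
            raise ConfigError("Eh/Ea ratio must exceed 1 (need Eh > Ea)")
        if not (0 < self.n0_od < self.carrying_k_od):
            raise ConfigError("need 0 < n0_od < carrying_k_od")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic substream per generator stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(stream,))
    )


def true_growth_rate(params: TrueTaxonParams, temp_c):
    """Ground-truth growth rate r(T) in h^-1 (strictly positive for all T)."""
    return np.exp(
        sharpe_schoolfield_ln_rate(
            temp_c, params.ea_ev, params.eh_ev, params.th_k,
            params.ln_r_tc, params.tc_k,
        )
    )


def _th_for_topt(topt_k: float, ea_ev: float, eh_ev: float) -> float:
    """Invert the closed-form optimum for Th given (Topt, Ea, Eh).

    From T_opt = Eh Th / (Eh + k Th ln(Eh/Ea - 1)):
    Th = T_opt Eh / (Eh - k T_opt ln(Eh/Ea - 1)).
    """
    log_term = math.log(eh_ev / ea_ev - 1.0)
    denom = eh_ev - BOLTZMANN_EV_PER_K * topt_k * log_term
    if denom <= 0:
        raise ConfigError("requested T_opt infeasible for drawn (Ea, Eh)")
    return topt_k * eh_ev / denom


def gen_taxon_params(config: SimulationConfig) -> list[TrueTaxonParams]:
    """Draw a taxon pool with optima and activation energies spanning the
    configured ranges (defaults: T_opt 18.7-35.3 degC, E_a 0.23-1.06 eV).

    Each draw takes T_opt and E_a uniform over their ranges, a deactivation
    ratio Eh/Ea uniform over ``eh_over_ea_range`` (so Eh > Ea always), and
    back-solves T_h from the closed-form optimum.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = _rng(config, 0)
    taxa = []
    for i in range(config.n_taxa):
        topt_c = rng.uniform(*config.topt_range_c)
        ea = rng.uniform(*config.ea_range_ev)
        eh = ea * rng.uniform(*config.eh_over_ea_range)
        th = _th_for_topt(topt_c + ZERO_C_IN_K, ea, eh)
        ln_r_tc = rng.uniform(*config.ln_r_tc_range)
        taxa.append(TrueTaxonParams(
            taxon_id=f"taxon_{i + 1:02d}", ea_ev=float(ea), eh_ev=float(eh),
            th_k=float(th), ln_r_tc=float(ln_r_tc),
            tc_k=config.tref_c + ZERO_C_IN_K,
        ))
    return taxa


def _series_duration_h(rate: float, config: SimulationConfig) -> float:
    """Sampling horizon: time to reach 99% of K, capped at max_duration_h."""
    a = (config.carrying_k_od - config.n0_od) / config.n0_od
    t_sat = math.log(99.0 * a) / max(rate, 1e-9)
    t_end = min(max(t_sat, 10 * config.sample_interval_h), config.max_duration_h)
    return config.sample_interval_h * math.ceil(t_end / config.sample_interval_h)


def gen_growth_plate(
    params: Sequence[TrueTaxonParams], config: SimulationConfig
) -> pd.DataFrame:
    """Simulate the monoculture plate-reader experiment.

    Each (taxon, assay temperature, technical replicate) well follows the
    logistic curve with the taxon's true r(T), K and N0 from the config,
    sitting on the medium baseline; additive Gaussian noise (sd
    ``noise_sd_od``) is applied and the result truncated at 0.  Wells are
    read every ``sample_interval_h`` hours until ~99% of carrying capacity
    (capped at ``max_duration_h``), and ``n_blanks`` medium-only blank wells
    per temperature are read on the longest schedule used at that
    temperature.  Deterministic given ``config.seed``.
    """
    if not params:
        raise ConfigError("params must be non-empty")
    config.validate()
    rng = _rng(config, 1)
    records = []
    for temp in config.assay_temps_c:
        t_end_max = 0.0
        for taxon in params:
            rate = float(true_growth_rate(taxon, temp))
            t_end = _series_duration_h(rate, config)
            t_end_max = max(t_end_max, t_end)
            times = np.arange(0.0, t_end + 1e-9, config.sample_interval_h)
            clean = config.blank_baseline_od + logistic_od(
                times, rate, config.carrying_k_od, config.n0_od)
            for rep in range(1, config.n_tech_reps + 1):
                od = clean.copy()
                if config.noise_sd_od > 0:
                    od = od + rng.normal(0.0, config.noise_sd_od, times.size)
                od = np.maximum(od, 0.0)
                records.append(pd.DataFrame({
                    "taxon": taxon.taxon_id, "temp_c": temp, "replicate": rep,
                    "time_h": times, "od600": od, "is_blank": False,
                }))
        blank_times = np.arange(0.0, t_end_max + 1e-9, config.sample_interval_h)
        for rep in range(1, config.n_blanks + 1):
            od = np.full(blank_times.size, config.blank_baseline_od)
            if config.noise_sd_od > 0:
                od = od + rng.normal(0.0, config.noise_sd_od, blank_times.size)
            od = np.maximum(od, 0.0)
            records.append(pd.DataFrame({
                "taxon": "blank", "temp_c": temp, "replicate": rep,
                "time_h": blank_times, "od600": od, "is_blank": True,
            }))
    return pd.concat(records, ignore_index=True)[PLATE_COLUMNS]


def selection_proportions(
    params: Sequence[TrueTaxonParams], temp_c: float, selection_exponent: float
) -> np.ndarray:
    """Expected community proportions under fitness-power selection at one T.

    p_i is proportional to ``max(r_i(T), eps)**q``; q = 0 returns the uniform
    vector.  If every rate is non-positive (cannot occur for the
    Sharpe-Schoolfield truth, but guarded for user-supplied pools), falls
    back to uniform with a logged warning.
    """
    rates = np.array([float(true_growth_rate(p, temp_c)) for p in params])
    if np.all(rates <= 0.0):
        logger.warning("all taxa have non-positive rate at %s degC; "
                       "using uniform proportions", temp_c)
        return np.full(len(params), 1.0 / len(params))
    weights = np.maximum(rates, RATE_FLOOR) ** float(selection_exponent)
    return weights / weights.sum()


def gen_community_counts(
    params: Sequence[TrueTaxonParams], config: SimulationConfig
) -> pd.DataFrame:
    """Simulate end-of-experiment colony counts along the thermal gradient.

    At each community temperature the expected proportions come from
    :func:`selection_proportions`; each of the ``n_community_reps`` replicate
    plates is an independent multinomial draw of ``total_colonies`` colonies.
    Returns a tidy table ``temp_c, replicate, taxon, count`` including zero
    counts.  Deterministic given ``config.seed``.
    """
    if not params:
        raise ConfigError("params must be non-empty")
    config.validate()
    rng = _rng(config, 2)
    taxa = [p.taxon_id for p in params]
    rows = []
    for temp in config.community_temps_c:
        props = selection_proportions(params, temp, config.selection_exponent)
        for rep in range(1, config.n_community_reps + 1):
            counts = rng.multinomial(config.total_colonies, props)
            for taxon, count in zip(taxa, counts):
                rows.append((temp, rep, taxon, int(count)))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def gen_community_biomass(
    params: Sequence[TrueTaxonParams], config: SimulationConfig
) -> pd.DataFrame:
    """Simulate the day-7 asymptotic community biomass (OD600) per replicate.

    Expected biomass at temperature T is ``K * mean_i s_i(T)`` where
    ``s_i(T) = r_i(T) / r_i(T_opt_i)`` is taxon i's performance relative to
    its own optimum — a niche-complementarity-style summary under which
    biomass peaks where many taxa perform well and falls at thermal extremes
    where few do.  Gaussian noise (sd ``biomass_noise_sd``) is added and the
    result floored at a small positive OD.
    """
    if not params:
        raise ConfigError("params must be non-empty")
    config.validate()
    rng = _rng(config, 3)
    rel_perf = []
    for p in params:
        peak = float(true_growth_rate(p, p.topt_c))
        rel_perf.append(
            lambda t, p=p, peak=peak: float(true_growth_rate(p, t)) / peak
        )
    rows = []
    for temp in config.community_temps_c:
        expected = config.carrying_k_od * float(
            np.mean([f(temp) for f in rel_perf]))
        for rep in range(1, config.n_community_reps + 1):
            od = expected + rng.normal(0.0, config.biomass_noise_sd)
            rows.append((temp, rep, max(od, 1e-3)))
    return pd.DataFrame(rows, columns=BIOMASS_COLUMNS)
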