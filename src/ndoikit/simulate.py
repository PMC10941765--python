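"""Synthetic monthly surveillance data with a pandemic-style step intervention.

The generator emulates the statistical structure of a metropolitan
notifiable-disease register: a few dozen diseases across four transmission
routes whose monthly counts are overdispersed (negative-binomial), seasonal,
and span several orders of magnitude in baseline incidence; a panel of
meteorological / air-quality / socioeconomic covariates with seasonal
structure; and a step intervention (the pandemic) that multiplicatively
suppresses incidence per route while shifting some covariates (mobility
collapse, pollutant decline).  Optional planted linear covariate–disease
effects act on the log-mean scale with covariates standardized inside the
generator, so coefficients read as log-rate change per covariate SD.

Counts for disease d in month m (0-based) are drawn as

    C_dm ~ NegBin(mean = mu_dm, overdispersion k),   Var = mu + mu^2 / k,

    mu_dm = baseline_d * (1 + A sin(2 pi m / 12 + phase_d))
            * route multiplier       (if m is at/after the intervention)
            * exp(sum_c coef_{c,d} * z_cm).

Output is a pure function of the config (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import CovariateTable, DiseaseCatalog, MonthlyCaseTable, ROUTES

_POISSON_LIMIT = 1e6  # overdispersion above this is numerically Poisson


class ConfigurationError(ValueError):
    """The simulation config produced a non-finite or absurd mean."""


@dataclass(frozen=True)
class CovariateSpec:
    """One synthetic covariate: level + sinusoid + intervention step + noise."""

    name: str
    mean: float
    seasonal_amplitude: float = 0.0
    phase: float = 0.0
    intervention_step: float = 0.0
    noise_sd: float = 1.0
    unit: str = ""


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic surveillance study.

    ``n_diseases_per_route`` orders routes as ``ROUTES``; ``baseline_mean``
    is one positive mean per disease (route-major order);
    ``intervention_start`` is the 1-based month ordinal at which the
    pandemic begins; ``intervention_multiplier`` maps routes to factors in
    (0, 1]; ``planted_effects`` is a list of (covariate, disease,
    coefficient) triples.
    """

    n_diseases_per_route: tuple[int, int, int, int]
    n_months: int
    baseline_mean: tuple[float, ...]
    seasonal_amplitude: float
    seasonal_phase: tuple[float, ...]
    overdispersion: float
    intervention_start: int
    intervention_multiplier: dict[str, float]
    covariates: tuple[CovariateSpec, ...] = ()
    planted_effects: tuple[tuple[str, str, float], ...] = ()
    start_year: int = 2017
    seed: int = 0

    def __post_init__(self) -> None:
        n = sum(self.n_diseases_per_route)
        if len(self.baseline_mean) != n or len(self.seasonal_phase) != n:
            raise ConfigurationError("baseline_mean and seasonal_phase must have one entry per disease")
        if any(b <= 0 for b in self.baseline_mean):
            raise ConfigurationError("baseline means must be positive")
        if not 0 <= self.seasonal_amplitude < 1:
            raise ConfigurationError("seasonal amplitude must lie in [0, 1)")
        if self.overdispersion <= 0:
            raise ConfigurationError("overdispersion must be positive")
        if not 1 <= self.intervention_start <= self.n_months:
            raise ConfigurationError("intervention start must fall inside the simulated window")
        for route, mult in self.intervention_multiplier.items():
            if route not in ROUTES:
                raise ConfigurationError(f"unknown route {route!r}")
            if not 0 < mult <= 1:
                raise ConfigurationError("intervention multipliers must lie in (0, 1]")

    @property
    def disease_names(self) -> tuple[str, ...]:
        prefixes = {"direct-contact": "DC", "water-food": "WF",
                    "airborne": "AB", "vector-borne": "VB"}
        names = []
        for route, k in zip(ROUTES, self.n_diseases_per_route):
            names += [f"{prefixes[route]}-{i + 1:02d}" for i in range(k)]
        return tuple(names)

    def catalog(self) -> DiseaseCatalog:
        entries = []
        i = 0
        for route, k in zip(ROUTES, self.n_diseases_per_route):
            for name in self.disease_names[i:i + k]:
                entries.append((name, route))
            i += k
        return DiseaseCatalog(entries)

    def to_dict(self) -> dict:
        return asdict(self)


def _covariate_panel(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = np.arange(config.n_months)
    after = (m >= config.intervention_start - 1).astype(float)
    cols = {}
    for spec in config.covariates:
        seasonal = spec.seasonal_amplitude * np.sin(2 * np.pi * m / 12 + spec.phase)
        noise = rng.normal(0.0, spec.noise_sd, size=config.n_months)
        cols[spec.name] = spec.mean + seasonal + spec.intervention_step * after + noise
    return pd.DataFrame(cols, index=_month_index(config))


def _month_index(config: SimulationConfig) -> pd.PeriodIndex:
    return pd.period_range(start=f"{config.start_year}-01", periods=config.n_months, freq="M")


def simulate_surveillance(config: SimulationConfig) -> tuple[MonthlyCaseTable, CovariateTable]:
    """Draw one synthetic (case table, covariate table) pair from a config."""
    rng = np.random.default_rng(config.seed)
    cov_df = _covariate_panel(config, rng)
    # standardize covariates before planting effects: coefficients are per-SD
    z = {}
    for name in cov_df.columns:
        col = cov_df[name].to_numpy()
        sd = col.std(ddof=1)
        z[name] = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)

    names = config.disease_names
    catalog = config.catalog()
    m = np.arange(config.n_months)
    after = m >= config.intervention_start - 1
    mu = np.empty((config.n_months, len(names)))
    for d, name in enumerate(names):
        route = catalog.route_of(name)
        season = 1.0 + config.seasonal_amplitude * np.sin(2 * np.pi * m / 12 + config.seasonal_phase[d])
        mult = np.where(after, config.intervention_multiplier.get(route, 1.0), 1.0)
        log_effect = np.zeros(config.n_months)
        for cov_name, disease, coef in config.planted_effects:
            if disease == name:
                if cov_name not in z:
                    raise ConfigurationError(f"planted effect references unknown covariate {cov_name!r}")
                log_effect += coef * z[cov_name]
        with np.errstate(over="ignore"):
            mu[:, d] = config.baseline_mean[d] * season * mult * np.exp(log_effect)
    if not np.all(np.isfinite(mu)) or np.any(mu > 1e12):
        raise ConfigurationError("simulated mean overflowed; check baselines and planted coefficients")
    k = config.overdispersion
    if k > _POISSON_LIMIT:
        counts = rng.poisson(mu)
    else:
        counts = rng.negative_binomial(k, k / (k + mu))
    case_df = pd.DataFrame(counts, index=_month_index(config), columns=list(names))
    units = {s.name: s.unit for s in config.covariates}
    return MonthlyCaseTable(case_df, catalog), CovariateTable(cov_df, units)


def default_shanghai_like_config(seed: int = 0) -> SimulationConfig:
    """A 48-month, 32-disease study shaped like the Shanghai 2017–2020 register.

    Route sizes 9/10/9/4 match the four-route grouping of the published
    annual summary; the intervention starts at month 37 (January of year 4,
    emulating the pandemic onset) with per-route case multipliers near the
    published per-route declines (~0.35, 0.47, 0.90, 0.36).  Baselines are
    log-spaced within each route so a few diseases dominate counts while the
    rarest drop in and out of the monthly register, which is what drives
    variation in the "types present" indicator.
    """
    sizes = (9, 10, 9, 4)
    baselines: list[float] = []
    for hi, lo, k in ((3000.0, 0.2, 9), (600.0, 0.5, 10), (1200.0, 0.3, 9), (4.0, 0.05, 4)):
        baselines += [float(v) for v in np.geomspace(hi, lo, k)]
    n = sum(sizes)
    # deterministic spread of seasonal peaks across the calendar
    phases = tuple(float(2 * np.pi * ((7 * d) % n) / n) for d in range(n))
    covariates = (
        CovariateSpec("temperature", 17.0, 10.0, -np.pi / 2, 0.0, 1.5, "degC"),
        CovariateSpec("atmospheric pressure", 101.3, 1.0, np.pi / 2, 0.0, 0.12, "kPa"),
        CovariateSpec("relative humidity", 75.0, 5.0, -np.pi / 2, 0.0, 3.0, "%"),
        CovariateSpec("wind speed", 3.0, 0.2, 0.0, 0.0, 0.4, "m/s"),
        CovariateSpec("precipitation", 110.0, 60.0, -np.pi / 2, 0.0, 30.0, "mm"),
        CovariateSpec("PM2.5", 40.0, 12.0, np.pi / 2, -4.6, 6.0, "ug/m3"),
        CovariateSpec("PM10", 55.0, 15.0, np.pi / 2, -9.9, 8.0, "ug/m3"),
        CovariateSpec("SO2", 10.0, 3.0, np.pi / 2, -3.0, 1.5, "ug/m3"),
        CovariateSpec("NO2", 42.0, 10.0, np.pi / 2, -4.5, 5.0, "ug/m3"),
        CovariateSpec("AQI", 70.0, 15.0, np.pi / 2, -7.0, 8.0, ""),
        CovariateSpec("inbound travel", 0.72, 0.06, 0.0, -0.61, 0.05, "million travelers"),
        CovariateSpec("airport passenger throughput", 6.2, 0.5, 0.0, -2.9, 0.4, "million passengers"),
        CovariateSpec("freight volume", 100.0, 5.0, 0.0, 33.0, 8.0, "million ton"),
        CovariateSpec("social consumption", 110.0, 8.0, 0.0, 11.0, 6.0, "billion yuan"),
    )
    planted = (
        ("temperature", "DC-01", 0.30),
        ("inbound travel", "WF-01", 0.25),
        ("PM2.5", "AB-01", 0.25),
    )
    return SimulationConfig(
        n_diseases_per_route=sizes,
        n_months=48,
        baseline_mean=tuple(baselines),
        seasonal_amplitude=0.4,
        seasonal_phase=phases,
        overdispersion=5.0,
        intervention_start=37,
        intervention_multiplier={
            "direct-contact": 0.35,
            "water-food": 0.47,
            "airborne": 0.90,
            "vector-borne": 0.36,
        },
        covariates=covariates,
        planted_effects=planted,
        seed=seed,
    )
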