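"""Synthetic site × year climate and occupancy world.

Emulates the data a factorial SDM-uncertainty analysis needs: monthly
temperature/precipitation series over a network of sites with spatial
gradients, seasonal cycles and lag-1 interannual persistence; an ensemble
of pseudo-GCMs built as delta perturbations (additive temperature,
multiplicative precipitation) of the observed series plus a
member-specific constant bias, so that hindcast ≠ observed; a
drought/wet-normal partition of years by annual P − PET quantile; and
water-limited Bernoulli occupancy for several species with known true
coefficients retained for recovery tests.

All generators are pure functions of (config, seed): each sub-generator
draws from its own named child stream, so adding species never shifts the
climate draws.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .hydrology import thornthwaite_pet

logger = logging.getLogger(__name__)

OBSERVED = "observed"
HINDCAST = "hindcast"
FORECAST = "forecast"
OBS_MEMBER = "obs"

WET_NORMAL = "wet_normal"
DROUGHT = "drought"

PANEL_COLUMNS = ["site", "year", "month", "temperature", "precipitation", "scenario", "member"]


class ConfigurationError(ValueError):
    """Raised for invalid world configurations."""


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic world.

    ``gcm_deltas`` is a per-member (ΔT °C, ΔP fraction) list spanning
    warm-dry to cool-wet; when omitted it is filled by linear
    interpolation from (+4.8, −0.12) to (+1.2, +0.28) across ``n_gcms``.
    ``interannual_sd`` scales every stochastic climate anomaly (year-level
    AR(1) terms and monthly residuals); zero makes every year identical.
    """

    n_sites: int = 50
    n_years: int = 39
    n_species: int = 6
    n_gcms: int = 10
    gcm_deltas: tuple[tuple[float, float], ...] | None = None
    drought_quantile: float = 0.18
    seed: int = 0
    interannual_sd: float = 1.0
    bucket_capacity_mm: float = 150.0
    breeding_months: tuple[int, ...] = (4, 5, 6, 7)
    start_year: int = 1970
    species_response: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_years", "n_species"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_gcms < 2:
            raise ConfigurationError(f"n_gcms must be >= 2, got {self.n_gcms}")
        if not 0.0 < self.drought_quantile < 1.0:
            raise ConfigurationError(
                f"drought_quantile must lie in (0, 1), got {self.drought_quantile}"
            )
        if self.interannual_sd < 0:
            raise ConfigurationError("interannual_sd must be nonnegative")
        if self.gcm_deltas is not None and len(self.gcm_deltas) != self.n_gcms:
            raise ConfigurationError(
                f"gcm_deltas has {len(self.gcm_deltas)} entries for n_gcms={self.n_gcms}"
            )

    def resolved_gcm_deltas(self) -> list[tuple[float, float]]:
        """Per-member (ΔT, ΔP), warm-dry first, cool-wet last."""
        if self.gcm_deltas is not None:
            deltas = [(float(dt), float(dp)) for dt, dp in self.gcm_deltas]
        else:
            dts = np.linspace(4.8, 1.2, self.n_gcms)
            dps = np.linspace(-0.12, 0.28, self.n_gcms)
            deltas = [(float(dt), float(dp)) for dt, dp in zip(dts, dps)]
        for dt, dp in deltas:
            if dp <= -1.0:
                raise ConfigurationError(f"ΔP must exceed -1 (got {dp}): precipitation scale")
        return deltas

    def gcm_names(self) -> list[str]:
        return [f"gcm{i:02d}" for i in range(self.n_gcms)]

    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0.0, innov_sd)
    return x


def _arrays_to_long(
    temp: np.ndarray, precip: np.ndarray, config: WorldConfig, scenario: str, member: str
) -> pd.DataFrame:
    ns, ny, nm = temp.shape
    sites = np.repeat(np.arange(ns), ny * nm)
    years = np.tile(np.repeat(config.years(), nm), ns)
    months = np.tile(np.arange(1, 13), ns * ny)
    return pd.DataFrame(
        {
            "site": sites,
            "year": years,
            "month": months,
            "temperature": temp.ravel(),
            "precipitation": precip.ravel(),
            "scenario": scenario,
            "member": member,
        }
    )


def panel_to_arrays(
    panel: pd.DataFrame, scenario: str = OBSERVED, member: str = OBS_MEMBER
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pivot a long climate panel to (sites, years, T[ns,ny,12], P[ns,ny,12]).

    Raises if any site-year is missing months, naming the gap.
    """
    sub = panel[(panel["scenario"] == scenario) & (panel["member"] == member)]
    if sub.empty:
        raise ValueError(f"no rows for scenario={scenario!r}, member={member!r}")
    sites = np.sort(sub["site"].unique())
    years = np.sort(sub["year"].unique())
    expected = len(sites) * len(years) * 12
    if len(sub) != expected:
        counts = sub.groupby(["site", "year"])["month"].count()
        bad = counts[counts != 12]
        raise ValueError(f"missing months for site-years: {bad.index.tolist()[:5]}")
    sub = sub.sort_values(["site", "year", "month"])
    shape = (len(sites), len(years), 12)
    return sites, years, sub["temperature"].to_numpy().reshape(shape), sub[
        "precipitation"
    ].to_numpy().reshape(shape)


def generate_climate(config: WorldConfig) -> pd.DataFrame:
    """Observed-period monthly climate for every site.

    Temperature: a south–north-like site gradient plus a seasonal cycle,
    a shared AR(1) year anomaly, and monthly residuals.  Precipitation:
    site-level annual totals with a summer-peaked monthly distribution,
    perturbed by a shared multiplicative (log-scale) AR(1) year anomaly
    and monthly log-normal residuals, hence strictly nonnegative.
    """
    rng = child_rng(config.seed, "climate")
    ns, ny = config.n_sites, config.n_years
    s = config.interannual_sd

    x = np.linspace(0.0, 1.0, ns) if ns > 1 else np.array([0.5])
    # temperature gradient kept gentle so PET does not cancel the much
    # stronger precipitation gradient in the P - PET water balance
    t_site = 6.0 + 3.0 * x + rng.normal(0.0, 0.4, ns)
    months = np.arange(12)
    t_seas = -13.0 * np.cos(2.0 * np.pi * (months + 0.5) / 12.0)
    t_year = _ar1(rng, ny, phi=0.5, sd=0.9) * s
    t_noise = rng.normal(0.0, 1.1, (ns, ny, 12)) * s
    temp = t_site[:, None, None] + t_seas[None, None, :] + t_year[None, :, None] + t_noise

    p_site_ann = 180.0 + 700.0 * x + rng.normal(0.0, 15.0, ns)
    w = 0.4 + 1.3 * np.exp(-((months - 5.0) ** 2) / (2.0 * 2.5**2))
    w = w / w.sum()
    p_year = _ar1(rng, ny, phi=0.6, sd=0.18) * s
    p_noise = rng.normal(0.0, 0.15, (ns, ny, 12)) * s
    precip = (
        p_site_ann[:, None, None]
        * w[None, None, :]
        * np.exp(p_year[None, :, None])
        * np.exp(p_noise)
    )
    return _arrays_to_long(temp, precip, config, OBSERVED, OBS_MEMBER)


def perturb_gcm(panel: pd.DataFrame, config: WorldConfig) -> pd.DataFrame:
    """Append hindcast and forecast panels for every pseudo-GCM member.

    Each member carries a constant bias (additive for temperature,
    multiplicative for precipitation) applied to the observed series to
    form its hindcast; its forecast adds the configured ΔT and scales
    precipitation by (1 + ΔP).  Forecast − hindcast therefore equals the
    configured deltas in expectation.  The observed panel is untouched.
    """
    deltas = config.resolved_gcm_deltas()
    _, _, temp, precip = panel_to_arrays(panel, OBSERVED, OBS_MEMBER)
    frames = [panel.copy()]
    for i, (name, (dt, dp)) in enumerate(zip(config.gcm_names(), deltas)):
        rng = child_rng(config.seed, "gcm_bias", i)
        bias_t = rng.normal(0.0, 0.7)
        bias_p = rng.normal(0.0, 0.07)
        if bias_p <= -1.0:  # pragma: no cover - 14σ event
            bias_p = -0.5
        hind_t = temp + bias_t
        hind_p = precip * (1.0 + bias_p)
        frames.append(_arrays_to_long(hind_t, hind_p, config, HINDCAST, name))
        frames.append(_arrays_to_long(hind_t + dt, hind_p * (1.0 + dp), config, FORECAST, name))
    return pd.concat(frames, ignore_index=True)


def annual_water_deficit(panel: pd.DataFrame, scenario: str = OBSERVED,
                         member: str = OBS_MEMBER) -> pd.DataFrame:
    """Annual P − PET (mm) per site-year, the drought-flagging quantity."""
    sites, years, temp, precip = panel_to_arrays(panel, scenario, member)
    pet = thornthwaite_pet(temp.reshape(len(sites), -1)).reshape(temp.shape)
    bal = precip.sum(axis=2) - pet.sum(axis=2)
    idx = pd.MultiIndex.from_product([sites, years], names=["site", "year"])
    return pd.DataFrame({"water_balance": bal.ravel()}, index=idx).reset_index()


def flag_drought_years(panel: pd.DataFrame, config: WorldConfig) -> dict[int, str]:
    """Partition years into drought vs wet/normal by annual P − PET quantile.

    The ``round(drought_quantile × n_years)`` driest years (regional mean
    annual water balance) are flagged drought; ties break by ascending
    year with a logged warning when the climate is degenerate.
    """
    bal = annual_water_deficit(panel, OBSERVED, OBS_MEMBER)
    regional = bal.groupby("year")["water_balance"].mean().sort_index()
    n_years = len(regional)
    k = int(round(config.drought_quantile * n_years))
    if k == 0:
        return {int(y): WET_NORMAL for y in regional.index}
    if regional.nunique() == 1:
        logger.warning("all years have identical water balance; drought ties broken by year order")
    order = np.lexsort((regional.index.to_numpy(), regional.to_numpy()))
    drought_years = set(regional.index.to_numpy()[order[:k]])
    return {int(y): (DROUGHT if y in drought_years else WET_NORMAL) for y in regional.index}


@dataclass
class OccurrenceResult:
    """Occupancy panel plus the generating truth, for recovery tests."""

    panel: pd.DataFrame                # site, year, species, presence, year_class
    truth: pd.DataFrame                # per-species alpha, beta_water, gamma_temp, prevalence
    latent: pd.DataFrame               # site, year, water_std, temp_std (true covariates)
    year_class: dict[int, str]


def _default_species_response(config: WorldConfig) -> pd.DataFrame:
    rng = child_rng(config.seed, "species")
    n = config.n_species
    # deliberately heterogeneous: rare-to-common species with weak-to-strong
    # water limitation, as in a real multi-species wetland assemblage
    return pd.DataFrame(
        {
            "species": [f"sp{i:02d}" for i in range(n)],
            "beta_water": rng.uniform(0.8, 2.2, n),
            "gamma_temp": rng.uniform(-0.6, 0.2, n),
            "target_prevalence": rng.uniform(0.25, 0.65, n),
        }
    )


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Scalar alpha with mean(expit(alpha + eta)) == target, by bisection."""
    lo, hi = -12.0, 12.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + eta)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_occurrences(panel: pd.DataFrame, config: WorldConfig) -> OccurrenceResult:
    """Water-limited Bernoulli occupancy per species, site and year.

    presence ~ Bernoulli(expit(α_s + β_s·water + γ_s·temperature)) with the
    latent covariates standardized annual P − PET and breeding-season mean
    temperature.  Intercepts are solved so each species hits its target
    prevalence; a species whose realized prevalence escapes (0.02, 0.98)
    is re-intercepted with a warning.
    """
    bal = annual_water_deficit(panel, OBSERVED, OBS_MEMBER)
    sites, years, temp, _ = panel_to_arrays(panel, OBSERVED, OBS_MEMBER)
    breeding = [m - 1 for m in config.breeding_months]
    t_breed = temp[:, :, breeding].mean(axis=2)

    w = bal["water_balance"].to_numpy()
    w_std = (w - w.mean()) / (w.std() if w.std() > 0 else 1.0)
    t = t_breed.ravel()
    t_std = (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)
    latent = bal[["site", "year"]].copy()
    latent["water_std"] = w_std
    latent["temp_std"] = t_std

    resp = config.species_response if config.species_response is not None else \
        _default_species_response(config)
    resp = resp.copy()
    if "target_prevalence" not in resp.columns:
        resp["target_prevalence"] = 0.45

    year_class = flag_drought_years(panel, config)
    rng = child_rng(config.seed, "occurrence")
    frames, truth_rows = [], []
    for _, row in resp.iterrows():
        eta = row["beta_water"] * w_std + row["gamma_temp"] * t_std
        target = float(row["target_prevalence"])
        alpha = _solve_intercept(eta, target)
        for attempt in range(10):
            p = 1.0 / (1.0 + np.exp(-(alpha + eta)))
            y = (rng.random(len(p)) < p).astype(int)
            prev = y.mean()
            if 0.02 < prev < 0.98:
                break
            warnings.warn(
                f"species {row['species']} realized prevalence {prev:.3f} outside (0.02, 0.98); "
                "resampling intercept"
            )
            alpha = _solve_intercept(eta, 0.5)
        frames.append(
            pd.DataFrame(
                {
                    "site": latent["site"],
                    "year": latent["year"],
                    "species": row["species"],
                    "presence": y,
                }
            )
        )
        truth_rows.append(
            {
                "species": row["species"],
                "alpha": alpha,
                "beta_water": row["beta_water"],
                "gamma_temp": row["gamma_temp"],
                "prevalence": prev,
            }
        )
    occ = pd.concat(frames, ignore_index=True)
    occ["year_class"] = occ["year"].map(year_class)
    return OccurrenceResult(
        panel=occ,
        truth=pd.DataFrame(truth_rows),
        latent=latent,
        year_class=year_class,
    )


def generate_world(config: WorldConfig) -> tuple[pd.DataFrame, OccurrenceResult]:
    """Convenience: full climate panel (obs + all members) and occupancy."""
    obs = generate_climate(config)
    full = perturb_gcm(obs, config)
    occ = generate_occurrences(obs, config)
    return full, occ
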