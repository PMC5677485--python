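"""Climate covariate hypothesis classes and collinearity filtering.

Three working hypotheses for how climate limits occurrence are encoded as
covariate derivations from monthly temperature/precipitation panels:

* **temporal** — plain summaries at several temporal scales (monthly,
  breeding-season, annual means/totals) plus site-level interannual
  standard deviations;
* **bioclimatic** — extremes and seasonality in the bioclim tradition
  (warmest/coldest month, wettest/driest quarter with December–February
  wrap-around, seasonality indices);
* **hydrological** — water availability from a Thornthwaite-PET +
  fixed-capacity soil bucket (soil moisture, AET, deficit, surplus, a
  standardized annual P − PET drought index).

Each candidate set is then filtered by iterative variance-inflation-factor
elimination at a cutoff of 10 (conventional) or 2 (stringent), or left
unfiltered ("all"), yielding the 3 × 3 covariate-set grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hydrology import bucket_water_balance, thornthwaite_pet
from .synthetic_world import OBSERVED, OBS_MEMBER, WorldConfig, panel_to_arrays

logger = logging.getLogger(__name__)

HYPOTHESES = ("temporal", "bioclimatic", "hydrological")
COLLINEARITY_LEVELS = ("all", "vif10", "vif2")
_CUTOFFS = {"all": None, "vif10": 10.0, "vif2": 2.0}

VIF_INF = np.inf


@dataclass
class CovariateSet:
    """A named covariate matrix tagged by hypothesis and collinearity level.

    ``matrix`` is indexed by (site, year); ``vif_report`` holds each
    surviving covariate's VIF at the end of filtering, ``removal_log`` the
    eliminated names in order.
    """

    hypothesis: str
    collinearity_level: str
    matrix: pd.DataFrame
    vif_report: dict[str, float] = field(default_factory=dict)
    removal_log: list[str] = field(default_factory=list)
    #: per-covariate (mean, sd) frozen at derivation time, so that scenario
    #: re-derivations standardize against the observed period, not themselves
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)


def _site_year_frame(sites, years, data: dict[str, np.ndarray]) -> pd.DataFrame:
    idx = pd.MultiIndex.from_product([sites, years], names=["site", "year"])
    return pd.DataFrame({k: v.ravel() for k, v in data.items()}, index=idx)


def derive_temporal(
    panel: pd.DataFrame,
    scenario: str = OBSERVED,
    member: str = OBS_MEMBER,
    breeding_months: tuple[int, ...] = (4, 5, 6, 7),
) -> CovariateSet:
    """Plain multi-scale summaries of monthly temperature and precipitation."""
    sites, years, temp, precip = panel_to_arrays(panel, scenario, member)
    bm = [m - 1 for m in breeding_months]
    cov = {
        "t_ann_mean": temp.mean(axis=2),
        "t_breed_mean": temp[:, :, bm].mean(axis=2),
        "t_may": temp[:, :, 4],
        "t_jun": temp[:, :, 5],
        "t_jul": temp[:, :, 6],
        "p_ann_total": precip.sum(axis=2),
        "p_breed_total": precip[:, :, bm].sum(axis=2),
        "p_apr": precip[:, :, 3],
        "p_may": precip[:, :, 4],
        "p_jun": precip[:, :, 5],
        "p_spring_total": precip[:, :, 2:5].sum(axis=2),
    }
    # Site-level interannual variability, broadcast across years.
    ny = temp.shape[1]
    for name, annual in (
        ("t_ann_interann_sd", cov["t_ann_mean"]),
        ("p_ann_interann_sd", cov["p_ann_total"]),
        ("p_breed_interann_sd", cov["p_breed_total"]),
    ):
        sd = annual.std(axis=1, ddof=0) if ny > 1 else np.zeros(annual.shape[0])
        cov[name] = np.repeat(sd[:, None], ny, axis=1)
    return CovariateSet("temporal", "all", _site_year_frame(sites, years, cov))


def _quarter_sums(x: np.ndarray) -> np.ndarray:
    """All 12 wrap-around 3-consecutive-month sums; shape (..., 12)."""
    xx = np.concatenate([x, x[..., :2]], axis=-1)
    return np.stack([xx[..., i : i + 3].sum(axis=-1) for i in range(12)], axis=-1)


def derive_bioclim(
    panel: pd.DataFrame, scenario: str = OBSERVED, member: str = OBS_MEMBER
) -> CovariateSet:
    """Bioclim-style extremes and seasonality covariates.

    Quarters are 3 consecutive calendar months with December–February
    wrap-around; precipitation seasonality is the coefficient of variation
    of monthly totals.
    """
    sites, years, temp, precip = panel_to_arrays(panel, scenario, member)
    q_p = _quarter_sums(precip)
    q_t = np.concatenate([temp, temp[..., :2]], axis=-1)
    q_t_mean = np.stack([q_t[..., i : i + 3].mean(axis=-1) for i in range(12)], axis=-1)
    warmest_q = q_t_mean.argmax(axis=-1)
    p_mean = precip.mean(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_cv = np.where(p_mean > 0, precip.std(axis=2, ddof=0) / p_mean, 0.0)
    take = np.take_along_axis
    cov = {
        "t_ann_mean": temp.mean(axis=2),
        "t_max_warmest_month": temp.max(axis=2),
        "t_min_coldest_month": temp.min(axis=2),
        "t_seasonality_sd": temp.std(axis=2, ddof=0),
        "t_warmest_quarter_mean": q_t_mean.max(axis=-1),
        "p_ann_total": precip.sum(axis=2),
        "p_wettest_quarter": q_p.max(axis=-1),
        "p_driest_quarter": q_p.min(axis=-1),
        "p_seasonality_cv": p_cv,
        "p_warmest_quarter": take(q_p, warmest_q[..., None], axis=-1)[..., 0],
    }
    return CovariateSet("bioclimatic", "all", _site_year_frame(sites, years, cov))


def derive_hydrological(
    panel: pd.DataFrame,
    scenario: str = OBSERVED,
    member: str = OBS_MEMBER,
    capacity: float = 150.0,
    growing_months: tuple[int, ...] = (4, 5, 6, 7, 8, 9),
    reference_stats: dict[str, tuple[float, float]] | None = None,
) -> CovariateSet:
    """Water-balance covariates from the Thornthwaite PET + bucket model.

    The bucket is iterated through the scenario's months in chronological
    order per site (carrying storage across years); annual and
    growing-season aggregates become the covariates.  The drought index is
    annual P − PET standardized with ``reference_stats`` when given
    (projection onto another scenario), else with this panel's own
    mean/sd, which are recorded on the returned set.
    """
    if capacity < 0:
        raise ValueError(f"bucket capacity must be nonnegative, got {capacity}")
    sites, years, temp, precip = panel_to_arrays(panel, scenario, member)
    ns, ny, _ = temp.shape
    t_flat = temp.reshape(ns, -1)
    p_flat = precip.reshape(ns, -1)
    pet_flat = thornthwaite_pet(t_flat)
    bal = bucket_water_balance(p_flat, pet_flat, capacity=capacity)
    shape = (ns, ny, 12)
    storage = bal["storage"].reshape(shape)
    aet = bal["aet"].reshape(shape)
    deficit = bal["deficit"].reshape(shape)
    surplus = bal["surplus"].reshape(shape)
    pet = pet_flat.reshape(shape)
    gm = [m - 1 for m in growing_months]

    pmpet = precip.sum(axis=2) - pet.sum(axis=2)
    if reference_stats and "drought_index" in reference_stats:
        mean, sd = reference_stats["drought_index"]
    else:
        mean, sd = float(pmpet.mean()), float(pmpet.std(ddof=0))
    drought_index = (pmpet - mean) / (sd if sd > 0 else 1.0)
    cov = {
        "sm_growing_mean": storage[:, :, gm].mean(axis=2),
        "sm_annual_min": storage.min(axis=2),
        "aet_annual": aet.sum(axis=2),
        "deficit_annual": deficit.sum(axis=2),
        "surplus_annual": surplus.sum(axis=2),
        "drought_index": drought_index,
    }
    return CovariateSet(
        "hydrological",
        "all",
        _site_year_frame(sites, years, cov),
        standardization={"drought_index": (mean, sd)},
    )


_DERIVERS = {
    "temporal": derive_temporal,
    "bioclimatic": derive_bioclim,
    "hydrological": derive_hydrological,
}


def derive(hypothesis: str, panel: pd.DataFrame, scenario: str = OBSERVED,
           member: str = OBS_MEMBER, **kwargs) -> CovariateSet:
    """Dispatch to the named hypothesis's derivation."""
    try:
        fn = _DERIVERS[hypothesis]
    except KeyError:
        raise ValueError(f"unknown hypothesis {hypothesis!r}; known: {HYPOTHESES}")
    return fn(panel, scenario=scenario, member=member, **kwargs)


def vif(matrix: pd.DataFrame, name: str) -> float:
    """Variance inflation factor of ``name`` regressed on the other columns.

    VIF = 1 / (1 − R²) from OLS (with intercept) of the named covariate on
    all others; perfect collinearity returns +inf.
    """
    if name not in matrix.columns:
        raise KeyError(f"covariate {name!r} not in matrix")
    others = matrix.drop(columns=[name])
    if others.shape[1] < 1:
        raise ValueError("VIF needs at least 2 covariates")
    if matrix.shape[0] <= matrix.shape[1]:
        raise ValueError("VIF needs more rows than columns")
    y = matrix[name].to_numpy(dtype=float)
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0.0:
        return VIF_INF  # constant column: flagged for removal
    X = np.column_stack([np.ones(len(y)), others.to_numpy(dtype=float)])
    _, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size == 0 or rank < X.shape[1]:
        fitted = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        rss = np.sum((y - fitted) ** 2)
    else:
        rss = float(res[0])
    r2 = 1.0 - rss / tss
    if r2 >= 1.0 - 1e-12:
        return VIF_INF
    return float(1.0 / (1.0 - r2))


def vif_report(matrix: pd.DataFrame) -> dict[str, float]:
    """VIF for every column."""
    return {name: vif(matrix, name) for name in matrix.columns}


def vif_filter(covset: CovariateSet, level: str) -> CovariateSet:
    """Iteratively remove the highest-VIF covariate until all pass the cutoff.

    ``level`` is one of ``all`` (identity), ``vif10`` or ``vif2``.  On
    equal VIFs the alphabetically last name is removed (deterministic
    runs).  Stops with a warning if fewer than 2 covariates would remain.
    """
    if level not in _CUTOFFS:
        raise ValueError(f"unknown collinearity level {level!r}; known: {COLLINEARITY_LEVELS}")
    cutoff = _CUTOFFS[level]
    matrix = covset.matrix.copy()
    if len(set(matrix.columns)) != len(matrix.columns):
        raise ValueError("covariate names must be unique")
    removal_log: list[str] = []
    if cutoff is None:
        report = {}
        if matrix.shape[1] >= 2:
            report = vif_report(matrix)
        return CovariateSet(
            covset.hypothesis, level, matrix, report, removal_log,
            standardization=dict(covset.standardization),
        )
    while True:
        if matrix.shape[1] < 2:
            warnings.warn(
                f"vif_filter({covset.hypothesis}, {level}): fewer than 2 covariates remain; stopping"
            )
            report = {}
            break
        report = vif_report(matrix)
        worst = max(report.values())
        if worst <= cutoff:
            break
        if matrix.shape[1] == 2:
            warnings.warn(
                f"vif_filter({covset.hypothesis}, {level}): cutoff unreachable with 2 covariates"
            )
            break
        candidates = sorted(n for n, v in report.items() if v == worst)
        drop = candidates[-1]  # alphabetically last among ties
        removal_log.append(drop)
        matrix = matrix.drop(columns=[drop])
    return CovariateSet(
        covset.hypothesis, level, matrix, report, removal_log,
        standardization=dict(covset.standardization),
    )


def build_covariate_grid(
    panel: pd.DataFrame,
    config: WorldConfig,
    hypotheses: tuple[str, ...] = HYPOTHESES,
    levels: tuple[str, ...] = COLLINEARITY_LEVELS,
) -> dict[tuple[str, str], CovariateSet]:
    """The hypothesis × collinearity grid of covariate sets (observed period)."""
    grid: dict[tuple[str, str], CovariateSet] = {}
    for hyp in hypotheses:
        kwargs = {"capacity": config.bucket_capacity_mm} if hyp == "hydrological" else {}
        if hyp == "temporal":
            kwargs = {"breeding_months": config.breeding_months}
        base = derive(hyp, panel, **kwargs)
        for level in levels:
            grid[(hyp, level)] = vif_filter(base, level)
    return grid


def scenario_matrix(
    panel: pd.DataFrame,
    covset: CovariateSet,
    scenario: str,
    member: str,
    config: WorldConfig,
    site_level: bool = True,
) -> pd.DataFrame:
    """Derive ``covset``'s surviving covariates on another scenario's climate.

    Used to project a fitted SDM onto hindcast/forecast members.  With
    ``site_level=True`` the site-year covariates are averaged across the
    scenario's years, yielding one climatological row per site.
    """
    kwargs = {}
    if covset.hypothesis == "hydrological":
        kwargs = {
            "capacity": config.bucket_capacity_mm,
            "reference_stats": covset.standardization,
        }
    elif covset.hypothesis == "temporal":
        kwargs = {"breeding_months": config.breeding_months}
    full = derive(covset.hypothesis, panel, scenario=scenario, member=member, **kwargs)
    missing = [c for c in covset.names if c not in full.matrix.columns]
    if missing:
        raise KeyError(f"scenario derivation lacks covariates: {missing}")
    mat = full.matrix[covset.names]
    if site_level:
        mat = mat.groupby(level="site").mean()
    return mat
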