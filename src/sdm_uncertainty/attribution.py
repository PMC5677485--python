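"""Attributing range-change uncertainty to its sources.

Two complementary analyses over the factorial RCI table (one row per
GCM × hypothesis × collinearity × threshold combination, per species):

* **deviance withholding** — a normal-error GLM of log-transformed RCI on
  all four factors is fit per species; each source's share is the
  deviance increase when that source is withheld from the model, divided
  by the null (intercept-only) deviance;
* **decision effects** — a linear mixed model of log-transformed RCI
  across species (species random intercept) with the reference level of
  each factor set to the level projecting the least loss, so every other
  level's coefficient measures how much *more* loss that choice projects;
  coefficients fall into qualitative magnitude bins.

RCI lives in [−1, ∞), so the log transform is ln(RCI + 1 + δ) with a
small δ keeping total loss finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .range_change import FACTOR_COLUMNS

SOURCES = tuple(FACTOR_COLUMNS)  # gcm, hypothesis, collinearity, threshold
MODEL_FACTORS = ("hypothesis", "collinearity", "threshold", "gcm")

MAGNITUDE_BINS = ("none", "low", "moderate", "high", "very_high", "out_of_scale")


def transform_rci(rci, delta: float = 0.01):
    """ln(RCI + 1 + δ); monotone on [−1, ∞), finite at total loss."""
    x = np.asarray(rci, dtype=float)
    if np.any(x < -1.0):
        raise ValueError("RCI below -1 is impossible (range cannot shrink past empty)")
    out = np.log(x + 1.0 + delta)
    return float(out) if np.isscalar(rci) else out


def _dummies(table: pd.DataFrame, factors, drop_first: bool = True) -> np.ndarray:
    d = pd.get_dummies(
        table[list(factors)].astype(str), drop_first=drop_first, dtype=float
    )
    return d.to_numpy()


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    X1 = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    return float(resid @ resid)


def _check_full_factorial(table: pd.DataFrame) -> None:
    levels = [table[f].nunique() for f in SOURCES]
    expected = int(np.prod(levels))
    cells = table.drop_duplicates(list(SOURCES)).shape[0]
    if cells != expected:
        raise ValueError(
            f"factorial table incomplete: {cells} distinct cells, expected {expected}"
        )


def deviance_partition(table: pd.DataFrame, delta: float = 0.01) -> pd.DataFrame:
    """Per-source proportional deviance for one species' factorial table.

    proportion(s) = (deviance without s − deviance of the full model)
    divided by the null-model deviance.  Normal-error GLM, main effects
    only, so on balanced designs this equals the source's share of the
    total sum of squares.
    """
    _check_full_factorial(table)
    y = transform_rci(table["rci"].to_numpy(), delta=delta)
    null_dev = float(np.sum((y - y.mean()) ** 2))
    if null_dev <= 1e-12:
        warnings.warn("constant RCI table: null deviance is zero; all proportions set to 0")
        return pd.DataFrame({"source": SOURCES, "proportion_deviance": 0.0})
    full_dev = _rss(_dummies(table, SOURCES), y)
    rows = []
    for s in SOURCES:
        others = [f for f in SOURCES if f != s]
        without = _rss(_dummies(table, others), y)
        rows.append(
            {"source": s, "proportion_deviance": max(0.0, (without - full_dev) / null_dev)}
        )
    return pd.DataFrame(rows)


def deviance_partition_by_species(
    records: pd.DataFrame, delta: float = 0.01, on_incomplete: str = "raise"
) -> pd.DataFrame:
    """Deviance shares per species; long table (species, source, proportion).

    A species whose factorial table has missing cells (e.g. skipped
    empty-hindcast configurations) raises by default; with
    ``on_incomplete='skip'`` it is dropped with a warning instead.
    """
    out = []
    for sp, sub in records.groupby("species"):
        try:
            part = deviance_partition(sub, delta=delta)
        except ValueError:
            if on_incomplete == "skip":
                warnings.warn(f"species {sp}: incomplete factorial table; skipped")
                continue
            raise
        part.insert(0, "species", sp)
        out.append(part)
    if not out:
        raise ValueError("no species with a complete factorial table")
    return pd.concat(out, ignore_index=True)


def classify_magnitude(coefficient: float) -> str:
    """Qualitative bin for a decision's extra-loss coefficient.

    0 → none; [−0.2, 0) → low; [−0.4, −0.2) → moderate; [−0.6, −0.4) →
    high; [−0.8, −0.6) → very_high; positive or below −0.8 →
    out_of_scale.
    """
    c = float(coefficient)
    if c == 0.0:
        return "none"
    if c > 0.0 or c < -0.8:
        return "out_of_scale"
    if c >= -0.2:
        return "low"
    if c >= -0.4:
        return "moderate"
    if c >= -0.6:
        return "high"
    return "very_high"


@dataclass
class MixedFitInfo:
    method: str  # "mixed" or "ols_fallback"
    converged: bool
    n_obs: int
    n_species: int


def _reference_levels(table: pd.DataFrame, y: np.ndarray, factors) -> dict[str, str]:
    """Per factor, the level with the highest mean response (least loss)."""
    refs = {}
    df = table.assign(_y=y)
    for f in factors:
        refs[f] = str(df.groupby(f)["_y"].mean().idxmax())
    return refs


def _design_with_refs(
    table: pd.DataFrame, factors, refs: dict[str, str]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    cols, names = [], []
    for f in factors:
        for level in sorted(table[f].astype(str).unique()):
            if level == refs[f]:
                continue
            cols.append((table[f].astype(str) == level).to_numpy(dtype=float))
            names.append((f, level))
    X = np.column_stack(cols) if cols else np.empty((len(table), 0))
    return X, names


def fit_effects_mixed(
    records: pd.DataFrame,
    delta: float = 0.01,
    factors=MODEL_FACTORS,
    reference: str = "least_loss",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, MixedFitInfo]:
    """Decision-effect coefficients from a species-random-intercept model.

    Returns a table with one row per factor level (reference rows have
    coefficient 0 and bin 'none') and a fit-info record.  With a single
    species, or when the mixed fit fails or does not converge, falls back
    to ordinary least squares with a warning.
    """
    table = records.copy()
    y = transform_rci(table["rci"].to_numpy(), delta=delta)
    if reference == "least_loss":
        refs = _reference_levels(table, y, factors)
    else:
        raise ValueError(f"unknown reference rule {reference!r}")
    X, names = _design_with_refs(table, factors, refs)
    groups = table["species"].to_numpy()
    n_species = len(np.unique(groups))
    exog = sm.add_constant(X)

    params = bse = None
    method, converged = "mixed", False
    if n_species >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, exog, groups=groups).fit(reml=True, method="lbfgs")
            if np.all(np.isfinite(res.fe_params)) and np.all(np.isfinite(res.bse_fe)):
                params, bse = res.fe_params, res.bse_fe
                converged = bool(res.converged)
        except (np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"mixed-model fit failed ({exc}); falling back to OLS")
    if params is None or not converged:
        if n_species >= 2 and params is not None:
            warnings.warn("mixed-model fit did not converge; using OLS coefficients")
        ols = sm.OLS(y, exog).fit()
        params, bse = ols.params, ols.bse
        method = "ols_fallback"
        converged = True

    z = float(-norm.ppf(alpha / 2.0))
    rows = []
    for f in factors:
        rows.append(
            {
                "factor": f,
                "level": refs[f],
                "coefficient": 0.0,
                "ci_low": 0.0,
                "ci_high": 0.0,
                "is_reference": True,
                "magnitude": "none",
            }
        )
    for j, (f, level) in enumerate(names):
        coef = float(params[j + 1])
        se = float(bse[j + 1])
        rows.append(
            {
                "factor": f,
                "level": level,
                "coefficient": coef,
                "ci_low": coef - z * se,
                "ci_high": coef + z * se,
                "is_reference": False,
                "magnitude": classify_magnitude(coef),
            }
        )
    effects = pd.DataFrame(rows)
    info = MixedFitInfo(method, converged, len(table), n_species)
    return effects, info


def species_influence(
    records: pd.DataFrame, delta: float = 0.01, factors=MODEL_FACTORS
) -> pd.DataFrame:
    """Leave-one-species-out refits of the decision-effect model.

    Reports, per withheld species, the maximum absolute coefficient
    change and how many magnitude bins changed relative to the all-species
    fit.
    """
    species = sorted(records["species"].unique())
    if len(species) < 3:
        raise ValueError("influence analysis needs at least 3 species")
    base, _ = fit_effects_mixed(records, delta=delta, factors=factors)
    base_idx = base.set_index(["factor", "level"])
    rows = []
    for sp in species:
        sub = records[records["species"] != sp]
        eff, _ = fit_effects_mixed(sub, delta=delta, factors=factors)
        eff_idx = eff.set_index(["factor", "level"])
        joined = base_idx.join(eff_idx, lsuffix="_all", rsuffix="_loo", how="inner")
        delta_coef = (joined["coefficient_all"] - joined["coefficient_loo"]).abs()
        bin_changes = int((joined["magnitude_all"] != joined["magnitude_loo"]).sum())
        rows.append(
            {
                "species": sp,
                "max_abs_coefficient_change": float(delta_coef.max()),
                "n_bin_changes": bin_changes,
            }
        )
    return pd.DataFrame(rows)
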