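"""Extrapolation vs cross-validation performance and the transferability test.

The performance grid evaluates every (species, hypothesis, collinearity,
threshold) cell twice: once on the extrapolation split (train on
wet/normal years, test on drought years — a proxy for a changed climate)
and once on 10 randomized year splits of the wet/normal data at the same
proportion.  Per metric, a species-random-intercept mixed model predicts
extrapolation performance from cross-validation performance; Spearman's ρ
between prediction and truth measures whether internal skill is a guide
to extrapolative skill.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, spearmanr

from .covariates import CovariateSet
from .ensemble import SplitPlan, fit_ensemble, predict_ensemble, training_frame
from .metrics import METRICS, metric_bundle
from .thresholding import PROCEDURES, binary_map, select_all_thresholds

logger = logging.getLogger(__name__)

PERF_FACTORS = ("hypothesis", "collinearity", "threshold")
CELL_KEYS = ["species", "hypothesis", "collinearity", "threshold"]


def evaluate_split(
    occ: pd.DataFrame,
    species: str,
    covset: CovariateSet,
    split: SplitPlan,
    seed: int = 0,
    procedures=PROCEDURES,
    members: dict | None = None,
    optimize_on: str = "train",
) -> list[dict]:
    """Fit on a split's train years, threshold, and score the test years.

    Thresholds are selected on the training predictions by default
    (``optimize_on='test'`` switches to test-side optimization).  Returns
    one record per thresholding procedure; a single-class test set yields
    records flagged invalid.
    """
    model = fit_ensemble(occ, species, covset, split, seed=seed, members=members)
    X_tr, y_tr = training_frame(occ, species, covset, split.train_years)
    X_te, y_te = training_frame(occ, species, covset, split.test_years)
    p_tr = predict_ensemble(model, X_tr)
    p_te = predict_ensemble(model, X_te)
    base = {
        "species": species,
        "hypothesis": covset.hypothesis,
        "collinearity": covset.collinearity_level,
        "split_kind": split.kind,
        "replicate": split.replicate,
    }
    if len(np.unique(y_te)) < 2:
        logger.warning(
            "single-class test set for %s %s/%s %s rep=%s; records flagged invalid",
            species, covset.hypothesis, covset.collinearity_level, split.kind, split.replicate,
        )
        return [
            {**base, "threshold": proc, "valid": False} for proc in procedures
        ]
    opt_p, opt_y = (p_tr, y_tr) if optimize_on == "train" else (p_te, y_te)
    specs = select_all_thresholds(opt_p, opt_y, procedures)
    records = []
    for proc in procedures:
        yhat = binary_map(p_te, specs[proc])
        vals = metric_bundle(p_te, y_te, yhat)
        records.append(
            {**base, "threshold": proc, "valid": True,
             "threshold_value": specs[proc].value, **vals}
        )
    return records


def run_performance_grid(
    occ: pd.DataFrame,
    covsets: dict[tuple[str, str], CovariateSet],
    extrapolation: SplitPlan,
    cv_splits: list[SplitPlan],
    seed: int = 0,
    procedures=PROCEDURES,
    members: dict | None = None,
    optimize_on: str = "train",
) -> pd.DataFrame:
    """All (species × covariate set × split) evaluations, long format."""
    species_list = sorted(occ["species"].unique())
    rows: list[dict] = []
    for species in species_list:
        for covset in covsets.values():
            for split in [extrapolation, *cv_splits]:
                rows.extend(
                    evaluate_split(
                        occ, species, covset, split, seed=seed,
                        procedures=procedures, members=members, optimize_on=optimize_on,
                    )
                )
    return pd.DataFrame(rows)


def average_cv_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """One value per cell: CV replicates averaged, extrapolation untouched."""
    valid = records[records["valid"]] if "valid" in records else records
    value_cols = [c for c in valid.columns
                  if c in METRICS or c.endswith("_logit") or c == "threshold_value"]
    cv = (
        valid[valid["split_kind"] == "cv"]
        .groupby(CELL_KEYS, as_index=False)[value_cols]
        .mean()
    )
    cv["split_kind"] = "cv"
    ex = valid[valid["split_kind"] == "extrapolation"][CELL_KEYS + value_cols + ["split_kind"]]
    return pd.concat([ex, cv], ignore_index=True)


@dataclass(frozen=True)
class CorrelationReport:
    metric: str
    rho: float
    n_cells: int
    method: str  # "mixed" or "ols_fallback"


def cv_extrapolation_correlation(records: pd.DataFrame, metric: str) -> CorrelationReport:
    """Spearman ρ between mixed-model-predicted and actual extrapolation skill.

    CV replicates are averaged per cell; the model is
    ``extrapolation_logit ~ cv_logit + (1 | species)`` and the prediction
    includes the species random intercepts (BLUPs).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; known: {METRICS}")
    col = f"{metric}_logit"
    cells = average_cv_replicates(records)
    wide = cells.pivot_table(index=CELL_KEYS, columns="split_kind", values=col).dropna()
    if len(wide) < 3:
        raise ValueError(f"only {len(wide)} matched cells; need at least 3")
    y = wide["extrapolation"].to_numpy()
    x = wide["cv"].to_numpy()
    species = wide.index.get_level_values("species").to_numpy()
    exog = sm.add_constant(x)
    method = "mixed"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, exog, groups=species).fit(reml=True, method="lbfgs")
        fixed = exog @ res.fe_params
        re = res.random_effects
        offsets = np.array([float(np.asarray(re[g]).ravel()[0]) for g in species])
        pred = fixed + offsets
        if not np.all(np.isfinite(pred)):
            raise ValueError("non-finite mixed-model predictions")
    except (np.linalg.LinAlgError, ValueError, KeyError) as exc:
        warnings.warn(f"mixed-model correlation fit failed ({exc}); OLS fallback")
        ols = sm.OLS(y, exog).fit()
        pred = ols.fittedvalues
        method = "ols_fallback"
    rho = float(spearmanr(pred, y).statistic)
    return CorrelationReport(metric=metric, rho=rho, n_cells=len(wide), method=method)


def _median_level(table: pd.DataFrame, factor: str, col: str) -> str:
    means = table.groupby(factor)[col].mean().sort_values()
    return str(means.index[(len(means) - 1) // 2])


def fit_performance_mixed(
    records: pd.DataFrame, metric: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Decision effects on extrapolation performance (logit scale).

    Species-random-intercept model of the metric on hypothesis +
    collinearity + threshold; the reference level of each factor is the
    one with the median marginal mean, and every level is labeled
    positive / intermediate / negative by its coefficient sign and
    whether the Wald interval excludes zero.
    """
    col = f"{metric}_logit"
    table = records[(records["split_kind"] == "extrapolation")]
    if "valid" in table:
        table = table[table["valid"]]
    table = table.reset_index(drop=True)
    refs = {f: _median_level(table, f, col) for f in PERF_FACTORS}
    cols, names = [], []
    for f in PERF_FACTORS:
        for level in sorted(table[f].astype(str).unique()):
            if level == refs[f]:
                continue
            cols.append((table[f].astype(str) == level).to_numpy(dtype=float))
            names.append((f, level))
    X = sm.add_constant(np.column_stack(cols))
    y = table[col].to_numpy()
    groups = table["species"].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=groups).fit(reml=True, method="lbfgs")
        params, bse = res.fe_params, res.bse_fe
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
            raise ValueError("non-finite mixed fit")
    except (np.linalg.LinAlgError, ValueError) as exc:
        warnings.warn(f"mixed performance fit failed ({exc}); OLS fallback")
        ols = sm.OLS(y, X).fit()
        params, bse = ols.params, ols.bse
    z = float(-norm.ppf(alpha / 2.0))
    rows = [
        {
            "factor": f,
            "level": refs[f],
            "coefficient": 0.0,
            "ci_low": 0.0,
            "ci_high": 0.0,
            "is_reference": True,
            "label": "intermediate",
        }
        for f in PERF_FACTORS
    ]
    for j, (f, level) in enumerate(names):
        coef, se = float(params[j + 1]), float(bse[j + 1])
        lo, hi = coef - z * se, coef + z * se
        label = "positive" if lo > 0 else "negative" if hi < 0 else "intermediate"
        rows.append(
            {
                "factor": f,
                "level": level,
                "coefficient": coef,
                "ci_low": lo,
                "ci_high": hi,
                "is_reference": False,
                "label": label,
            }
        )
    out = pd.DataFrame(rows)
    out.insert(0, "metric", metric)
    return out


def summarize_decision_table(
    rci_effects: pd.DataFrame,
    tss_effects: pd.DataFrame,
    prevalence_effects: pd.DataFrame,
) -> pd.DataFrame:
    """The combined per-decision summary grid.

    One row per decision level of hypothesis + collinearity + threshold
    (3 + 3 + 12 = 18 at the full design): the RCI extra-loss magnitude
    bin, the locational-accuracy label (TSS), and the prevalence-accuracy
    label (prevalence match).  Reference rows are tagged "(reference)".
    """
    def _frame(effects, value_col, out_col):
        sub = effects[effects["factor"].isin(PERF_FACTORS)].copy()
        sub[out_col] = np.where(
            sub["is_reference"], sub[value_col] + " (reference)", sub[value_col]
        )
        return sub.set_index(["factor", "level"])[[out_col]]

    rci_f = _frame(rci_effects.assign(_v=rci_effects["magnitude"]), "_v", "range_loss_effect")
    tss_f = _frame(tss_effects.assign(_v=tss_effects["label"]), "_v", "locational_accuracy")
    prev_f = _frame(
        prevalence_effects.assign(_v=prevalence_effects["label"]), "_v", "prevalence_accuracy"
    )
    grid = rci_f.join(tss_f, how="outer").join(prev_f, how="outer").reset_index()
    missing = grid[grid.isna().any(axis=1)]
    if len(missing):
        raise ValueError(
            f"decision table has unmatched factor levels: "
            f"{missing[['factor', 'level']].to_records(index=False).tolist()}"
        )
    order = {f: i for i, f in enumerate(PERF_FACTORS)}
    grid["_order"] = grid["factor"].map(order)
    grid = grid.sort_values(["_order", "level"]).drop(columns="_order")
    return grid.reset_index(drop=True)
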