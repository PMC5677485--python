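"""Weighted-consensus occurrence ensembles and year-level data splits.

The ensemble is a configurable committee of scikit-learn classifiers —
by default a quadratic logistic regression, a shallow classification
tree, gradient-boosted stumps, and k-nearest-neighbours — whose
probabilities are averaged with weights proportional to each member's
True Skill Statistic on an internal holdout of training *years* (negative
skill floors to zero weight).  Splits are always by year: all sites of a
year move together, respecting the interannual design in which drought
years are the extrapolation test set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from ._rng import child_rng, child_seed
from .covariates import CovariateSet
from .metrics import tss
from .synthetic_world import DROUGHT, WET_NORMAL
from .thresholding import confusion, select_threshold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    """Year-level train/test partition."""

    kind: str  # "extrapolation" | "cv"
    train_years: tuple[int, ...]
    test_years: tuple[int, ...]
    replicate: int | None = None

    def __post_init__(self) -> None:
        if set(self.train_years) & set(self.test_years):
            raise ValueError("train and test years overlap")
        if self.kind == "cv" and self.replicate is None:
            raise ValueError("cv splits need a replicate index")


def _year_classes(occ: pd.DataFrame) -> pd.Series:
    return occ.drop_duplicates("year").set_index("year")["year_class"].sort_index()


def make_extrapolation_split(occ: pd.DataFrame) -> SplitPlan:
    """Train on all wet/normal years, test on all drought years."""
    classes = _year_classes(occ)
    train = tuple(int(y) for y in classes.index[classes == WET_NORMAL])
    test = tuple(int(y) for y in classes.index[classes == DROUGHT])
    if not train or not test:
        raise ValueError(
            f"extrapolation split needs both year classes "
            f"(wet/normal: {len(train)}, drought: {len(test)})"
        )
    return SplitPlan("extrapolation", train, test)


def make_cv_splits(occ: pd.DataFrame, n_splits: int = 10, seed: int = 0) -> list[SplitPlan]:
    """Randomized year splits of the wet/normal years at the extrapolation ratio.

    The test fraction equals the drought fraction of all years (the
    82:18-style proportion), rounded to whole years, at least 1.
    """
    classes = _year_classes(occ)
    wet = np.array([int(y) for y in classes.index[classes == WET_NORMAL]])
    n_total = len(classes)
    n_drought = int((classes == DROUGHT).sum())
    if len(wet) < 2:
        raise ValueError("cross-validation needs at least 2 wet/normal years")
    n_test = max(1, int(round(len(wet) * n_drought / n_total)))
    if n_test >= len(wet):
        raise ValueError("cv test proportion leaves no training years")
    rng = child_rng(seed, "cv")
    plans = []
    for rep in range(1, n_splits + 1):
        test = np.sort(rng.choice(wet, size=n_test, replace=False))
        train = np.sort(np.setdiff1d(wet, test))
        plans.append(
            SplitPlan("cv", tuple(int(y) for y in train), tuple(int(y) for y in test), rep)
        )
    return plans


def _append_squares(X):
    return np.hstack([X, X**2])


def default_members(seed: int = 0) -> dict[str, object]:
    """The four default member algorithms (parametric → nonparametric)."""
    return {
        # linear + quadratic terms (no interactions), ridge-penalized
        "glm_quadratic": make_pipeline(
            StandardScaler(),
            FunctionTransformer(_append_squares),
            LogisticRegression(C=1.0, max_iter=500),
        ),
        "tree": DecisionTreeClassifier(max_depth=4, min_samples_leaf=15, random_state=seed),
        "boosted_stumps": GradientBoostingClassifier(
            n_estimators=25, max_depth=1, learning_rate=0.2, random_state=seed
        ),
        "knn": make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=25)),
    }


@dataclass
class EnsembleModel:
    """A fitted weighted-consensus model for one (species, covariate set)."""

    species: str
    covset_key: tuple[str, str]
    feature_names: list[str]
    members: dict[str, object]
    weights: dict[str, float]
    split: SplitPlan | None = None
    diagnostics: dict = field(default_factory=dict)

    def describe(self) -> dict:
        """JSON-ready descriptor (no fitted estimators)."""
        return {
            "species": self.species,
            "hypothesis": self.covset_key[0],
            "collinearity": self.covset_key[1],
            "features": self.feature_names,
            "weights": self.weights,
            "split": None
            if self.split is None
            else {
                "kind": self.split.kind,
                "train_years": list(self.split.train_years),
                "test_years": list(self.split.test_years),
                "replicate": self.split.replicate,
            },
        }


def _member_probs(est, X: np.ndarray) -> np.ndarray:
    proba = est.predict_proba(X)
    classes = getattr(est, "classes_", None)
    if classes is None:  # pipeline
        classes = est[-1].classes_
    if len(classes) == 1:
        return np.full(len(X), float(classes[0]))
    return proba[:, int(np.flatnonzero(classes == 1)[0])]


def training_frame(
    occ: pd.DataFrame, species: str, covset: CovariateSet, years
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix and response for one species over the given years."""
    sub = occ[(occ["species"] == species) & (occ["year"].isin(list(years)))]
    X = covset.matrix.loc[list(zip(sub["site"], sub["year"]))]
    return X, sub["presence"].to_numpy()


def fit_ensemble(
    occ: pd.DataFrame,
    species: str,
    covset: CovariateSet,
    split: SplitPlan,
    seed: int = 0,
    members: dict[str, object] | None = None,
    holdout_fraction: float = 0.2,
) -> EnsembleModel:
    """Fit the consensus ensemble on a split's training years.

    Member weights ∝ max(holdout TSS, 0) on an internal 20% holdout of
    training years; members are then refit on the full training data.  A
    member that fails to fit is dropped with a warning; if every member
    has nonpositive holdout skill, weights fall back to uniform.
    """
    if members is None:
        members = default_members(child_seed(seed, "ensemble"))
    train_years = np.array(split.train_years)
    X_full, y_full = training_frame(occ, species, covset, train_years)
    n_cov = X_full.shape[1]
    if len(X_full) < 10 * n_cov:
        warnings.warn(
            f"only {len(X_full)} training rows for {n_cov} covariates "
            f"({species}, {covset.hypothesis}/{covset.collinearity_level})"
        )
    rng = child_rng(seed, "ensemble", 1)
    n_hold = max(1, int(round(holdout_fraction * len(train_years))))
    if n_hold >= len(train_years):
        raise ValueError("not enough training years for an internal holdout")
    hold_years = rng.choice(train_years, size=n_hold, replace=False)
    inner_years = np.setdiff1d(train_years, hold_years)
    X_in, y_in = training_frame(occ, species, covset, inner_years)
    X_ho, y_ho = training_frame(occ, species, covset, hold_years)

    fitted: dict[str, object] = {}
    weights: dict[str, float] = {}
    holdout_tss: dict[str, float] = {}
    for name, proto in members.items():
        try:
            est = clone(proto).fit(X_in.to_numpy(), y_in)
            probs = _member_probs(est, X_ho.to_numpy())
            if len(np.unique(y_ho)) < 2:
                score = 0.0
            else:
                spec = select_threshold(probs, y_ho, "TSS")
                score = tss(confusion(probs, y_ho, spec.value))
            holdout_tss[name] = score
            weights[name] = max(score, 0.0)
            fitted[name] = clone(proto).fit(X_full.to_numpy(), y_full)
        except Exception as exc:  # noqa: BLE001 - member failure is survivable
            warnings.warn(f"ensemble member {name!r} failed ({exc}); dropped")
    if not fitted:
        raise RuntimeError(f"all ensemble members failed for species {species}")
    total = sum(weights.get(n, 0.0) for n in fitted)
    if total <= 0:
        warnings.warn("no member achieved positive holdout TSS; using uniform weights")
        weights = {n: 1.0 / len(fitted) for n in fitted}
    else:
        weights = {n: weights.get(n, 0.0) / total for n in fitted}
    return EnsembleModel(
        species=species,
        covset_key=(covset.hypothesis, covset.collinearity_level),
        feature_names=list(covset.matrix.columns),
        members=fitted,
        weights=weights,
        split=split,
        diagnostics={"holdout_tss": holdout_tss, "n_train_rows": int(len(X_full))},
    )


def predict_ensemble(model: EnsembleModel, X: pd.DataFrame) -> np.ndarray:
    """Weighted-average probability of occurrence for each row of ``X``."""
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise KeyError(f"missing covariate columns: {missing}")
    Xa = X[model.feature_names].to_numpy()
    out = np.zeros(len(Xa))
    for name, est in model.members.items():
        out += model.weights[name] * _member_probs(est, Xa)
    return np.clip(out, 0.0, 1.0)
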