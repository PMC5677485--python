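import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from sdm_uncertainty.covariates import CovariateSet, derive_hydrological
from sdm_uncertainty.ensemble import (
    EnsembleModel,
    SplitPlan,
    fit_ensemble,
    make_cv_splits,
    make_extrapolation_split,
    predict_ensemble,
)


class ConstantProb(BaseEstimator, ClassifierMixin):
    """Stub member returning a fixed probability everywhere."""

    def __init__(self, p=0.5):
        self.p = p

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        out = np.full((len(X), 2), [1 - self.p, self.p])
        return out


class TestSplits:
    def test_extrapolation_split_partitions_year_classes(self, occurrences):
        plan = make_extrapolation_split(occurrences.panel)
        assert len(plan.train_years) == 32
        assert len(plan.test_years) == 7
        assert not set(plan.train_years) & set(plan.test_years)

    def test_extrapolation_split_order_invariant(self, occurrences):
        shuffled = occurrences.panel.sample(frac=1.0, random_state=0)
        assert make_extrapolation_split(shuffled) == make_extrapolation_split(
            occurrences.panel
        )

    def test_extrapolation_requires_both_classes(self, occurrences):
        wet_only = occurrences.panel[occurrences.panel["year_class"] == "wet_normal"]
        with pytest.raises(ValueError, match="both year classes"):
            make_extrapolation_split(wet_only)

    def test_cv_yields_ten_seeded_plans(self, occurrences):
        plans = make_cv_splits(occurrences.panel, n_splits=10, seed=5)
        assert len(plans) == 10
        assert [p.replicate for p in plans] == list(range(1, 11))
        again = make_cv_splits(occurrences.panel, n_splits=10, seed=5)
        assert plans == again
        assert plans != make_cv_splits(occurrences.panel, n_splits=10, seed=6)

    def test_cv_test_fraction_matches_drought_fraction(self, occurrences):
        plans = make_cv_splits(occurrences.panel, seed=1)
        classes = occurrences.panel.drop_duplicates("year")
        drought_frac = (classes["year_class"] == "drought").mean()
        n_wet = (classes["year_class"] == "wet_normal").sum()
        for p in plans:
            test_frac = len(p.test_years) / n_wet
            assert abs(test_frac - drought_frac) <= 1.0 / n_wet
            # cv splits draw only from wet/normal years
            assert set(p.test_years) <= set(
                classes[classes["year_class"] == "wet_normal"]["year"]
            )

    def test_overlapping_years_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan("extrapolation", (2000, 2001), (2001,))


@pytest.fixture(scope="module")
def hydro_covset(observed_panel):
    return derive_hydrological(observed_panel)


@pytest.fixture(scope="module")
def fitted(occurrences, hydro_covset):
    plan = make_extrapolation_split(occurrences.panel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_ensemble(occurrences.panel, "sp00", hydro_covset, plan, seed=2)


class TestFitEnsemble:
    def test_weights_are_a_probability_vector(self, fitted):
        total = sum(fitted.weights.values())
        assert total == pytest.approx(1.0, abs=1e-9)
        assert all(w >= 0 for w in fitted.weights.values())

    def test_refit_is_bit_identical(self, occurrences, hydro_covset):
        plan = make_extrapolation_split(occurrences.panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_ensemble(occurrences.panel, "sp00", hydro_covset, plan, seed=2)
            b = fit_ensemble(occurrences.panel, "sp00", hydro_covset, plan, seed=2)
        assert a.weights == b.weights

    def test_single_member_gets_unit_weight(self, occurrences, hydro_covset):
        plan = make_extrapolation_split(occurrences.panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_ensemble(
                occurrences.panel, "sp00", hydro_covset, plan, seed=2,
                members={"only": ConstantProb(0.7)},
            )
        assert model.weights == {"only": 1.0}

    def test_zero_skill_member_floored_to_uniform_with_warning(
        self, occurrences, hydro_covset
    ):
        plan = make_extrapolation_split(occurrences.panel)
        with pytest.warns(UserWarning, match="uniform"):
            model = fit_ensemble(
                occurrences.panel, "sp00", hydro_covset, plan, seed=2,
                members={"flat1": ConstantProb(0.6), "flat2": ConstantProb(0.4)},
            )
        # constant probabilities have TSS = 0 on any holdout -> uniform
        assert model.weights == {"flat1": 0.5, "flat2": 0.5}

    def test_strong_water_response_is_learnable(self, observed_panel, hydro_covset):
        """A species with a strong water-balance response is modeled with
        AUC > 0.8, and better than chance on held-out drought years."""
        from sdm_uncertainty.ensemble import training_frame
        from sdm_uncertainty.metrics import auc
        from sdm_uncertainty.synthetic_world import WorldConfig, generate_occurrences

        resp = pd.DataFrame(
            {
                "species": ["strong"],
                "beta_water": [2.2],
                "gamma_temp": [-0.3],
                "target_prevalence": [0.45],
            }
        )
        cfg = WorldConfig(
            n_sites=25, n_years=39, n_species=1, seed=7, species_response=resp
        )
        occ = generate_occurrences(observed_panel, cfg)
        plan = make_extrapolation_split(occ.panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_ensemble(occ.panel, "strong", hydro_covset, plan, seed=2)
        X_tr, y_tr = training_frame(occ.panel, "strong", hydro_covset, plan.train_years)
        X_te, y_te = training_frame(occ.panel, "strong", hydro_covset, plan.test_years)
        assert auc(predict_ensemble(model, X_tr), y_tr) > 0.8
        assert auc(predict_ensemble(model, X_te), y_te) > 0.6


class TestPredictEnsemble:
    def test_consensus_equals_members_when_identical(self, occurrences, hydro_covset):
        plan = make_extrapolation_split(occurrences.panel)
        model = EnsembleModel(
            species="sp00",
            covset_key=("hydrological", "all"),
            feature_names=list(hydro_covset.matrix.columns),
            members={"m1": ConstantProb(0.3).fit(None, None),
                     "m2": ConstantProb(0.3).fit(None, None)},
            weights={"m1": 0.5, "m2": 0.5},
            split=plan,
        )
        probs = predict_ensemble(model, hydro_covset.matrix.head(10))
        assert np.allclose(probs, 0.3)

    def test_weighted_average_arithmetic(self, hydro_covset):
        model = EnsembleModel(
            species="sp00",
            covset_key=("hydrological", "all"),
            feature_names=list(hydro_covset.matrix.columns),
            members={"lo": ConstantProb(0.2).fit(None, None),
                     "hi": ConstantProb(0.8).fit(None, None)},
            weights={"lo": 0.5, "hi": 0.5},
        )
        probs = predict_ensemble(model, hydro_covset.matrix.head(4))
        assert np.allclose(probs, 0.5)

    def test_site_permutation_equivariance(self, fitted, hydro_covset):
        X = hydro_covset.matrix.head(30)
        perm = np.random.default_rng(0).permutation(30)
        p1 = predict_ensemble(fitted, X)
        p2 = predict_ensemble(fitted, X.iloc[perm])
        assert np.allclose(p1[perm], p2)

    def test_missing_column_named_in_error(self, fitted, hydro_covset):
        X = hydro_covset.matrix.drop(columns=["aet_annual"]).head(5)
        with pytest.raises(KeyError, match="aet_annual"):
            predict_ensemble(fitted, X)

    def test_consensus_within_member_envelope(self, occurrences, hydro_covset):
        """Convexity: the weighted consensus lies inside the min/max of
        member probabilities."""
        plan = make_extrapolation_split(occurrences.panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_ensemble(occurrences.panel, "sp01", hydro_covset, plan, seed=3)
        X = hydro_covset.matrix.head(50)
        from sdm_uncertainty.ensemble import _member_probs

        member_probs = np.array(
            [_member_probs(m, X.to_numpy()) for m in model.members.values()]
        )
        consensus = predict_ensemble(model, X)
        assert np.all(consensus >= member_probs.min(axis=0) - 1e-12)
        assert np.all(consensus <= member_probs.max(axis=0) + 1e-12)
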