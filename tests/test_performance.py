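import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from sdm_uncertainty.attribution import fit_effects_mixed
from sdm_uncertainty.metrics import METRICS, logit_metric
from sdm_uncertainty.performance import (
    average_cv_replicates,
    cv_extrapolation_correlation,
    fit_performance_mixed,
    summarize_decision_table,
)
from sdm_uncertainty.thresholding import PROCEDURES

HYPS = ["temporal", "bioclimatic", "hydrological"]
LEVELS = ["all", "vif10", "vif2"]


def make_records(
    extrap_fn,
    cv_fn,
    n_species=4,
    thresholds=PROCEDURES,
    n_replicates=3,
    seed=0,
):
    """Synthetic performance records; *_fn(species_idx, cell_idx, rng) give
    the auc value on the logit scale (other metrics mirror it)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_species):
        for ci, (h, l, t) in enumerate(itertools.product(HYPS, LEVELS, thresholds)):
            base = {
                "species": f"sp{s}",
                "hypothesis": h,
                "collinearity": l,
                "threshold": t,
                "valid": True,
            }
            ex = extrap_fn(s, ci, rng)
            rows.append(
                {
                    **base,
                    "split_kind": "extrapolation",
                    "replicate": None,
                    **_vals(ex),
                }
            )
            for rep in range(1, n_replicates + 1):
                cv = cv_fn(s, ci, rng)
                rows.append(
                    {
                        **base,
                        "split_kind": "cv",
                        "replicate": rep,
                        **_vals(cv),
                    }
                )
    return pd.DataFrame(rows)


def _vals(logit_value):
    p = 1.0 / (1.0 + np.exp(-logit_value))
    out = {}
    for m in METRICS:
        raw = 2 * p - 1 if m in ("kappa", "tss") else p
        out[m] = raw
        out[f"{m}_logit"] = logit_metric(raw, metric=m)
    return out


class TestCorrelation:
    def test_identical_cv_and_extrapolation_is_perfect(self):
        fn = lambda s, c, rng: 0.1 * s + 0.01 * c - 0.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = cv_extrapolation_correlation(make_records(fn, fn), "auc")
        assert rep.rho == pytest.approx(1.0)

    def test_sign_reversal_absorbed_by_model(self):
        """extrapolation = -cv exactly: the fitted slope is negative, so the
        model's predictions still rank the truth perfectly."""
        cv = lambda s, c, rng: 0.02 * c - 1.0
        ex = lambda s, c, rng: -(0.02 * c - 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = cv_extrapolation_correlation(make_records(ex, cv), "auc")
        assert rep.rho == pytest.approx(1.0)

    def test_independent_cv_is_uncorrelated(self):
        ex = lambda s, c, rng: rng.normal()
        cv = lambda s, c, rng: rng.normal()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = cv_extrapolation_correlation(
                make_records(ex, cv, n_species=5, seed=11), "auc"
            )
        assert abs(rep.rho) < 0.15

    def test_preaveraged_replicates_equivalent(self):
        ex = lambda s, c, rng: 0.3 * s - 0.01 * c + rng.normal(0, 0.1)
        cv = lambda s, c, rng: 0.3 * s - 0.01 * c + rng.normal(0, 0.1)
        records = make_records(ex, cv, seed=4)
        pre = average_cv_replicates(records)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = cv_extrapolation_correlation(records, "tss")
            r2 = cv_extrapolation_correlation(pre, "tss")
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)

    def test_too_few_cells_rejected(self):
        records = make_records(
            lambda s, c, rng: 0.0, lambda s, c, rng: 0.0, n_species=1,
            thresholds=("Fixed",),
        )
        records = records[records["hypothesis"] == "temporal"]
        records = records[records["collinearity"] == "all"]
        with pytest.raises(ValueError, match="matched cells"):
            cv_extrapolation_correlation(records, "auc")

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            cv_extrapolation_correlation(make_records(
                lambda s, c, rng: 0.0, lambda s, c, rng: 0.0), "brier")


class TestPerformanceEffects:
    def test_planted_advantage_labeled_positive(self):
        def ex(s, c, rng):
            h = HYPS[(c // (len(LEVELS) * len(PROCEDURES)))]
            return (0.5 if h == "temporal" else 0.0) + rng.normal(0, 0.1)

        records = make_records(ex, ex, n_species=6, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            effects = fit_performance_mixed(records, "auc")
        row = effects[(effects["factor"] == "hypothesis") & (effects["level"] == "temporal")]
        assert row["label"].iloc[0] == "positive"
        assert row["coefficient"].iloc[0] == pytest.approx(0.5, abs=0.1)

    def test_reference_level_has_zero_coefficient(self):
        records = make_records(
            lambda s, c, rng: rng.normal(0, 0.2),
            lambda s, c, rng: rng.normal(0, 0.2),
            seed=3,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            effects = fit_performance_mixed(records, "kappa")
        refs = effects[effects["is_reference"]]
        assert len(refs) == 3  # one per factor
        assert (refs["coefficient"] == 0).all()

    def test_null_simulation_mostly_intermediate(self):
        records = make_records(
            lambda s, c, rng: rng.normal(0, 0.3),
            lambda s, c, rng: rng.normal(0, 0.3),
            n_species=6,
            seed=5,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            effects = fit_performance_mixed(records, "auc")
        non_ref = effects[~effects["is_reference"]]
        assert (non_ref["label"] == "intermediate").mean() >= 0.9


@pytest.fixture(scope="module")
def tables():
        rng = np.random.default_rng(7)
        # RCI effects over the full four-factor design (2 GCMs suffice)
        rows = []
        for sp in ("a", "b", "c"):
            for g, h, l, t in itertools.product(
                ("g0", "g1"), HYPS, LEVELS, PROCEDURES
            ):
                y = (
                    -0.3 * (t == "Fixed")
                    - 0.1 * (h == "bioclimatic")
                    + rng.normal(0, 0.05)
                )
                rows.append(
                    {
                        "species": sp, "gcm": g, "hypothesis": h,
                        "collinearity": l, "threshold": t,
                        "rci": np.exp(y) - 1.01,
                    }
                )
        rci_records = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rci_effects, _ = fit_effects_mixed(rci_records)
            perf = make_records(
                lambda s, c, rng2: rng2.normal(0, 0.2),
                lambda s, c, rng2: rng2.normal(0, 0.2),
                seed=8,
            )
            tss_eff = fit_performance_mixed(perf, "tss")
            prev_eff = fit_performance_mixed(perf, "prevalence_match")
        return rci_effects, tss_eff, prev_eff


class TestDecisionTable:
    def test_grid_has_eighteen_decision_rows(self, tables):
        grid = summarize_decision_table(*tables)
        assert len(grid) == 3 + 3 + 12
        assert set(grid["factor"]) == {"hypothesis", "collinearity", "threshold"}

    def test_reference_rows_are_tagged(self, tables):
        grid = summarize_decision_table(*tables)
        assert grid["locational_accuracy"].str.contains("reference").sum() == 3
        assert grid["range_loss_effect"].str.contains("reference").sum() == 3

    def test_missing_level_rejected(self, tables):
        rci_effects, tss_eff, prev_eff = tables
        with pytest.raises(ValueError, match="unmatched"):
            summarize_decision_table(
                rci_effects[rci_effects["level"] != "Fixed"], tss_eff, prev_eff
            )
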