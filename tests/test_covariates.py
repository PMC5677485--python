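import numpy as np
import pandas as pd
import pytest

from conftest import toy_panel
from sdm_uncertainty.covariates import (
    COLLINEARITY_LEVELS,
    CovariateSet,
    build_covariate_grid,
    derive_bioclim,
    derive_hydrological,
    derive_temporal,
    vif,
    vif_filter,
    vif_report,
)
from sdm_uncertainty.hydrology import thornthwaite_pet


def _ols_r2(y, X):
    """Independent OLS oracle for VIF checks."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    return 1.0 - resid @ resid / np.sum((y - y.mean()) ** 2)


class TestDeriveTemporal:
    def test_annual_total_is_sum_of_months(self, observed_panel):
        cs = derive_temporal(observed_panel)
        manual = observed_panel.groupby(["site", "year"])["precipitation"].sum()
        np.testing.assert_allclose(cs.matrix["p_ann_total"].to_numpy(), manual.to_numpy())

    def test_constant_climate_zeroes_variability_covariates(self):
        panel = toy_panel(np.full(12, 10.0), np.full(12, 50.0), n_years=3)
        cs = derive_temporal(panel)
        for col in ("t_ann_interann_sd", "p_ann_interann_sd", "p_breed_interann_sd"):
            assert np.all(cs.matrix[col] == 0.0)

    def test_breeding_season_mean_matches_hand_sum(self):
        temps = np.arange(1.0, 13.0)  # Jan=1 .. Dec=12
        panel = toy_panel(temps, np.full(12, 10.0), n_years=2)
        cs = derive_temporal(panel, breeding_months=(4, 5, 6, 7))
        assert np.allclose(cs.matrix["t_breed_mean"], (4 + 5 + 6 + 7) / 4)

    def test_missing_month_raises_with_gap_named(self, observed_panel):
        broken = observed_panel[
            ~((observed_panel["year"] == 1975) & (observed_panel["month"] == 6))
        ]
        with pytest.raises(ValueError, match="missing months"):
            derive_temporal(broken)


class TestDeriveBioclim:
    def test_single_warm_month_spike(self):
        temps = np.full(12, 5.0)
        temps[6] = 30.0
        panel = toy_panel(temps, np.full(12, 40.0))
        cs = derive_bioclim(panel)
        assert np.all(cs.matrix["t_max_warmest_month"] == 30.0)

    def test_uniform_precipitation_has_zero_seasonality(self):
        panel = toy_panel(np.linspace(0, 20, 12), np.full(12, 42.0))
        cs = derive_bioclim(panel)
        assert np.allclose(cs.matrix["p_seasonality_cv"], 0.0)

    def test_wettest_quarter_matches_wraparound_bruteforce(self):
        rng = np.random.default_rng(5)
        precip = rng.uniform(0, 100, 12)
        panel = toy_panel(np.full(12, 10.0), precip)
        cs = derive_bioclim(panel)
        wrapped = np.concatenate([precip, precip[:2]])
        brute = max(wrapped[i : i + 3].sum() for i in range(12))
        assert cs.matrix["p_wettest_quarter"].iloc[0] == pytest.approx(brute)
        brute_min = min(wrapped[i : i + 3].sum() for i in range(12))
        assert cs.matrix["p_driest_quarter"].iloc[0] == pytest.approx(brute_min)

    def test_temperature_shift_equivariance(self, observed_panel):
        """Adding a constant to all temperatures shifts mean-temperature
        covariates by exactly that constant."""
        shifted = observed_panel.copy()
        shifted["temperature"] += 3.0
        a = derive_bioclim(observed_panel).matrix
        b = derive_bioclim(shifted).matrix
        for col in ("t_ann_mean", "t_max_warmest_month", "t_min_coldest_month"):
            np.testing.assert_allclose(b[col], a[col] + 3.0)
        np.testing.assert_allclose(b["t_seasonality_sd"], a["t_seasonality_sd"])


class TestDeriveHydrological:
    def test_zero_precipitation_dries_out(self):
        panel = toy_panel(np.full(12, 15.0), np.zeros(12), n_years=3)
        cs = derive_hydrological(panel, capacity=100.0)
        last_year = cs.matrix.xs(2002, level="year")
        assert np.allclose(last_year["aet_annual"], 0.0, atol=1e-6)
        assert np.allclose(last_year["sm_annual_min"], 0.0, atol=1e-6)

    def test_energy_limited_regime_has_zero_deficit(self):
        temps = np.full(12, 10.0)
        pet = thornthwaite_pet(temps)
        precip = pet + 20.0
        panel = toy_panel(temps, precip, n_years=2)
        cs = derive_hydrological(panel, capacity=100.0)
        assert np.allclose(cs.matrix["deficit_annual"], 0.0, atol=1e-9)
        # once the bucket is full, surplus = P - PET
        year2 = cs.matrix.xs(2001, level="year")
        assert np.allclose(year2["surplus_annual"], (precip - pet).sum(), atol=1e-6)

    def test_negative_capacity_rejected(self, observed_panel):
        with pytest.raises(ValueError, match="capacity"):
            derive_hydrological(observed_panel, capacity=-5.0)

    def test_reference_stats_reused_for_scenarios(self, observed_panel):
        base = derive_hydrological(observed_panel)
        again = derive_hydrological(
            observed_panel, reference_stats=base.standardization
        )
        np.testing.assert_allclose(
            base.matrix["drought_index"], again.matrix["drought_index"]
        )


class TestVif:
    def test_orthogonal_covariate_has_unit_vif(self):
        # mutually orthogonal, zero-mean Rademacher contrasts: R2 = 0 exactly
        n = 400
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        m = pd.DataFrame({"a": x1, "b": x2, "c": x1 * x2})
        assert vif(m, "a") == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_is_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        m = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        assert np.isinf(vif(m, "a"))

    def test_engineered_r2_gives_vif_ten(self):
        """x3 = x1 + x2 + noise scaled so the OLS oracle gives R2 = 0.9."""
        rng = np.random.default_rng(2)
        n = 2000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        noise = rng.normal(size=n)
        # scale pieces exactly so that var(signal)/var(total) = 0.9
        signal = x1 + x2
        signal = (signal - signal.mean()) / signal.std()
        # project noise off span{1, x1, x2} so it is exactly unexplainable
        basis = np.column_stack([np.ones(n), x1, x2])
        noise = noise - basis @ np.linalg.lstsq(basis, noise, rcond=None)[0]
        noise = noise / noise.std()
        x3 = np.sqrt(0.9) * signal + np.sqrt(0.1) * noise
        m = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        r2 = _ols_r2(x3, np.column_stack([x1, x2]))
        assert r2 == pytest.approx(0.9, abs=1e-6)
        assert vif(m, "x3") == pytest.approx(10.0, rel=1e-4)


class TestVifFilter:
    def test_orthogonal_matrix_untouched_at_cutoff_two(self):
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(200, 4)))
        m = pd.DataFrame(q, columns=list("abcd"))
        cs = vif_filter(CovariateSet("temporal", "all", m), "vif2")
        assert cs.names == list("abcd")
        assert cs.removal_log == []

    def test_no_cutoff_is_identity(self, observed_panel):
        base = derive_temporal(observed_panel)
        cs = vif_filter(base, "all")
        pd.testing.assert_frame_equal(cs.matrix, base.matrix)

    def test_duplicate_column_resolved_and_survivors_compliant(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        m = pd.DataFrame(
            {"a": x, "b": x + rng.normal(scale=1e-12, size=300), "c": rng.normal(size=300)}
        )
        cs = vif_filter(CovariateSet("temporal", "all", m), "vif10")
        assert len(cs.removal_log) == 1
        assert cs.removal_log[0] in ("a", "b")
        # independent recomputation of survivor VIFs
        survivors = vif_report(cs.matrix)
        assert all(v <= 10.0 for v in survivors.values())

    def test_filter_compliance_reverified_by_oracle(self, observed_panel, world_config):
        grid = build_covariate_grid(observed_panel, world_config)
        for (hyp, level), cs in grid.items():
            if level == "all" or cs.matrix.shape[1] < 2:
                continue
            cutoff = {"vif10": 10.0, "vif2": 2.0}[level]
            recomputed = vif_report(cs.matrix)
            assert all(v <= cutoff + 1e-9 for v in recomputed.values()), (hyp, level)

    def test_covariate_count_monotone_in_cutoff(self, observed_panel, world_config):
        grid = build_covariate_grid(observed_panel, world_config)
        for hyp in ("temporal", "bioclimatic", "hydrological"):
            n_all = grid[(hyp, "all")].matrix.shape[1]
            n_10 = grid[(hyp, "vif10")].matrix.shape[1]
            n_2 = grid[(hyp, "vif2")].matrix.shape[1]
            assert n_2 <= n_10 <= n_all

    def test_unknown_level_rejected(self, observed_panel):
        base = derive_temporal(observed_panel)
        with pytest.raises(ValueError, match="collinearity level"):
            vif_filter(base, "vif5")
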