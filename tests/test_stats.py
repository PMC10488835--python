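import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eamap import (
    emm_at,
    fit_mixed_model,
    pairwise_contrasts,
    pearson_correlation,
    sample_measurement_table,
    sex_effect_test,
)
from eamap.stats import IdentifiabilityError, sidak_adjust


def noiseless_table(cv_means=None, slope=-0.002, n_animals=3, circles=20):
    """Deterministic measurement table: zero animal and residual noise."""
    design = pd.DataFrame(
        [
            {"animal_id": str(a), "chamber": c, "heart_rate": hr + 7 * a + 12 * rep,
             "map_id": f"{a}-{c}-{rep}", "sex": "male" if a % 2 else "female"}
            for a in range(n_animals)
            for rep in range(2)
            for c, hr in (("LA", 80), ("RA", 100), ("LV", 120), ("RV", 95))
        ]
    )
    tab, truth = sample_measurement_table(
        design=design, circles_per_map=circles, cv_means=cv_means,
        slope_log_cv=slope, animal_sd_log_cv=0.0, animal_sd_va=0.0,
        resid_sd_log_cv=0.0, resid_sd_va=0.0, seed=1,
    )
    return tab, truth


class TestFitMixedModel:
    def test_noiseless_fixed_effects_recovered_exactly(self):
        tab, truth = noiseless_table()
        res = fit_mixed_model(tab, "log_cv")
        sl = truth["slope_log_cv"]
        assert res.params["heart_rate"] == pytest.approx(sl, abs=1e-8)
        assert res.params["Intercept"] == pytest.approx(
            np.log(truth["cv_means"]["LA"]) - 90 * sl, abs=1e-7
        )
        for lv in ("LV", "RA", "RV"):
            assert res.params[f"C(chamber)[T.{lv}]"] == pytest.approx(
                np.log(truth["cv_means"][lv] / truth["cv_means"]["LA"]), abs=1e-7
            )
        assert res.singular  # zero planted animal variance

    def test_one_group_flags_singular(self):
        tab, _ = noiseless_table(n_animals=1)
        res = fit_mixed_model(tab, "va")
        assert res.singular
        assert res.n_groups == 1

    def test_rank_deficient_design_raises(self):
        tab, _ = noiseless_table()
        tab["heart_rate"] = 100.0  # confounded constant column
        with pytest.raises(IdentifiabilityError):
            fit_mixed_model(tab, "log_cv")

    def test_log_cv_requires_positive_cv(self):
        tab, _ = noiseless_table()
        tab.loc[0, "cv"] = -0.1
        with pytest.raises(ValueError, match="cv > 0"):
            fit_mixed_model(tab, "log_cv")

    def test_invalid_rows_never_enter_model(self):
        tab, _ = noiseless_table()
        spoiled = tab.copy()
        bad = spoiled.sample(40, random_state=0).index
        spoiled.loc[bad, "cv"] = 50.0
        spoiled.loc[bad, "valid"] = False
        a = fit_mixed_model(tab, "log_cv")
        b = fit_mixed_model(spoiled, "log_cv")
        pd.testing.assert_series_equal(
            a.params, b.params, rtol=1e-6, check_names=False
        )


class TestEmm:
    def test_intercept_only_equals_grand_mean(self):
        rng = np.random.default_rng(5)
        n = 300
        tab = pd.DataFrame(
            {
                "animal_id": rng.choice(list("abc"), n),
                "chamber": "LA",
                "heart_rate": rng.uniform(80, 100, n).round(),
                "sex": "female",
                "map_id": "m",
                "cv": np.exp(rng.normal(0.2, 0.1, n)),
                "va": rng.uniform(2, 8, n),
                "valid": True,
            }
        )
        res = fit_mixed_model(tab, "va")
        emm = emm_at(res, heart_rate=90.0)
        # random-intercept model: EMM is the (shrunken) grand mean;
        # balanced-ish groups keep it close to the raw mean
        assert emm["estimate"].iloc[0] == pytest.approx(tab["va"].mean(), rel=0.01)

    def test_zero_slope_makes_emms_rate_invariant(self):
        tab, _ = noiseless_table(slope=0.0)
        res = fit_mixed_model(tab, "log_cv")
        with pytest.warns(RuntimeWarning, match="outside the observed range"):
            e60 = emm_at(res, heart_rate=60.0)  # deliberate extrapolation
        e90 = emm_at(res, heart_rate=90.0)
        assert np.allclose(e60["estimate"], e90["estimate"], rtol=1e-8)

    def test_back_transform_identity(self):
        tab, _ = noiseless_table()
        res = fit_mixed_model(tab, "log_cv")
        emm = emm_at(res)
        assert np.allclose(np.exp(emm["link_estimate"]), emm["estimate"], rtol=1e-12)
        assert (emm["estimate"] > 0).all()
        assert np.allclose(emm["se"], emm["estimate"] * emm["link_se"], rtol=1e-12)

    def test_extrapolation_warns(self):
        tab, _ = noiseless_table()
        res = fit_mixed_model(tab, "log_cv")
        with pytest.warns(RuntimeWarning, match="outside the observed range"):
            emm_at(res, heart_rate=300.0)

    def test_noiseless_emms_hit_planted_chamber_means(self):
        planted = {"LA": 0.79, "LV": 0.59, "RV": 0.54, "RA": 0.50}
        tab, _ = noiseless_table(cv_means=planted)
        res = fit_mixed_model(tab, "log_cv")
        emm = emm_at(res, heart_rate=90.0)
        for _, row in emm.iterrows():
            assert row["estimate"] == pytest.approx(planted[row["chamber"]], rel=1e-6)


class TestContrasts:
    def test_all_pairs_row_count(self):
        tab, _ = noiseless_table()
        res = fit_mixed_model(tab, "log_cv")
        ct = pairwise_contrasts(res)
        assert len(ct) == 6  # k=4 -> k(k-1)/2
        assert set(ct["adjust"]) == {"tukey"}

    def test_ratio_equals_exp_of_link_difference(self):
        tab, _ = noiseless_table()
        res = fit_mixed_model(tab, "log_cv")
        ct = pairwise_contrasts(res)
        assert np.allclose(np.exp(ct["link_estimate"]), ct["estimate"], rtol=1e-12)

    def test_adjusted_p_dominates_raw_and_capped(self):
        tab, truth = noiseless_table()
        rng = np.random.default_rng(2)
        tab["cv"] *= np.exp(rng.normal(0, 0.2, len(tab)))
        res = fit_mixed_model(tab, "log_cv")
        for which, adj in (("all_pairs", "tukey"), ([("LA", "RA"), ("LV", "RV")], "sidak")):
            ct = pairwise_contrasts(res, which=which, adjust=adj)
            assert (ct["p_adj"] >= ct["p_raw"] - 1e-12).all()
            assert (ct["p_adj"] <= 1.0).all()

    def test_sidak_matches_closed_form(self):
        tab, _ = noiseless_table()
        rng = np.random.default_rng(3)
        tab["cv"] *= np.exp(rng.normal(0, 0.2, len(tab)))
        res = fit_mixed_model(tab, "log_cv")
        pairs = [("LA", "LV"), ("RA", "RV"), ("LA", "RA")]
        ct = pairwise_contrasts(res, which=pairs, adjust="sidak")
        m = len(pairs)
        assert np.allclose(ct["p_adj"], 1 - (1 - ct["p_raw"]) ** m, rtol=1e-12)
        assert sidak_adjust(0.02, 3) == pytest.approx(1 - 0.98**3)

    def test_null_groups_give_ratio_one_large_p(self):
        """Two identical chambers: ratio ~ 1, Tukey p deep in the null."""
        rng = np.random.default_rng(11)
        rows = []
        for i, a in enumerate("abcd"):
            for c in ("LA", "LV"):
                mu = 0.7  # identical truth
                for _ in range(500):
                    rows.append(
                        {"animal_id": a, "chamber": c, "heart_rate": 85.0 + 4 * i,
                         "sex": "female", "map_id": f"{a}{c}",
                         "cv": mu * np.exp(rng.normal(0, 0.1)),
                         "va": 5.0, "valid": True}
                    )
        res = fit_mixed_model(pd.DataFrame(rows), "log_cv")
        ct = pairwise_contrasts(res)
        assert ct["estimate"].iloc[0] == pytest.approx(1.0, abs=0.02)
        assert ct["p_adj"].iloc[0] > 0.05  # non-significant under the null
        assert ct["p_adj"].iloc[0] >= ct["p_raw"].iloc[0]

    def test_targeted_default_is_sidak(self):
        tab, _ = noiseless_table()
        res = fit_mixed_model(tab, "log_cv")
        ct = pairwise_contrasts(res, which=[("LA", "RA")])
        assert set(ct["adjust"]) == {"sidak"}


class TestPearson:
    @staticmethod
    def frame(cv, va, chamber="LA"):
        return pd.DataFrame(
            {"cv": cv, "va": va, "chamber": chamber, "valid": True}
        )

    def test_exact_linear_data(self):
        cv = np.linspace(0.2, 1.5, 30)
        res = pearson_correlation(self.frame(cv, 2 + 3 * cv))
        assert res.r == pytest.approx(1.0)
        assert res.df == 28

    def test_bivariate_normal_within_fisher_ci(self):
        """Sampled r at rho=0.30, n=410 must fall inside the exact
        Fisher-z 95% interval around the estimate."""
        rho, n = 0.30, 410
        rng = np.random.default_rng(2024)
        xy = rng.multivariate_normal([0.8, 6.0], [[1, rho], [rho, 1]], size=n)
        res = pearson_correlation(self.frame(xy[:, 0] - xy[:, 0].min() + 0.1, xy[:, 1]))
        z = np.arctanh(res.r)
        half = 1.959964 / np.sqrt(n - 3)
        assert np.tanh(z - half) < rho < np.tanh(z + half)
        assert res.df == n - 2

    def test_interpretation_band(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=400)
        weak = pearson_correlation(self.frame(x + 3, 0.05 * x + rng.normal(size=400)))
        assert abs(weak.r) < 0.2
        assert weak.interpretation == "no linear correlation"
        strong = pearson_correlation(self.frame(x + 3, 0.5 * x + rng.normal(size=400)))
        assert "positive linear correlation" in strong.interpretation

    def test_cv_cap_filters_before_correlating(self):
        cv = np.array([0.5, 0.7, 1.0, 1.4, 2.0, 3.0])
        va = np.array([3.0, 4.0, 5.0, 6.0, 1.0, 0.5])
        res = pearson_correlation(self.frame(cv, va), cv_cap=1.5)
        assert res.n == 4
        assert res.df == 2
        assert res.r == pytest.approx(1.0, abs=0.02)

    def test_scope_restricts_to_chamber(self):
        d = pd.concat(
            [self.frame(np.linspace(0.2, 1, 20), np.linspace(1, 9, 20), "LA"),
             self.frame(np.linspace(0.2, 1, 20), np.linspace(9, 1, 20), "RV")]
        )
        assert pearson_correlation(d, scope="LA").r == pytest.approx(1.0)
        assert pearson_correlation(d, scope="RV").r == pytest.approx(-1.0)

    def test_constant_input_and_small_n_raise(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation(self.frame([1, 2, 3], [5, 5, 5]))
        with pytest.raises(ValueError, match="at least 3"):
            pearson_correlation(self.frame([1, 2], [3, 4]))


class TestSexEffect:
    def test_large_planted_effect_detected(self):
        design = pd.DataFrame(
            [
                {"animal_id": str(a), "chamber": c, "heart_rate": 88.0 + 5 * a + (c == "RA") * 9,
                 "map_id": f"{a}{c}", "sex": "male" if a % 2 else "female"}
                for a in range(6)
                for c in ("LA", "RA")
            ]
        )
        tab, _ = sample_measurement_table(
            design=design, circles_per_map=40, sex_effect_va=10.0,
            animal_sd_va=0.3, resid_sd_va=1.0, seed=42,
        )
        p, res = sex_effect_test(tab, "va")
        assert p < 0.001

    def test_null_effect_p_not_degenerate(self):
        design = pd.DataFrame(
            [
                {"animal_id": str(a), "chamber": c, "heart_rate": 88.0 + 5 * a + (c == "RA") * 9,
                 "map_id": f"{a}{c}", "sex": "male" if a % 2 else "female"}
                for a in range(6)
                for c in ("LA", "RA")
            ]
        )
        tab, _ = sample_measurement_table(design=design, circles_per_map=40, seed=9)
        p, _ = sex_effect_test(tab, "log_cv")
        assert 0.0 < p <= 1.0

    def test_null_p_values_roughly_uniform(self):
        """With no planted sex effect, animal-level df keep the test
        honest: p-values over replications pass a KS uniformity check."""
        design = pd.DataFrame(
            [
                {"animal_id": str(a), "chamber": c, "heart_rate": hr + 4 * a,
                 "map_id": f"{a}{c}", "sex": "male" if a % 2 else "female"}
                for a in range(8)
                for c, hr in (("LA", 85), ("RA", 110))
            ]
        )
        ps = []
        for rep in range(120):
            tab, _ = sample_measurement_table(
                design=design, circles_per_map=10, animal_sd_log_cv=0.08,
                resid_sd_log_cv=0.25, seed=50_000 + rep,
            )
            ps.append(sex_effect_test(tab, "log_cv")[0])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_single_sex_raises(self):
        tab, _ = noiseless_table()
        tab["sex"] = "female"
        with pytest.raises(IdentifiabilityError, match="both sexes"):
            sex_effect_test(tab, "va")
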