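import math

import numpy as np
import pytest

import shoalmix as sm
from shoalmix.errors import DomainError, FittingError
from shoalmix.foraging import build_design_matrix

CAT = sm.BALANCED_CATALOG


def simulate_records(n=500, seed=0, params=None, design_seed=None):
    params = params or sm.default_foraging_params()
    design = sm.balanced_design(n, seed=seed if design_seed is None else design_seed)
    return sm.generate_foraging_observations(params, design, seed=seed)


@pytest.fixture(scope="module")
def sim_fit():
    records = simulate_records(n=600, seed=21)
    fit = sm.fit_tweedie_glm(records, CAT)
    return records, fit


class TestIRLSFit:
    def test_constant_response_recovers_log_intercept(self, foraging_record, catalog):
        # constant 30 bites/min over varied covariates: the unique perfect fit
        # is intercept = log 30 with every other coefficient zero
        records = []
        rng = np.random.default_rng(1)
        for i in range(40):
            records.append(
                foraging_record(
                    individual_id=f"f{i}",
                    species=["sp1", "sp3"][i % 2],
                    shoal_type=["mono_specific", "multi_specific"][(i // 2) % 2],
                    shoal_size=int(rng.integers(2, 20)),
                    length_cm=float(rng.uniform(12, 30)),
                    duration_s=60.0,
                    n_bites=30,
                    n_bouts=5,
                )
            )
        fit = sm.fit_tweedie_glm(records, catalog)
        assert fit.coefficients["intercept"] == pytest.approx(math.log(30), abs=1e-8)
        for term, value in fit.coefficients.items():
            if term != "intercept":
                assert value == pytest.approx(0.0, abs=1e-8)

    def test_fit_is_deterministic(self, sim_fit):
        records, fit = sim_fit
        again = sm.fit_tweedie_glm(records, CAT)
        assert fit.coefficients == again.coefficients
        assert fit.deviance == again.deviance

    def test_matches_statsmodels_tweedie_glm(self, sim_fit):
        import statsmodels.api as sms

        records, _ = sim_fit
        fit = sm.fit_tweedie_glm(records, CAT, tol=1e-12, max_iter=200)
        y = np.array([sm.compute_rates(r)[0] for r in records])
        x, _ = build_design_matrix(records, CAT, fit.design)
        ref = sms.GLM(
            y,
            x,
            family=sms.families.Tweedie(
                link=sms.families.links.Log(), var_power=1.5
            ),
        ).fit(scale="X2", maxiter=300, tol=1e-12)
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.vcov)), ref.bse, rtol=1e-4
        )
        assert fit.dispersion == pytest.approx(ref.scale, rel=1e-4)

    def test_gamma_limit_matches_gamma_glm(self):
        import statsmodels.api as sms

        records = [
            r for r in simulate_records(n=400, seed=3) if r.n_bites > 0
        ]
        fit = sm.fit_tweedie_glm(records, CAT, power=2.0, tol=1e-12, max_iter=200)
        y = np.array([sm.compute_rates(r)[0] for r in records])
        x, _ = build_design_matrix(records, CAT, fit.design)
        ref = sms.GLM(
            y, x, family=sms.families.Gamma(link=sms.families.links.Log())
        ).fit(scale="X2", maxiter=300, tol=1e-12)
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-5, atol=1e-7)

    def test_score_equation_at_convergence(self, sim_fit):
        """At the optimum the working score Σ w (y−μ)/μ^{p−1} is zero."""
        records, fit = sim_fit
        y = np.array([sm.compute_rates(r)[0] for r in records])
        x, _ = build_design_matrix(records, CAT, fit.design)
        mu = np.exp(x @ fit.beta)
        score = (y - mu) / mu ** (fit.power - 1.0)
        assert abs(score.sum()) < 1e-6 * y.sum()

    def test_nested_model_never_has_lower_deviance(self, sim_fit):
        records, fit = sim_fit
        reduced = sm.fit_tweedie_glm(
            records, CAT, design=sm.DesignSpec(three_way=False)
        )
        assert fit.deviance <= reduced.deviance + 1e-8

    def test_rank_deficient_design_reports_aliased_terms(self, foraging_record, catalog):
        records = [
            foraging_record(individual_id=f"f{i}", shoal_size=5, length_cm=20.0)
            for i in range(30)
        ]  # every record mono-specific and native: type/interaction columns aliased
        with pytest.raises(FittingError, match="aliased"):
            sm.fit_tweedie_glm(records, catalog)

    def test_invalid_power_rejected(self, sim_fit):
        records, _ = sim_fit
        with pytest.raises(DomainError):
            sm.fit_tweedie_glm(records, CAT, power=2.5)


class TestProfilePower:
    def test_degenerate_grid_returns_single_point(self):
        records = simulate_records(n=200, seed=5)
        best, profile = sm.profile_power(records, CAT, grid=[1.4])
        assert best == 1.4
        assert len(profile) == 1

    def test_objective_finite_with_zero_responses(self):
        # low mean and high dispersion put substantial Tweedie mass at zero
        params = sm.ForagingSimParams(
            beta={"intercept": math.log(2.0)}, dispersion=2.0
        )
        records = simulate_records(n=200, seed=6, params=params)
        assert any(r.n_bites == 0 for r in records)
        _, profile = sm.profile_power(
            records, CAT, grid=[1.2, 1.5, 1.8]
        )
        assert np.isfinite(profile.eql).all()

    def test_orders_low_vs_high_power_data(self):
        """Data generated at p=1.3 should profile below data generated at
        p=1.7 in at least 90% of replicates."""
        correct = 0
        n_rep = 50
        for s in range(n_rep):
            fits = []
            for p_true, offset in [(1.3, 0), (1.7, 10_000)]:
                params = sm.ForagingSimParams(
                    beta=dict(sm.default_foraging_params().beta),
                    tweedie_power=p_true,
                    dispersion=1.2,
                )
                records = simulate_records(
                    n=1500, seed=s + offset, params=params, design_seed=s
                )
                best, _ = sm.profile_power(
                    records,
                    CAT,
                    grid=[1.2, 1.35, 1.5, 1.65, 1.8],
                )
                fits.append(best)
            correct += fits[0] < fits[1]
        assert correct >= 0.9 * n_rep


class TestGroupSlopes:
    def test_requires_three_way_design(self):
        records = simulate_records(n=300, seed=8)
        fit = sm.fit_tweedie_glm(
            records, CAT, design=sm.DesignSpec(three_way=False)
        )
        with pytest.raises(DomainError):
            sm.group_slopes_and_contrasts(fit)

    def test_slope_map_is_linear_combination_of_coefficients(self, sim_fit):
        _, fit = sim_fit
        res = sm.group_slopes_and_contrasts(fit)
        b = fit.coefficients
        expected = {
            "range_extending/mono_specific": b["shoal_size"],
            "range_extending/multi_specific": b["shoal_size"]
            + b["shoal_type[multi_specific]:shoal_size"],
            "native/mono_specific": b["shoal_size"]
            + b["origin[native]:shoal_size"],
            "native/multi_specific": b["shoal_size"]
            + b["origin[native]:shoal_size"]
            + b["shoal_type[multi_specific]:shoal_size"]
            + b["origin[native]:shoal_type[multi_specific]:shoal_size"],
        }
        got = dict(zip(res.slopes.cell, res.slopes.slope))
        for cell, val in expected.items():
            assert got[cell] == pytest.approx(val)

    def test_no_interaction_null_keeps_contrasts_quiet(self):
        """With identical slopes in every cell, slope-difference contrasts
        should be non-significant in ≥ 90% of replicates (Tukey controls the
        familywise error at 5%)."""
        beta = dict(sm.default_foraging_params().beta)
        for term in list(beta):
            if "shoal_size" in term and term != "shoal_size":
                beta[term] = 0.0
        beta["shoal_size"] = 0.02
        params = sm.ForagingSimParams(beta=beta, dispersion=1.2)
        quiet = 0
        n_rep = 50
        for s in range(n_rep):
            records = simulate_records(n=600, seed=s, params=params)
            fit = sm.fit_tweedie_glm(records, CAT)
            res = sm.group_slopes_and_contrasts(fit)
            quiet += (res.slope_contrasts.p_tukey >= 0.05).all()
        assert quiet >= 0.9 * n_rep

    def test_rate_ratios_exponentiate_predictor_differences(self, sim_fit):
        _, fit = sim_fit
        res = sm.group_slopes_and_contrasts(fit, at_shoal_size=3)
        for _, row in res.rate_ratios.iterrows():
            assert row.ratio == pytest.approx(math.exp(row.estimate))
            assert row.ratio > 0


class TestSummaries:
    def test_hand_computed_mean_and_se(self, foraging_record, catalog):
        records = [
            foraging_record(individual_id="a", n_bites=10, n_bouts=2, duration_s=60.0),
            foraging_record(individual_id="b", n_bites=30, n_bouts=6, duration_s=60.0),
        ]
        table = sm.summarize_rates(records, catalog)
        row = table[table.origin == "native"].iloc[0]
        assert row.bite_rate_mean == pytest.approx(20.0)
        assert row.bite_rate_se == pytest.approx(10.0)

    def test_constant_rates_have_zero_se(self, foraging_record, catalog):
        records = [
            foraging_record(individual_id=f"x{i}", n_bites=12, n_bouts=3)
            for i in range(5)
        ]
        table = sm.summarize_rates(records, catalog)
        assert table.bite_rate_se.iloc[0] == 0.0
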