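"""Estimator suite: regression fits, Cochran's Q, contrasts, diagnostics."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proxymr import (
    SimulationConfig,
    StratumEstimate,
    cochran_q,
    confounder_scan,
    difference_of_differences,
    fit_association,
    generate_cohort,
    stratify_and_fit,
    stratum_difference,
)


def _make_estimate(beta, se, family="linear", label="", n=100):
    return StratumEstimate(
        stratum_label=label,
        n=n,
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        p=2 * stats.norm.sf(abs(beta / se)) if se > 0 else np.nan,
        family=family,
    )


class TestFitAssociation:
    def test_noiseless_linear(self):
        x = np.array([0, 1, 2, 0, 1, 2], float)
        est = fit_association(2 * x, x, None, "linear")
        assert est.beta == pytest.approx(2.0, abs=1e-10)
        assert est.se == pytest.approx(0.0, abs=1e-8)

    def test_six_row_toy_slope(self):
        # hand normal equations: slope = 2.0 / 4 = 0.5
        x = [0, 0, 1, 1, 2, 2]
        y = [1.0, 1.2, 1.5, 1.7, 2.0, 2.2]
        est = fit_association(y, x, None, "linear")
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_logistic_matches_contingency_table(self):
        # cells (a,b,c,d) = (30,70,50,50): beta = ln(30*50 / (70*50))
        exposure = np.r_[np.ones(100), np.zeros(100)]
        outcome = np.r_[np.ones(30), np.zeros(70), np.ones(50), np.zeros(50)]
        est = fit_association(outcome, exposure, None, "logistic")
        assert est.beta == pytest.approx(np.log(30 * 50 / (70 * 50)), abs=1e-6)
        assert est.odds_ratio == pytest.approx(3 / 7, abs=1e-6)

    def test_linear_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = 50
            X = rng.standard_normal((n, 3))
            y = rng.standard_normal(n)
            est = fit_association(y, X[:, 0], X[:, 1:], "linear")
            design = np.column_stack([np.ones(n), X])
            beta_hat = np.linalg.solve(design.T @ design, design.T @ y)
            assert abs(est.beta - beta_hat[1]) <= 1e-8 * max(1.0, abs(beta_hat[1]))

    def test_ordinal_recovers_sign_and_scale(self, rng):
        n = 4000
        x = rng.integers(0, 3, n).astype(float)
        latent = 0.5 * x + stats.logistic.rvs(size=n, random_state=rng)
        y = np.digitize(latent, [-1.0, 0.5, 2.0, 3.5])
        est = fit_association(y, x, None, "ordinal")
        assert est.converged
        assert abs(est.beta - 0.5) < 4 * est.se

    def test_constant_exposure_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_association([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], None, "linear")

    def test_non_binary_outcome_rejected_for_logistic(self):
        with pytest.raises(ValueError):
            fit_association([0, 1, 2, 1, 0], [0, 1, 0, 1, 0], None, "logistic")

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="parameter count"):
            fit_association([1.0, 2.0], [0.0, 1.0], None, "linear")

    def test_separation_flagged_not_raised(self):
        x = np.r_[np.zeros(30), np.ones(30)]
        est = fit_association(x.copy(), x, None, "logistic")
        assert not est.converged
        assert est.note != ""


class TestCochranQ:
    def test_identical_estimates_give_zero(self):
        a = _make_estimate(0.5, 0.1)
        res = cochran_q([a, a])
        assert res.q_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_two_strata(self):
        res = cochran_q([_make_estimate(1.0, 1.0), _make_estimate(-1.0, 1.0)])
        assert res.q_stat == pytest.approx(2.0, abs=1e-12)
        assert res.df == 1
        assert res.p == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-12)
        assert res.p == pytest.approx(0.15730, abs=5e-6)

    def test_q_equals_z_squared_for_two_strata(self, rng):
        for _ in range(200):
            a = _make_estimate(rng.normal(), rng.uniform(0.05, 2))
            b = _make_estimate(rng.normal(), rng.uniform(0.05, 2))
            q = cochran_q([a, b])
            d = stratum_difference(a, b)
            assert q.q_stat == pytest.approx(d.z**2, rel=1e-12)
            assert q.p == pytest.approx(d.p, rel=1e-12)

    def test_shift_invariance_and_quadratic_scaling(self, rng):
        ests = [_make_estimate(rng.normal(), rng.uniform(0.1, 1)) for _ in range(5)]
        q0 = cochran_q(ests).q_stat
        shifted = [_make_estimate(e.beta + 3.7, e.se) for e in ests]
        assert cochran_q(shifted).q_stat == pytest.approx(q0, rel=1e-10)
        scaled = [_make_estimate(2.5 * e.beta, e.se) for e in ests]
        assert cochran_q(scaled).q_stat == pytest.approx(2.5**2 * q0, rel=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cochran_q([_make_estimate(1.0, 1.0)])
        with pytest.raises(ValueError):
            cochran_q([_make_estimate(1.0, 0.0), _make_estimate(1.0, 1.0)])


class TestContrasts:
    def test_identical_estimates_null_difference(self):
        a = _make_estimate(0.3, 0.2)
        d = stratum_difference(a, a)
        assert d.delta == 0 and d.p == pytest.approx(1.0)

    def test_difference_arithmetic(self):
        d = stratum_difference(_make_estimate(0.5, 0.3), _make_estimate(0.1, 0.4))
        assert d.delta == pytest.approx(0.4)
        assert d.se == pytest.approx(0.5)
        assert d.z == pytest.approx(0.8)
        assert d.p == pytest.approx(0.4237, abs=1e-4)
        assert d.ci_high - d.ci_low == pytest.approx(2 * 1.96 * d.se)

    def test_family_mismatch_rejected(self):
        with pytest.raises(ValueError, match="famil"):
            stratum_difference(
                _make_estimate(0.1, 0.1, "linear"), _make_estimate(0.1, 0.1, "logistic")
            )

    def test_difference_of_differences_arithmetic(self):
        d1 = stratum_difference(_make_estimate(-0.4, 0.18), _make_estimate(0.0, 0.24))
        d2 = stratum_difference(_make_estimate(0.2, 0.3), _make_estimate(0.0, 0.2646))
        dod = difference_of_differences(d1, d2)
        assert dod.delta == pytest.approx(d1.delta - d2.delta)
        # variance is the sum of all four stratum variances
        assert dod.se**2 == pytest.approx(
            0.18**2 + 0.24**2 + 0.3**2 + 0.2646**2, rel=1e-12
        )

    def test_difference_of_differences_example(self):
        from proxymr import DifferenceEstimate

        d1 = DifferenceEstimate(-0.4, 0.3, -0.988, 0.188, -4 / 3, 0.18)
        d2 = DifferenceEstimate(0.2, 0.4, -0.584, 0.984, 0.5, 0.617)
        dod = difference_of_differences(d1, d2)
        assert dod.delta == pytest.approx(-0.6)
        assert dod.se == pytest.approx(0.5)
        assert dod.z == pytest.approx(-1.2)


class TestStratifyAndFit:
    def test_two_by_two_partition(self, default_cohort):
        estimates = stratify_and_fit(
            default_cohort,
            "g1_birthweight_kg",
            ["g0_preg_smoker", "g1_ever"],
            "linear",
        )
        assert len(estimates) == 4
        assert sum(e.n for e in estimates) == len(default_cohort)
        labels = {e.stratum_label for e in estimates}
        assert "g0_preg_smoker=0,g1_ever=0" in labels

    def test_small_strata_skipped(self, default_cohort, caplog):
        tiny = default_cohort.head(60).copy()
        tiny["flag"] = [0] * 55 + [1] * 5
        with caplog.at_level("WARNING", logger="proxymr.estimate"):
            estimates = stratify_and_fit(
                tiny, "g1_birthweight_kg", ["flag"], "linear", min_n=50
            )
        assert len(estimates) == 1
        assert any("skipped" in r.message for r in caplog.records)

    def test_missing_column_raises(self, default_cohort):
        with pytest.raises(KeyError):
            stratify_and_fit(default_cohort, "no_such_outcome", ["g0_preg_smoker"])

    def test_implanted_effect_recovered_in_exposed_stratum(self):
        # gene->cigs 1/day/allele, cigs->bw -0.02 kg/day: direct slope about
        # -0.02 kg/allele among exposed, null among unexposed; proxy halves it
        config = SimulationConfig(
            n_families=200_000, seed=31, adult_outcome_specs=(), include_g2=False
        )
        cohort = generate_cohort(config)
        direct = stratify_and_fit(
            cohort, "g1_birthweight_kg", ["g0_preg_smoker"], "linear",
            exposure_col="g0_dosage",
        )
        proxy = stratify_and_fit(
            cohort, "g1_birthweight_kg", ["g0_preg_smoker"], "linear",
            exposure_col="g1_dosage",
        )
        by_label = {e.stratum_label: e for e in direct}
        assert abs(by_label["g0_preg_smoker=1"].beta - (-0.02)) < 3 * by_label[
            "g0_preg_smoker=1"
        ].se
        assert abs(by_label["g0_preg_smoker=0"].beta) < 3 * by_label[
            "g0_preg_smoker=0"
        ].se
        proxy_exposed = {e.stratum_label: e for e in proxy}["g0_preg_smoker=1"]
        assert abs(proxy_exposed.beta - (-0.01)) < 3 * proxy_exposed.se


class TestConfounderScan:
    def test_constant_variable_rejected(self, default_cohort):
        df = default_cohort.head(500).copy()
        df["constant"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            confounder_scan(df, "g1_dosage", ["constant"])

    def test_unknown_variable_lists_available(self, default_cohort):
        with pytest.raises(KeyError, match="available"):
            confounder_scan(default_cohort, "g1_dosage", ["nonexistent"])

    def test_gene_smoking_association_detected_when_implanted(self):
        config = SimulationConfig(
            n_families=150_000, seed=41, or_gene_smoker=1.25,
            adult_outcome_specs=(), include_g2=False,
        )
        cohort = generate_cohort(config)
        (est,) = confounder_scan(cohort, "g1_dosage", ["g0_preg_smoker"])
        assert est.family == "logistic"
        assert est.beta > 0 and est.beta / est.se > 3

    def test_null_scan_pvalues_uniform(self):
        # independent confounders: p-values approximately U(0,1) over replicates
        pvals = []
        for seed in range(300):
            config = SimulationConfig(
                n_families=2_000, seed=5_000 + seed,
                adult_outcome_specs=(), include_g2=False,
            )
            cohort = generate_cohort(config)
            ests = confounder_scan(cohort, "g1_dosage", ["confounder", "pc1", "g1_age"])
            pvals.extend(e.p for e in ests)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
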