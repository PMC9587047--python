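"""Dose-effect mixed models: covariate, candidate fits, AIC selection."""

import numpy as np
import pandas as pd
import pytest

from gillwave.errors import DomainError, SectionError
from gillwave.mixedmodel import (
    LMMSpec,
    RANDOM_TERMS,
    fit_candidate,
    log_concentration,
    piecewise_fit,
    report,
    select_model_aic,
    significance_stars,
)
from gillwave.synth import CohortSimSpec, gen_cohort_indices


class TestLogConcentration:
    def test_values(self):
        assert log_concentration(0.0) == 0.0
        assert log_concentration(100.0) == pytest.approx(4.6151, abs=1e-4)
        np.testing.assert_allclose(
            log_concentration(np.array([0.0, 1.0, 50.0, 100.0])),
            [0.0, 0.6931, 3.9318, 4.6151],
            atol=1e-4,
        )

    def test_log10_option(self):
        assert log_concentration(99.0, base="10") == pytest.approx(2.0)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            log_concentration(-1.0)


def line_table(beta0=2.0, beta1=0.5, noise_sd=0.0, seed=0, n_seg=24):
    rng = np.random.default_rng(seed)
    rows = []
    for d in (0.0, 1.0, 50.0, 100.0):
        C = log_concentration(d)
        for i in range(5):
            for s in range(n_seg):
                rows.append(
                    {
                        "individual_id": f"d{d:g}i{i}",
                        "concentration_mg_per_l": d,
                        "segment": s,
                        "value": beta1 * C + beta0 + noise_sd * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestFitCandidate:
    def test_noise_free_line_model1_exact(self):
        fit = fit_candidate(line_table(), LMMSpec(1))
        assert fit.beta1 == pytest.approx(0.5, abs=1e-8)
        assert fit.beta0 == pytest.approx(2.0, abs=1e-8)

    def test_model1_equals_closed_form_ols(self):
        table = line_table(noise_sd=0.7, seed=3)
        fit = fit_candidate(table, LMMSpec(1))
        C = log_concentration(table["concentration_mg_per_l"].to_numpy())
        X = np.column_stack([np.ones_like(C), C])
        beta = np.linalg.solve(X.T @ X, X.T @ table["value"].to_numpy())
        assert fit.beta0 == pytest.approx(beta[0], abs=1e-8)
        assert fit.beta1 == pytest.approx(beta[1], abs=1e-8)

    def test_aic_is_ml_based(self):
        fit = fit_candidate(line_table(noise_sd=0.5, seed=4), LMMSpec(2))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)

    def test_recovery_from_generating_structure(self):
        hits = 0
        for seed in range(10):
            table, truth = gen_cohort_indices(CohortSimSpec(seed=seed))
            # the dose-level variance is truly zero, so some fits sit on the
            # boundary; the fit is still returned and its CI is evaluated
            fit = fit_candidate(table, LMMSpec(6))
            if fit.ci1[0] <= truth["beta1"] <= fit.ci1[1]:
                hits += 1
        assert hits >= 8

    def test_confounded_terms_share_likelihood(self):
        # with one concentration per individual, "individual" and
        # "(concentration, individual)" random intercepts are the same
        # grouping, so models 2 and 5 are likelihood-equivalent
        table, _ = gen_cohort_indices(CohortSimSpec(seed=2))
        f2 = fit_candidate(table, LMMSpec(2))
        f5 = fit_candidate(table, LMMSpec(5))
        assert f2.loglik == pytest.approx(f5.loglik, abs=1e-6)

    def test_order_invariance(self):
        table, _ = gen_cohort_indices(CohortSimSpec(seed=7))
        fit = fit_candidate(table, LMMSpec(6))
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = fit_candidate(shuffled, LMMSpec(6))
        assert fit.beta1 == pytest.approx(fit2.beta1, abs=1e-10)
        assert fit.loglik == pytest.approx(fit2.loglik, abs=1e-8)

    def test_single_dose_rejected(self):
        table = line_table()
        with pytest.raises(SectionError):
            fit_candidate(table[table["concentration_mg_per_l"] == 0.0], LMMSpec(1))


class TestSelectModelAic:
    def test_aic_table_lists_all_candidates(self):
        table, _ = gen_cohort_indices(CohortSimSpec(seed=1))
        best, aic_table = select_model_aic(table)
        assert list(aic_table["model_id"]) == list(range(1, 9))
        assert best.converged

    def test_random_structure_preferred_when_present(self):
        preferred = 0
        for seed in range(10):
            table, _ = gen_cohort_indices(CohortSimSpec(seed=30 + seed))
            best, _ = select_model_aic(table)
            if best.spec.model_id != 1:
                preferred += 1
        assert preferred >= 9

    def test_no_random_effects_recovers_simple_model(self):
        # data generated without random intercepts: model 1's AIC must be
        # within 2 of the richest candidate (boundary-equivalent fits)
        table = line_table(noise_sd=0.8, seed=5)
        best, aic_table = select_model_aic(table)
        a = aic_table.set_index("model_id")["aic"]
        assert a[1] <= a.dropna().min() + 2.0


class TestPiecewise:
    def _humped(self, seed=0):
        # rises 0->1 mg/L, falls 1->100 mg/L (heartbeat-CV-like shape)
        rng = np.random.default_rng(seed)
        rows = []
        means = {0.0: 0.12, 1.0: 0.18, 50.0: 0.10, 100.0: 0.06}
        for d, mu in means.items():
            for i in range(5):
                for s in range(24):
                    rows.append(
                        {
                            "individual_id": f"d{d:g}i{i}",
                            "concentration_mg_per_l": d,
                            "segment": s,
                            "value": mu + 0.02 * rng.standard_normal(),
                        }
                    )
        return pd.DataFrame(rows)

    def test_opposite_slopes(self):
        fits = piecewise_fit(self._humped())
        low = fits[(0.0, 1.0)][0]
        high = fits[(1.0, 100.0)][0]
        assert low.beta1 > 0
        assert high.beta1 < 0

    def test_shared_boundary_dose(self):
        table = self._humped()
        fits = piecewise_fit(table)
        n_low = fits[(0.0, 1.0)][0].n_obs
        n_high = fits[(1.0, 100.0)][0].n_obs
        # the 1 mg/L dose belongs to both closed sections
        assert n_low + n_high == len(table) + (table["concentration_mg_per_l"] == 1.0).sum()

    def test_empty_section_rejected(self):
        table = self._humped()
        only_zero = table[table["concentration_mg_per_l"] == 0.0]
        with pytest.raises(SectionError):
            piecewise_fit(only_zero)


class TestReport:
    def test_significance_stars(self):
        assert significance_stars(0.03) == "*"
        assert significance_stars(8.47e-3) == "**"
        assert significance_stars(5e-4) == "***"
        assert significance_stars(0.2) == ""

    def test_report_rows(self):
        table, _ = gen_cohort_indices(CohortSimSpec(seed=3))
        best, _ = select_model_aic(table)
        df = report({"peak_frequency": best})
        assert list(df["metric"]) == ["peak_frequency"]
        row = df.iloc[0]
        assert row["ci_beta1_low"] <= row["beta1"] <= row["ci_beta1_high"]
        assert row["random_sd"] >= 0

    def test_empty_report(self):
        assert report({}).empty

    def test_random_terms_table_matches_model_ids(self):
        assert RANDOM_TERMS[1] == ()
        assert set(RANDOM_TERMS[8]) == {"C", "j", "Cj"}
        for mid, terms in RANDOM_TERMS.items():
            assert LMMSpec(mid).random_terms == terms
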