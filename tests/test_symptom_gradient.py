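"""Tests for M1/M2 regression, permutation, bootstrap, and profile tools."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inthier import (
    CohortSpec,
    bca_ci,
    diagnosis_overall_test,
    exemplary_profiles,
    fit_gradient_glm,
    fit_parcelwise_glm,
    gen_cohort,
    permutation_null_gradient,
    rank_binned_profile,
    rescale_panss,
    set_level_test,
)
from inthier.symptom_gradient import SYMPTOM_COLUMNS, _M2Engine, build_design


AUD_REF = {"symptom": "hallucinations", "system": "auditory"}


def tiny_cohort(n_patients=12, n_controls=0, seed=0, n_parcels=23):
    spec = CohortSpec(n_patients=n_patients, n_controls=n_controls,
                      n_parcels=n_parcels, seed=seed)
    return gen_cohort(spec)


class TestParcelwiseGlm:
    def test_matches_pseudoinverse_oracle(self, small_cohort):
        """Coefficients equal an independent normal-equation solve to 1e-8."""
        int_matrix, cohort, _ = small_cohort
        m1 = fit_parcelwise_glm(int_matrix, cohort, "M1_primary")
        x, rows = build_design(cohort, "M1_primary")
        xa = x.to_numpy(dtype=float)
        y = int_matrix.loc[rows].to_numpy()
        beta_oracle = np.linalg.pinv(xa.T @ xa) @ xa.T @ y
        np.testing.assert_allclose(m1.coefficients.to_numpy(), beta_oracle,
                                   atol=1e-8)
        assert m1.df_resid == xa.shape[0] - xa.shape[1]

    def test_planted_effect_dominates(self, rng):
        int_matrix, cohort, _ = tiny_cohort(n_patients=60, seed=5)
        y = int_matrix.copy()
        y["A1"] = 2.0 * cohort.loc[y.index, "hallucinations"] + 1e-6 * rng.standard_normal(len(y))
        m1 = fit_parcelwise_glm(y, cohort, "M1_primary")
        t_hall = abs(m1.tstats.loc["hallucinations", "A1"])
        others = m1.tstats.loc[[s for s in SYMPTOM_COLUMNS
                                if s != "hallucinations"], "A1"].abs()
        assert t_hall > 1e3
        assert (others < 10).all()

    def test_type_one_error_rate_near_nominal(self, rng):
        """INT independent of predictors: ~5% of |t| beyond the 0.975 quantile."""
        spec = CohortSpec(n_patients=80, n_controls=0, n_parcels=23, seed=11,
                          hallucination_effect=(0.0, 0.0),
                          delusion_effect=(0.0, 0.0))
        int_matrix, cohort, _ = gen_cohort(spec)
        noise = pd.DataFrame(rng.standard_normal((len(cohort), 100)),
                             columns=[f"n{i}" for i in range(100)])
        m1 = fit_parcelwise_glm(noise, cohort, "M1_primary")
        t_crit = stats.t.ppf(0.975, m1.df_resid)
        frac = (m1.tstats.loc[SYMPTOM_COLUMNS].abs() > t_crit).to_numpy().mean()
        assert 0.02 < frac < 0.09

    def test_rank_deficient_design_names_columns(self):
        int_matrix, cohort, _ = tiny_cohort(n_patients=30, seed=2)
        cohort = cohort.copy()
        cohort["alogia"] = cohort["blunted_affect"]  # exact duplicate
        with pytest.raises(ValueError, match="alogia"):
            fit_parcelwise_glm(int_matrix, cohort, "M1_primary")


class TestGradientGlm:
    def test_planted_opposed_gradients(self, hierarchies):
        """t = -level for hallucinations, +level for delusions, all systems:
        slopes are recovered exactly and the interaction dominates."""
        int_matrix, cohort, _ = tiny_cohort(n_patients=40, seed=1)
        m1 = fit_parcelwise_glm(int_matrix, cohort, "M1_primary")
        for system, ordering in hierarchies.items():
            for parcel, level in ordering.assignment:
                m1.tstats.loc["hallucinations", parcel] = -float(level)
                m1.tstats.loc["delusions", parcel] = float(level)
        m2 = fit_gradient_glm(m1, hierarchies, reference=AUD_REF)
        assert m2.params["level"] == pytest.approx(-1.0, abs=1e-10)
        assert m2.params["sym[delusions]:level"] == pytest.approx(2.0, abs=1e-10)
        assert m2.r_squared == pytest.approx(1.0)

    def test_constant_tvalues_zero_slopes(self, hierarchies):
        int_matrix, cohort, _ = tiny_cohort(n_patients=40, seed=1)
        m1 = fit_parcelwise_glm(int_matrix, cohort, "M1_primary")
        m1.tstats.loc["hallucinations"] = 0.7
        m1.tstats.loc["delusions"] = 0.7
        m2 = fit_gradient_glm(m1, hierarchies, reference=AUD_REF)
        for term, value in m2.params.items():
            expected = 0.7 if term == "Intercept" else 0.0
            assert value == pytest.approx(expected, abs=1e-10)

    def test_design_counts_and_df(self, small_cohort, hierarchies):
        """54 points, 12 coefficients, residual df 42; oracle coefficients."""
        int_matrix, cohort, _ = small_cohort
        m1 = fit_parcelwise_glm(int_matrix, cohort, "M1_primary")
        m2 = fit_gradient_glm(m1, hierarchies, reference=AUD_REF)
        assert m2.df_resid == 42
        assert m2.df_model == 11
        assert len(m2.params) == 12
        # independent normal-equation oracle on the same 54-point table
        from inthier.symptom_gradient import _m2_design, build_gradient_table

        table = build_gradient_table(m1, hierarchies)
        assert len(table) == 54
        x = _m2_design(table, "hallucinations", "auditory").to_numpy()
        beta = np.linalg.solve(x.T @ x, x.T @ table["t"].to_numpy())
        np.testing.assert_allclose(m2.params.to_numpy(), beta, atol=1e-8)

    def test_two_system_and_single_symptom_variants(self, small_cohort,
                                                    hierarchies):
        int_matrix, cohort, _ = small_cohort
        m1 = fit_parcelwise_glm(int_matrix, cohort, "M1_primary")
        two = {k: hierarchies[k] for k in ("auditory", "visual")}
        m2 = fit_gradient_glm(m1, two, reference=AUD_REF)
        assert len(m2.params) == 8  # 2 x 2 x 2 design
        m2_single = fit_gradient_glm(m1, hierarchies,
                                     symptoms=("hallucinations",),
                                     reference=AUD_REF)
        assert len(m2_single.params) == 6  # 1 x 2 x 3

    def test_missing_cell_lists_triple(self, small_cohort, hierarchies):
        int_matrix, cohort, _ = small_cohort
        m1 = fit_parcelwise_glm(int_matrix.drop(columns=["A4"]), cohort,
                                "M1_primary")
        with pytest.raises(ValueError, match="level 6, auditory"):
            fit_gradient_glm(m1, hierarchies, reference=AUD_REF)

    def test_cohens_f2_positive_for_strong_terms(self, cohort_default,
                                                 hierarchies):
        int_matrix, cohort, _ = cohort_default
        m1 = fit_parcelwise_glm(int_matrix, cohort, "M1_primary")
        m2 = fit_gradient_glm(m1, hierarchies, reference=AUD_REF)
        assert m2.f_squared["sym[delusions]:level"] > 0.1
        assert (m2.f_squared.drop("Intercept") >= 0).all()


class TestPermutation:
    def test_engine_matches_public_pipeline(self, small_cohort, hierarchies):
        int_matrix, cohort, _ = small_cohort
        from inthier.symptom_gradient import _pipeline_m2

        engine = _M2Engine(int_matrix, cohort, hierarchies,
                           ("hallucinations", "delusions"), AUD_REF)
        slow = _pipeline_m2(int_matrix, cohort, hierarchies,
                            ("hallucinations", "delusions"), AUD_REF)
        np.testing.assert_allclose(engine.tvalues(),
                                   slow.tvalues.to_numpy(), atol=1e-10)

    def test_planted_strong_effect_gets_minimal_p(self, hierarchies):
        """An interaction well beyond the null range earns the smallest
        attainable add-one p-value."""
        spec = CohortSpec(seed=7,
                          hallucination_effect=(0.05, -0.010),
                          delusion_effect=(-0.05, 0.010))
        int_matrix, cohort, _ = gen_cohort(spec)
        res = permutation_null_gradient(
            int_matrix, cohort, hierarchies,
            terms=["sym[delusions]:level"], n_perm=500, seed=3,
            reference=AUD_REF)
        assert res["p"]["sym[delusions]:level"] == pytest.approx(1 / 501)

    def test_null_draws_match_independent_refit(self, small_cohort,
                                                hierarchies):
        """Each stored null draw equals a from-scratch M1+M2 refit of the
        correspondingly shuffled cohort (slow-path oracle for the fast
        permutation engine)."""
        from inthier.symptom_gradient import _pipeline_m2

        int_matrix, cohort, _ = small_cohort
        n_perm, seed = 100, 17
        res = permutation_null_gradient(
            int_matrix, cohort, hierarchies, terms=["level"],
            n_perm=n_perm, seed=seed, reference=AUD_REF)
        # replay the implementation's permutation stream
        patients = cohort.index[cohort["diagnosis"].astype(int) == 1]
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(len(patients)) for _ in range(n_perm)]
        block = cohort.loc[patients, SYMPTOM_COLUMNS].to_numpy()
        for i in (0, 3, 57, 99):
            shuffled = cohort.copy()
            shuffled.loc[patients, SYMPTOM_COLUMNS] = block[perms[i]]
            oracle = _pipeline_m2(int_matrix, shuffled, hierarchies,
                                  ("hallucinations", "delusions"), AUD_REF)
            assert res["null_draws"]["level"].iloc[i] == pytest.approx(
                oracle.tvalues["level"], abs=1e-10)

    def test_joint_permutation_preserves_symptom_correlations(self,
                                                              cohort_default):
        int_matrix, cohort, _ = cohort_default
        patients = cohort[cohort["diagnosis"] == 1]
        block = patients[SYMPTOM_COLUMNS].to_numpy()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(block))
        corr_before = np.corrcoef(block.T)
        corr_after = np.corrcoef(block[perm].T)
        np.testing.assert_allclose(corr_before, corr_after, atol=1e-12)

    def test_identical_seed_identical_results(self, small_cohort, hierarchies):
        int_matrix, cohort, _ = small_cohort
        kwargs = dict(terms=["level"], n_perm=120, seed=42, reference=AUD_REF)
        a = permutation_null_gradient(int_matrix, cohort, hierarchies, **kwargs)
        b = permutation_null_gradient(int_matrix, cohort, hierarchies, **kwargs)
        assert a["p"]["level"] == b["p"]["level"]
        np.testing.assert_array_equal(a["null_draws"], b["null_draws"])


class TestSetLevelTest:
    def test_always_satisfied_predicate_p_near_one(self, rng):
        null = pd.DataFrame({"a": rng.standard_normal(500)})
        obs = pd.Series({"a": 3.0})
        pred = [{"terms": [("a", 1)], "min_count": 0}]
        res = set_level_test(null, obs, pred)
        assert res["p"] == pytest.approx(1.0, abs=0.01)

    def test_independent_terms_multiply(self, rng):
        """Joint sign-specific extremes of two independent nulls occur at
        roughly the product of the marginal rates."""
        n = 40_000
        null = pd.DataFrame({"a": rng.standard_normal(n),
                             "b": rng.standard_normal(n)})
        obs = pd.Series({"a": 5.0, "b": -5.0})
        pred = [{"terms": [("a", 1)], "min_count": 1},
                {"terms": [("b", -1)], "min_count": 1}]
        res = set_level_test(null, obs, pred)
        assert res["p"] == pytest.approx(0.025**2, rel=0.4)
        assert res["observed_satisfies"]

    def test_unknown_term_raises(self, rng):
        null = pd.DataFrame({"a": rng.standard_normal(100)})
        with pytest.raises(ValueError, match="unknown term"):
            set_level_test(null, pd.Series({"a": 1.0}),
                           [{"terms": [("zzz", 1)], "min_count": 1}])

    def test_auditory_predicate_on_planted_cohort(self, cohort_default,
                                                  hierarchies):
        """Negative hallucination gradient AND positive delusion gradient AND
        positive interaction, jointly rare under the permutation null."""
        int_matrix, cohort, _ = cohort_default
        res = permutation_null_gradient(
            int_matrix, cohort, hierarchies,
            terms=["level", "sym[delusions]:level"], n_perm=400, seed=5,
            reference=AUD_REF)
        predicate = [
            {"terms": [("level", -1)], "min_count": 1},
            {"terms": [("sym[delusions]:level", 1)], "min_count": 1},
        ]
        out = set_level_test(res["null_draws"],
                             res["observed"].tvalues, predicate)
        assert out["observed_satisfies"]
        assert out["p"] < 0.05


class TestBcaBootstrap:
    def test_symmetric_limit_matches_percentile(self, rng):
        """Unbiased symmetric bootstrap distribution: BCa ~ percentile."""
        from inthier.symptom_gradient import _bca_interval

        boot = rng.standard_normal(20_000)
        observed = float(np.median(boot))  # z0 ~ 0
        jack = rng.standard_normal(50) * 1e-3  # symmetric: a ~ 0
        lo, hi, degenerate = _bca_interval(boot, jack, observed)
        assert not degenerate
        assert lo == pytest.approx(np.quantile(boot, 0.025), abs=0.05)
        assert hi == pytest.approx(np.quantile(boot, 0.975), abs=0.05)

    def test_matches_scipy_bca_on_sample_mean(self, rng):
        """Textbook statistic (mean of a small fixed vector): our BCa
        machinery agrees with scipy.stats.bootstrap(method='BCa')."""
        from inthier.symptom_gradient import _bca_interval

        data = np.array([3.2, 1.7, 4.4, 2.9, 5.1, 2.2, 3.8, 4.0, 1.9, 3.5])
        n = data.size
        n_boot = 4000
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = data[idx].mean(axis=1)
        jack = np.array([np.delete(data, i).mean() for i in range(n)])
        lo, hi, _ = _bca_interval(boot, jack, float(data.mean()))

        ref = stats.bootstrap(
            (data,), np.mean, n_resamples=n_boot, method="BCa",
            confidence_level=0.95, random_state=np.random.default_rng(1),
            vectorized=False)
        assert lo == pytest.approx(ref.confidence_interval.low, abs=0.12)
        assert hi == pytest.approx(ref.confidence_interval.high, abs=0.12)

    def test_planted_interaction_excludes_zero(self, cohort_default,
                                               hierarchies):
        int_matrix, cohort, _ = cohort_default
        res = bca_ci(int_matrix, cohort, hierarchies,
                     terms=["sym[delusions]:level"], n_boot=400, seed=2,
                     reference=AUD_REF)
        lo, hi = res["ci"].loc["sym[delusions]:level"]
        assert lo > 0
        assert lo < res["observed"].tvalues["sym[delusions]:level"] < hi

    def test_degenerate_distribution_collapses_to_point(self):
        from inthier.symptom_gradient import _bca_interval

        lo, hi, degenerate = _bca_interval(np.full(300, 2.5), np.full(10, 2.5),
                                           2.5)
        assert degenerate and lo == hi == 2.5


class TestDiagnosisOverallTest:
    def test_global_patient_reduction_detected(self, hierarchies):
        spec = CohortSpec(n_patients=60, n_controls=60, n_parcels=40,
                          diagnosis_effect_pct=-5.0, seed=13)
        int_matrix, cohort, _ = gen_cohort(spec)
        res = diagnosis_overall_test(int_matrix, cohort, n_perm=200, seed=1)
        assert res["p"] < 0.05
        assert res["n_significant_parcels"] > res["n_parcels"] * 0.1
        assert res["n_negative"] >= res["n_significant_parcels"] * 0.9


class TestExemplaryProfiles:
    def test_zero_symptom_coefficients_zero_delta(self, small_cohort,
                                                  hierarchies):
        int_matrix, cohort, _ = small_cohort
        m1 = fit_parcelwise_glm(int_matrix, cohort, "M1_primary")
        m1.coefficients.loc["hallucinations"] = 0.0
        m1.coefficients.loc["delusions"] = 0.0
        prof = exemplary_profiles(m1, cohort, hierarchies["auditory"])
        np.testing.assert_allclose(prof.delta.to_numpy(), 0.0, atol=1e-12)

    def test_single_level_coefficient_scales_by_score(self, small_cohort,
                                                      hierarchies):
        """+0.02 s/point at level 1 only: ΔINT(hall case, level 1) = 0.10 s."""
        int_matrix, cohort, _ = small_cohort
        m1 = fit_parcelwise_glm(int_matrix, cohort, "M1_primary")
        m1.coefficients.loc["hallucinations"] = 0.0
        m1.coefficients.loc["delusions"] = 0.0
        m1.coefficients.loc["hallucinations", "A1"] = 0.02
        prof = exemplary_profiles(m1, cohort, hierarchies["auditory"])
        assert prof.delta.loc["hallucinations", 1] == pytest.approx(0.10)
        assert prof.delta.loc["hallucinations", 2:].abs().max() < 1e-12
        assert prof.delta.loc["delusions"].abs().max() < 1e-12

    def test_combined_case_is_additive(self, small_cohort, hierarchies):
        int_matrix, cohort, _ = small_cohort
        m1 = fit_parcelwise_glm(int_matrix, cohort, "M1_primary")
        prof = exemplary_profiles(m1, cohort, hierarchies["auditory"])
        np.testing.assert_allclose(
            prof.delta.loc["both"],
            prof.delta.loc["hallucinations"] + prof.delta.loc["delusions"],
            atol=1e-10)


class TestRankBinnedProfile:
    def test_600_voxels_10_bins(self, rng):
        t = rng.standard_normal(600)
        ref = rng.standard_normal(600)
        res = rank_binned_profile(t, ref, n_bins=10)
        assert res["voxels_per_bin"] == 60
        assert res["bin_means"].size == 10

    def test_constant_t_zero_slope(self, rng):
        res = rank_binned_profile(np.full(300, 1.3),
                                  rng.standard_normal(300), n_bins=10)
        np.testing.assert_allclose(res["bin_means"], 1.3)
        assert res["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_t_gives_monotone_bins(self, rng):
        ref = rng.standard_normal(500)
        t = 2.0 * ref + 0.5  # strictly monotone in the reference
        with pytest.warns(UserWarning, match="leftover"):
            res = rank_binned_profile(t, ref, n_bins=7)
        assert (np.diff(res["bin_means"]) > 0).all()
        assert res["slope"] > 0

    def test_more_bins_than_voxels_raises(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            rank_binned_profile(rng.standard_normal(5),
                                rng.standard_normal(5), n_bins=10)


class TestPanssRescaling:
    def test_shift_and_top_merge(self):
        panss = np.array([1, 2, 3, 4, 5, 6, 7])
        np.testing.assert_array_equal(rescale_panss(panss),
                                      [0, 1, 2, 3, 4, 5, 5])
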