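import numpy as np
import pytest
from scipy import stats

from fourierreg import (
    Constraint,
    DesignMatrix,
    EstimabilityError,
    FourierSpec,
    SpecificationError,
    assemble_design,
    constrained_fit,
    fit_ols,
    generate_dataset,
    hat_matrix,
    likelihood_ratio,
    partial_test,
    partial_test_all,
    quadratic_form_check,
    simultaneous_test,
)


class TestSimultaneous:
    def test_zero_projection_fails_to_reject(self, full_rank_model):
        model, ds = full_rank_model
        # make y orthogonal to the column space: delta_hat = 0, Lambda = 0
        U = hat_matrix(model.design)
        y_perp = (np.eye(model.n) - U) @ model.y
        m2 = fit_ols(model.design, y_perp)
        res = simultaneous_test(m2)
        assert abs(res.statistic) < 1e-8
        assert res.decision == "fail-to-reject"

    def test_paper_critical_value_configuration(self):
        # p=5, T=(1,2,4,3,5), n=38 -> df (21, 17), F crit 2.219 at alpha=0.05
        spec = FourierSpec(T=(1, 2, 4, 3, 5))
        ds = generate_dataset(38, spec, np.linspace(-1, 1, spec.L), 0.5, seed=8)
        model = fit_ols(assemble_design(ds.predictors, spec), ds.y)
        res = simultaneous_test(model, alpha=0.05)
        assert res.df == (21, 17)
        assert round(res.critical_value, 3) == 2.219

    def test_matches_dense_matrix_oracle(self, rank_deficient_model):
        model, ds = rank_deficient_model
        X = model.design.values
        d = np.linalg.lstsq(X, ds.y, rcond=None)[0]
        df1, df2 = model.design.rank, model.n - model.design.rank
        lam = ((X @ d) @ ds.y / df1) / (((ds.y - X @ d) @ (ds.y - X @ d)) / df2)
        res = simultaneous_test(model)
        assert res.statistic == pytest.approx(lam, rel=1e-10)
        assert res.p_value == pytest.approx(stats.f.sf(lam, df1, df2), rel=1e-10)

    def test_decision_consistency(self, rank_deficient_model):
        model, _ = rank_deficient_model
        res = simultaneous_test(model, alpha=0.05)
        assert (res.p_value < res.alpha) == (res.statistic > res.critical_value)
        assert 0.0 <= res.p_value <= 1.0


class TestConstrainedFit:
    def test_already_zero_collapses(self, full_rank_model):
        model, _ = full_rank_model
        zero_y = np.zeros(model.n)
        m0 = fit_ols(model.design, zero_y)
        cf = constrained_fit(m0, Constraint(2))
        np.testing.assert_allclose(cf.delta_omega, m0.delta_hat, atol=1e-12)
        assert cf.theta_hat == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("l", [0, 1, 2, 3, 4])
    def test_constraint_satisfied(self, full_rank_model, l):
        model, _ = full_rank_model
        cf = constrained_fit(model, Constraint(l))
        assert abs(cf.delta_omega[l]) < 1e-10

    def test_constrained_rss_never_below_unconstrained(self, rank_deficient_model):
        model, _ = rank_deficient_model
        for l in range(model.L):
            cf = constrained_fit(model, Constraint(l))
            assert cf.rss_omega >= model.rss - 1e-9
            assert cf.sigma2_omega == pytest.approx(cf.rss_omega / model.n)

    def test_column_deletion_oracle(self):
        # full-rank 15 x 4 instance: constraining delta_l = 0 equals refitting
        # with column l removed
        spec = FourierSpec(T=(2,))
        ds = generate_dataset(15, spec, np.array([0.8, -0.4, 1.1, 0.6]), 0.5, seed=17)
        design = assemble_design(ds.predictors, spec)
        model = fit_ols(design, ds.y)
        for l in range(4):
            cf = constrained_fit(model, Constraint(l))
            keep = [j for j in range(4) if j != l]
            sub = np.linalg.lstsq(design.values[:, keep], ds.y, rcond=None)[0]
            expected = np.zeros(4)
            expected[keep] = sub
            np.testing.assert_allclose(cf.delta_omega, expected, atol=1e-8)

    def test_unestimable_direction_rejected(self, full_rank_model):
        model, _ = full_rank_model
        design = model.design
        # append an all-zero column: its coefficient direction is not estimable
        padded = DesignMatrix(
            values=np.hstack([design.values, np.zeros((design.n, 1))]),
            spec=design.spec,
            blocks=design.blocks,
            labels=design.labels + ("zero",),
            rank=design.rank,
        )
        m2 = fit_ols(padded, model.y)
        with pytest.raises(EstimabilityError, match="not estimable"):
            constrained_fit(m2, Constraint(design.L))

    def test_bad_index(self, full_rank_model):
        model, _ = full_rank_model
        with pytest.raises(SpecificationError):
            constrained_fit(model, Constraint(model.L))
        with pytest.raises(SpecificationError):
            Constraint(-1)


class TestPartialTest:
    def test_zero_estimate_gives_zero_statistic(self, full_rank_model):
        model, _ = full_rank_model
        m0 = fit_ols(model.design, np.zeros(model.n))
        res = partial_test(m0, Constraint(1))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_paper_critical_value_r17(self):
        spec = FourierSpec(T=(1, 2, 4, 3, 5))
        ds = generate_dataset(38, spec, np.linspace(-1, 1, spec.L), 0.5, seed=8)
        model = fit_ols(assemble_design(ds.predictors, spec), ds.y)
        res = partial_test(model, Constraint(1), alpha=0.05)
        assert model.df_resid == 17
        assert round(res.critical_value, 2) == 2.11

    def test_matches_reference_implementation(self, full_rank_model):
        statsmodels = pytest.importorskip("statsmodels.api")
        model, ds = full_rank_model
        ref = statsmodels.OLS(ds.y, model.design.values).fit()
        for l in range(model.L):
            res = partial_test(model, Constraint(l))
            assert res.statistic == pytest.approx(ref.tvalues[l], abs=1e-8)
            assert res.p_value == pytest.approx(ref.pvalues[l], abs=1e-8)
        np.testing.assert_allclose(model.delta_hat, ref.params, atol=1e-8)

    def test_decision_consistency(self, rank_deficient_model):
        model, _ = rank_deficient_model
        for l in range(model.L):
            res = partial_test(model, Constraint(l), alpha=0.05)
            assert (res.p_value < 0.05) == (abs(res.statistic) >= res.critical_value)

    def test_rss_gap_equals_z2_scale(self, rank_deficient_model):
        # constrained rss - rss = (a delta)^2 / (a G a') = Z^2 * Q / r
        model, _ = rank_deficient_model
        for l in range(model.L):
            cf = constrained_fit(model, Constraint(l))
            z = partial_test(model, Constraint(l)).statistic
            gap = cf.rss_omega - model.rss
            assert gap == pytest.approx(z**2 * model.rss / model.df_resid, rel=1e-6, abs=1e-9)


class TestPartialTestAll:
    def test_row_count_25(self):
        spec = FourierSpec(T=(1, 2, 4, 3, 5))
        ds = generate_dataset(38, spec, np.linspace(-1, 1, spec.L), 0.5, seed=8)
        model = fit_ols(assemble_design(ds.predictors, spec), ds.y)
        table = partial_test_all(model)
        assert len(table) == 25
        assert list(table.columns) == [
            "Parameter",
            "Estimation",
            "Statistic |Z|",
            "P-value",
            "Decision",
        ]

    def test_rows_match_individual_calls(self, rank_deficient_model):
        model, _ = rank_deficient_model
        table = partial_test_all(model, alpha=0.05)
        for l in range(model.L):
            res = partial_test(model, Constraint(l), alpha=0.05)
            row = table.iloc[l]
            assert row["Statistic |Z|"] == pytest.approx(abs(res.statistic))
            assert row["P-value"] == pytest.approx(res.p_value)
            assert row["Decision"] == res.decision

    def test_collinear_mu_rows_identical(self, rank_deficient_model):
        # the minimum-norm split makes every mu_j/2 row identical
        model, _ = rank_deficient_model
        table = partial_test_all(model)
        mu_rows = table[table["Parameter"].str.startswith("mu")]
        assert mu_rows["Statistic |Z|"].nunique() == 1 or np.allclose(
            mu_rows["Statistic |Z|"], mu_rows["Statistic |Z|"].iloc[0]
        )

    def test_bonferroni_inflates_pvalues(self, rank_deficient_model):
        model, _ = rank_deficient_model
        raw = partial_test_all(model)
        adj = partial_test_all(model, adjust="bonferroni")
        assert np.all(adj["P-value"].to_numpy() >= raw["P-value"].to_numpy() - 1e-15)
        assert np.all(adj["P-value"].to_numpy() <= 1.0)

    def test_bh_between_raw_and_bonferroni(self, rank_deficient_model):
        model, _ = rank_deficient_model
        raw = partial_test_all(model)["P-value"].to_numpy()
        bh = partial_test_all(model, adjust="bh")["P-value"].to_numpy()
        bonf = partial_test_all(model, adjust="bonferroni")["P-value"].to_numpy()
        assert np.all(bh >= raw - 1e-15)
        assert np.all(bh <= bonf + 1e-15)


class TestLikelihoodRatio:
    def test_identity_with_z(self, rank_deficient_model):
        # w = (1 + Z^2/r)^(-n/2); in (0, 1]; monotone decreasing in |Z|
        model, _ = rank_deficient_model
        pairs = []
        for l in range(model.L):
            w = likelihood_ratio(model, Constraint(l))
            z = partial_test(model, Constraint(l)).statistic
            assert 0.0 < w <= 1.0
            expected = (1.0 + z**2 / model.df_resid) ** (-model.n / 2.0)
            assert w == pytest.approx(expected, rel=1e-9)
            pairs.append((abs(z), w))
        pairs.sort()
        ws = [w for _, w in pairs]
        assert all(a >= b - 1e-12 for a, b in zip(ws, ws[1:]))

    def test_equals_one_iff_estimate_zero(self, full_rank_model):
        model, _ = full_rank_model
        m0 = fit_ols(model.design, np.zeros(model.n))
        assert likelihood_ratio(m0, Constraint(0)) == pytest.approx(1.0)
        # with a nonzero estimate, w < 1
        l = int(np.argmax(np.abs(model.delta_hat)))
        assert likelihood_ratio(model, Constraint(l)) < 1.0


class TestPowerMonotonicity:
    def test_rejection_rate_nondecreasing_in_effect_size(self):
        spec = FourierSpec(T=(2, 2))
        base = np.array([0.35, 0.3, 1.2, -0.7, 0.35, -0.2, 0.9, 0.0])
        idx = 7
        rates = []
        for effect in (0.0, 0.6, 1.5):
            delta = base.copy()
            delta[idx] = effect
            rejections = 0
            reps = 60
            for s in np.random.SeedSequence(73).generate_state(reps):
                ds = generate_dataset(40, spec, delta, sigma2=1.0, seed=int(s))
                model = fit_ols(assemble_design(ds.predictors, spec), ds.y)
                rejections += partial_test(model, Constraint(idx)).decision == "reject"
            rates.append(rejections / reps)
        assert rates[0] <= rates[1] + 0.1
        assert rates[1] <= rates[2] + 0.1
        assert rates[2] > rates[0]


class TestQuadraticForm:
    @pytest.mark.parametrize("fixture", ["full_rank_model", "rank_deficient_model"])
    def test_identities(self, fixture, request):
        model, _ = request.getfixturevalue(fixture)
        for l in (0, 1, model.L - 1):
            rec = quadratic_form_check(model, Constraint(l))
            assert rec["symmetry"] < 1e-10
            assert rec["idempotency"] < 1e-10
            assert abs(rec["trace_minus_1"]) < 1e-10
            assert rec["M_times_I_minus_U"] < 1e-10
            assert rec["z2_gap"] < 1e-8
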