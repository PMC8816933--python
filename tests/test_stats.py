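"""Domain scores, regressions, FDR, bootstrap, VIF, tertiles, gamma GLM."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bullseye.stats import (
    COVARIATES,
    age_tertiles,
    bh_fdr,
    bootstrap_ci,
    demographic_associations,
    fit_component_models,
    fit_parcel_models,
    gamma_glm_compare,
    standardize_scores,
    vif,
)


def _bh_oracle(p, level=0.05):
    """Literal step-up definition: reject H_(1..k) for the largest k with
    p_(k) <= k * level / m; q_i = min over feasible levels."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)]
        q[idx] = min(1.0, min(candidates))
    sorted_p = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * level / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return q, reject


class TestBhFdr:
    def test_single_p(self):
        q, rej = bh_fdr(np.array([0.03]))
        assert q[0] == 0.03 and rej[0]

    def test_all_equal(self):
        q, _ = bh_fdr(np.full(7, 0.2))
        np.testing.assert_allclose(q, 0.2)

    def test_worked_example(self):
        q, _ = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04, 0.05]))
        np.testing.assert_allclose(q, 0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.2]))
        with pytest.raises(ValueError):
            bh_fdr(np.array([-0.1]))

    def test_oracle_equivalence_exhaustive(self):
        grid = [0.001, 0.01, 0.04, 0.2, 0.7, 1.0]
        rng = np.random.default_rng(0)
        for m in range(1, 9):
            for _ in range(30):
                p = rng.choice(grid, size=m)
                q, rej = bh_fdr(p)
                q0, rej0 = _bh_oracle(p)
                np.testing.assert_allclose(q, q0, atol=1e-12)
                np.testing.assert_array_equal(rej, rej0)

    def test_fdr_control_under_global_null(self):
        # realized false-rejection proportion over 1000 replicates of 36 nulls
        rng = np.random.default_rng(1)
        any_false = 0
        total_rejections = 0
        for _ in range(1000):
            p = rng.random(36)
            _, rej = bh_fdr(p, level=0.05)
            total_rejections += rej.sum()
            any_false += rej.any()
        assert any_false / 1000 <= 0.05 + 0.02


class TestStandardizeScores:
    def _tasks(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        domains = ["memory", "speed", "reasoning", "vocabulary"]
        cols = {}
        domain_map = {}
        for d in domains:
            for i in range(3):
                name = f"{d}_task{i}"
                cols[name] = rng.standard_normal(n) * (i + 1) + i
                domain_map[name] = d
        return pd.DataFrame(cols), domain_map

    def test_mean_zero_sd_one(self):
        tasks, dmap = self._tasks()
        out = standardize_scores(tasks, dmap, reverse={"speed"})
        for d in out.columns:
            assert out[d].mean() == pytest.approx(0.0, abs=1e-8)
            assert out[d].std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_zero_variance_task_rejected(self):
        tasks, dmap = self._tasks()
        tasks["memory_task0"] = 5.0
        with pytest.raises(ValueError, match="memory_task0"):
            standardize_scores(tasks, dmap)

    def test_reversal_flips_correlation_sign(self):
        tasks, dmap = self._tasks(seed=2)
        external = np.random.default_rng(3).standard_normal(len(tasks)) + tasks["speed_task0"].to_numpy()
        plain = standardize_scores(tasks, dmap)
        reversed_ = standardize_scores(tasks, dmap, reverse={"speed"})
        r1 = np.corrcoef(plain["speed"], external)[0, 1]
        r2 = np.corrcoef(reversed_["speed"], external)[0, 1]
        assert r1 == pytest.approx(-r2, abs=1e-10)

    def test_missing_task_propagates(self):
        tasks, dmap = self._tasks()
        tasks.loc[0, "memory_task1"] = np.nan
        out = standardize_scores(tasks, dmap)
        assert np.isnan(out.loc[0, "memory"])
        assert out["memory"].notna().sum() == len(tasks) - 1

    def test_wrong_task_count_rejected(self):
        tasks, dmap = self._tasks()
        dmap.pop("memory_task2")
        with pytest.raises(ValueError, match="3 tasks"):
            standardize_scores(tasks, dmap)


def _covariates(n, rng):
    return pd.DataFrame({
        "age": rng.uniform(58, 84, n),
        "sex": rng.choice(["female", "male"], n),
        "education": rng.normal(15, 2.5, n),
        "bpf": rng.normal(78, 2, n),
        "hypertension": rng.integers(0, 2, n),
    })


class TestOlsMachinery:
    def test_beta_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        n = 150
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 4))])
        y = X @ np.array([1.0, 0.5, -0.3, 0.0, 2.0]) + rng.standard_normal(n)
        import statsmodels.api as sm

        beta_sm = sm.OLS(y, X).fit().params
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(beta_sm, beta_ne, atol=1e-10)


class TestParcelModels:
    def _parcel_frame(self, values, rng, n):
        cols = {f"p{c}": rng.standard_normal(n) for c in
                [r * 10 + l for r in range(1, 10) for l in range(1, 5)]}
        df = pd.DataFrame(cols)
        if values is not None:
            df["p11"] = values
        return df

    def test_known_effect_recovery(self):
        # beta* = -0.3 of p11 on memory, mean estimate within +-0.05
        betas = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 500
            parcels = self._parcel_frame(rng.standard_normal(n), rng, n)
            cov = _covariates(n, rng)
            y = -0.3 * parcels["p11"].to_numpy() + 0.02 * cov["age"] + rng.standard_normal(n)
            scores = pd.DataFrame({"memory": y})
            out = fit_parcel_models(parcels, scores, cov)
            betas.append(out.query("predictor == 'p11'")["beta"].iloc[0])
        assert abs(np.mean(betas) - (-0.3)) < 0.05

    def test_null_effect_centred(self):
        betas = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = 200
            parcels = self._parcel_frame(None, rng, n)
            cov = _covariates(n, rng)
            scores = pd.DataFrame({"memory": rng.standard_normal(n)})
            out = fit_parcel_models(parcels, scores, cov)
            betas.append(out.query("predictor == 'p11'")["beta"].iloc[0])
        assert abs(np.mean(betas)) < 0.05

    def test_q_within_domain_family(self):
        rng = np.random.default_rng(9)
        n = 120
        parcels = self._parcel_frame(None, rng, n)
        cov = _covariates(n, rng)
        scores = pd.DataFrame({"memory": rng.standard_normal(n),
                               "speed": rng.standard_normal(n)})
        out = fit_parcel_models(parcels, scores, cov)
        for domain in ("memory", "speed"):
            sub = out.query("outcome == @domain")
            assert len(sub) == 36
            q, _ = bh_fdr(sub["p"].to_numpy())
            np.testing.assert_allclose(sub["q"].to_numpy(), q)
            assert (sub["q"] >= sub["p"] - 1e-15).all()

    def test_complete_case_per_model(self):
        rng = np.random.default_rng(10)
        n = 100
        parcels = self._parcel_frame(None, rng, n)
        cov = _covariates(n, rng)
        y = rng.standard_normal(n)
        y[:10] = np.nan
        out = fit_parcel_models(parcels, pd.DataFrame({"memory": y}), cov)
        assert (out["n"] == 90).all()

    def test_aliased_covariate_rejected(self):
        rng = np.random.default_rng(11)
        n = 80
        parcels = self._parcel_frame(None, rng, n)
        cov = _covariates(n, rng)
        cov["bpf"] = cov["age"] * 2.0  # exact aliasing
        with pytest.raises(ValueError, match="rank deficient"):
            fit_parcel_models(parcels, pd.DataFrame({"memory": rng.standard_normal(n)}), cov)

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(12)
        n = 6
        parcels = self._parcel_frame(None, rng, n)
        cov = _covariates(n, rng)
        with pytest.raises(ValueError, match="n="):
            fit_parcel_models(parcels, pd.DataFrame({"memory": rng.standard_normal(n)}), cov)


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        X = np.zeros((n, 3))
        X[:, 0] = np.tile([1, -1], n // 2)
        X[:, 1] = np.tile([1, 1, -1, -1], n // 4)
        X[:, 2] = np.tile([1, 1, 1, 1, -1, -1, -1, -1], n // 8)
        np.testing.assert_allclose(vif(X), 1.0, atol=1e-10)

    def test_r06_closed_form(self):
        rng = np.random.default_rng(13)
        n = 200000
        a = rng.standard_normal(n)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        out = vif(np.column_stack([a, b]))
        np.testing.assert_allclose(out, 1.5625, atol=0.02)

    def test_exact_r_gives_exact_vif(self):
        # construct two columns with sample correlation exactly adjusted
        rng = np.random.default_rng(14)
        a = rng.standard_normal(500)
        e = rng.standard_normal(500)
        a = (a - a.mean()) / a.std()
        e = e - e.mean()
        e -= a * (a @ e) / (a @ a)  # exactly orthogonal residual
        e /= e.std()
        b = 0.6 * a + np.sqrt(1 - 0.36) * e
        out = vif(np.column_stack([a, b]))
        np.testing.assert_allclose(out, 1 / (1 - 0.36), atol=1e-9)

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(15)
        a = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="collinearity"):
            out = vif(np.column_stack([a, a]))
        assert np.isinf(out).all()

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            vif(np.ones((10, 1)))


class TestBootstrapCi:
    def _exact_data(self, n=50):
        rng = np.random.default_rng(16)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([2.0, -1.5])  # zero noise
        return X, y

    def test_zero_noise_zero_width(self):
        X, y = self._exact_data()
        res = bootstrap_ci(X, y, B=200, seed=0)
        np.testing.assert_allclose(res.lower, res.upper, atol=1e-10)
        np.testing.assert_allclose(res.lower, [2.0, -1.5], atol=1e-10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(17)
        X = np.column_stack([np.ones(100), rng.standard_normal((100, 2))])
        y = X @ np.array([1.0, 0.5, -0.5]) + rng.standard_normal(100)
        a = bootstrap_ci(X, y, B=300, seed=42)
        b = bootstrap_ci(X, y, B=300, seed=42)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)

    def test_coverage(self):
        # 95% interval should cover the true slope ~95% +- 3 of the time
        true_beta = 0.7
        covered = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(20000 + seed)
            n = 200
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            y = X @ np.array([0.3, true_beta]) + rng.standard_normal(n)
            res = bootstrap_ci(X, y, B=1000, seed=seed)
            covered += res.lower[1] <= true_beta <= res.upper[1]
        assert abs(covered / reps - 0.95) <= 0.03

    def test_endpoint_stabilization(self):
        rng = np.random.default_rng(18)
        n = 150
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([0.0, 1.0]) + rng.standard_normal(n)
        import statsmodels.api as sm

        se = sm.OLS(y, X).fit().bse[1]
        big1 = bootstrap_ci(X, y, B=5000, seed=1)
        big2 = bootstrap_ci(X, y, B=5000, seed=2)
        small = bootstrap_ci(X, y, B=1000, seed=3)
        drift_big = abs(big1.lower[1] - big2.lower[1])
        drift_small = abs(big1.lower[1] - small.lower[1])
        assert drift_big < 0.1 * se
        assert drift_big <= drift_small + 0.02 * se

    def test_b_too_small_rejected(self):
        X, y = self._exact_data()
        with pytest.raises(ValueError):
            bootstrap_ci(X, y, B=1, seed=0)


class TestComponentModels:
    def _setup(self, n, seed, effect_on=None, beta=0.0):
        rng = np.random.default_rng(seed)
        comp = pd.DataFrame(rng.standard_normal((n, 3)), columns=["C1", "C2", "C3"])
        cov = _covariates(n, rng)
        y = rng.standard_normal(n)
        if effect_on is not None:
            y = y + beta * comp[effect_on].to_numpy()
        scores = pd.DataFrame({"memory": y})
        return scores, comp, cov

    def test_null_p_uniform(self):
        from scipy.stats import kstest

        ps = []
        for seed in range(150):
            scores, comp, cov = self._setup(80, 300 + seed)
            out = fit_component_models(scores, comp, cov, B=10, seed=seed)
            ps.append(out.query("predictor == 'C1'")["p"].iloc[0])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_effect_isolated_to_component3(self):
        b1, b2, b3 = [], [], []
        for seed in range(100):
            scores, comp, cov = self._setup(250, 700 + seed, effect_on="C3", beta=-0.4)
            out = fit_component_models(scores, comp, cov, B=10, seed=seed)
            b1.append(out.query("predictor == 'C1'")["beta"].iloc[0])
            b2.append(out.query("predictor == 'C2'")["beta"].iloc[0])
            b3.append(out.query("predictor == 'C3'")["beta"].iloc[0])
        assert abs(np.mean(b1)) < 0.05 and abs(np.mean(b2)) < 0.05
        assert np.mean(b3) == pytest.approx(-0.4, abs=0.05)

    def test_collinear_components_rejected(self):
        scores, comp, cov = self._setup(100, 19)
        comp["C2"] = comp["C1"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_component_models(scores, comp, cov, B=10, seed=0)

    def test_vif_and_bootstrap_reported(self):
        scores, comp, cov = self._setup(120, 21)
        out = fit_component_models(scores, comp, cov, B=50, seed=5)
        assert {"vif", "boot_ci_low", "boot_ci_high"} <= set(out.columns)
        assert (out["boot_ci_low"] <= out["boot_ci_high"]).all()
        assert (out["vif"] >= 1.0).all()


class TestAgeTertiles:
    def test_balanced_split(self):
        labels = age_tertiles(np.arange(1, 10))
        assert list(labels) == ["T1"] * 3 + ["T2"] * 3 + ["T3"] * 3

    def test_ties_go_lower(self):
        ages = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 9.0])
        q1 = np.quantile(ages, 1 / 3)
        labels = age_tertiles(ages)
        assert all(l == "T1" for a, l in zip(ages, labels) if a <= q1)

    def test_partition(self):
        rng = np.random.default_rng(22)
        ages = rng.uniform(58, 84, 101)
        labels = age_tertiles(ages)
        assert len(labels) == 101
        assert set(labels) == {"T1", "T2", "T3"}

    def test_too_few_distinct_rejected(self):
        with pytest.raises(ValueError):
            age_tertiles([5.0, 5.0, 5.0, 5.0])


class TestGammaGlm:
    def test_null_contrast_centred(self):
        coefs = []
        for seed in range(40):
            rng = np.random.default_rng(3000 + seed)
            y = np.concatenate([rng.gamma(2.0, 50.0, 200), rng.gamma(2.0, 50.0, 200)])
            g = np.array(["A"] * 200 + ["B"] * 200)
            out = gamma_glm_compare(y, g)
            coefs.append(out["log_ratio"].iloc[0])
        assert abs(np.mean(coefs)) < 0.05

    def test_ratio_recovery(self):
        rng = np.random.default_rng(23)
        y = np.concatenate([rng.gamma(2.0, 50.0, 500), rng.gamma(2.0, 100.0, 500)])
        g = np.array(["A"] * 500 + ["B"] * 500)
        out = gamma_glm_compare(y, g)
        assert 1.8 <= out["ratio"].iloc[0] <= 2.2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            gamma_glm_compare(np.ones(10) + 1, np.array(["A"] * 10))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gamma_glm_compare(np.array([1.0, 0.0]), np.array(["A", "B"]))

    def test_three_groups_pairwise(self):
        rng = np.random.default_rng(24)
        y = rng.gamma(2.0, 50.0, 300)
        g = np.repeat(["T1", "T2", "T3"], 100)
        out = gamma_glm_compare(y, g)
        assert len(out) == 3
        assert set(map(tuple, out[["group_a", "group_b"]].to_numpy())) == {
            ("T1", "T2"), ("T1", "T3"), ("T2", "T3")}


class TestDemographics:
    def test_self_correlation(self):
        rng = np.random.default_rng(25)
        age = rng.uniform(58, 84, 120)
        comp = pd.DataFrame({"C1": age})
        sex = rng.choice(["female", "male"], 120)
        out = demographic_associations(comp, age, sex)
        assert out["age_r"].iloc[0] == pytest.approx(1.0)

    def test_null_correlation_small(self):
        rs = []
        for seed in range(100):
            rng = np.random.default_rng(4000 + seed)
            age = rng.uniform(58, 84, 500)
            comp = pd.DataFrame({"C1": rng.standard_normal(500)})
            sex = rng.choice(["female", "male"], 500)
            out = demographic_associations(comp, age, sex)
            rs.append(out["age_r"].iloc[0])
        assert abs(np.mean(rs)) < 0.05

    def test_equal_groups_t_near_zero(self):
        v = np.tile([1.0, 1.0, 2.0, 2.0], 25)  # identical values in both groups
        sex = np.array(["female", "male"] * 50)
        comp = pd.DataFrame({"C1": v})
        age = np.linspace(58, 84, 100)
        out = demographic_associations(comp, age, sex)
        assert out["sex_t"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_rejected(self):
        comp = pd.DataFrame({"C1": np.ones(20)})
        with pytest.raises(ValueError):
            demographic_associations(
                comp, np.linspace(58, 84, 20), np.array(["female", "male"] * 10)
            )
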