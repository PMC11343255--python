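import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from sklearn.metrics import adjusted_rand_score

import phenomix as px
from phenomix.data import Feature, FeatureSchema
from phenomix.gfmm import (
    FitConfig,
    MixtureParams,
    component_log_density,
    e_step,
    fit,
    m_step,
    n_parameters,
    predict,
)

from conftest import make_cohort


def two_class_params(schema, mu, var, p, cat):
    """Hand-assembled two-class parameter set for the 3-feature test schema."""
    return MixtureParams(
        K=2,
        schema=schema,
        prior_coef=np.zeros((2, 3)),
        cont_mean=np.asarray(mu, dtype=float),
        cont_var=np.asarray(var, dtype=float),
        bin_p=np.asarray(p, dtype=float),
        cat_p=[np.asarray(cat, dtype=float)],
    )


class TestComponentLogDensity:
    def test_standard_normal_at_mean(self, small_schema):
        params = two_class_params(small_schema, [[0.0], [1.0]], [[1.0], [1.0]],
                                  [[0.5], [0.5]], [[0.25] * 4] * 2)
        # isolate the Gaussian term by choosing flat binary/categorical masses
        val = component_log_density(params, 0, [0.0, 1.0, 2.0], small_schema)
        expected = -0.5 * np.log(2 * np.pi) + np.log(0.5) + np.log(0.25)
        assert val == pytest.approx(expected, abs=1e-12)
        assert -0.5 * np.log(2 * np.pi) == pytest.approx(-0.9189385332046727)

    def test_bernoulli_half(self, small_schema):
        params = two_class_params(small_schema, [[0.0], [0.0]], [[1.0], [1.0]],
                                  [[0.5], [0.9]], [[0.25] * 4] * 2)
        v0 = component_log_density(params, 0, [0.0, 1.0, 0.0], small_schema)
        v1 = component_log_density(params, 0, [0.0, 0.0, 0.0], small_schema)
        assert v0 - v1 == pytest.approx(np.log(0.5) - np.log(0.5), abs=1e-12)
        # uniform 4-level categorical contributes ln 0.25
        vq = component_log_density(params, 0, [0.0, 1.0, 3.0], small_schema)
        assert vq == pytest.approx(v0, abs=1e-12)  # level 3 same mass as level 0

    def test_categorical_level_out_of_range(self, small_schema):
        params = two_class_params(small_schema, [[0.0], [0.0]], [[1.0], [1.0]],
                                  [[0.5], [0.5]], [[0.25] * 4] * 2)
        with pytest.raises(Exception):
            component_log_density(params, 0, [0.0, 1.0, 7.0], small_schema)

    def test_class_index_out_of_range(self, small_schema):
        params = two_class_params(small_schema, [[0.0], [0.0]], [[1.0], [1.0]],
                                  [[0.5], [0.5]], [[0.25] * 4] * 2)
        with pytest.raises(IndexError):
            component_log_density(params, 5, [0.0, 1.0, 0.0], small_schema)


class TestEStep:
    def _cohort(self, small_schema, rows):
        df = pd.DataFrame(rows, columns=small_schema.names)
        return make_cohort(df, small_schema)

    def test_identical_classes_give_half(self, small_schema):
        params = two_class_params(small_schema, [[0.0], [0.0]], [[1.0], [1.0]],
                                  [[0.5], [0.5]], [[0.25] * 4] * 2)
        cohort = self._cohort(small_schema, [[0.3, 1.0, 2.0], [-1.2, 0.0, 0.0]])
        gamma, _ = e_step(params, cohort, small_schema)
        np.testing.assert_allclose(gamma, 0.5, atol=1e-12)

    def test_degenerate_prior(self, small_schema):
        params = two_class_params(small_schema, [[0.0], [5.0]], [[1.0], [1.0]],
                                  [[0.5], [0.5]], [[0.25] * 4] * 2)
        params.prior_coef = np.array([[0.0, 0.0, 0.0], [-1e8, 0.0, 0.0]])  # pi ~ (1, 0)
        cohort = self._cohort(small_schema, [[5.0, 1.0, 2.0]])  # density favors class 1
        gamma, _ = e_step(params, cohort, small_schema)
        np.testing.assert_allclose(gamma, [[1.0, 0.0]], atol=1e-12)

    def test_matches_bayes_rule_oracle(self, small_schema):
        # brute-force Bayes arithmetic on 3 hand-set rows
        params = two_class_params(
            small_schema,
            [[0.0], [2.0]], [[1.0], [0.5]],
            [[0.3], [0.8]],
            [[0.1, 0.2, 0.3, 0.4], [0.4, 0.3, 0.2, 0.1]],
        )
        params.prior_coef = np.array([[0.0, 0.0, 0.0], [0.4, -0.2, 0.01]])
        rows = [[0.5, 1.0, 2.0], [2.5, 0.0, 0.0], [-1.0, 1.0, 3.0]]
        cohort = self._cohort(small_schema, rows)
        gamma, ll = e_step(params, cohort, small_schema)

        def normpdf(x, m, v):
            return np.exp(-0.5 * (x - m) ** 2 / v) / np.sqrt(2 * np.pi * v)

        C = np.column_stack([np.ones(3), np.zeros(3), np.full(3, 10.0)])
        ll_direct = 0.0
        for i, (x, b, c) in enumerate(rows):
            logits = C[i] @ params.prior_coef.T
            pi = np.exp(logits - logsumexp(logits))
            dens = np.array(
                [
                    normpdf(x, params.cont_mean[k, 0], params.cont_var[k, 0])
                    * (params.bin_p[k, 0] if b else 1 - params.bin_p[k, 0])
                    * params.cat_p[0][k, int(c)]
                    for k in range(2)
                ]
            )
            post = pi * dens / (pi * dens).sum()
            np.testing.assert_allclose(gamma[i], post, atol=1e-12)
            ll_direct += np.log((pi * dens).sum())
        assert ll == pytest.approx(ll_direct, abs=1e-10)

    def test_no_underflow_for_extreme_rows(self, small_schema):
        params = two_class_params(small_schema, [[0.0], [1.0]], [[1.0], [1.0]],
                                  [[0.5], [0.5]], [[0.25] * 4] * 2)
        cohort = self._cohort(small_schema, [[37.0, 1.0, 0.0]])  # density ~ exp(-685)
        gamma, ll = e_step(params, cohort, small_schema)
        assert np.isfinite(ll)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_hard_assignment_reduces_to_subgroup_stats(self, small_schema):
        rng = np.random.default_rng(0)
        n = 50
        df = pd.DataFrame(
            {
                "x_cont": rng.normal(size=n),
                "x_bin": rng.integers(0, 2, n).astype(float),
                "x_cat": rng.integers(0, 4, n).astype(float),
            }
        )
        cohort = make_cohort(df, small_schema)
        lab = (np.arange(n) % 2 == 0).astype(int)
        gamma = np.zeros((n, 2))
        gamma[np.arange(n), lab] = 1.0
        params = m_step(cohort, small_schema, gamma)
        for k in range(2):
            sub = df[lab == k]
            assert params.cont_mean[k, 0] == pytest.approx(sub["x_cont"].mean(), abs=1e-10)
            mle_var = max(sub["x_cont"].var(ddof=0), 1e-4)
            assert params.cont_var[k, 0] == pytest.approx(mle_var, abs=1e-10)
            assert params.bin_p[k, 0] == pytest.approx(sub["x_bin"].mean(), abs=1e-10)

    def test_uniform_responsibilities_give_global_params(self, small_schema):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "x_cont": rng.normal(size=30),
                "x_bin": rng.integers(0, 2, 30).astype(float),
                "x_cat": rng.integers(0, 4, 30).astype(float),
            }
        )
        cohort = make_cohort(df, small_schema)
        gamma = np.full((30, 2), 0.5)
        params = m_step(cohort, small_schema, gamma)
        np.testing.assert_allclose(params.cont_mean[0], params.cont_mean[1], atol=1e-12)
        assert params.cont_mean[0, 0] == pytest.approx(df["x_cont"].mean(), abs=1e-10)

    def test_weighted_mean_arithmetic(self, small_schema):
        df = pd.DataFrame({"x_cont": [1.0, 2.0, 4.0], "x_bin": [0.0, 1.0, 1.0],
                           "x_cat": [0.0, 1.0, 2.0]})
        cohort = make_cohort(df, small_schema)
        w = np.array([0.2, 0.3, 0.5])
        gamma = np.column_stack([w, 1 - w])
        params = m_step(cohort, small_schema, gamma)
        expected = (w * df["x_cont"]).sum() / w.sum()  # 0.2*1+0.3*2+0.5*4 = 2.8
        assert expected == pytest.approx(2.8)
        assert params.cont_mean[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_class_raises(self, small_schema):
        df = pd.DataFrame({"x_cont": [0.0, 1.0], "x_bin": [0.0, 1.0], "x_cat": [0.0, 1.0]})
        cohort = make_cohort(df, small_schema)
        gamma = np.array([[1.0, 0.0], [1.0, 0.0]])
        gamma[:, 1] = 1e-9
        gamma[:, 0] = 1 - 1e-9
        with pytest.raises(px.gfmm.DegenerateClassError):
            m_step(cohort, small_schema, gamma)


class TestFit:
    def test_k1_closed_form(self, small_schema):
        rng = np.random.default_rng(2)
        n = 200
        df = pd.DataFrame(
            {
                "x_cont": rng.normal(2.0, 1.5, n),
                "x_bin": (rng.random(n) < 0.3).astype(float),
                "x_cat": rng.integers(0, 4, n).astype(float),
            }
        )
        cohort = make_cohort(df, small_schema)
        res = fit(cohort, small_schema, K=1, config=FitConfig(n_init=1, seed=0))
        x = df["x_cont"].to_numpy()
        mu, var = x.mean(), x.var(ddof=0)
        ll_cont = -0.5 * n * (np.log(2 * np.pi * var) + 1.0)
        p = df["x_bin"].mean()
        ll_bin = n * (p * np.log(p) + (1 - p) * np.log(1 - p))
        counts = df["x_cat"].value_counts().reindex(range(4), fill_value=0).to_numpy()
        pr = counts / n
        ll_cat = float((counts[pr > 0] * np.log(pr[pr > 0])).sum())
        assert res.log_likelihood == pytest.approx(ll_cont + ll_bin + ll_cat, abs=1e-6)

    def test_k_exceeds_n(self, small_schema):
        df = pd.DataFrame({"x_cont": [0.0], "x_bin": [0.0], "x_cat": [0.0]})
        with pytest.raises(ValueError):
            fit(make_cohort(df, small_schema), small_schema, K=5)

    def test_recovers_well_separated_classes(self, separated_cohort, separated_fit):
        truth = separated_cohort.true_class.astype(int)
        assert adjusted_rand_score(truth, separated_fit.labels) >= 0.99

    def test_ll_trace_monotone(self, separated_fit):
        assert np.all(np.diff(separated_fit.ll_trace) >= -1e-8)

    def test_feature_permutation_invariance(self, small_schema):
        rng = np.random.default_rng(3)
        n = 150
        df = pd.DataFrame(
            {
                "x_cont": rng.normal(size=n),
                "x_bin": rng.integers(0, 2, n).astype(float),
                "x_cat": rng.integers(0, 4, n).astype(float),
            }
        )
        cohort = make_cohort(df, small_schema)
        res = fit(cohort, small_schema, K=2, config=FitConfig(n_init=2, seed=4))
        perm_schema = FeatureSchema(tuple(reversed(small_schema.features)))
        cohort_p = make_cohort(df[list(reversed(small_schema.names))], perm_schema)
        res_p = fit(cohort_p, perm_schema, K=2, config=FitConfig(n_init=2, seed=4))
        assert res.log_likelihood == pytest.approx(res_p.log_likelihood, abs=1e-9)

    def test_duplicated_points_terminate_finite(self, small_schema):
        df = pd.DataFrame({"x_cont": [1.0] * 20, "x_bin": [1.0] * 20, "x_cat": [2.0] * 20})
        cohort = make_cohort(df, small_schema)
        res = fit(cohort, small_schema, K=2, config=FitConfig(n_init=2, seed=5))
        assert np.isfinite(res.log_likelihood)
        assert (res.params.cont_var >= 1e-4).all()  # variance floor engaged


class TestPredict:
    def test_idempotent_on_training_cohort(self, separated_cohort, separated_fit):
        labels, gamma = predict(separated_fit, separated_cohort)
        np.testing.assert_array_equal(labels, separated_fit.labels)
        np.testing.assert_allclose(gamma, separated_fit.responsibilities, atol=1e-9)

    def test_centroid_assigned_with_confidence(self, separated_cohort, separated_fit):
        params = separated_fit.params
        row = {}
        k = 1
        i_cont = 0
        for f in separated_cohort.schema:
            if f.ftype == "continuous":
                row[f.name] = params.cont_mean[k, i_cont]
                i_cont += 1
            elif f.ftype == "binary":
                row[f.name] = float(params.bin_p[k, len([x for x in row if x.startswith('scq')])] > 0.5)
            else:
                j = [x.name for x in separated_cohort.schema if x.ftype == "categorical"].index(f.name)
                row[f.name] = float(np.argmax(params.cat_p[j][k]))
        df = pd.DataFrame([row])[separated_cohort.schema.names]
        from conftest import make_cohort

        cohort1 = make_cohort(df, separated_cohort.schema)
        labels, gamma = predict(separated_fit, cohort1)
        assert labels[0] == k
        assert gamma[0, k] > 0.99

    def test_exact_tie_goes_to_lower_index(self, small_schema):
        params = two_class_params(small_schema, [[0.0], [0.0]], [[1.0], [1.0]],
                                  [[0.5], [0.5]], [[0.25] * 4] * 2)
        df = pd.DataFrame({"x_cont": [0.7], "x_bin": [1.0], "x_cat": [2.0]})
        labels, gamma = predict(params, make_cohort(df, small_schema))
        np.testing.assert_allclose(gamma[0], [0.5, 0.5], atol=1e-12)
        assert labels[0] == 0


class TestSerialization:
    def test_model_json_roundtrip(self, separated_fit, separated_cohort, tmp_path):
        path = tmp_path / "model.json"
        separated_fit.save(path)
        params = px.MixtureFit.load_params(path)
        labels, _ = predict(params, separated_cohort)
        np.testing.assert_array_equal(labels, separated_fit.labels)


def test_parameter_count_rule():
    schema = FeatureSchema(
        (
            Feature("a", "continuous"),
            Feature("b", "continuous"),
            Feature("c", "binary"),
            Feature("d", "categorical", 4),
        )
    )
    # per class: 2+2+1+3 = 8; K=3: 2*3 prior + 24 = 30
    assert n_parameters(schema, 3) == 30
    assert n_parameters(schema, 1) == 8


def test_parameter_recovery_within_3se():
    """Hungarian-aligned per-class continuous means recovered within 3 SE."""
    from scipy.optimize import linear_sum_assignment

    spec = px.spark_like_spec(n_individuals=2000, n_siblings=0, separation=3.0, seed=77)
    cohort = px.generate_cohort(spec).probands()
    res = px.fit(cohort, cohort.schema, 4, FitConfig(n_init=4, seed=1))
    truth = cohort.true_class.astype(int)
    # align by confusion-matrix overlap
    K = 4
    overlap = np.zeros((K, K))
    for t in range(K):
        for e in range(K):
            overlap[t, e] = np.sum((truth == t) & (res.labels == e))
    rows, cols = linear_sum_assignment(-overlap)
    mapping = dict(zip(cols, rows))
    cont_names = [f.name for f in cohort.schema if f.ftype == "continuous"]
    for e in range(K):
        t = mapping[e]
        nk = max(int((res.labels == e).sum()), 1)
        for j, name in enumerate(cont_names):
            x = cohort.features[name].to_numpy()[truth == t]
            true_mean = x.mean()
            se = np.sqrt(res.params.cont_var[e, j] / nk)
            assert abs(res.params.cont_mean[e, j] - true_mean) < 3 * se + 3 * x.std() / np.sqrt(len(x))
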