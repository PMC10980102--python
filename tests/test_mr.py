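"""Unit and oracle tests for the Mendelian-randomization pipeline stages."""

import numpy as np
import pandas as pd
import pytest

from survmr import mr
from survmr.containers import ClinicalTable
from survmr.hazards import CoxFit
from tests.conftest import clinical_from_arrays, genotypes_from_array, small_expression


def _corr_dosages(R, n=600, seed=0):
    """Continuous dosage-like columns with target correlation matrix R."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((n, R.shape[0])) @ L.T
    # squash into [0, 2] by an affine map (correlations preserved)
    Z = (Z - Z.min()) / (Z.max() - Z.min()) * 2
    return Z


class TestClusterGenes:
    def _expr(self, X):
        return small_expression(X, scale="log2")

    def test_separable_groups_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[5, 5, 0, 0], [0, 0, 5, 5], [5, 0, 5, 0], [0, 5, 0, 5]])
        profiles = np.repeat(centers, 5, axis=0) + rng.normal(0, 0.05, (20, 4))
        labels = mr.cluster_genes(self._expr(profiles), k=4, seed=1)
        for block in range(4):
            grp = labels.iloc[block * 5 : (block + 1) * 5]
            assert grp.nunique() == 1

    def test_k_equals_genes_gives_singletons(self):
        rng = np.random.default_rng(1)
        E = self._expr(rng.normal(size=(5, 6)))
        labels = mr.cluster_genes(E, k=5, seed=0)
        assert labels.nunique() == 5

    def test_k_too_large_errors(self):
        E = self._expr(np.random.default_rng(2).normal(size=(3, 4)))
        with pytest.raises(ValueError, match="exceeds"):
            mr.cluster_genes(E, k=4)

    def test_deterministic_and_beats_random_partitions(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 10))
        E = self._expr(X)
        l1 = mr.cluster_genes(E, k=4, seed=5)
        l2 = mr.cluster_genes(E, k=4, seed=5)
        assert (l1 == l2).all()

        Z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)

        def sse(labels):
            tot = 0.0
            for c in np.unique(labels):
                pts = Z[labels == c]
                tot += ((pts - pts.mean(0)) ** 2).sum()
            return tot

        ours = sse(l1.to_numpy())
        rand_sse = [sse(rng.integers(1, 5, size=20)) for _ in range(100)]
        assert ours <= min(rand_sse)


class TestPruneIvs:
    def _eqtls(self, vids, ps, betas):
        return pd.DataFrame(
            {"gene_id": "g0", "variant_id": vids, "beta": betas, "se": 0.1,
             "p_nominal": ps}
        )

    def test_single_iv_is_its_own_proxy(self):
        G = genotypes_from_array(np.clip(np.random.default_rng(0).normal(1, 0.5, (50, 1)), 0, 2))
        ivset = mr.prune_ivs(self._eqtls(["v0"], [0.01], [0.7]), G)
        assert ivset.ivs == [("v0", 0.7)]

    def test_three_variant_ld_structure(self):
        # r2(A,B)=0.5, r2(A,C)=0.01, r2(B,C)=0.02 -> clusters {A,B},{C}
        R = np.array([[1.0, np.sqrt(0.5), 0.1],
                      [np.sqrt(0.5), 1.0, np.sqrt(0.02)],
                      [0.1, np.sqrt(0.02), 1.0]])
        G = genotypes_from_array(_corr_dosages(R, seed=1))
        r2 = np.corrcoef(G.dosages.to_numpy().T) ** 2
        assert r2[0, 1] > 0.3 and r2[0, 2] < 0.1 and r2[1, 2] < 0.1  # sanity
        eqtls = self._eqtls(["v0", "v1", "v2"], [0.03, 0.001, 0.02], [0.5, 0.6, -0.4])
        ivset = mr.prune_ivs(eqtls, G)
        # proxy of {A,B} is B (best p); C is its own proxy
        assert dict(ivset.ivs) == {"v1": 0.6, "v2": -0.4}

    def test_all_uncorrelated_all_proxies(self):
        rng = np.random.default_rng(4)
        G = genotypes_from_array(rng.binomial(2, 0.4, size=(500, 4)).astype(float))
        eqtls = self._eqtls([f"v{i}" for i in range(4)], [0.01] * 4, [0.1] * 4)
        ivset = mr.prune_ivs(eqtls, G)
        assert len(ivset.ivs) == 4

    def test_empty_errors(self):
        G = genotypes_from_array(np.ones((5, 1)))
        with pytest.raises(ValueError, match="no surviving"):
            mr.prune_ivs(self._eqtls([], [], []), G)


class TestPredictOneSample:
    def test_zero_weights_zero_prediction(self):
        G = genotypes_from_array(np.random.default_rng(0).binomial(2, 0.3, (10, 2)).astype(float))
        ivset = mr.IvSet("g0", [("v0", 0.0), ("v1", 0.0)])
        assert (mr.predict_expression_one_sample(ivset, G) == 0).all()

    def test_single_iv_unit_weight_is_dosage(self):
        G = genotypes_from_array(np.random.default_rng(1).binomial(2, 0.3, (10, 2)).astype(float))
        ghat = mr.predict_expression_one_sample(mr.IvSet("g0", [("v1", 1.0)]), G)
        assert np.allclose(ghat.to_numpy(), G.dosages["v1"].to_numpy())

    def test_hand_matrix_product(self):
        Q = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0]])
        G = genotypes_from_array(Q)
        ghat = mr.predict_expression_one_sample(mr.IvSet("g0", [("v0", 0.5), ("v1", -1.0)]), G)
        assert np.allclose(ghat.to_numpy(), [-1.0, -1.5, 1.0])

    def test_missing_variant_errors(self):
        G = genotypes_from_array(np.ones((4, 1)))
        with pytest.raises(KeyError, match="v9"):
            mr.predict_expression_one_sample(mr.IvSet("g0", [("v9", 1.0)]), G)


class TestPredictTwoSample:
    def test_projection_on_same_cohort_is_fitted_values(self):
        rng = np.random.default_rng(5)
        Q = rng.binomial(2, 0.3, size=(40, 3)).astype(float)
        g = rng.normal(size=40)
        ghat = mr.predict_expression_two_sample(Q, g, Q)
        fitted = Q @ np.linalg.lstsq(Q, g, rcond=None)[0]
        assert np.allclose(ghat, fitted, atol=1e-10)

    def test_orthogonal_expression_gives_zero(self):
        rng = np.random.default_rng(6)
        Q = rng.normal(size=(30, 2))
        g = rng.normal(size=30)
        g -= Q @ np.linalg.lstsq(Q, g, rcond=None)[0]  # project out col(Q)
        ghat = mr.predict_expression_two_sample(Q, g, rng.normal(size=(10, 2)))
        assert np.max(np.abs(ghat)) < 1e-10

    def test_hand_toy_matches_pseudoinverse_oracle(self):
        Q = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, 0.0]])
        g = np.array([1.0, -1.0, 0.5, 2.0])
        Qstar = np.array([[1.0, 2.0], [0.0, 1.0], [2.0, 1.0]])
        oracle = Qstar @ np.linalg.pinv(Q) @ g
        assert np.allclose(mr.predict_expression_two_sample(Q, g, Qstar), oracle, atol=1e-10)

    def test_singular_ridge_fallback_warns(self):
        Q = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])  # collinear
        with pytest.warns(UserWarning, match="ridge"):
            out = mr.predict_expression_two_sample(Q, np.array([1.0, 2.0, 3.0]), Q)
        assert np.all(np.isfinite(out))

    def test_reduces_to_one_sample_with_joint_weights(self):
        rng = np.random.default_rng(7)
        Q = rng.binomial(2, 0.4, size=(50, 2)).astype(float)
        g = rng.normal(size=50)
        theta = np.linalg.lstsq(Q, g, rcond=None)[0]
        ivset = mr.IvSet("g0", [("v0", theta[0]), ("v1", theta[1])])
        G = genotypes_from_array(Q)
        one = mr.predict_expression_one_sample(ivset, G)
        two = mr.predict_expression_two_sample(Q, g, Q)
        assert np.allclose(one.to_numpy(), two, atol=1e-10)


def _mr_world(n=400, seed=0, causal=0.0, arm_causal="bevacizumab"):
    """Small cohort with valid instruments; optional causal hazard effect."""
    rng = np.random.default_rng(seed)
    dos = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
    g_expr = 8.0 + 0.4 * dos[:, 0] - 0.4 * dos[:, 1] + rng.normal(0, 0.6, n)
    arm = np.where(rng.binomial(1, 0.5, n) == 1, "bevacizumab", "cetuximab")
    lam = 1.0 + causal * (g_expr - g_expr.mean()) * (arm == arm_causal)
    lam = np.maximum(lam, 0.05)
    t = rng.exponential(1 / lam)
    c = rng.exponential(1 / 0.15, n)
    clinical = clinical_from_arrays(np.minimum(t, c), (t <= c).astype(int), arm,
                                    age=rng.normal(60, 8, n).round(1))
    G = genotypes_from_array(dos)
    ghat = pd.Series(dos @ np.array([0.4, -0.4]), index=G.samples, name="g0")
    cov = clinical.table[["age"]].astype(float)
    return clinical, cov, ghat, G


class TestOneSampleMr:
    def test_planted_effect_detected_with_direction(self):
        hits = 0
        for seed in range(30):
            clinical, cov, ghat, _ = _mr_world(n=500, seed=seed, causal=0.9)
            res = mr.one_sample_mr({"g0": ghat}, clinical, cov, "bevacizumab")
            r = res[0]
            hits += r.p_value < 0.05 and r.direction == 1
        assert hits >= 24

    def test_null_instruments_detect_nothing(self):
        # expression affects the hazard but the prediction is built from
        # unrelated variants: rejection should stay near the nominal level
        rng = np.random.default_rng(8)
        rej = 0
        reps = 150
        for seed in range(reps):
            clinical, cov, _, _ = _mr_world(n=300, seed=seed + 1000, causal=0.8)
            junk = pd.Series(rng.binomial(2, 0.3, 300).astype(float),
                             index=clinical.samples, name="g0")
            res = mr.one_sample_mr({"g0": junk}, clinical, cov, "bevacizumab")
            rej += res[0].p_value < 0.05
        assert rej / reps < 0.12

    def test_confounded_gene_mr_stays_calibrated_while_screen_rejects(self):
        # a shared frailty drives expression and hazard with no causal path:
        # the naive expression-OS screen fires, MR on the genetic prediction
        # does not
        from survmr.hazards import aalen_test, fit_aalen

        rng = np.random.default_rng(9)
        naive_rej = mr_rej = 0
        reps = 80
        for rep in range(reps):
            n = 400
            u = rng.standard_normal(n)
            dos = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
            g_expr = 8.0 + 0.4 * dos[:, 0] - 0.4 * dos[:, 1] + 0.8 * u + rng.normal(0, 0.4, n)
            lam = np.maximum(1.0 + 0.45 * u, 0.05)
            t = rng.exponential(1 / lam)
            clinical = clinical_from_arrays(t, np.ones(n, int),
                                            np.repeat("bevacizumab", n))
            X = np.column_stack([np.ones(n), g_expr - g_expr.mean()])
            fit = fit_aalen(X, t, np.ones(n, int))
            naive_rej += aalen_test(fit, 1)[2] < 0.05
            ghat = pd.Series(dos @ np.array([0.4, -0.4]), index=clinical.samples, name="g0")
            res = mr.one_sample_mr({"g0": ghat}, clinical, None, "bevacizumab")
            mr_rej += res[0].p_value < 0.05
        assert naive_rej / reps > 0.5
        assert mr_rej / reps < 0.15

    def test_collinear_predictions_dropped_with_warning(self):
        clinical, cov, ghat, _ = _mr_world(n=200, seed=3)
        with pytest.warns(UserWarning, match="collinear"):
            res = mr.one_sample_mr({"g0": ghat, "g1": 2 * ghat}, clinical, cov, "bevacizumab")
        assert [r.gene_id for r in res] == ["g0"]

    def test_constant_prediction_errors(self):
        clinical, cov, _, _ = _mr_world(n=100, seed=4)
        const = pd.Series(1.0, index=clinical.samples, name="g0")
        with pytest.raises(ValueError, match="constant"):
            mr.one_sample_mr({"g0": const}, clinical, cov, "bevacizumab")

    def test_allele_flip_invariance(self):
        clinical, cov, _, G = _mr_world(n=300, seed=5, causal=0.6)
        ivset = mr.IvSet("g0", [("v0", 0.4), ("v1", -0.4)])
        ghat = mr.predict_expression_one_sample(ivset, G)
        G2 = G.flip_variants(["v0"])
        ivset2 = mr.IvSet("g0", [("v0", -0.4), ("v1", -0.4)])
        ghat2 = mr.predict_expression_one_sample(ivset2, G2)
        diff = ghat - ghat2
        assert np.allclose(diff, diff.iloc[0])  # equal up to additive constant
        p1 = mr.one_sample_mr({"g0": ghat}, clinical, cov, "bevacizumab")[0].p_value
        p2 = mr.one_sample_mr({"g0": ghat2}, clinical, cov, "bevacizumab")[0].p_value
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestScreenBoundaries:
    def test_screen_strict_threshold(self, monkeypatch):
        """A gene whose test p equals alpha exactly must not pass."""
        clinical, cov, ghat, _ = _mr_world(n=120, seed=6)
        rng = np.random.default_rng(0)
        E = small_expression(
            np.vstack([ghat.to_numpy(), rng.normal(8, 1, len(ghat))]),
            gene_ids=["gA", "gB"], sample_ids=list(clinical.samples), scale="log2",
        )
        clusters = pd.Series([1, 1], index=["gA", "gB"])
        fixed = {"gA": 0.1, "gB": 0.0999999}
        monkeypatch.setattr(
            mr, "aalen_test", lambda fit, name, **kw: (1.0, 1.0, fixed[name])
        )
        rep = mr.screen_gene_os(E, clinical, cov, clusters, "bevacizumab", min_events=5)
        assert [r.gene_id for r in rep.results] == ["gB"]

    def test_pleiotropy_strict_threshold(self, monkeypatch):
        """Wald p exactly 1e-4 is retained; strictly below is excluded."""
        clinical, cov, _, G = _mr_world(n=120, seed=7)
        ps = {"v0": 1e-4, "v1": 0.99999e-4}

        def fake_cox(X, t, e, names=None, **kw):
            v = fake_cox.order.pop(0)
            return CoxFit(np.array([0.1]), np.array([0.05]), np.array([ps[v]]),
                          ["dosage"], True, 10, 3, -5.0)

        fake_cox.order = ["v0", "v1"]
        monkeypatch.setattr(mr, "fit_coxph", fake_cox)
        excluded, pvals = mr.pleiotropy_screen(G, clinical, cov, ["v0", "v1"])
        assert excluded == {"v1"}

    def test_overfitting_guard_splits_large_cluster(self):
        rng = np.random.default_rng(10)
        n = 60
        arm = np.repeat("bevacizumab", n)
        t = rng.exponential(1.0, n)
        clinical = clinical_from_arrays(t, np.ones(n, int), arm)
        X = rng.normal(8, 1, size=(30, n))
        E = small_expression(X, scale="log2",
                             gene_ids=[f"g{i}" for i in range(30)],
                             sample_ids=list(clinical.samples))
        clusters = pd.Series(1, index=E.genes)
        with pytest.warns(UserWarning, match="sub-splitting"):
            mr.screen_gene_os(E, clinical, None, clusters, "bevacizumab", min_events=5)
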