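import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mlmwas.io import MwasTable, ValidationError
from mlmwas.orm import compute_orm
from mlmwas.reml import reml_fit
from mlmwas.scoring import (
    ProfileScore,
    WeightTable,
    blup_effects,
    classify,
    combine_scores,
    ctp_score,
    mps,
    threshold_weights,
)
from mlmwas.sim import simulate_oreml_phenotype

from conftest import standardized_matrix


class TestBlup:
    def test_matches_ridge_closed_form(self):
        """BLUP equals ridge regression with penalty sigma_e^2/sigma_u^2."""
        n, m = 90, 120
        M = standardized_matrix(n, m, seed=1)
        y = simulate_oreml_phenotype(M.values, 0.4, seed=2)
        wt, fit = blup_effects(y, None, M)
        W = M.values
        lam = fit.sigma_e2 / (fit.sigma_o2 / m)
        ytilde = y - fit.beta_hat[0]
        u_ridge = np.linalg.solve(W.T @ W + lam * np.eye(m), W.T @ ytilde)
        np.testing.assert_allclose(wt.weights.to_numpy(), u_ridge, atol=1e-8)
        assert wt.source == "blup"

    def test_reuses_supplied_fit(self):
        n, m = 60, 80
        M = standardized_matrix(n, m, seed=3)
        y = simulate_oreml_phenotype(M.values, 0.3, seed=4)
        fit = reml_fit(y, None, [compute_orm(M)])
        wt1, _ = blup_effects(y, None, M, fit=fit)
        wt2, _ = blup_effects(y, None, M)
        np.testing.assert_allclose(
            wt1.weights.to_numpy(), wt2.weights.to_numpy(), atol=1e-10
        )

    def test_shrinks_toward_zero_relative_to_ols(self):
        n, m = 100, 150
        M = standardized_matrix(n, m, seed=5)
        y = simulate_oreml_phenotype(M.values, 0.3, seed=6)
        wt, _ = blup_effects(y, None, M)
        ols = (M.values.T @ (y - y.mean())) / n
        assert np.abs(wt.weights.to_numpy()).mean() < np.abs(ols).mean()


class TestWeightsAndMps:
    def _table(self):
        t = pd.DataFrame(
            {
                "Chr": ["1", "1", "2"],
                "Probe": ["a", "b", "c"],
                "bp": [100, 200, 100],
                "Gene": "g",
                "Orientation": "F",
                "b": [0.5, -0.2, 0.1],
                "se": [0.1, 0.1, 0.1],
                "p": [1e-6, 0.01, 0.5],
            }
        )
        return MwasTable(table=t, method="moa", lambda_gc=1.0)

    def test_threshold_weights_monotone_and_correct(self):
        wts = threshold_weights(self._table(), [1e-5, 0.05, 1.0])
        assert [w.m_used for w in wts] == [1, 2, 3]
        assert wts[0].weights["a"] == pytest.approx(0.5)
        assert wts[1].weights["b"] == pytest.approx(-0.2)

    def test_mps_hand_example(self):
        M = standardized_matrix(5, 3, seed=7)
        w = WeightTable(
            weights=pd.Series([2.0, -1.0], index=["p0", "p2"]), source="moa"
        )
        ps = mps(M, w)
        Z = M.values
        expected = 2.0 * Z[:, 0] - 1.0 * Z[:, 2]
        np.testing.assert_allclose(ps.mps_probe, expected, atol=1e-10)
        assert ps.n_matched == 2 and ps.n_missing == 0

    def test_mps_counts_missing_probes(self):
        M = standardized_matrix(5, 3, seed=8)
        w = WeightTable(
            weights=pd.Series([1.0, 1.0], index=["p0", "zz"]), source="moa"
        )
        ps = mps(M, w)
        assert ps.n_matched == 1 and ps.n_missing == 1

    def test_mps_no_overlap_rejected(self):
        M = standardized_matrix(4, 2, seed=9)
        w = WeightTable(weights=pd.Series([1.0], index=["zz"]), source="moa")
        with pytest.raises(ValidationError):
            mps(M, w)

    def test_mps_standardizes_within_target(self):
        """Scores are invariant to affine rescaling of the target values."""
        M = standardized_matrix(20, 4, seed=10)
        M2 = standardized_matrix(20, 4, seed=10)
        M2.values[:] = M.values * 3.0 + 1.0
        w = WeightTable(
            weights=pd.Series([1.0, -2.0], index=["p1", "p3"]), source="moa"
        )
        np.testing.assert_allclose(
            mps(M, w).mps_probe, mps(M2, w).mps_probe, atol=1e-10
        )

    def test_profile_score_total_sums_components(self):
        ps = ProfileScore(mps_probe=np.array([1.0, 2.0]),
                          mps_ctp=np.array([0.5, -0.5]))
        np.testing.assert_allclose(ps.mps_total, [1.5, 1.5])
        with pytest.raises(ValidationError):
            ProfileScore().mps_total

    def test_duplicate_weight_ids_rejected(self):
        with pytest.raises(ValidationError):
            WeightTable(
                weights=pd.Series([1.0, 2.0], index=["a", "a"]), source="moa"
            )


class TestCtpScore:
    def test_matches_matrix_product(self):
        rng = np.random.default_rng(11)
        ctp = pd.DataFrame(rng.dirichlet(np.ones(3), 10),
                           columns=["a", "b", "c"])
        eff = pd.Series([1.0, -2.0], index=["a", "c"])
        s = ctp_score(ctp, eff)
        np.testing.assert_allclose(
            s, ctp["a"].to_numpy() - 2 * ctp["c"].to_numpy(), atol=1e-12
        )

    def test_missing_cell_type_rejected(self):
        ctp = pd.DataFrame({"a": [0.5], "b": [0.5]})
        with pytest.raises(ValidationError, match="zz"):
            ctp_score(ctp, pd.Series([1.0], index=["zz"]))


class TestCombineScores:
    def _cohort(self, n, seed):
        """One informative score, one pure-noise score, plus status."""
        rng = np.random.default_rng(seed)
        status = np.repeat([0, 1], n // 2)
        good = status * 1.2 + rng.normal(0, 1, n)
        noise = rng.normal(0, 1, n)
        return good, noise, status

    def test_noise_component_does_not_dilute(self):
        gd, nd, sd = self._cohort(400, seed=21)
        gt, nt, st = self._cohort(400, seed=22)
        comb = combine_scores([gd, nd], sd, [gt, nt])
        auc_comb = classify(comb, st).auc
        auc_good = classify(gt, st).auc
        # an unweighted sum would sit well below the strong component
        naive = gt / gt.std() + nt / nt.std()
        assert auc_comb > classify(naive, st).auc
        assert auc_comb > auc_good - 0.02

    def test_affine_invariance_under_shared_transform(self):
        gd, nd, sd = self._cohort(400, seed=23)
        gt, nt, st = self._cohort(400, seed=24)
        # applying the same affine map to a component in both cohorts
        # leaves the combination unchanged
        c1 = combine_scores([gd, nd], sd, [gt, nt])
        c2 = combine_scores([2.0 * gd + 1.0, nd], sd, [2.0 * gt + 1.0, nt])
        np.testing.assert_allclose(c1, c2, atol=1e-8)

    def test_validation(self):
        g, n_, s = self._cohort(60, seed=25)
        with pytest.raises(ValidationError, match="at least two"):
            combine_scores([g], s, [g])
        with pytest.raises(ValidationError, match="differ in length"):
            combine_scores([g, n_], s, [g])
        with pytest.raises(ValidationError, match="both classes"):
            combine_scores([g, n_], np.zeros(60, dtype=int), [g, n_])


class TestClassify:
    def test_perfect_separation_auc_one(self):
        scores = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 1.2])
        status = np.array([0, 0, 0, 1, 1, 1])
        res = classify(scores, status)
        assert res.auc == pytest.approx(1.0)
        assert res.n_cases == 3 and res.n_controls == 3

    def test_auc_matches_pairwise_count(self):
        rng = np.random.default_rng(12)
        status = rng.integers(0, 2, 200)
        status[:5] = 1
        status[5:10] = 0
        scores = rng.normal(0, 1, 200) + 0.4 * status
        res = classify(scores, status)
        x = scores[status == 1][:, None]
        y = scores[status == 0][None, :]
        pairwise = (np.mean(x > y) + 0.5 * np.mean(x == y))
        assert res.auc == pytest.approx(pairwise, abs=1e-12)

    def test_ties_give_half(self):
        res = classify(np.ones(10), np.array([0, 1] * 5))
        assert res.auc == pytest.approx(0.5)
        assert res.logit_or == 1.0 and res.logit_p == 1.0

    def test_informative_score_has_significant_or(self):
        rng = np.random.default_rng(13)
        n = 400
        status = np.array([0] * 200 + [1] * 200)
        scores = rng.normal(0, 1, n) + 0.8 * status
        res = classify(scores, status)
        assert res.logit_or > 1.0
        assert res.logit_p < 1e-6
        assert res.ci_low < res.auc < res.ci_high

    def test_binormal_auc_matches_theory(self):
        """AUC for two unit-variance normals separated by d is
        Phi(d / sqrt(2))."""
        rng = np.random.default_rng(14)
        d = 1.0
        n = 20_000
        scores = np.concatenate(
            [rng.normal(0, 1, n // 2), rng.normal(d, 1, n // 2)]
        )
        status = np.array([0] * (n // 2) + [1] * (n // 2))
        res = classify(scores, status)
        assert res.auc == pytest.approx(stats.norm.cdf(d / np.sqrt(2)),
                                        abs=0.012)

    def test_delong_ci_covers_truth(self):
        """Jackknife-free check: over replicates the 95% DeLong interval
        covers the binormal truth most of the time."""
        rng = np.random.default_rng(15)
        truth = stats.norm.cdf(0.5 / np.sqrt(2))
        cover = 0
        reps = 40
        for _ in range(reps):
            s0 = rng.normal(0, 1, 150)
            s1 = rng.normal(0.5, 1, 150)
            res = classify(
                np.concatenate([s0, s1]),
                np.array([0] * 150 + [1] * 150),
            )
            cover += res.ci_low <= truth <= res.ci_high
        assert cover >= int(0.85 * reps)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            classify(np.arange(5.0), np.ones(5, dtype=int))
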