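import numpy as np
import pytest
from scipy import stats

from mlmwas.io import ValidationError
from mlmwas.mwas import (
    MomentConfig,
    bonferroni_threshold,
    genomic_lambda,
    linear_mwas,
    moa,
    moment,
    pc_adjusted_mwas,
)
from mlmwas.orm import compute_orm
from mlmwas.preprocess import filter_probes, standardize
from mlmwas.reml import reml_fit
from mlmwas.sim import simulate_oreml_phenotype

from conftest import standardized_matrix


class TestThresholdAndLambda:
    def test_bonferroni_at_methylome_scale(self):
        assert bonferroni_threshold(160_304) == pytest.approx(3.119e-7,
                                                              rel=1e-3)
        assert bonferroni_threshold(94) == pytest.approx(5.3e-4, rel=1e-2)
        with pytest.raises(ValidationError):
            bonferroni_threshold(0)

    def test_lambda_one_for_null_chi2(self):
        rng = np.random.default_rng(0)
        chi2 = rng.chisquare(1, size=200_000)
        assert genomic_lambda(chi2_stats=chi2) == pytest.approx(1.0, abs=0.02)

    def test_lambda_scales_with_inflation(self):
        rng = np.random.default_rng(1)
        chi2 = 1.5 * rng.chisquare(1, size=200_000)
        assert genomic_lambda(chi2_stats=chi2) == pytest.approx(1.5, abs=0.03)

    def test_lambda_from_p_matches_chi2(self):
        rng = np.random.default_rng(2)
        chi2 = rng.chisquare(1, size=5_000)
        p = stats.chi2.sf(chi2, 1)
        assert genomic_lambda(p_values=p) == pytest.approx(
            genomic_lambda(chi2_stats=chi2), rel=1e-10
        )

    def test_lambda_requires_input(self):
        with pytest.raises(ValidationError):
            genomic_lambda()


class TestLinear:
    def test_matches_per_probe_ols(self):
        n, m = 60, 5
        M = standardized_matrix(n, m, seed=3)
        rng = np.random.default_rng(4)
        y = M.values[:, 0] * 0.4 + rng.standard_normal(n)
        C = rng.standard_normal(n)
        res = linear_mwas(y, M, C).table.set_index("Probe")
        import statsmodels.api as sm

        for j, pid in enumerate(M.probe_ids):
            X = sm.add_constant(np.column_stack([C, M.values[:, j]]))
            ols = sm.OLS(y, X).fit()
            row = res.loc[pid]
            assert row["b"] == pytest.approx(ols.params[-1], abs=1e-10)
            assert row["se"] == pytest.approx(ols.bse[-1], abs=1e-10)
            assert row["p"] == pytest.approx(ols.pvalues[-1], rel=1e-8)

    def test_collinear_probe_rejected(self):
        n = 40
        M = standardized_matrix(n, 3, seed=5)
        C = M.values[:, 1].copy()
        y = np.random.default_rng(6).standard_normal(n)
        with pytest.raises(ValidationError, match="collinear"):
            linear_mwas(y, M, C)

    def test_pc_adjustment_reduces_structure_inflation(self):
        """A dominant latent factor inflates the naive scan; projecting it
        out via ORM principal components restores calibration."""
        rng = np.random.default_rng(7)
        n, m = 200, 400
        f = rng.standard_normal(n)
        W = 0.8 * f[:, None] + rng.standard_normal((n, m))
        W = (W - W.mean(0)) / W.std(0)
        M = standardized_matrix(n, m, seed=8)
        M.values[:] = W
        y = f + rng.standard_normal(n)
        lam_naive = linear_mwas(y, M).lambda_gc
        lam_pc = pc_adjusted_mwas(y, M, compute_orm(M), k=5).lambda_gc
        assert lam_naive > 1.5
        assert lam_pc < lam_naive * 0.5


class TestMoa:
    def test_matches_explicit_gls(self):
        """The eigenbasis score statistic equals the brute-force GLS
        estimate with the fitted covariance."""
        n, m = 100, 150
        M = standardized_matrix(n, m, seed=9)
        y = simulate_oreml_phenotype(M.values, 0.4, seed=10)
        A = compute_orm(M)
        res = moa(y, M, orm=A).table.set_index("Probe")
        fit = reml_fit(y, None, [A])
        V = fit.sigma_o2 * A.A + fit.sigma_e2 * np.eye(n)
        Vinv = np.linalg.inv(V)
        yt = y - np.ones(n) * fit.beta_hat[0]
        for j in [0, 7, 149]:
            w = M.values[:, j]
            den = w @ Vinv @ w
            b = (w @ Vinv @ yt) / den
            se = 1.0 / np.sqrt(den)
            row = res.loc[M.probe_ids[j]]
            assert row["b"] == pytest.approx(b, abs=1e-8)
            assert row["se"] == pytest.approx(se, abs=1e-8)

    def test_null_scan_calibrated(self, null_cohort):
        _, M, S, _ = null_cohort
        Z = standardize(filter_probes(M)[0])
        y = S["status"].to_numpy(float)
        res = moa(y, Z)
        assert 0.75 < res.lambda_gc < 1.3

    def test_detects_causal_probes(self, small_cohort):
        _, M, S, T = small_cohort
        Z = standardize(filter_probes(M)[0])
        y = S["status"].to_numpy(float)
        res = moa(y, Z).table
        top = set(res.nsmallest(25, "p")["Probe"])
        causal = set(T.causal_probe_ids) & set(Z.probe_ids)
        assert len(top & causal) >= len(causal) // 3


class TestMoment:
    def test_null_scan_calibrated_and_valid(self, null_cohort):
        _, M, S, _ = null_cohort
        Z = standardize(filter_probes(M)[0])
        y = S["status"].to_numpy(float)
        res = moment(y, Z)
        assert 0.75 < res.lambda_gc < 1.3
        t = res.table
        assert (t["se"] > 0).all()
        assert ((t["p"] > 0) & (t["p"] <= 1)).all()
        assert len(t) == Z.n_probes

    def test_detects_causal_probes(self, small_cohort):
        _, M, S, T = small_cohort
        Z = standardize(filter_probes(M)[0])
        y = S["status"].to_numpy(float)
        res = moment(y, Z).table
        top = set(res.nsmallest(25, "p")["Probe"])
        causal = set(T.causal_probe_ids) & set(Z.probe_ids)
        assert len(top & causal) >= len(causal) // 3

    def test_fallback_note_when_no_probe_passes(self):
        n, m = 80, 60
        M = standardized_matrix(n, m, seed=11)
        y = np.random.default_rng(12).standard_normal(n)
        res = moment(y, M, cfg=MomentConfig(group_p_threshold=1e-12))
        assert any("fallback" in note for note in res.notes)

    def test_refit_agrees_with_reuse_on_effects(self):
        """Per-probe variance refitting changes little when groups are
        stable; effect estimates agree closely with the fast path."""
        n, m = 80, 90
        M = standardized_matrix(n, m, seed=13)
        y = simulate_oreml_phenotype(M.values, 0.3, seed=14)
        fast = moment(y, M).table.set_index("Probe")["b"]
        slow = moment(
            y, M, cfg=MomentConfig(refit_variance_per_probe=True)
        ).table.set_index("Probe")["b"]
        r = np.corrcoef(fast.to_numpy(), slow.loc[fast.index].to_numpy())[0, 1]
        assert r > 0.99

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            MomentConfig(window_bp=-1)
        with pytest.raises(ValidationError):
            MomentConfig(group_p_threshold=1.5)
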