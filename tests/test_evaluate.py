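import numpy as np
import pandas as pd
import pytest

from mlmwas.evaluate import (
    UndefinedEstimateError,
    rb,
    rb_from_mwas,
    replication_n,
    stepwise_ctp_logistic,
)
from mlmwas.io import MwasTable


def _noisy_effects(n, r_true, se_scale, seed):
    """Two noisy views of correlated true effects with known SEs."""
    rng = np.random.default_rng(seed)
    t1 = rng.normal(0, 1, n)
    t2 = r_true * t1 + np.sqrt(max(1 - r_true**2, 0)) * rng.normal(0, 1, n)
    se1 = np.full(n, se_scale)
    se2 = np.full(n, se_scale)
    b1 = t1 + rng.normal(0, se_scale, n)
    b2 = t2 + rng.normal(0, se_scale, n)
    return b1, se1, b2, se2


class TestRb:
    def test_recovers_unit_correlation(self):
        ests = [
            rb(*_noisy_effects(500, 1.0, 0.6, seed)).rb for seed in range(20)
        ]
        assert np.mean(ests) == pytest.approx(1.0, abs=0.03)

    def test_recovers_partial_correlation(self):
        ests = [
            rb(*_noisy_effects(500, 0.5, 0.6, seed)).rb
            for seed in range(100, 120)
        ]
        assert np.mean(ests) == pytest.approx(0.5, abs=0.06)

    def test_corrects_naive_attenuation(self):
        b1, se1, b2, se2 = _noisy_effects(2000, 1.0, 0.8, seed=3)
        naive = np.corrcoef(b1, b2)[0, 1]
        corrected = rb(b1, se1, b2, se2).rb
        assert naive < 0.7
        assert corrected > naive + 0.2

    def test_jackknife_se_tracks_replicate_spread(self):
        ests, ses = [], []
        for seed in range(200, 230):
            r = rb(*_noisy_effects(300, 0.8, 0.5, seed))
            ests.append(r.rb)
            ses.append(r.se)
        emp = np.std(ests, ddof=1)
        assert np.mean(ses) == pytest.approx(emp, rel=0.6)
        assert all(s > 0 for s in ses)

    def test_clipping_flagged(self):
        # tiny samples can push the point estimate outside [-1, 1]
        found = False
        for seed in range(400, 460):
            r = rb(*_noisy_effects(12, 1.0, 1.0, seed))
            if r.clipped:
                assert abs(r.rb) == 1.0
                found = True
                break
        assert found

    def test_noise_dominated_raises(self):
        rng = np.random.default_rng(5)
        b = rng.normal(0, 0.1, 50)
        se = np.full(50, 5.0)  # claimed noise far exceeds observed spread
        with pytest.raises(UndefinedEstimateError):
            rb(b, se, b, se)

    def test_input_validation(self):
        b = np.arange(12.0) + 1
        with pytest.raises(ValueError, match="equal length"):
            rb(b, b, b[:-1], b[:-1])
        with pytest.raises(ValueError, match="at least 10"):
            rb(b[:5], b[:5], b[:5], b[:5])
        se_bad = np.full(12, -1.0)
        with pytest.raises(ValueError, match="positive"):
            rb(b, se_bad, b, np.full(12, 0.1))


class TestRbFromMwas:
    def _table(self, probes, b, p, seed=0):
        n = len(probes)
        t = pd.DataFrame(
            {
                "Chr": ["1"] * n,
                "Probe": probes,
                "bp": range(1, n + 1),
                "Gene": "g",
                "Orientation": "F",
                "b": b,
                "se": np.full(n, 0.05),
                "p": p,
            }
        )
        return MwasTable(table=t, method="linear", lambda_gc=1.0)

    def test_intersects_shared_probes(self):
        rng = np.random.default_rng(6)
        ids = [f"cg{j}" for j in range(40)]
        b = rng.normal(0, 1, 40)
        t1 = self._table(ids, b, np.full(40, 0.5))
        t2 = self._table(ids[5:], b[5:] + rng.normal(0, 0.05, 35),
                         np.full(35, 0.5))
        res = rb_from_mwas(t1, t2)
        assert res.n_probes == 35
        assert res.rb > 0.9

    def test_p_max_selection_on_discovery(self):
        rng = np.random.default_rng(7)
        ids = [f"cg{j}" for j in range(40)]
        b = rng.normal(0, 1, 40)
        p = np.where(np.arange(40) < 15, 1e-8, 0.9)
        t1 = self._table(ids, b, p)
        t2 = self._table(ids, b + rng.normal(0, 0.05, 40), np.full(40, 0.5))
        res = rb_from_mwas(t1, t2, p_max=1e-4, select_on=1)
        assert res.n_probes == 15


class TestStepwise:
    def _ctp(self, n, seed, informative=True):
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(np.ones(5) * 12, size=n)
        # estimated proportions sum to slightly less than 1 in practice
        pi = pi * rng.uniform(0.9, 1.0, size=n)[:, None]
        ctp = pd.DataFrame(pi * 100.0,
                           columns=["neu", "lym", "mono", "eos", "baso"])
        logits = -0.2 + (0.25 * (ctp["neu"] - ctp["neu"].mean())
                         if informative else 0.0)
        status = rng.random(n) < 1 / (1 + np.exp(-logits))
        return ctp, status.astype(int)

    def test_informative_cell_type_retained_with_positive_or(self):
        ctp, status = self._ctp(600, seed=8)
        out = stepwise_ctp_logistic(ctp, status)
        assert "neu" in out["cell_type"].tolist()
        row = out.set_index("cell_type").loc["neu"]
        assert row["odds_ratio"] > 1.0
        assert row["ci_low"] < row["odds_ratio"] < row["ci_high"]

    def test_null_composition_drops_everything(self):
        hits = 0
        for seed in range(9, 14):
            ctp, status = self._ctp(300, seed=seed, informative=False)
            out = stepwise_ctp_logistic(ctp, status)
            hits += len(out)
        # a 5% per-term false-positive rate leaves most runs empty
        assert hits <= 3

    def test_single_class_rejected(self):
        ctp, _ = self._ctp(50, seed=15)
        with pytest.raises(ValueError, match="both classes"):
            stepwise_ctp_logistic(ctp, np.ones(50, dtype=int))

    def test_exactly_compositional_table_rejected(self):
        rng = np.random.default_rng(16)
        pi = rng.dirichlet(np.ones(4) * 10, size=80)  # rows sum to 1
        ctp = pd.DataFrame(pi * 100.0, columns=list("abcd"))
        status = rng.integers(0, 2, 80)
        status[:2] = [0, 1]
        with pytest.raises(ValueError, match="compositional"):
            stepwise_ctp_logistic(ctp, status)


class TestReplicationN:
    def test_standard_power_calculation(self):
        assert replication_n(0.2, 0.05, 0.8) == 786

    def test_stringent_alpha_small_effect(self):
        alpha = 0.05 / 94
        assert replication_n(0.14, alpha, 0.8, two_sided=True) == 3784
        assert replication_n(0.14, alpha, 0.8, two_sided=False) == 3456

    def test_monotonicity(self):
        assert replication_n(0.1, 0.05, 0.8) > replication_n(0.2, 0.05, 0.8)
        assert replication_n(0.2, 0.01, 0.8) > replication_n(0.2, 0.05, 0.8)
        assert replication_n(0.2, 0.05, 0.9) > replication_n(0.2, 0.05, 0.8)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            replication_n(0.0, 0.05, 0.8)
        with pytest.raises(ValueError):
            replication_n(0.2, 1.5, 0.8)
        with pytest.raises(ValueError):
            replication_n(0.2, 0.05, 0.0)
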