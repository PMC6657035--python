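"""Logistic and linear EWAS models, Storey q-values, replication."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from ewasforest import (
    BetaMatrix,
    PhenotypeTable,
    assess_replication,
    ewas_linear,
    fit_logistic,
    phenotype_correlations,
    storey_qvalues,
)
from ewasforest.association import estimate_pi0, replication_summary


class TestFitLogistic:
    def test_two_by_two_cross_product(self):
        """On a saturated 2x2 design the MLE odds ratio is the cross-product."""
        y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        x = np.r_[np.ones(30), np.zeros(30)]
        res = fit_logistic(y, x)
        assert res.or_value == pytest.approx(4.0, abs=1e-6)
        assert res.converged and res.n_used == 60
        assert res.ci_low < 4.0 < res.ci_high

    def test_perfect_separation_flagged(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        res = fit_logistic(y, y.copy())
        assert not res.converged
        assert np.isnan(res.or_value)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones(10), np.random.default_rng(0).normal(size=10))

    def test_complete_case_count(self, rng):
        y = (rng.random(50) < 0.4).astype(float)
        x = rng.normal(size=50)
        x[:5] = np.nan
        res = fit_logistic(y, x)
        assert res.n_used == 45

    def test_null_ci_coverage(self):
        """Wald 95% CI covers OR = 1 about 95% of the time under the null."""
        covered = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            n = 150
            y = (rng.random(n) < 0.3).astype(float)
            x = rng.normal(size=n)
            res = fit_logistic(y, x)
            if res.converged and res.ci_low <= 1.0 <= res.ci_high:
                covered += 1
        assert 0.90 <= covered / n_sims <= 0.99


class TestEwasLinear:
    def test_effect_recovery(self, rng):
        n = 200
        y = (rng.random(n) < 0.5).astype(float)
        beta_vals = 0.5 + 0.02 * y[:, None] + rng.normal(scale=0.005, size=(n, 3))
        beta = BetaMatrix(pd.DataFrame(beta_vals, columns=["a", "b", "c"]))
        res = ewas_linear(beta, y)
        assert np.abs(res["coefficient"] - 0.02).max() < 0.005
        assert (res["model_kind"] == "linear_crude").all()

    def test_null_type_one_error(self, rng):
        n, p = 150, 2000
        y = (rng.random(n) < 0.3).astype(float)
        beta_vals = rng.uniform(0.3, 0.7, size=(n, p))
        beta = BetaMatrix(pd.DataFrame(beta_vals, columns=[f"c{j}" for j in range(p)]))
        res = ewas_linear(beta, y)
        frac = (res["p_value"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.02

    def test_compositional_collinearity_error(self, rng):
        n = 50
        y = (rng.random(n) < 0.4).astype(float)
        cells = rng.dirichlet(np.ones(7), size=n)
        covs = pd.DataFrame(cells, columns=[f"cell{j}" for j in range(7)])
        beta = BetaMatrix(pd.DataFrame(rng.uniform(0.2, 0.8, size=(n, 2)), columns=["a", "b"]))
        with pytest.raises(ValueError, match="collinear"):
            ewas_linear(beta, y, covariates=covs)


class TestStoreyQvalues:
    def test_bh_equivalence_with_pi0_one(self, rng):
        """With pi0 = 1 the q-values equal BH step-up adjusted p exactly."""
        for _ in range(50):
            m = int(rng.integers(5, 300))
            p = rng.uniform(1e-6, 1.0, size=m)
            qset = storey_qvalues(p, pi0=1.0)
            _, bh, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(qset.q_values, bh, rtol=0, atol=1e-12)

    def test_worked_example(self):
        qset = storey_qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        np.testing.assert_allclose(qset.q_values, [0.04, 0.04, 0.04, 0.04])

    def test_small_m_fallback(self):
        qset = storey_qvalues([0.05])
        assert qset.pi0 == 1.0
        assert qset.q_values[0] == pytest.approx(0.05)

    def test_pi0_recovery_on_uniform_null(self):
        # the single-replicate estimator has sd ~0.027 at m = 10000, so
        # recovery is judged on the mean over replicates
        ests = [estimate_pi0(np.random.default_rng(s).uniform(size=10000))
                for s in range(10)]
        assert np.mean(ests) == pytest.approx(1.0, abs=0.05)

    def test_qvalue_bounds_and_monotonicity(self, rng):
        p = rng.uniform(1e-8, 1.0, size=500)
        qset = storey_qvalues(p)
        q = qset.q_values
        assert (q <= 1.0).all()
        assert (q >= qset.pi0 * p / len(p) - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            storey_qvalues([])
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 0.0])
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.2])


class TestReplication:
    def _frame(self, or_values, p_values, kind="logistic_crude", converged=True):
        return pd.DataFrame(
            {
                "cpg_id": [f"cg{i}" for i in range(len(or_values))],
                "model_kind": kind,
                "coefficient": np.log(or_values),
                "or_value": or_values,
                "ci_low": np.asarray(or_values) * 0.5,
                "ci_high": np.asarray(or_values) * 2.0,
                "p_value": p_values,
                "n_used": 100,
                "converged": converged,
            }
        )

    def test_same_direction(self):
        out = assess_replication(self._frame([0.17], [0.001]), self._frame([0.57], [0.01]))
        assert bool(out["direction_consistent"].iloc[0])
        assert bool(out["replication_significant"].iloc[0])

    def test_sign_flip(self):
        out = assess_replication(self._frame([0.5], [0.001]), self._frame([2.0], [0.01]))
        assert not bool(out["direction_consistent"].iloc[0])

    def test_boundary_p_not_significant(self):
        out = assess_replication(self._frame([0.5], [0.001]), self._frame([0.6], [0.05]),
                                 alpha=0.05)
        assert not bool(out["replication_significant"].iloc[0])

    def test_unconverged_not_assessed(self):
        out = assess_replication(
            self._frame([0.5], [0.001]), self._frame([0.6], [0.01], converged=False)
        )
        assert pd.isna(out["direction_consistent"].iloc[0])

    def test_no_overlap_error(self):
        a = self._frame([0.5], [0.01])
        b = self._frame([0.5], [0.01], kind="logistic_adjusted")
        with pytest.raises(ValueError, match="overlap"):
            assess_replication(a, b)

    def test_summary_counts(self):
        disc = self._frame([0.2, 0.5, 0.8], [0.001] * 3)
        rep = self._frame([0.3, 2.0, 0.9], [0.01, 0.01, 0.5])
        counts = replication_summary(assess_replication(disc, rep))
        assert counts == {"n_pairs": 3, "n_direction_consistent": 2, "n_replicated": 1}


class TestPhenotypeCorrelations:
    def _pheno(self, n, rng):
        return PhenotypeTable(
            pd.DataFrame(
                {
                    "asthma": (rng.random(n) < 0.2).astype(int),
                    "sex": (rng.random(n) < 0.5).astype(int),
                    "atopy": (rng.random(n) < 0.4).astype(int),
                    "feno": np.exp(rng.normal(np.log(15), 0.5, size=n)),
                    "fev1_fvc": rng.uniform(0.6, 1.0, size=n),
                },
                index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
            )
        )

    def test_monotone_gives_rho_one(self, rng):
        pheno = self._pheno(30, rng)
        m = pd.Series(np.log(pheno.frame["feno"].to_numpy()) * 2 + 1,
                      index=pheno.frame.index)
        report = phenotype_correlations(m, pheno)
        row = report[report["variable"] == "log_feno"].iloc[0]
        assert row["estimate"] == pytest.approx(1.0)

    def test_negated_gives_minus_one(self, rng):
        pheno = self._pheno(30, rng)
        m = pd.Series(-np.log(pheno.frame["feno"].to_numpy()), index=pheno.frame.index)
        row = phenotype_correlations(m, pheno).set_index("variable").loc["log_feno"]
        assert row["estimate"] == pytest.approx(-1.0)

    def test_welch_power(self, rng):
        n = 100
        pheno = self._pheno(n, rng)
        atopy = pheno.frame["atopy"].to_numpy()
        m = pd.Series(rng.normal(size=n) + 1.0 * atopy, index=pheno.frame.index)
        row = phenotype_correlations(m, pheno).set_index("variable").loc["atopy"]
        assert row["p_value"] < 0.001

    def test_zero_variance_flagged(self, rng):
        pheno = self._pheno(30, rng)
        m = pd.Series(np.ones(30), index=pheno.frame.index)
        report = phenotype_correlations(m, pheno)
        assert (report["flag"] == "insufficient_or_constant").all()
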