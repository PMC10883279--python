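import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import reference_bh, reference_welch
from pilot import (
    CellDataset,
    association_tests,
    bh_adjust,
    fit_trend_models,
    moderated_de_test,
    wald_cluster_test,
    welch_proportion_test,
)
from pilot.interpretation import _huber_irls, _squeeze_var, welch_test


class TestTrendModels:
    def test_noiseless_linear_recovered_exactly(self):
        p = np.linspace(0, 1, 50)
        fit = fit_trend_models(2.0 * p, p)
        assert fit.family == "linear"
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-8)
        assert fit.r2_mod == pytest.approx(1.0, abs=1e-8)

    def test_planted_quadratic_recovered(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, 200)
        y = p**2 + rng.normal(0, 0.05, 200)
        fit = fit_trend_models(y, p)
        assert fit.family in ("quadratic", "linear_quadratic")
        quad = fit.coefficients[-1] if fit.family == "linear_quadratic" else fit.coefficients[0]
        assert quad == pytest.approx(1.0, rel=0.10)

    def test_huge_delta_matches_ordinary_least_squares(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, 80)
        y = 1.0 + 3.0 * p + rng.normal(0, 0.1, 80)
        x = np.column_stack([np.ones_like(p), p])
        beta, *_ = _huber_irls(x, y, delta=1e6)
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-6)

    def test_matches_statsmodels_rlm(self):
        """Huber IRLS agrees with the reference robust-regression implementation."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 1, 120)
        y = 0.5 + 2.0 * p + rng.normal(0, 0.3, 120)
        y[::17] += 4.0  # outliers
        x = np.column_stack([np.ones_like(p), p])
        beta, *_ = _huber_irls(x, y, delta=1.345)
        ref = sm.RLM(y, x, M=sm.robust.norms.HuberT(t=1.345)).fit(scale_est="mad")
        np.testing.assert_allclose(beta, ref.params, atol=5e-3)

    def test_huber_resists_single_large_outlier(self):
        rng = np.random.default_rng(14)
        n, sigma = 30, 0.3
        p = np.linspace(0, 1, n)
        y = 1.0 + 2.0 * p + rng.normal(0, sigma, n)
        clean = fit_trend_models(y, p).coefficients[0]
        y_out = y.copy()
        y_out[-1] += 10 * sigma
        robust = fit_trend_models(y_out, p).coefficients[0]
        x = np.column_stack([np.ones_like(p), p])
        ols_clean = np.linalg.lstsq(x, y, rcond=None)[0][1]
        ols_out = np.linalg.lstsq(x, y_out, rcond=None)[0][1]
        assert abs(robust - clean) < 0.25 * abs(clean)
        assert abs(ols_out - ols_clean) > abs(robust - clean)

    def test_result_independent_of_observation_order(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(0, 1, 100)
        y = 1 + p - p**2 + rng.normal(0, 0.1, 100)
        perm = rng.permutation(100)
        f1 = fit_trend_models(y, p)
        f2 = fit_trend_models(y[perm], p[perm])
        assert f1.family == f2.family
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-8)

    def test_constant_inputs_handled(self):
        p = np.linspace(0, 1, 20)
        fit = fit_trend_models(np.full(20, 3.0), p)
        assert fit.family == "none" and fit.p_value == 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_trend_models(p, np.full(20, 0.5))

    def test_family_selection_accuracy_at_high_snr(self):
        rng = np.random.default_rng(16)
        shapes = {
            "linear": lambda p: p,
            "quadratic": lambda p: p**2,
            "linear_quadratic": lambda p: p - p**2,
        }
        for fam, f in shapes.items():
            hits = 0
            for _ in range(30):
                p = rng.uniform(0, 1, 100)
                sig = f(p)
                y = 1 + sig + rng.normal(0, sig.std() / np.sqrt(10), 100)
                hits += fit_trend_models(y, p).family == fam
            assert hits >= 24, fam


class TestWaldClusterTest:
    def test_identical_data_gives_zero_statistic(self):
        rng = np.random.default_rng(20)
        n = 60
        p = rng.uniform(0, 1, n)
        y = 1 + 2 * p + rng.normal(0, 0.3, n)
        values = np.concatenate([y, y])
        pseudo = np.concatenate([p, p])
        mask = np.zeros(2 * n, bool)
        mask[:n] = True
        res = wald_cluster_test(values, pseudo, mask)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(21)
        n = 150
        p = rng.uniform(0, 1, 2 * n)
        y = 1 + 2 * p + rng.normal(0, 0.5, 2 * n)
        y[:n] += 2.5  # 5 sigma
        mask = np.zeros(2 * n, bool)
        mask[:n] = True
        assert wald_cluster_test(y, p, mask).p_value < 1e-4

    def test_null_rejection_rate_roughly_nominal(self):
        rng = np.random.default_rng(22)
        rej = 0
        reps = 120
        for _ in range(reps):
            n = 120
            p = rng.uniform(0, 1, 2 * n)
            y = 1 + 2 * p + rng.normal(0, 0.5, 2 * n)
            mask = np.zeros(2 * n, bool)
            mask[:n] = True
            rej += wald_cluster_test(y, p, mask).p_value < 0.05
        assert 0.005 <= rej / reps <= 0.12

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            wald_cluster_test(np.ones(15), np.linspace(0, 1, 15), np.arange(15) < 5)


class TestWelch:
    def test_worked_example(self):
        """A=(1,2,3), B=(4,5,6): t = -3.6742, dof = 4, p ~ 0.0214."""
        res = welch_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        t_ref, dof_ref = reference_welch(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert res.statistic == pytest.approx(t_ref, abs=1e-6)
        assert res.statistic == pytest.approx(-3.6742, abs=1e-4)
        assert res.dof == pytest.approx(4.0, abs=1e-9)
        assert res.p_value == pytest.approx(0.0214, abs=2e-4)

    def test_identical_groups_and_label_swap(self):
        a = np.array([0.3, 0.4, 0.5])
        res = welch_test(a, a.copy())
        assert res.statistic == 0.0 and res.p_value == 1.0
        b = np.array([0.6, 0.8, 0.7])
        fwd = welch_test(a, b)
        rev = welch_test(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_proportion_wrapper_selects_cluster(self, small_groups_cohort):
        ds, truth = small_groups_cohort
        from pilot import estimate_proportions

        props = estimate_proportions(ds)
        res = welch_proportion_test(
            props, truth.group_labels, cluster=ds.cluster_names[0],
            group_a="group0", group_b="group1",
        )
        # cluster c00 dominates group0 by construction
        assert res.effect > 0 and res.p_value < 1e-3


class TestModeratedDE:
    @staticmethod
    def _dataset(x, groups_of_sample):
        """Two cells per sample in the target cluster, plus filler cells in a
        second cluster (ignored by the test) to satisfy dataset invariants."""
        n = x.shape[0]
        samples = np.array([f"s{i // 2}" for i in range(n)] + ["s0", "s1"])
        clusters = np.array(["c1"] * n + ["c2", "c2"])
        x_full = np.vstack([x, np.zeros((2, x.shape[1]))])
        return (
            CellDataset(
                features=x_full,
                sample_of_cell=samples,
                cluster_of_cell=clusters,
                embedding=np.zeros((n + 2, 2)),
                feature_names=[f"g{j}" for j in range(x.shape[1])],
            ),
            pd.Series({f"s{i // 2}": groups_of_sample[i // 2] for i in range(n)}),
        )

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(30)
        x = rng.normal(0, 1, (40, 500))
        ds, groups = self._dataset(x, ["A"] * 10 + ["B"] * 10)
        out = moderated_de_test(ds, "c1", groups)
        frac = float((out["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_spiked_gene_ranks_first(self):
        rng = np.random.default_rng(31)
        x = rng.normal(0, 1, (40, 200))
        x[:20, 7] += 2.0
        ds, groups = self._dataset(x, ["A"] * 10 + ["B"] * 10)
        out = moderated_de_test(ds, "c1", groups)
        assert out.iloc[0]["feature"] == "g7"

    def test_infinite_prior_df_equals_pooled_variance_t(self):
        rng = np.random.default_rng(32)
        x = rng.normal(0, 1, (30, 50))
        ds, groups = self._dataset(x, ["A"] * 8 + ["B"] * 7)
        out = moderated_de_test(ds, "c1", groups, prior_df=np.inf).set_index("feature")
        na, nb = 16, 14
        xa, xb = x[:na], x[na:]
        dof = na + nb - 2
        s2 = (xa.var(0, ddof=0) * na + xb.var(0, ddof=0) * nb) / dof
        pooled = s2.mean()
        t_ref = (xa.mean(0) - xb.mean(0)) / np.sqrt(pooled * (1 / na + 1 / nb))
        got = out.loc[[f"g{j}" for j in range(50)], "t"].to_numpy()
        np.testing.assert_allclose(got, t_ref, atol=1e-10)

    def test_matches_limma_ebayes(self, tmp_path):
        """Variance shrinkage and moderated t agree with limma on a reference fixture."""
        rng = np.random.default_rng(33)
        n1, n2, n_genes = 12, 10, 80
        v = 6.0 / rng.chisquare(6.0, n_genes)
        x = rng.normal(0, np.sqrt(v)[:, None], (n_genes, n1 + n2))
        expr = tmp_path / "expr.tsv"
        pd.DataFrame(x).to_csv(expr, sep="\t", index=False)
        rfile = tmp_path / "cc.R"
        rfile.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{expr}"))\n'
            f'group <- factor(c(rep("A",{n1}), rep("B",{n2})), levels=c("B","A"))\n'
            "fit <- eBayes(lmFit(x, model.matrix(~group)))\n"
            'out <- data.frame(t=fit$t[,2], d0=fit$df.prior, s02=fit$s2.prior)\n'
            f'write.table(out, "{tmp_path}/limma_out.tsv", sep="\\t", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(rfile)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t")
        dof = n1 + n2 - 2
        xa, xb = x[:, :n1], x[:, n1:]
        s2 = (xa.var(1, ddof=0) * n1 + xb.var(1, ddof=0) * n2) / dof
        post, d0, s02 = _squeeze_var(s2, dof)
        t = (xa.mean(1) - xb.mean(1)) / np.sqrt(post * (1 / n1 + 1 / n2))
        assert d0 == pytest.approx(float(ref["d0"][0]), rel=1e-6)
        assert s02 == pytest.approx(float(ref["s02"][0]), rel=1e-6)
        np.testing.assert_allclose(t, ref["t"].to_numpy(), atol=1e-6)


class TestBHAdjust:
    def test_worked_examples_match_stepup_recursion(self):
        for p in ([0.01, 0.02, 0.03, 0.04], [0.005, 0.5], [0.2]):
            np.testing.assert_allclose(bh_adjust(np.array(p)), reference_bh(np.array(p)))
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust(np.array([0.005, 0.5])), [0.01, 0.5])

    def test_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(40)
        p = rng.uniform(0, 1, 200)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_adjust(np.array([0.1, np.nan]))


class TestAssociations:
    @staticmethod
    def _clustering(labels, ids):
        from pilot.clustering import SampleClustering

        return SampleClustering(
            labels=np.asarray(labels), resolution=1.0, silhouette=0.5,
            knn=5, sample_ids=ids,
        )

    def test_identical_discrete_covariate_is_detected(self):
        ids = [f"s{i:02d}" for i in range(40)]
        labels = np.array([1] * 20 + [2] * 20)
        meta = pd.DataFrame({"status": ["ctrl"] * 20 + ["case"] * 20}, index=ids)
        out = association_tests(self._clustering(labels, ids), meta)
        assert out.loc[0, "test"] == "chi2"
        assert out.loc[0, "p_value"] < 1e-6

    def test_progression_against_itself_is_perfectly_correlated(self):
        from pilot.trajectory import TrajectoryResult

        ids = [f"s{i}" for i in range(20)]
        prog = np.arange(1, 21)
        traj = TrajectoryResult(
            sample_ids=ids, coordinates=np.zeros((20, 2)), backbone=np.zeros((2, 2)),
            backbone_samples=ids[:2], root_sample=ids[0],
            arc_position=prog.astype(float), progression=prog,
        )
        meta = pd.DataFrame({"score": prog.astype(float)}, index=ids)
        out = association_tests(traj, meta)
        assert out.loc[0, "test"] == "spearman"
        assert out.loc[0, "statistic"] == pytest.approx(1.0)
        assert out.loc[0, "p_value"] < 1e-10

    def test_independent_covariate_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(41)
        ids = [f"s{i:02d}" for i in range(40)]
        labels = np.array([1] * 20 + [2] * 20)
        clustering = self._clustering(labels, ids)
        rej = 0
        reps = 400
        for _ in range(reps):
            meta = pd.DataFrame({"x": rng.normal(size=40)}, index=ids)
            out = association_tests(clustering, meta)
            rej += out.loc[0, "p_value"] < 0.05
        assert 0.025 <= rej / reps <= 0.085

    def test_single_level_covariate_skipped(self):
        ids = [f"s{i}" for i in range(10)]
        labels = np.array([1] * 5 + [2] * 5)
        meta = pd.DataFrame({"const": ["x"] * 10, "ok": ["a", "b"] * 5}, index=ids)
        out = association_tests(self._clustering(labels, ids), meta).set_index("covariate")
        assert out.loc["const", "test"] == "skipped"
        assert out.loc["ok", "test"] == "chi2"
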