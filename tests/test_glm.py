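"""NB GLM fitting, likelihood-ratio contrast tests, logCPM, BH and
ranking — checked against closed forms, independent optimizers and the
reference implementation."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import methdiff as md
from methdiff.glm import benjamini_hochberg, nb_deviance


def fit_toy(toy, dispersion=None):
    disp = toy.dispersion if dispersion is None else dispersion
    return md.fit(toy.counts, toy.design, toy.lib_sizes, dispersion=disp)


class TestReportedCoefficients:
    def test_single_example_closed_form(self, toys):
        # the 4-observation design is saturated, so augmented-fit
        # coefficients are exact log ratios of prior-augmented counts
        fit = fit_toy(toys["single"])
        coefs = fit.reported_coefficients[0]
        assert coefs[2] == pytest.approx(np.log2(2.125 / 12.125), abs=1e-8)
        assert coefs[3] == pytest.approx(np.log2(11.125 / 0.125), abs=1e-8)

    def test_saturated_deviance_zero(self, toys):
        fit = fit_toy(toys["single"])
        assert fit.deviance[0] == pytest.approx(0.0, abs=1e-6)

    def test_poisson_fit_matches_logistic_regression(self):
        # dispersion 0: per-condition coefficient = logit of pooled proportion
        counts = np.array([[3, 9, 10, 2, 8, 8]])
        des = md.design_from_groups(["A", "A", "B"])
        fit = md.fit(counts, des, lib_sizes=100.0, dispersion=0.0, prior_count=0.0)
        beta = fit.coefficients[0]
        # pooled A: me 13, un 11; B: me 8, un 8
        assert beta[3] == pytest.approx(np.log(13 / 11), abs=1e-6)
        assert beta[4] == pytest.approx(np.log(8 / 8), abs=1e-6)

    def test_negative_counts_rejected(self, toys):
        toy = toys["single"]
        with pytest.raises(ValueError, match="non-negative"):
            md.fit(np.array([[-1, 2, 3, 4]]), toy.design, toy.lib_sizes, dispersion=0.1)


class TestLRT:
    def test_replicated_example_against_numeric_optimizer(self, toys):
        """LR equals the deviance gap found by direct NB likelihood
        maximization under the null constraint (independent route)."""
        toy = toys["replicated"]
        fit = fit_toy(toy)
        res = md.lrt(fit, toy.contrast)

        y = toy.counts[0].astype(float)
        X = toy.design.matrix
        offset = np.log(toy.lib_sizes)
        phi = toy.dispersion
        r = 1.0 / phi

        def nll(beta, design):
            mu = np.exp(design @ beta + offset)
            return -np.sum(stats.nbinom.logpmf(y, r, r / (r + mu)))

        def grad(beta, design):
            mu = np.exp(design @ beta + offset)
            return -design.T @ ((y - mu) / (1.0 + phi * mu))

        # null: one shared methylation coefficient for A and B
        X_null = np.column_stack([X[:, :4], X[:, 4] + X[:, 5]])
        best_full = optimize.minimize(nll, np.full(6, -2.0), args=(X,), jac=grad,
                                      method="BFGS", options={"gtol": 1e-10, "maxiter": 5000})
        best_null = optimize.minimize(nll, np.full(5, -2.0), args=(X_null,), jac=grad,
                                      method="BFGS", options={"gtol": 1e-10, "maxiter": 5000})
        lr_oracle = 2.0 * (best_null.fun - best_full.fun)
        assert res.table["LR"][0] == pytest.approx(lr_oracle, abs=1e-4)
        assert res.table["PValue"][0] == pytest.approx(stats.chi2.sf(lr_oracle, 1), rel=1e-4)

    def test_identical_conditions_null(self):
        counts = np.array([[5, 7, 5, 7]])
        des = md.design_from_groups(["A", "B"])
        fit = md.fit(counts, des, lib_sizes=100.0, dispersion=0.05)
        res = md.lrt(fit, "ConditionB - ConditionA")
        assert res.table["LR"][0] == pytest.approx(0.0, abs=1e-8)
        assert res.table["PValue"][0] == pytest.approx(1.0, abs=1e-6)

    def test_contrast_on_sample_columns_rejected(self, toys):
        toy = toys["single"]
        fit = fit_toy(toy)
        bad = np.array([1.0, 0.0, -1.0, 1.0])
        with pytest.raises(ValueError, match="sample-coverage"):
            md.lrt(fit, bad)

    def test_lr_monotone_nonincreasing_in_dispersion(self, toys):
        toy = toys["replicated"]
        lrs = []
        for phi in [0.0, 0.01, 0.05, 0.2, 1.0]:
            res = md.lrt(fit_toy(toy, dispersion=phi), toy.contrast)
            lrs.append(res.table["LR"][0])
        assert all(a >= b - 1e-9 for a, b in zip(lrs, lrs[1:]))

    def test_multi_contrast_df(self):
        counts = np.array([[3, 9, 10, 2, 8, 8]])
        des = md.design_from_groups(["A", "B", "C"])
        fit = md.fit(counts, des, lib_sizes=100.0, dispersion=0.02)
        contrasts = md.make_contrasts(des, {"BvsA": "ConditionB - ConditionA",
                                            "CvsA": "ConditionC - ConditionA"}).to_numpy()
        res = md.lrt(fit, contrasts)
        assert res.df == 2


class TestInvariances:
    def test_reparametrization_invariance(self, toys):
        toy = toys["replicated"]
        res_gm = md.lrt(fit_toy(toy), toy.contrast)

        des_int = md.design_from_groups(["A", "A", "B", "B"], intercept=True)
        fit_int = md.fit(toy.counts, des_int, toy.lib_sizes, dispersion=toy.dispersion)
        res_int = md.lrt(fit_int, "ConditionB")

        assert res_int.table["LR"][0] == pytest.approx(res_gm.table["LR"][0], abs=1e-6)
        assert res_int.table["PValue"][0] == pytest.approx(res_gm.table["PValue"][0], rel=1e-6)
        assert res_int.table["logFC"][0] == pytest.approx(res_gm.table["logFC"][0], abs=1e-6)

    def test_library_size_scale_invariance(self, toys):
        toy = toys["replicated"]
        res1 = md.lrt(fit_toy(toy), toy.contrast)
        fit_scaled = md.fit(toy.counts, toy.design, toy.lib_sizes * 73.0, dispersion=toy.dispersion)
        res2 = md.lrt(fit_scaled, toy.contrast)
        assert res2.table["PValue"][0] == pytest.approx(res1.table["PValue"][0], rel=1e-8)
        assert res2.table["logFC"][0] == pytest.approx(res1.table["logFC"][0], abs=1e-8)

    def test_lr_invariant_to_sample_block_offset_shift(self, toys):
        """Adding a per-sample constant to the offsets (a vector in the
        sample-coverage column space) must not change the LR."""
        toy = toys["replicated"]
        res1 = md.lrt(fit_toy(toy), toy.contrast)
        per_sample = np.repeat([0.3, -0.7, 1.1, 0.05], 2)
        libs = toy.lib_sizes * np.exp(per_sample)
        res2 = md.lrt(md.fit(toy.counts, toy.design, libs, dispersion=toy.dispersion), toy.contrast)
        assert res2.table["LR"][0] == pytest.approx(res1.table["LR"][0], abs=1e-6)


class TestAveLogCPM:
    def test_worked_examples(self, toys):
        single = md.ave_log_cpm(toys["single"].counts, toys["single"].lib_sizes)
        repl = md.ave_log_cpm(toys["replicated"].counts, toys["replicated"].lib_sizes)
        assert single[0] == pytest.approx(np.log2(1e6 * 8.25 / 104), abs=1e-10)
        assert repl[0] == pytest.approx(np.log2(1e6 * 10.375 / 104), abs=1e-10)

    def test_zero_counts_near_zero_logcpm(self):
        out = md.ave_log_cpm(np.zeros((1, 4)), np.full(4, 2e6), prior=2)
        assert out[0] == pytest.approx(0.0, abs=1e-5)


class TestBHAndRanking:
    def test_bh_matches_direct_definition(self):
        p = np.array([0.001, 0.02, 0.04, 0.8])
        adj = benjamini_hochberg(p)
        # direct step-up: p_(i) * n / i, cumulative min from the right
        n = len(p)
        expected = np.minimum.accumulate((np.sort(p) * n / np.arange(1, n + 1))[::-1])[::-1]
        assert np.allclose(np.sort(adj), expected)
        # step-up rule: largest i with p_(i) <= i/n * alpha is i=2
        calls_sig = adj <= 0.05
        assert calls_sig.tolist() == [True, True, False, False]

    def test_bh_monotone_and_dominates_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_decide_tests_signs(self):
        table = pd.DataFrame({
            "logFC": [2.0, -1.0, 3.0, 0.5],
            "logCPM": 1.0,
            "LR": 1.0,
            "PValue": [0.001, 0.02, 0.04, 0.8],
        })
        table["FDR"] = benjamini_hochberg(table["PValue"].to_numpy())
        res = md.DMTestResult(table=table, contrast=np.array([1.0]), df=1)
        calls, summary = md.decide_tests(res, fdr=0.05)
        assert calls.tolist() == [1, -1, 0, 0]
        assert summary.tolist() == [1, 2, 1]

    def test_all_p_one_gives_no_calls(self):
        table = pd.DataFrame({"logFC": [1.0, -2.0], "logCPM": 0.0, "LR": 0.0,
                              "PValue": [1.0, 1.0], "FDR": [1.0, 1.0]})
        res = md.DMTestResult(table=table, contrast=np.array([1.0]), df=1)
        calls, _ = md.decide_tests(res)
        assert calls.tolist() == [0, 0]

    def test_top_tags_orders_by_p(self):
        table = pd.DataFrame({"logFC": [0.1, 5.0, -2.0], "logCPM": 0.0, "LR": 0.0,
                              "PValue": [0.5, 0.001, 0.01]})
        table["FDR"] = benjamini_hochberg(table["PValue"].to_numpy())
        res = md.DMTestResult(table=table, contrast=np.array([1.0]), df=1)
        ranked = md.top_tags(res)
        assert ranked.index.tolist() == [1, 2, 0]

    def test_top_tags_matches_brute_force(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame({
            "logFC": rng.normal(size=50),
            "logCPM": 0.0,
            "LR": rng.chisquare(1, 50),
            "PValue": rng.uniform(size=50),
        })
        table["FDR"] = benjamini_hochberg(table["PValue"].to_numpy())
        res = md.DMTestResult(table=table, contrast=np.array([1.0]), df=1)
        got = md.top_tags(res, n=10, p_cutoff=0.9)
        brute = table.sort_values("PValue", kind="stable")
        brute = brute[brute["FDR"] <= 0.9].head(10)
        assert got.index.tolist() == brute.index.tolist()


class TestAgainstReferenceImplementation:
    """Cross-check logFC/LR/PValue against the reference NB GLM fitter
    (edgeR via Rscript) on a small random dataset."""

    def test_matches_edger_on_random_data(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the reference cross-check")
        rng = np.random.default_rng(17)
        counts = rng.integers(0, 40, size=(25, 8))
        np.savetxt(tmp_path / "counts.tsv", counts, fmt="%d", delimiter="\t")
        script = tmp_path / "ref.R"
        script.write_text(
            """
            suppressMessages(library(edgeR))
            counts <- as.matrix(read.delim('%s', header=FALSE))
            Condition <- factor(c('A','A','B','B'))
            design <- modelMatrixMeth(~0+Condition)
            fit <- glmFit(counts, design, lib.size=rep(1000,8), dispersion=0.05)
            lrt <- glmLRT(fit, contrast=makeContrasts(ConditionB-ConditionA, levels=design))
            write.table(lrt$table, '%s', sep='\\t', row.names=FALSE)
            """
            % (tmp_path / "counts.tsv", tmp_path / "ref.tsv")
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t")

        des = md.design_from_groups(["A", "A", "B", "B"])
        fit = md.fit(counts, des, lib_sizes=1000.0, dispersion=0.05)
        res = md.lrt(fit, "ConditionB - ConditionA")
        assert np.allclose(res.table["LR"], ref["LR"], atol=1e-4)
        # reported coefficients differ only by iterative-convergence noise
        assert np.allclose(res.table["logFC"], ref["logFC"], atol=2e-3)
        assert np.allclose(res.table["PValue"], ref["PValue"], rtol=1e-4, atol=1e-12)


def test_nb_deviance_zero_at_exact_fit():
    y = np.array([[1.0, 4.0, 9.0]])
    assert nb_deviance(y, y, 0.3)[0] == pytest.approx(0.0, abs=1e-12)
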