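"""Moderated-t screening, BH, CV, correlation and Kruskal-Wallis."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import surfquant as sq
from surfquant.diffstats import ModeratedFitParams, estimate_prior


def design_for(columns, n_biotin):
    return pd.DataFrame(
        {
            "sample_id": list(columns),
            "group": ["biotin"] * n_biotin + ["mock"] * (len(columns) - n_biotin),
        }
    )


class TestModeratedTTest:
    def test_fixed_prior_worked_example(self):
        """biotin [5,6] vs mock [3,4] with d0=4, s0²=0.5: pooled s²=0.5,
        posterior (4·0.5+2·0.5)/6=0.5, SE=√0.5, t=2.8284, df=6."""
        data = pd.DataFrame(
            {"b1": [5.0], "b2": [6.0], "m1": [3.0], "m2": [4.0]}, index=["P1"]
        )
        res = sq.moderated_ttest(
            data, design_for(data.columns, 2), ModeratedFitParams(4.0, 0.5)
        )
        row = res.loc["P1"]
        assert row["log2fc"] == pytest.approx(2.0)
        assert row["s2_pooled"] == pytest.approx(0.5)
        assert row["t_mod"] == pytest.approx(2.0 / np.sqrt(0.5), abs=1e-4)
        assert row["df"] == 6.0
        assert row["p"] == pytest.approx(2 * stats.t.sf(2.8284271, 6), rel=1e-6)

    def test_moderation_off_limit_matches_pooled_t(self):
        """d0 -> 0 reduces to the textbook pooled two-sample t (1e-12)."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n1, n2 = rng.integers(2, 6, size=2)
            X = pd.DataFrame(
                rng.normal(size=(50, n1 + n2)),
                columns=[f"s{i}" for i in range(n1 + n2)],
            )
            res = sq.moderated_ttest(
                X, design_for(X.columns, n1), ModeratedFitParams(1e-300, 1.0)
            )
            ref = stats.ttest_ind(X.iloc[:, :n1], X.iloc[:, n1:], axis=1)
            np.testing.assert_allclose(res["t_mod"], ref.statistic, atol=1e-12)
            np.testing.assert_allclose(res["p"], ref.pvalue, atol=1e-12)

    def test_identical_group_means_give_zero(self):
        data = pd.DataFrame(
            {"b1": [1.0, 5.0], "b2": [3.0, 7.0], "m1": [1.0, 5.0], "m2": [3.0, 7.0]},
            index=["P1", "P2"],
        )
        res = sq.moderated_ttest(
            data, design_for(data.columns, 2), ModeratedFitParams(4.0, 0.5)
        )
        assert (res["log2fc"] == 0).all()
        assert (res["t_mod"] == 0).all()

    def test_underobserved_protein_skipped(self):
        data = pd.DataFrame(
            {"b1": [1.0, 1.0], "b2": [np.nan, 2.0], "m1": [0.0, 0.5], "m2": [1.0, 1.5]},
            index=["P1", "P2"],
        )
        res = sq.moderated_ttest(
            data, design_for(data.columns, 2), ModeratedFitParams(4.0, 0.5)
        )
        assert not res.loc["P1", "tested"]
        assert np.isnan(res.loc["P1", "p"])
        assert res.attrs["n_skipped"] == 1

    def test_prior_estimation_recovers_hierarchy(self):
        """Variances drawn from the scaled inverse-chi2 hierarchy are
        recovered by the moment fit."""
        rng = np.random.default_rng(3)
        n = 5000
        d0_true, s0_true, d = 8.0, 2.0, 4.0
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(int(d), n) / d
        fit = estimate_prior(s2, np.full(n, d))
        assert fit.d0 == pytest.approx(d0_true, rel=0.25)
        assert fit.s0_sq == pytest.approx(s0_true, rel=0.15)

    def test_constant_variance_gives_infinite_prior_df(self):
        rng = np.random.default_rng(4)
        d = np.full(200, 1e6)  # enormous df: observed s2 almost constant
        s2 = 1.0 + rng.normal(0, 1e-9, 200)
        fit = estimate_prior(s2, d)
        assert np.isinf(fit.d0)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
    def test_matches_bioconductor_limma(self, tmp_path):
        """Independent oracle: lmFit/eBayes on the same matrix."""
        rng = np.random.default_rng(7)
        X = pd.DataFrame(
            rng.normal(0, rng.uniform(0.5, 2, size=(60, 1)), size=(60, 8)),
            index=[f"P{i}" for i in range(60)],
            columns=[f"s{i}" for i in range(8)],
        )
        X.iloc[:20, :4] += 1.0
        res = sq.moderated_ttest(X, design_for(X.columns, 4), "estimate")
        X.to_csv(tmp_path / "mat.csv")
        script = tmp_path / "cmp.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.csv("{tmp_path}/mat.csv", row.names=1))\n'
            'design <- cbind(Intercept=1, biotin=c(1,1,1,1,0,0,0,0))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'out <- data.frame(t=fit$t[,"biotin"], p=fit$p.value[,"biotin"])\n'
            f'write.csv(out, "{tmp_path}/limma.csv")\n'
            'cat(fit$df.prior, fit$s2.prior)\n'
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        d0_r, s0_r = map(float, proc.stdout.split())
        fit = res.attrs["fit"]
        assert fit.d0 == pytest.approx(d0_r, rel=1e-5)
        assert fit.s0_sq == pytest.approx(s0_r, rel=1e-5)
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        np.testing.assert_allclose(res["t_mod"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(res["p"], ref["p"], atol=1e-8)


def brute_force_bh(p):
    """min over j >= i (in sorted order) of p_(j) * m / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    for rank_pos, i in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        out[i] = min(1.0, min(candidates))
    return out


class TestBhAdjust:
    def test_worked_example(self):
        assert sq.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_is_itself(self):
        assert sq.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sq.bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            sq.bh_adjust([1.5])

    @settings(max_examples=300, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_brute_force_and_contract(self, p):
        got = sq.bh_adjust(p)
        np.testing.assert_allclose(got, brute_force_bh(p), rtol=1e-12)
        assert (got >= np.asarray(p) - 1e-15).all()
        assert (got <= 1.0).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 200)
        np.testing.assert_allclose(
            sq.bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12
        )


class TestSignificantProteins:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["log2fc", "p_adj", "reportable"],
            index=[f"P{i}" for i in range(len(rows))],
        )

    def test_threshold_gating(self):
        res = self._results(
            [(0.6, 0.05, True), (0.4, 0.01, True), (0.6, 0.05, False), (0.6, 0.2, True)]
        )
        assert sq.significant_proteins(res) == {"P0"}

    def test_configurable_thresholds(self):
        res = self._results([(0.3, 0.2, True)])
        assert sq.significant_proteins(res, lfc_min=0.25, padj_max=0.25) == {"P0"}


class TestCv:
    def test_examples(self):
        assert sq.cv([10, 10, 10]) == 0.0
        assert sq.cv([8, 12]) == pytest.approx(28.284, abs=1e-3)

    @settings(max_examples=50, deadline=None)
    @given(
        values=st.lists(st.floats(min_value=1.0, max_value=1e4), min_size=2, max_size=10),
        c=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, values, c):
        assert sq.cv(np.asarray(values) * c) == pytest.approx(
            sq.cv(values), rel=1e-9, abs=1e-9
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            sq.cv([5.0])
        with pytest.raises(ValueError):
            sq.cv([-2.0, 2.0])


class TestPrecisionReport:
    def test_identical_replicates_zero_cv(self, two_group_design):
        linear = pd.DataFrame(
            {s: [100.0, 50.0] for s in two_group_design["sample_id"]},
            index=["P1", "P2"],
        )
        cv_table, summary = sq.precision_report(linear, two_group_design)
        assert (cv_table.to_numpy() == 0).all()
        assert (summary["median_cv"] == 0).all()

    def test_median_matches_hand_computation(self, two_group_design):
        rng = np.random.default_rng(0)
        linear = pd.DataFrame(
            rng.uniform(10, 100, size=(7, 6)),
            index=[f"P{i}" for i in range(7)],
            columns=two_group_design["sample_id"],
        )
        cv_table, summary = sq.precision_report(linear, two_group_design)
        b_cols = two_group_design.query("group=='biotin'")["sample_id"]
        hand = [sq.cv(linear.loc[p, list(b_cols)]) for p in linear.index]
        assert summary.loc["X/biotin", "median_cv"] == pytest.approx(np.median(hand))

    def test_protein_cv_shrinks_with_peptide_count(self):
        """Summing ~10 independently noisy peptides shrinks the protein
        CV by about sqrt(n_eff) relative to the per-peptide CV."""
        rng = np.random.default_rng(8)
        n_prot, n_pep, n_rep, cv_pep = 300, 10, 4, 0.05
        sigma = np.sqrt(np.log(1 + cv_pep**2))
        areas = rng.uniform(1e3, 1e5, size=(n_prot, n_pep))
        noise = np.exp(rng.normal(0, sigma, size=(n_prot, n_pep, n_rep)) - sigma**2 / 2)
        protein = (areas[:, :, None] * noise).sum(axis=1)
        cvs = protein.std(axis=1, ddof=1) / protein.mean(axis=1) * 100
        # variance-of-sum closed form per protein
        expected = 100 * cv_pep * np.sqrt((areas**2).sum(1)) / areas.sum(1)
        assert np.median(cvs) == pytest.approx(np.median(expected), rel=0.15)
        assert np.median(cvs) < 2.5


class TestPearson:
    def test_perfect_correlations(self):
        t = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 4, 6], "c": [-1.0, -2, -3]})
        r, p = sq.pearson_method_correlation(t)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 3, 2, 4])
        t = pd.DataFrame({"x": x, "y": y})
        r, p = sq.pearson_method_correlation(t)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r.loc["x", "y"] == pytest.approx(num / den, rel=1e-12)
        rr = num / den
        tstat = rr * np.sqrt(2 / (1 - rr**2))
        assert p.loc["x", "y"] == pytest.approx(2 * stats.t.sf(abs(tstat), 2), rel=1e-9)

    def test_zero_variance_rejected(self):
        t = pd.DataFrame({"x": [1.0, 1, 1], "y": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="variance"):
            sq.pearson_method_correlation(t)


class TestKruskalWallis:
    def test_symmetric_groups_give_zero(self):
        h, p = sq.kruskal_wallis([1, 2], [1, 2])
        assert h == pytest.approx(0.0)

    def test_hand_computed_example(self):
        """Ranks 1..4, R1=3, R2=7: H = 0.6 * 29 - 15 = 2.4."""
        h, p = sq.kruskal_wallis([1, 2], [3, 4])
        assert h == pytest.approx(2.4)
        assert p == pytest.approx(float(stats.chi2.sf(2.4, 1)), rel=1e-9)

    def test_all_identical_values(self):
        assert sq.kruskal_wallis([5, 5], [5, 5]) == (0.0, 1.0)

    def test_null_calibration(self):
        """Under identical distributions the p-value is ~uniform."""
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(300):
            g = [rng.normal(size=30) for _ in range(3)]
            ps.append(sq.kruskal_wallis(*g)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
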