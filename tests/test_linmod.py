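import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from _oracles import naive_bh
from conftest import make_matrix
from crossdiff.data import DegenerateDataError, DesignError, InsufficientDataError
from crossdiff.linmod import (
    StrainContrastModel,
    adjust_bh,
    fit_condition_model,
    moderate_variances,
    moderated_t,
    run_strain_contrasts,
)
from crossdiff.simdata import SimConfig, generate_dataset


class TestConditionModel:
    def test_hand_example_two_conditions(self):
        """Samples {0,0} and {1,3}: means 0 and 2, pooled s² = 1, df = 2."""
        m = make_matrix([[0.0, 0.0, 1.0, 3.0]],
                        strains=["A"] * 4,
                        treatments=["control", "control", "exposed", "exposed"])
        means, s2, df, counts = fit_condition_model(m)
        assert means.loc["g0", "A:control"] == 0.0
        assert means.loc["g0", "A:exposed"] == 2.0
        assert s2.loc["g0"] == pytest.approx(1.0)
        assert df == 2

    def test_constant_gene(self):
        m = make_matrix([[5.0] * 8],
                        strains=["A"] * 4 + ["B"] * 4,
                        treatments=["control", "control", "exposed", "exposed"] * 2)
        means, s2, df, _ = fit_condition_model(m)
        assert (means.loc["g0"] == 5.0).all()
        assert s2.loc["g0"] == 0.0

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 16))
        strains = ["A"] * 8 + ["B"] * 8
        treatments = (["control"] * 4 + ["exposed"] * 4) * 2
        m = make_matrix(vals, strains, treatments)
        means, s2, df, _ = fit_condition_model(m)
        cond = [f"{s}:{t}" for s, t in zip(strains, treatments)]
        levels = sorted(set(cond))
        X = np.array([[c == lev for lev in levels] for c in cond], dtype=float)
        for g in range(20):
            beta, rss, *_ = np.linalg.lstsq(X, vals[g], rcond=None)
            np.testing.assert_allclose(
                means.iloc[g][levels].to_numpy(), beta, rtol=1e-10)
            assert s2.iloc[g] == pytest.approx(rss[0] / df, rel=1e-10)

    def test_zero_residual_df_raises(self):
        m = make_matrix([[1.0, 2.0]], strains=["A", "A"],
                        treatments=["control", "exposed"])
        with pytest.raises(DesignError):
            fit_condition_model(m)

    def test_effect_estimate_unbiased(self):
        """Mean of β̂ over 500 simulated genes with a common true effect
        lands within 3 SEs of that effect."""
        delta = 0.7
        cfg = SimConfig(n_genes=500,
                        class_counts={"TYPE_I_UP": 500},
                        effect_size={"TYPE_I_UP": delta},
                        seed=2)
        matrix, _ = generate_dataset(cfg)
        res = run_strain_contrasts(matrix)
        betas = res.contrasts["L-E"]["log2fc"]
        se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - delta) < 3 * se


class TestModerateVariances:
    def test_prior_parameter_recovery(self):
        """Sample variances from the d0=4, s0²=0.05 hierarchy are inverted
        back to both hyperparameters within 10%."""
        rng = np.random.default_rng(1)
        d0_true, s0_true, df = 4.0, 0.05, 24
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=10000)
        s2 = sigma2 * rng.chisquare(df, size=10000) / df
        d0, s0_sq, _ = moderate_variances(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.10)
        assert s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_homoskedastic_input_gives_infinite_d0(self):
        s2 = np.full(100, 0.3)
        d0, s0_sq, s_tilde = moderate_variances(s2, 24)
        assert math.isinf(d0)
        assert np.allclose(s_tilde, s0_sq)

    def test_forced_d0_zero_disables_moderation(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(5, size=50)
        _, _, s_tilde = moderate_variances(s2, 10, d0=0.0)
        np.testing.assert_array_equal(s_tilde, s2)

    def test_shrinkage_direction(self):
        rng = np.random.default_rng(3)
        s2 = 0.05 * 4 / rng.chisquare(4, size=2000) * rng.chisquare(24, 2000) / 24
        d0, s0_sq, s_tilde = moderate_variances(s2, 24)
        sign_shift = np.sign(s_tilde - s2)
        sign_target = np.sign(s0_sq - s2)
        assert (sign_shift == sign_target)[s2 != s0_sq].all()
        assert np.all(s_tilde >= np.minimum(s2, s0_sq))
        assert np.all(s_tilde <= np.maximum(s2, s0_sq))

    def test_zero_variances_handled(self):
        s2 = np.concatenate([np.zeros(5), np.full(50, 0.1)])
        d0, s0_sq, s_tilde = moderate_variances(s2, 4)
        assert np.isfinite(s0_sq) and s0_sq > 0
        assert np.all(np.isfinite(s_tilde))

    def test_degenerate_and_insufficient_inputs(self):
        with pytest.raises(DegenerateDataError):
            moderate_variances(np.zeros(100), 4)
        with pytest.raises(InsufficientDataError):
            moderate_variances(np.array([0.1, 0.2]), 4)

    def test_matches_limma_squeezevar(self, tmp_path):
        """Cross-check against the Bioconductor reference implementation."""
        import subprocess

        rng = np.random.default_rng(9)
        sigma2 = 0.05 * 4 / rng.chisquare(4, size=200)
        s2 = sigma2 * rng.chisquare(10, size=200) / 10
        np.savetxt(tmp_path / "s2.txt", s2)
        script = tmp_path / "squeeze.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f's2 <- scan("{tmp_path / "s2.txt"}")\n'
            'fit <- squeezeVar(s2, df=10)\n'
            'cat(fit$df.prior, fit$var.prior, "\\n")\n'
            f'write(fit$var.post, "{tmp_path / "post.txt"}", ncolumns=1)\n'
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        d0_r, s0_r = map(float, out.stdout.split())
        post_r = np.loadtxt(tmp_path / "post.txt")
        d0, s0_sq, s_tilde = moderate_variances(s2, 10)
        assert d0 == pytest.approx(d0_r, rel=1e-4)
        assert s0_sq == pytest.approx(s0_r, rel=1e-4)
        np.testing.assert_allclose(s_tilde, post_r, rtol=1e-4)


class TestModeratedT:
    def test_zero_effect_gives_zero_t_unit_p(self):
        t, p = moderated_t(np.array([0.0]), np.array([0.2]), 0.5, 4.0, 24)
        assert t[0] == 0.0
        assert p[0] == 1.0

    def test_monotone_in_effect_size(self):
        beta = np.linspace(0, 3, 50)
        _, p = moderated_t(beta, np.full(50, 0.1), 0.5, 4.0, 24)
        assert (np.diff(p) <= 0).all()

    def test_invalid_variance_factor(self):
        with pytest.raises(ValueError):
            moderated_t(np.array([1.0]), np.array([0.1]), 0.0, 4.0, 24)

    def test_null_pvalues_uniform(self):
        """On a fully null simulation the moderated p-values are U(0,1)."""
        cfg = SimConfig(n_genes=5000, class_counts={}, seed=8)
        matrix, _ = generate_dataset(cfg)
        res = run_strain_contrasts(matrix)
        p = res.contrasts["LnA"]["p"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestAdjustBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04])

    def test_single_and_tied_inputs(self):
        assert adjust_bh([0.05])[0] == pytest.approx(0.05)
        np.testing.assert_allclose(adjust_bh([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_matches_naive_oracle(self, pvals):
        np.testing.assert_allclose(adjust_bh(pvals), naive_bh(pvals),
                                   rtol=1e-12, atol=1e-12)


class TestStrainContrasts:
    def test_d0_zero_equals_plain_pooled_t(self):
        """With moderation disabled the chain is an ordinary equal-variance
        two-sample t-test, to 10 significant figures."""
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(100, 8))
        m = make_matrix(vals, strains=["A"] * 8,
                        treatments=["control"] * 4 + ["exposed"] * 4)
        res = run_strain_contrasts(m, d0=0.0)
        c = res.contrasts["A"]
        t_ref, p_ref = stats.ttest_ind(vals[:, 4:], vals[:, :4], axis=1,
                                       equal_var=True)
        np.testing.assert_allclose(c["t"].to_numpy(), t_ref, rtol=1e-10)
        np.testing.assert_allclose(c["p"].to_numpy(), p_ref, rtol=1e-10)

    def test_planted_strong_gene_significant_everywhere(self):
        """A 6.4-log2FC gene with typical variance is detected in all four
        strains at adjusted p < 0.01 in (at least) 99% of runs."""
        hits = 0
        n_runs = 30
        for seed in range(n_runs):
            cfg = SimConfig(n_genes=400,
                            class_counts={"TYPE_I_UP": 1},
                            effect_size={"TYPE_I_UP": 6.4},
                            seed=100 + seed)
            matrix, _ = generate_dataset(cfg)
            res = run_strain_contrasts(matrix)
            if all(res.contrasts[s]["p_adj"].iloc[0] < 0.01
                   for s in res.strains):
                hits += 1
        assert hits == n_runs

    def test_null_false_positive_control(self):
        cfg = SimConfig(n_genes=4000, class_counts={}, seed=13)
        matrix, _ = generate_dataset(cfg)
        res = run_strain_contrasts(matrix)
        n = len(res.genes)
        bound = 0.01 + 3 * np.sqrt(0.01 * 0.99 / n)
        for s in res.strains:
            frac = (res.contrasts[s]["p_adj"] < 0.01).mean()
            assert frac <= bound

    def test_per_strain_fit_df(self, small_sim):
        _, matrix, _ = small_sim
        res = run_strain_contrasts(matrix, per_strain_fit=True)
        assert all(m["df"] == 6 for m in res.meta.values())
        pooled = run_strain_contrasts(matrix)
        assert all(m["df"] == 24 for m in pooled.meta.values())

    def test_missing_strain_raises(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(30, 4)),
                        strains=["A"] * 4,
                        treatments=["control", "control", "exposed", "exposed"])
        with pytest.raises(DesignError):
            m.subset_strain("B")

    def test_model_results_roundtrip(self, small_sim, tmp_path):
        _, matrix, _ = small_sim
        res = StrainContrastModel(matrix).fit()
        res.to_tsv(tmp_path)
        assert (tmp_path / "contrast_L-E.tsv").exists()
        text = res.summary()
        assert "L-E" in text and "pooled" in text
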