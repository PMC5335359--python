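"""Moderated-t model: contrasts, variance moderation, BH FDR, DEG calling."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from bicellnet.deg import (ModerationParams, bh_fdr, call_degs, contrast_stats,
                           deg_table, fit_moderation, moderated_t)
from bicellnet.errors import DataError
from bicellnet.simulate import SimulationConfig, simulate_expression

from conftest import make_matrix


def _two_group_matrix(values_a, values_b):
    values = np.hstack([values_a, values_b])
    matrix = make_matrix(values)
    na = values_a.shape[1]
    matrix.sample_meta["group"] = ["a"] * na + ["b"] * values_b.shape[1]
    return matrix


class TestContrastStats:
    def test_constant_identical_groups(self):
        a = np.full((5, 3), 4.0)
        matrix = _two_group_matrix(a, a)
        stats = contrast_stats(matrix, ("SC", "a"), ("SC", "b"))
        assert (stats["log2fc"] == 0).all()
        assert (stats["s2"] == 0).all()

    def test_fourfold_change_arithmetic(self):
        a = np.full((1, 3), 4.0)
        b = np.full((1, 3), 2.0)
        stats = contrast_stats(_two_group_matrix(a, b), ("SC", "a"), ("SC", "b"))
        assert stats["log2fc"].iloc[0] == 2.0
        assert 2.0 ** abs(stats["log2fc"].iloc[0]) == 4.0
        assert stats["s2"].iloc[0] == 0.0

    def test_pooled_variance_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(40, 4)), rng.normal(size=(40, 5))
        stats = contrast_stats(_two_group_matrix(a, b), ("SC", "a"), ("SC", "b"))
        expected = ((a.var(axis=1, ddof=1) * 3 + b.var(axis=1, ddof=1) * 4) / 7)
        assert np.allclose(stats["s2"], expected)
        assert (stats["df"] == 7).all()

    def test_small_group_rejected(self):
        a = np.zeros((3, 1))
        b = np.zeros((3, 3))
        with pytest.raises(DataError):
            contrast_stats(_two_group_matrix(a, b), ("SC", "a"), ("SC", "b"))


class TestFitModeration:
    def test_parameter_recovery_from_scaled_chisquare(self):
        rng = np.random.default_rng(1)
        d0_true, s0_true, df = 4.0, 0.25, 4
        # s2 ~ s0 * F(df, d0) marginally; simulate hierarchically
        gene_var = s0_true * d0_true / rng.chisquare(d0_true, size=10_000)
        s2 = gene_var * rng.chisquare(df, size=10_000) / df
        params = fit_moderation(s2, df)
        assert abs(params.d0 - d0_true) / d0_true < 0.2
        assert abs(params.s0_sq - s0_true) / s0_true < 0.2

    def test_constant_variances_give_infinite_d0(self):
        from scipy import special
        params = fit_moderation(np.full(50, 0.3), df=4)
        assert math.isinf(params.d0)
        # the log-scale moments estimator carries the chi-square bias
        # correction exp(log(df/2) - digamma(df/2)); it tends to s2 as df grows
        expected = 0.3 * math.exp(math.log(2.0) - special.digamma(2.0))
        assert params.s0_sq == pytest.approx(expected, rel=1e-9)
        params_large_df = fit_moderation(np.full(50, 0.3), df=200)
        assert params_large_df.s0_sq == pytest.approx(0.3, rel=0.01)

    def test_too_few_genes_rejected(self):
        with pytest.raises(DataError):
            fit_moderation(np.array([0.1, 0.2]), df=4)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(DataError):
            fit_moderation(np.zeros(100), df=4)


class TestModeratedT:
    def _stats(self, n_genes=20, seed=0):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(n_genes, 3)), rng.normal(size=(n_genes, 3))
        return contrast_stats(_two_group_matrix(a, b), ("SC", "a"), ("SC", "b"))

    def test_infinite_d0_gives_z_statistic(self):
        stats = self._stats()
        params = ModerationParams(d0=math.inf, s0_sq=0.5)
        out = moderated_t(stats, params)
        expected = stats["log2fc"] / np.sqrt(0.5 * (1 / 3 + 1 / 3))
        assert np.allclose(out["t_mod"], expected, atol=1e-10)
        assert np.allclose(out["s2_post"], 0.5)

    def test_vanishing_d0_gives_ordinary_pooled_t(self):
        stats = self._stats()
        params = ModerationParams(d0=1e-12, s0_sq=1.0)
        out = moderated_t(stats, params)
        ordinary = stats["log2fc"] / np.sqrt(stats["s2"] * (1 / 3 + 1 / 3))
        assert np.allclose(out["t_mod"], ordinary, atol=1e-6)

    def test_posterior_variance_hand_formula(self):
        stats = self._stats(n_genes=1, seed=3)
        d0, s0 = 3.0, 0.4
        out = moderated_t(stats, ModerationParams(d0=d0, s0_sq=s0))
        s2, df = stats["s2"].iloc[0], stats["df"].iloc[0]
        post = (d0 * s0 + df * s2) / (d0 + df)
        assert out["s2_post"].iloc[0] == pytest.approx(post, abs=1e-12)
        t_hand = stats["log2fc"].iloc[0] / math.sqrt(post * (2 / 3))
        assert out["t_mod"].iloc[0] == pytest.approx(t_hand, abs=1e-12)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(30, 3)), rng.normal(size=(30, 4))
        m = _two_group_matrix(a, b)
        s_ab = contrast_stats(m, ("SC", "a"), ("SC", "b"))
        s_ba = contrast_stats(m, ("SC", "b"), ("SC", "a"))
        params = fit_moderation(s_ab["s2"], s_ab["df"].iloc[0])
        t_ab = moderated_t(s_ab, params)
        t_ba = moderated_t(s_ba, params)
        assert np.allclose(t_ab["t_mod"], -t_ba["t_mod"])
        assert np.allclose(t_ab["p"], t_ba["p"])


class TestBHFdr:
    def test_stepup_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_vectors(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([0.2]).tolist() == [0.2]

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 200))
    def test_matches_statsmodels_and_exhaustive_definition(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.random(n)
        q = bh_fdr(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)
        # exhaustive step-up definition
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        for i, gi in enumerate(order):
            candidates = [m * p[order[j]] / (j + 1) for j in range(i, m)]
            assert q[gi] == pytest.approx(min(1.0, min(candidates)), abs=1e-12)
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in p


class TestCallDegs:
    def _row(self, log2fc, q):
        return pd.DataFrame({"log2fc": [log2fc], "q": [q]}, index=["G"])

    def test_threshold_logic(self):
        assert call_degs(self._row(1.1, 0.01))["called"].iloc[0]
        assert not call_degs(self._row(2.0, 0.2))["called"].iloc[0]
        assert not call_degs(self._row(1.0, 0.01))["called"].iloc[0]  # fold == cut, strict
        down = call_degs(self._row(-1.5, 0.01))
        assert down["called"].iloc[0] and down["direction"].iloc[0] == -1

    def test_planted_simulation_recovery(self):
        recovered, false_calls, planted_n = 0, 0, 0
        for seed in range(20):
            config = SimulationConfig(n_genes=2000, de_fraction=0.05,
                                      de_log2fc_magnitude=2.0, noise_sd=0.5,
                                      n_lr_pairs_planted=0, seed=seed)
            matrix, truth = simulate_expression(config)
            for cell in ("SC", "MAC"):
                table = call_degs(deg_table(matrix, (cell, "mut-7mo"), (cell, "mut-1mo")))
                called = set(table.index[table["called"]])
                planted = truth.de_genes_for(cell)
                recovered += len(called & planted)
                false_calls += len(called - planted)
                planted_n += len(planted)
        assert recovered / planted_n >= 0.8
        assert false_calls / max(1, recovered + false_calls) <= 0.1

    def test_null_simulations_control_fdr(self):
        props = []
        for seed in range(25):
            config = SimulationConfig(n_genes=1000, de_fraction=0.0,
                                      n_lr_pairs_planted=0, seed=seed)
            matrix, _ = simulate_expression(config)
            table = deg_table(matrix, ("SC", "mut-7mo"), ("SC", "mut-1mo"))
            props.append((table["q"] < 0.05).mean())
        assert np.mean(props) <= 0.05


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_moderated_t_matches_limma_reference(tmp_path):
    """Independent cross-check of the full empirical-Bayes chain against the
    Bioconductor reference on one simulated two-group comparison."""
    rng = np.random.default_rng(12)
    n_genes, n = 400, 4
    gene_var = 0.2 * 4 / rng.chisquare(4, size=n_genes)
    a = 6 + rng.normal(size=(n_genes, n)) * np.sqrt(gene_var)[:, None]
    b = 6 + rng.normal(size=(n_genes, n)) * np.sqrt(gene_var)[:, None]
    b[:40] += 1.5
    matrix = _two_group_matrix(a, b)
    table = deg_table(matrix, ("SC", "a"), ("SC", "b"))

    frame = pd.DataFrame(np.hstack([a, b]),
                         index=[f"G{i}" for i in range(n_genes)])
    frame.to_csv(tmp_path / "y.tsv", sep="\t")
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        y <- as.matrix(read.delim("y.tsv", row.names=1, check.names=FALSE))
        group <- factor(c(rep("a", {n}), rep("b", {n})), levels=c("b", "a"))
        design <- model.matrix(~group)
        fit <- eBayes(lmFit(y, design))
        out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                          d0=fit$df.prior, s0=fit$s2.prior)
        write.table(out, "limma_out.tsv", sep="\t", quote=FALSE)
    """)
    (tmp_path / "run.R").write_text(script)
    subprocess.run(["Rscript", "run.R"], cwd=tmp_path, check=True, capture_output=True)
    r_out = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t")

    params = table.attrs["moderation"]
    assert params.d0 == pytest.approx(r_out["d0"].iloc[0], rel=1e-4)
    assert params.s0_sq == pytest.approx(r_out["s0"].iloc[0], rel=1e-4)
    assert np.allclose(table["t_mod"].to_numpy(), r_out["t"].to_numpy(), atol=1e-6)
    assert np.allclose(table["p"].to_numpy(), r_out["p"].to_numpy(), atol=1e-8)
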