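import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ctprofiler import (
    EBayesPrior,
    GroupDesign,
    ModeratedTTest,
    anova_dunnett,
    bh_adjust,
    estimate_prior,
    fit_moderated_t,
)

from conftest import make_matrix


def two_group_matrix(rng, n=60, shift_first=0):
    arr = rng.normal(22, 2, size=(n, 6))
    arr += np.sqrt(0.5 * 4 / rng.chisquare(4, size=n))[:, None] * 0
    if shift_first:
        arr[:shift_first, :3] -= 2.0  # lower Ct = higher expression
    groups = ["A"] * 3 + ["B"] * 3
    return make_matrix(arr, groups=groups), GroupDesign(
        {"A": ["s1", "s2", "s3"], "B": ["s4", "s5", "s6"]}
    )


def brute_force_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0], [1.0]),
            ([0.05, 0.01], [0.05, 0.02]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_and_dominates_input(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, brute_force_bh(p), atol=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestModeratedT:
    def test_equal_means_give_zero_t_unit_p(self):
        arr = np.tile([[20.0, 21.0, 22.0, 20.0, 21.0, 22.0]], (5, 1))
        arr += np.arange(5)[:, None]  # distinct rows, equal group means
        mat = make_matrix(arr, groups=["A"] * 3 + ["B"] * 3)
        design = GroupDesign({"A": ["s1", "s2", "s3"], "B": ["s4", "s5", "s6"]})
        res = fit_moderated_t(mat, design, ("A", "B"))
        np.testing.assert_allclose(res.t_mod, 0.0)
        np.testing.assert_allclose(res.p_value, 1.0)

    def test_d0_zero_reduces_to_ordinary_t(self, rng):
        mat, design = two_group_matrix(rng)
        res = fit_moderated_t(
            mat, design, ("A", "B"), prior=EBayesPrior(d0=0.0, s0_sq=1.0)
        )
        expr = 35.0 - mat.values.to_numpy()
        t_ref, p_ref = stats.ttest_ind(expr[:, :3], expr[:, 3:], axis=1)
        np.testing.assert_allclose(res.t_mod, t_ref, atol=1e-10)
        np.testing.assert_allclose(res.p_value, p_ref, atol=1e-10)

    def test_d0_infinite_orders_by_effect_size(self, rng):
        mat, design = two_group_matrix(rng)
        res = fit_moderated_t(
            mat, design, ("A", "B"), prior=EBayesPrior(d0=np.inf, s0_sq=0.8)
        )
        np.testing.assert_allclose(
            res.t_mod, res.log_fc / np.sqrt(0.8 * (2 / 3)), atol=1e-12
        )

    def test_p_monotone_in_abs_t(self, rng):
        mat, design = two_group_matrix(rng, shift_first=10)
        res = fit_moderated_t(mat, design, ("A", "B"))
        order = np.argsort(np.abs(res.t_mod))
        assert np.all(np.diff(res.p_value[order]) <= 1e-12)

    def test_sign_convention_positive_means_higher_in_group_a(self):
        # group A sits 2 cycles lower (more abundant)
        arr = np.array([[20.0, 20.1, 19.9, 22.0, 22.1, 21.9]])
        mat = make_matrix(arr, groups=["A"] * 3 + ["B"] * 3)
        design = GroupDesign({"A": ["s1", "s2", "s3"], "B": ["s4", "s5", "s6"]})
        res = fit_moderated_t(mat, design, ("A", "B"))
        assert res.log_fc[0] == pytest.approx(2.0, abs=0.2)
        assert res.t_mod[0] > 0

    def test_requires_two_replicates_per_group(self):
        mat = make_matrix([[20.0, 21.0]], samples=["a1", "b1"],
                          groups=["A", "B"])
        design = GroupDesign({"A": ["a1"], "B": ["b1"]})
        with pytest.raises(ValueError, match="2 replicates"):
            ModeratedTTest(mat, design, ("A", "B"))

    def test_zero_variance_everywhere_is_error(self):
        arr = np.tile([[20.0] * 6], (4, 1))
        with pytest.raises(ValueError, match="zero"):
            estimate_prior(np.zeros(4), 4)
        mat = make_matrix(arr, groups=["A"] * 3 + ["B"] * 3)
        design = GroupDesign({"A": ["s1", "s2", "s3"], "B": ["s4", "s5", "s6"]})
        with pytest.raises(ValueError):
            fit_moderated_t(mat, design, ("A", "B"))

    def test_summary_mentions_contrast_and_counts(self, rng):
        mat, design = two_group_matrix(rng)
        res = fit_moderated_t(mat, design, ("A", "B"))
        text = res.summary()
        assert "A vs B" in text and "60" in text

    def test_similarity_fraction_threshold_degeneracy(self, rng):
        mat, design = two_group_matrix(rng)
        res = fit_moderated_t(mat, design, ("A", "B"))
        assert res.similarity_fraction(alpha=0.0) == 1.0


class TestAgainstLimma:
    """Independent oracle: Bioconductor limma's lmFit + eBayes."""

    def test_t_and_prior_match_limma(self, tmp_path, rng):
        n, na, nb = 150, 3, 3
        sig = np.sqrt(0.3 * 4 / rng.chisquare(4, size=n))
        X = rng.normal(20, 1, size=(n, 1)) + sig[:, None] * rng.standard_normal(
            (n, na + nb)
        )
        X[:10, :na] += 2.0
        cols = [f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)]
        df = pd.DataFrame(X, index=[f"m{i}" for i in range(n)], columns=cols)
        infile = tmp_path / "expr.csv"
        outfile = tmp_path / "limma.csv"
        df.to_csv(infile)
        rscript = f"""
        suppressMessages(library(limma))
        x <- read.csv("{infile}", row.names=1)
        design <- cbind(Intercept=1, AvsB=c(rep(1,{na}), rep(0,{nb})))
        fit <- eBayes(lmFit(as.matrix(x), design))
        out <- data.frame(t=fit$t[,"AvsB"], p=fit$p.value[,"AvsB"])
        out$d0 <- fit$df.prior; out$s0sq <- fit$s2.prior
        write.csv(out, "{outfile}")
        """
        subprocess.run(["Rscript", "-e", rscript], check=True,
                       capture_output=True, timeout=120)
        ref = pd.read_csv(outfile, index_col=0)
        groups = pd.Series(
            {**{f"A{i}": "A" for i in range(na)},
             **{f"B{i}": "B" for i in range(nb)}}
        )
        # feed expression directly: with ct_max=0, E = -Ct = X
        res = ModeratedTTest.from_dataframe(-df, groups, ("A", "B"),
                                            ct_max=0.0).fit()
        assert res.prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert res.prior.s0_sq == pytest.approx(ref["s0sq"].iloc[0], rel=1e-6)
        mine_t = pd.Series(res.t_mod, index=res.mirna_ids)
        np.testing.assert_allclose(mine_t, ref["t"], atol=1e-8)


class TestAnovaDunnett:
    def test_identical_groups_give_unit_p(self):
        arr = np.tile([[20.0] * 9], (3, 1))
        mat = make_matrix(arr, groups=["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        design = GroupDesign(
            {"A": ["s1", "s2", "s3"], "B": ["s4", "s5", "s6"],
             "C": ["s7", "s8", "s9"]}
        )
        res = anova_dunnett(mat, design, "A", seed=0)
        np.testing.assert_allclose(res.f_p_value, 1.0)
        np.testing.assert_allclose(res.dunnett_p.to_numpy(), 1.0)

    def test_two_groups_reduce_to_t_test(self, rng):
        arr = rng.normal(22, 1, size=(8, 6))
        mat = make_matrix(arr, groups=["A"] * 3 + ["B"] * 3)
        design = GroupDesign({"A": ["s1", "s2", "s3"], "B": ["s4", "s5", "s6"]})
        res = anova_dunnett(mat, design, "A", seed=0)
        expr = 35.0 - arr
        _, p_ref = stats.ttest_ind(expr[:, 3:], expr[:, :3], axis=1)
        np.testing.assert_allclose(
            res.dunnett_p["B"].to_numpy(), p_ref, atol=5e-4
        )

    def test_large_shift_is_significant(self, rng):
        sigma = 0.5
        arr = rng.normal(25, sigma, size=(5, 9))
        arr[:, 3:6] -= 10 * sigma  # one group shifted by 10 sigma
        mat = make_matrix(arr, groups=["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        design = GroupDesign(
            {"A": ["s1", "s2", "s3"], "B": ["s4", "s5", "s6"],
             "C": ["s7", "s8", "s9"]}
        )
        res = anova_dunnett(mat, design, "A", seed=0)
        assert (res.dunnett_p["B"] < 0.001).all()

    def test_missing_control_is_error(self, rng):
        mat = make_matrix(rng.normal(22, 1, size=(3, 6)),
                          groups=["A"] * 3 + ["B"] * 3)
        design = GroupDesign({"A": ["s1", "s2", "s3"], "B": ["s4", "s5", "s6"]})
        with pytest.raises(ValueError, match="control"):
            anova_dunnett(mat, design, "Z", seed=0)
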