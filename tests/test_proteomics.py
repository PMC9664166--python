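"""Imputation, filtering, effect statistics, moderated t and BH q-values."""

import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

from rvomics import IntensityMatrix, SimConfig
from rvomics.proteomics import (
    add_zscores,
    bh_adjust,
    classify_significant,
    effect_stats,
    impute_zeros,
    moderated_test,
    presence_filter,
    run_differential,
    squeeze_variances,
)
from rvomics.simulate import gen_proteome


def _matrix(values, n_ctrl, n_case):
    values = np.asarray(values, dtype=float)
    cols = [f"c{i}" for i in range(n_ctrl)] + [f"m{i}" for i in range(n_case)]
    design = pd.Series(["control"] * n_ctrl + ["MCT"] * n_case, index=cols)
    idx = pd.Index([f"P{i}" for i in range(values.shape[0])], name="accession")
    return IntensityMatrix(pd.DataFrame(values, index=idx, columns=cols), design)


# ---------------------------------------------------------------- imputation

class TestImputeZeros:
    def test_no_zeros_is_identity(self, tiny_matrix):
        out = impute_zeros(tiny_matrix)
        pd.testing.assert_frame_equal(out.intensities, tiny_matrix.intensities)

    def test_zeros_become_per_column_low_quantile(self):
        # column of 100 nonzero values 10..1000 plus zeros; the oracle is
        # the sorted-and-linearly-interpolated quantile of the nonzero set
        nonzero = np.arange(10.0, 1001.0, 10.0)
        col = np.concatenate([nonzero, [0.0, 0.0]])
        other = np.full_like(col, 500.0)
        m = _matrix(np.column_stack([col, other, other, other]), 2, 2)
        out = impute_zeros(m, quantile=0.01)
        s = np.sort(nonzero)
        pos = 0.01 * (len(s) - 1)
        lo = int(np.floor(pos))
        oracle = s[lo] + (pos - lo) * (s[lo + 1] - s[lo])
        imputed = out.intensities.iloc[100:, 0]
        assert np.allclose(imputed, oracle)
        # nonzero cells untouched, everything strictly positive
        assert np.array_equal(out.intensities.iloc[:100, 0], nonzero)
        assert (out.intensities.to_numpy() > 0).all()

    def test_all_zero_column_raises_naming_sample(self):
        vals = np.array([[1.0, 0.0, 2.0, 3.0], [4.0, 0.0, 5.0, 6.0]])
        m = _matrix(vals, 2, 2)
        with pytest.raises(ValueError, match="c1"):
            impute_zeros(m)


# ------------------------------------------------------------ presence filter

class TestPresenceFilter:
    def test_each_group_rule(self):
        # P0: 3+3 positives -> kept; P1: 3 in control but 2 in MCT -> dropped
        vals = np.array(
            [[1, 1, 1, 0, 0, 1, 1, 1, 0, 0],
             [1, 1, 1, 0, 0, 1, 1, 0, 0, 0]], dtype=float)
        m = _matrix(vals, 5, 5)
        kept, dropped = presence_filter(m, min_pos=3)
        assert list(kept.accessions) == ["P0"]
        assert dropped == ["P1"]

    def test_min_pos_zero_drops_nothing(self, tiny_matrix):
        kept, dropped = presence_filter(tiny_matrix, min_pos=0)
        assert dropped == []
        assert len(kept.accessions) == 2

    def test_min_pos_beyond_group_size_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            presence_filter(tiny_matrix, min_pos=4)

    def test_filter_decision_independent_of_imputation(self):
        """The retained-row set is fixed by the raw zero pattern, so
        applying the filter before or after imputation keeps the same
        proteins, and imputation never changes an observed value of a
        retained protein."""
        rng = np.random.default_rng(0)
        vals = rng.lognormal(10, 1, size=(50, 10))
        vals[rng.random(vals.shape) < 0.2] = 0.0
        m = _matrix(vals, 5, 5)
        keep_before = presence_filter(m, 3)[0].accessions
        imputed = impute_zeros(m)
        # post-imputation the matrix has no zeros: the filter must be fed
        # the original flags, under which the decision is unchanged
        keep_after = presence_filter(m, 3)[0].accessions
        assert list(keep_before) == list(keep_after)
        retained = imputed.subset(keep_before).intensities.to_numpy()
        original = m.subset(keep_before).intensities.to_numpy()
        mask = original > 0
        assert np.array_equal(retained[mask], original[mask])
        assert (retained > 0).all()


# ------------------------------------------------------------- effect stats

class TestEffectStats:
    def test_hand_arithmetic(self, tiny_matrix):
        stats_df = effect_stats(tiny_matrix)
        a = stats_df.set_index("accession")
        assert a.loc["A", "mean_control"] == pytest.approx(100.0)
        assert a.loc["A", "mean_mct"] == pytest.approx(400.0)
        assert a.loc["A", "ratio"] == pytest.approx(4.0)
        assert a.loc["A", "log2_ratio"] == pytest.approx(2.0)
        assert a.loc["B", "mean_mct"] == pytest.approx(50.0)
        assert a.loc["B", "log2_ratio"] == pytest.approx(-1.0)

    def test_equal_means_give_zero_log_ratio(self):
        m = _matrix(np.full((3, 6), 7.0), 3, 3)
        assert (effect_stats(m)["log2_ratio"] == 0).all()


# ----------------------------------------------------------------- z-scores

class TestZScores:
    def test_symmetric_triple(self):
        df = pd.DataFrame({"accession": list("abc"), "log2_ratio": [-1.0, 0.0, 1.0]})
        z = add_zscores(df)["z"]
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])

    def test_location_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        a = add_zscores(pd.DataFrame({"accession": range(30), "log2_ratio": x}))
        b = add_zscores(pd.DataFrame({"accession": range(30), "log2_ratio": x + 5}))
        np.testing.assert_allclose(a["z"], b["z"])

    def test_standardization_tight(self):
        rng = np.random.default_rng(2)
        z = add_zscores(
            pd.DataFrame({"accession": range(500), "log2_ratio": rng.normal(size=500)})
        )["z"]
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1.0) < 1e-10

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            add_zscores(pd.DataFrame({"accession": ["a"], "log2_ratio": [1.0]}))
        with pytest.raises(ValueError):
            add_zscores(pd.DataFrame({"accession": list("ab"), "log2_ratio": [1.0, 1.0]}))


# -------------------------------------------------------------- moderated t

class TestModeratedT:
    def test_posterior_variance_formula(self):
        # d0=4, s0^2=1, s_g^2=2, d_g=8 -> posterior (4*1+8*2)/12 = 5/3
        d0, s02, s2, dg = 4.0, 1.0, 2.0, 8.0
        post = (d0 * s02 + dg * s2) / (d0 + dg)
        assert post == pytest.approx(5.0 / 3.0)
        # and the estimator's posterior obeys the same blend with its own
        # hyperparameters, staying between s2 and s2_prior
        rng = np.random.default_rng(0)
        s2_vec = rng.chisquare(8, size=300) / 8
        df_prior, s2_prior, s2_post = squeeze_variances(s2_vec, 8)
        if np.isfinite(df_prior):
            expected = (df_prior * s2_prior + 8 * s2_vec) / (df_prior + 8)
            np.testing.assert_allclose(s2_post, expected)
        lo = np.minimum(s2_vec, s2_prior)
        hi = np.maximum(s2_vec, s2_prior)
        assert ((s2_post >= lo - 1e-12) & (s2_post <= hi + 1e-12)).all()

    def test_ordinary_mode_is_pooled_t(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(8, 1, size=(40, 10))
        m = _matrix(vals, 5, 5)
        res = moderated_test(m, ordinary=True)
        logs = np.log2(vals)
        t_ref, p_ref = ss.ttest_ind(logs[:, 5:], logs[:, :5], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, rtol=1e-10)

    def test_null_pvalues_uniform(self):
        # two groups from one distribution: the p histogram must be flat
        rng = np.random.default_rng(4)
        vals = np.power(2.0, rng.normal(20, 1, size=(1000, 10)))
        m = _matrix(vals, 5, 5)
        res = moderated_test(m)
        assert ss.kstest(res["p"], "uniform").pvalue > 0.01

    def test_matches_limma_reference(self, tmp_path):
        """Independent oracle: the same matrix through R limma's eBayes."""
        cfg = SimConfig(n_proteins=300, seed=0)
        matrix, _ = gen_proteome(cfg)
        filtered, _ = presence_filter(matrix)
        imputed = impute_zeros(filtered)
        res = moderated_test(imputed)
        log_path = tmp_path / "log2.tsv"
        out_path = tmp_path / "limma.tsv"
        np.log2(imputed.intensities).to_csv(log_path, sep="\t")
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{log_path}", row.names=1, check.names=FALSE))\n'
            'design <- cbind(Intercept=1, MCT=grepl("^MCT", colnames(x)))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'out <- data.frame(accession=rownames(x), t=fit$t[,"MCT"], p=fit$p.value[,"MCT"])\n'
            f'write.table(out, "{out_path}", sep="\\t", row.names=FALSE, quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t")
        merged = res.merge(ref, on="accession", suffixes=("", "_r"))
        np.testing.assert_allclose(merged["t"], merged["t_r"], atol=1e-8)
        np.testing.assert_allclose(merged["p"], merged["p_r"], atol=1e-8)

    def test_too_few_samples_rejected(self):
        m = _matrix(np.ones((3, 3)), 1, 2)
        with pytest.raises(ValueError):
            moderated_test(m)


# ---------------------------------------------------------------------- BH

class TestBHAdjust:
    def test_hand_stepup_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(bh_adjust(p), [0.05, 0.05, 0.05, 0.05, 0.05])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        p = rng.random(200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_monotone_and_dominates_p(self, p):
        q = bh_adjust(p)
        assert ((q >= np.asarray(p) - 1e-15) & (q <= 1.0)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


# ------------------------------------------------------------ classification

class TestClassify:
    @pytest.mark.parametrize(
        "q,z,in_sig,in_strict",
        [
            (0.049, 0.5, True, False),
            (0.001, -1.97, True, True),   # retained at just past the cut
            (0.001, 1.96, True, True),    # the cut itself is inclusive
            (0.05, 3.0, False, False),    # q threshold is strict
        ],
    )
    def test_rule_application(self, q, z, in_sig, in_strict):
        df = pd.DataFrame({"accession": ["x", "pad"], "q": [q, 0.9], "z": [z, 0.0]})
        sig, strict = classify_significant(df)
        assert ("x" in sig) is in_sig
        assert ("x" in strict) is in_strict
        assert strict <= sig


# --------------------------------------------------------------- full chain

def test_run_differential_contract():
    cfg = SimConfig(n_proteins=300, seed=8)
    matrix, _ = gen_proteome(cfg)
    stats_df, dropped = run_differential(matrix)
    assert len(stats_df) + len(dropped) == 300
    assert (stats_df["q"] >= stats_df["p"] - 1e-15).all()
    assert np.isfinite(stats_df["z"]).all()
    np.testing.assert_allclose(
        stats_df["ratio"], stats_df["mean_mct"] / stats_df["mean_control"]
    )
    assert abs(stats_df["z"].mean()) < 1e-10
    assert abs(stats_df["z"].std(ddof=1) - 1.0) < 1e-10
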