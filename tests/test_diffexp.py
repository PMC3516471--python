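"""Linear fit, empirical-Bayes moderation, BH FDR and DE calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ferrotime import diffexp, preprocess
from ferrotime.diffexp import (
    DEThresholds,
    bh_fdr,
    call_de,
    differential_expression,
    fit_linear_model,
    moderate_variances,
    moderated_test,
)


def _eset(rows: dict, timepoints=(0.0, 3.0), reps=2) -> preprocess.ExpressionSet:
    """rows: transcript -> flat list of log2 values, grouped by time point."""
    cols, design_rows = [], []
    for t_i, t in enumerate(timepoints):
        for r in range(1, reps + 1):
            cols.append(f"T{t_i}R{r}")
            design_rows.append((f"T{t_i}R{r}", t, r))
    values = pd.DataFrame.from_dict(rows, orient="index", columns=cols).astype(float)
    design = pd.DataFrame(design_rows, columns=["array_id", "timepoint", "replicate"])
    return preprocess.ExpressionSet(
        values=values, design=design, expressed=pd.Series(True, index=values.index)
    )


class TestFitLinearModel:
    def test_noiseless_groups(self):
        fit = fit_linear_model(_eset({"g": [5, 5, 7, 7]}))
        assert fit.coefficients.loc["g", 3.0] == pytest.approx(2.0)
        assert fit.s2["g"] == pytest.approx(0.0)

    def test_no_change_gives_zero_beta(self):
        fit = fit_linear_model(_eset({"g": [5, 6, 5, 6]}))
        assert fit.coefficients.loc["g", 3.0] == pytest.approx(0.0)

    def test_hand_ols(self):
        # each group contributes variance 2 with 1 df -> pooled s2 = 2, d = 2
        fit = fit_linear_model(_eset({"g": [4, 6, 7, 9]}))
        assert fit.coefficients.loc["g", 3.0] == pytest.approx(3.0)
        assert fit.s2["g"] == pytest.approx(2.0)
        assert fit.df_residual == 2

    def test_requires_reference_timepoint(self):
        eset = _eset({"g": [4, 6, 7, 9]}, timepoints=(3.0, 12.0))
        with pytest.raises(ValueError, match="reference"):
            fit_linear_model(eset)


class TestModerateVariances:
    def _fit_with_s2(self, s2_values, d=6):
        n = len(s2_values)
        fit = diffexp.LinearFitResult(
            coefficients=pd.DataFrame({3.0: np.zeros(n)}),
            s2=pd.Series(s2_values, dtype=float),
            df_residual=d,
            group_sizes={0.0: 2, 3.0: 2},
        )
        return fit

    def test_identical_variances_give_degenerate_prior(self):
        fit = moderate_variances(self._fit_with_s2([2.0] * 50))
        assert np.isinf(fit.d0)
        assert fit.s0_2 == pytest.approx(2.0)
        np.testing.assert_allclose(fit.s2_moderated, 2.0)

    def test_moderated_between_raw_and_prior(self):
        rng = np.random.default_rng(4)
        s2 = rng.chisquare(6, size=300) / 6
        fit = moderate_variances(self._fit_with_s2(s2))
        lo = np.minimum(fit.s2, fit.s0_2)
        hi = np.maximum(fit.s2, fit.s0_2)
        assert ((fit.s2_moderated >= lo - 1e-12) & (fit.s2_moderated <= hi + 1e-12)).all()

    def test_parametric_recovery_of_prior_scale(self):
        # s2 ~ s0^2 * chi2_d / d with s0^2 = 1, d = 6: no extra dispersion,
        # so the prior scale must come back near 1 and d0 must be large
        rng = np.random.default_rng(123)
        d = 6
        s2 = rng.chisquare(d, size=5000) / d
        fit = moderate_variances(self._fit_with_s2(s2, d=d))
        assert fit.s0_2 == pytest.approx(1.0, rel=0.05)
        assert fit.d0 > 20


class TestModeratedTest:
    def _fit(self, beta, s2_mod, d_total=8):
        fit = diffexp.LinearFitResult(
            coefficients=pd.DataFrame({3.0: [beta]}),
            s2=pd.Series([s2_mod]),
            df_residual=int(d_total),
            group_sizes={0.0: 2, 3.0: 2},
        )
        fit.d0, fit.s0_2 = 0.0, s2_mod
        fit.s2_moderated = pd.Series([s2_mod])
        return fit

    def test_zero_beta_gives_p_one(self):
        p = moderated_test(self._fit(0.0, 1.0))
        assert p.iloc[0, 0] == pytest.approx(1.0)

    def test_sign_symmetry(self):
        p_pos = moderated_test(self._fit(1.7, 1.0)).iloc[0, 0]
        p_neg = moderated_test(self._fit(-1.7, 1.0)).iloc[0, 0]
        assert p_pos == pytest.approx(p_neg)

    def test_closed_form_t8(self):
        # s2=1, n_t=n_0=2 -> se = sqrt(1*(1/2+1/2)) = 1, t = 3, df = 8
        p = moderated_test(self._fit(3.0, 1.0, d_total=8)).iloc[0, 0]
        assert p == pytest.approx(2 * stats.t.sf(3.0, df=8))


def _bh_bruteforce(p):
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for rank_pos, idx in enumerate(order):
        candidates = [
            n * p[order[j]] / (j + 1) for j in range(rank_pos, n)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_bruteforce_and_dominates_p(self, p):
        q = bh_fdr(p)
        np.testing.assert_allclose(q, _bh_bruteforce(p), atol=1e-12)
        assert (q >= np.asarray(p) - 1e-12).all()


class TestCallDE:
    def _table(self, q, fc):
        return pd.DataFrame({"log2fc_3h": [fc], "p_3h": [q], "q_3h": [q]})

    def test_passes_both_gates(self):
        assert bool(call_de(self._table(0.04, 1.2))["de_3h"].iloc[0])

    def test_fold_change_gate(self):
        assert not bool(call_de(self._table(0.04, 0.9))["de_3h"].iloc[0])

    def test_q_gate(self):
        assert not bool(call_de(self._table(0.06, 1.2))["de_3h"].iloc[0])


class TestEndToEnd:
    def _simulate_expr(self, seed, n=2000, effect=0.0, noise=0.25):
        rng = np.random.default_rng(seed)
        tps = (0.0, 3.0, 12.0)
        cols, design_rows = [], []
        for t_i, t in enumerate(tps):
            for r in (1, 2):
                cols.append(f"T{t_i}R{r}")
                design_rows.append((f"T{t_i}R{r}", t, r))
        base = rng.uniform(8, 12, size=n)[:, None]
        shift = np.zeros((n, len(cols)))
        n_true = 0
        if effect:
            n_true = n // 10
            for j, (_, t, _) in enumerate(design_rows):
                if t > 0:
                    shift[:n_true, j] = effect
        values = base + shift + rng.normal(0, noise, size=(n, len(cols)))
        eset = preprocess.ExpressionSet(
            values=pd.DataFrame(values, columns=cols,
                                index=[f"g{i}" for i in range(n)]),
            design=pd.DataFrame(design_rows, columns=["array_id", "timepoint", "replicate"]),
            expressed=pd.Series(True, index=[f"g{i}" for i in range(n)]),
        )
        return eset, n_true

    def test_null_simulations_control_fdr(self):
        # no planted responders: DE calls are all false positives; across
        # seeds their fraction stays below q_max + 3 * MC sd
        rates = []
        for seed in range(20):
            eset, _ = self._simulate_expr(seed, n=2000)
            fc = differential_expression(eset)
            rates.append(fc["de_any"].mean())
        rates = np.asarray(rates)
        mc_sd = rates.std(ddof=1) / np.sqrt(len(rates))
        assert rates.mean() <= 0.05 + 3 * mc_sd

    def test_planted_responders_detected(self):
        eset, n_true = self._simulate_expr(99, n=1000, effect=2.0, noise=0.25)
        fc = differential_expression(eset)
        sens = fc["de_any"].iloc[:n_true].mean()
        assert sens >= 0.9

    def test_no_moderation_variant_runs(self):
        eset, _ = self._simulate_expr(5, n=50)
        fc = differential_expression(eset, moderation=False)
        assert {"log2fc_3h", "q_12h", "de_any"} <= set(fc.columns)

    def test_global_fdr_scope(self):
        eset, _ = self._simulate_expr(6, n=50)
        fc = differential_expression(eset, fdr_scope="global")
        assert ((fc.filter(like="q_") >= fc.filter(like="p_").to_numpy() - 1e-12)).all().all()
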