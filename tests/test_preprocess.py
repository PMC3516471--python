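"""Preprocessing: background clip, detection filter, quantile normalization,
transcript summarization and relative abundance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ferrotime import preprocess
from ferrotime.preprocess import (
    background_correct,
    expression_filter,
    quantile_normalize,
    relative_abundance,
    summarize_transcripts,
)


def _design(n_tp=2):
    rows = []
    for t_i, t in enumerate([0.0, 3.0, 12.0][:n_tp + 1]):
        for r in (1, 2):
            rows.append((f"T{t_i}R{r}", t, r))
    return pd.DataFrame(rows, columns=["array_id", "timepoint", "replicate"])


class TestBackgroundCorrect:
    def test_clips_below_floor_only(self):
        m = pd.DataFrame({"a": [0.0, 500.0], "b": [0.5, 2.0]})
        out = background_correct(m, floor=1.0)
        assert out["a"].tolist() == [1.0, 500.0]
        assert out["b"].tolist() == [1.0, 2.0]

    def test_all_zero_matrix_becomes_floors(self):
        m = pd.DataFrame(np.zeros((3, 2)))
        assert (background_correct(m, 1.0) == 1.0).all().all()

    def test_negative_floor_rejected(self):
        with pytest.raises(ValueError):
            background_correct(pd.DataFrame([[1.0]]), floor=-1.0)


class TestExpressionFilter:
    def _fixture(self, probe_rows):
        """probe_rows: {probe: [signals per array]} plus controls defining maxima."""
        design = _design(2)  # 0, 3, 12 h with 2 replicates each
        data = dict(probe_rows)
        # control maxima per array: t0: 9,9  t3: 11,11  t12: 15,15
        data["CTRL|1"] = [9, 9, 11, 11, 15, 15]
        matrix = pd.DataFrame.from_dict(data, orient="index", columns=design["array_id"])
        pm = pd.DataFrame(
            {
                "probe_id": list(data),
                "transcript_id": [p.split("|")[0] if not p.startswith("CTRL") else "" for p in data],
                "is_control": [p.startswith("CTRL") for p in data],
            }
        )
        return matrix.astype(float), pm, design

    def test_passes_when_above_controls_on_both_replicates_of_one_timepoint(self):
        # below at 3 h (10,12 vs 11,11) but above at 12 h (20,22 vs 15,15)
        m, pm, d = self._fixture({"g1|p1": [1, 1, 10, 12, 20, 22]})
        probe_expr, tx_expr = expression_filter(m, pm, d)
        assert bool(tx_expr["g1"])

    def test_fails_when_below_on_one_replicate_everywhere(self):
        m, pm, d = self._fixture({"g1|p1": [1, 1, 12, 10, 22, 14]})
        _, tx_expr = expression_filter(m, pm, d)
        assert not bool(tx_expr["g1"])

    def test_invariant_to_global_rescale_of_one_array(self):
        m, pm, d = self._fixture({"g1|p1": [1, 1, 10, 12, 20, 22]})
        scaled = m.copy()
        scaled.iloc[:, 4] *= 7.3  # probe and control signals scale together
        _, a = expression_filter(m, pm, d)
        _, b = expression_filter(scaled, pm, d)
        pd.testing.assert_series_equal(a, b)

    def test_no_controls_is_an_error(self):
        m, pm, d = self._fixture({"g1|p1": [1, 1, 10, 12, 20, 22]})
        pm_nc = pm[~pm["is_control"]]
        with pytest.raises(ValueError, match="control"):
            expression_filter(m.loc[pm_nc["probe_id"]], pm_nc, d)

    def test_planted_undetectable_transcripts_flagged(self, small_dataset, small_expr):
        truth = small_dataset.truth.transcripts.set_index("transcript_id")
        planted_low = truth.index[~truth["expressed"]]
        flagged = ~small_expr.expressed.reindex(planted_low)
        assert flagged.sum() >= 0.95 * len(planted_low)


class TestQuantileNormalize:
    def test_hand_computed_two_columns(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_are_fixed_point(self):
        col = [3.0, 1.0, 2.0, 10.0]
        m = pd.DataFrame({"a": col, "b": col})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_ties_get_mean_of_spanned_reference(self):
        # reference = mean of sorted columns = ((1+2)/2, (1+4)/2, (3+6)/2)
        m = pd.DataFrame({"a": [1.0, 1.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["b"], [1.5, 2.5, 4.5])
        # the tied 1.0s span reference ranks 1-2 and share their mean
        np.testing.assert_allclose(out["a"], [2.0, 2.0, 4.5])

    @settings(max_examples=25, deadline=None)
    @given(
        arrays(
            np.float64,
            (7, 3),
            elements=st.floats(min_value=-50, max_value=50, allow_nan=False),
            unique=True,  # exact idempotence holds for tie-free columns
        )
    )
    def test_columns_share_distribution_and_idempotent(self, x):
        m = pd.DataFrame(x, columns=list("abc"))
        out = quantile_normalize(m)
        for i in "bc":
            np.testing.assert_allclose(
                np.sort(out["a"]), np.sort(out[i]), atol=1e-12
            )
        pd.testing.assert_frame_equal(quantile_normalize(out), out, atol=1e-12, rtol=0)

    def test_missing_values_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            quantile_normalize(m)


class TestSummarizeTranscripts:
    def test_probe_means(self):
        m = pd.DataFrame({"A1": [4.0, 6.0, 3.0, 3.0, 3.3, 3.6]},
                         index=[f"p{i}" for i in range(6)])
        pm = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(6)],
                "transcript_id": ["t1", "t1", "t2", "t3", "t3", "t3"],
                "is_control": [False] * 6,
            }
        )
        out = summarize_transcripts(m, pm)
        assert out.loc["t1", "A1"] == pytest.approx(5.0)
        assert out.loc["t2", "A1"] == pytest.approx(3.0)  # single probe passthrough
        assert out.loc["t3", "A1"] == pytest.approx(3.3)


class TestRelativeAbundance:
    def _eset(self, values):
        df = pd.DataFrame(values)
        return preprocess.ExpressionSet(
            values=df,
            design=_design(1),
            expressed=pd.Series(True, index=df.index),
        )

    def test_equal_transcripts_give_unit_ratio(self):
        eset = self._eset({"A": [3.0, 3.0], "B": [3.0, 3.0]})
        assert relative_abundance(eset).tolist() == pytest.approx([1.0, 1.0])

    def test_ranking_follows_planted_baseline(self, small_dataset, small_expr):
        from scipy import stats

        ratios = relative_abundance(small_expr)
        truth = small_dataset.truth.transcripts.set_index("transcript_id")
        expressed_flat = truth[(truth["archetype"] == "flat") & truth["expressed"]]
        sub = ratios.reindex(expressed_flat.index).dropna()
        rho = stats.spearmanr(sub, expressed_flat.loc[sub.index, "baseline_log2"]).statistic
        assert rho > 0.95


class TestPipelineEquivariance:
    def test_probe_row_permutation_permutes_outputs(self, small_dataset):
        expr1 = preprocess.preprocess(
            small_dataset.probes, small_dataset.probe_map, small_dataset.design
        )
        shuffled = small_dataset.probes.sample(frac=1.0, random_state=0).reset_index(drop=True)
        expr2 = preprocess.preprocess(
            shuffled, small_dataset.probe_map, small_dataset.design
        )
        pd.testing.assert_frame_equal(expr1.values.sort_index(), expr2.values.sort_index())
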