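"""Sense-antisense pair machinery, checked against the published pair table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ferrotime import datasets, pairs
from ferrotime.pairs import (
    build_pairs,
    classify_pair,
    classify_pairs,
    compare_class_abundance,
    median_direction,
    profile_correlation,
)


class TestProfileCorrelation:
    def test_identical_profiles(self):
        x = np.array([1.0, 2.0, 0.5, -1.0, 3.0])
        assert profile_correlation(x, x) == pytest.approx(1.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x, y = rng.normal(size=(2, 5))
            xm, ym = x - x.mean(), y - y.mean()
            naive = float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
            assert profile_correlation(x, y) == pytest.approx(naive, abs=1e-12)

    def test_spearman_uses_average_ranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 4.0, 5.0])
        assert profile_correlation(x, y, "spearman") == pytest.approx(
            stats.spearmanr(x, y).statistic
        )

    def test_zero_variance_profile_undefined(self):
        assert np.isnan(profile_correlation(np.ones(5), np.arange(5.0)))

    def test_short_profiles_rejected(self):
        with pytest.raises(ValueError):
            profile_correlation([1.0, 2.0], [1.0, 2.0])


class TestClassifyPair:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.89, "I"), (0.51, "I"), (0.5, "II"), (0.0, "II"), (-0.5, "II"),
         (-0.51, "III"), (-0.97, "III")],
    )
    def test_thresholds_with_inclusive_class_ii_boundaries(self, r, expected):
        assert classify_pair(r) == expected

    def test_agrees_with_bruteforce_threshold(self):
        rng = np.random.default_rng(0)
        for r in rng.uniform(-1, 1, size=10000):
            expected = "I" if r > 0.5 else ("III" if r < -0.5 else "II")
            assert classify_pair(float(r)) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(1.5)


class TestMedianDirection:
    def test_published_up_profile(self):
        assert median_direction([2.52, 5.99, 5.53, 6.14, 6.15]) == "up"

    def test_positive_median_despite_negative_points(self):
        assert median_direction([1.01, 0.64, 0.25, -0.23, -0.17]) == "up"

    def test_all_zero_is_flat(self):
        assert median_direction([0.0] * 5) == "flat"


class TestBuildPairs:
    def _annotation(self):
        return pd.DataFrame(
            {
                "transcript_id": ["m1", "m2", "a1", "a2", "a3"],
                "class": ["mRNA", "mRNA", "asRNA", "asRNA", "asRNA"],
                "partner_id": ["", "", "m1", "m2", ""],
            }
        )

    def test_both_members_must_be_de(self):
        de = pd.Series({"m1": True, "m2": False, "a1": True, "a2": True, "a3": True})
        with pytest.warns(UserWarning, match="partner"):
            result, solo = build_pairs(self._annotation(), de)
        assert result.to_records(index=False).tolist() == [("a1", "m1")]
        assert solo == ["a2"]

    def test_planted_pairs_recovered(self, small_dataset, small_fc):
        found, _ = build_pairs(small_dataset.annotation, small_fc["de_any"])
        planted = small_dataset.truth.pairs
        merged = found.merge(planted, on=["antisense_id", "sense_id"])
        assert len(merged) >= 0.9 * len(planted)


@pytest.fixture(scope="module")
def classified():
    return classify_pairs(datasets.load_sense_antisense_pairs())


class TestPublishedPairTable:
    """Checks against the printed 62-pair table of the motivating study."""

    def test_recomputed_r_matches_printed_for_most_pairs(self, classified):
        close = (classified["r"] - classified["r_printed"]).abs() <= 0.02
        assert close.mean() >= 0.9

    @pytest.mark.parametrize(
        "sense_id,printed_r",
        [("slr1968", 0.89), ("slr0534", -0.97), ("sll0247", -1.00)],
    )
    def test_named_rows_reproduce_printed_r(self, classified, sense_id, printed_r):
        row = classified.loc[classified["sense_id"] == sense_id].iloc[0]
        assert row["r"] == pytest.approx(printed_r, abs=0.02)

    def test_printed_r_class_counts(self):
        table = datasets.load_sense_antisense_pairs()
        classes = table["r_printed"].map(classify_pair)
        counts = classes.value_counts()
        assert counts["I"] == 25
        assert counts["II"] == 19
        assert counts["III"] == 18

    def test_median_direction_counts(self, classified):
        assert (classified["antisense_direction"] == "down").sum() == 59
        assert (classified["antisense_direction"] == "up").sum() == 3
        assert (classified["sense_direction"] == "up").sum() == 30
        assert (classified["sense_direction"] == "down").sum() == 32


class TestCompareClassAbundance:
    def test_separated_deltas_give_tiny_p(self):
        intensity = pd.Series(
            {**{f"a{i}": 10.0 + i for i in range(10)},
             **{f"m{i}": 5.0 for i in range(10)},
             **{f"b{i}": 2.0 - 0.05 * i for i in range(10)},
             **{f"n{i}": 5.0 for i in range(10)}}
        )
        class_i = pd.DataFrame(
            {"antisense_id": [f"a{i}" for i in range(10)],
             "sense_id": [f"m{i}" for i in range(10)]}
        )
        class_iii = pd.DataFrame(
            {"antisense_id": [f"b{i}" for i in range(10)],
             "sense_id": [f"n{i}" for i in range(10)]}
        )
        result = compare_class_abundance(class_i, class_iii, intensity)
        assert result["p"] < 0.001
        assert result["median_delta_class_I"] > 0 > result["median_delta_class_III"]

    def test_identical_distributions_give_uniform_p(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            d = rng.normal(size=20)
            intensity = pd.Series(
                {**{f"a{i}": d[i] for i in range(10)},
                 **{f"b{i}": d[10 + i] for i in range(10)},
                 **{f"s{i}": 0.0 for i in range(20)}}
            )
            ci = pd.DataFrame({"antisense_id": [f"a{i}" for i in range(10)],
                               "sense_id": [f"s{i}" for i in range(10)]})
            ciii = pd.DataFrame({"antisense_id": [f"b{i}" for i in range(10)],
                                 "sense_id": [f"s{10 + i}" for i in range(10)]})
            ps.append(compare_class_abundance(ci, ciii, intensity)["p"])
        assert np.mean(np.asarray(ps) < 0.3) == pytest.approx(0.3, abs=0.1)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            compare_class_abundance(pd.DataFrame(), pd.DataFrame({"antisense_id": ["a"], "sense_id": ["s"]}), pd.Series(dtype=float))


class TestEndToEndRecovery:
    def test_planted_classes_recovered_at_low_noise(self):
        from ferrotime import diffexp, preprocess, synthdata

        cfg = synthdata.SimulationConfig(
            seed=17, n_mrna=300, n_asrna=40, n_srna=10, n_control=80,
            n_unexpressed=20, noise_sd=0.1, fraction_responders=0.2,
        )
        ds = synthdata.generate_dataset(cfg)
        expr = preprocess.preprocess(ds.probes, ds.probe_map, ds.design)
        fc = diffexp.differential_expression(expr)
        table = pairs.analyze_pairs(fc, ds.annotation)
        merged = table.merge(
            ds.truth.pairs, on=["antisense_id", "sense_id"],
            suffixes=("_called", "_true"),
        )
        agree = (merged["pair_class_called"] == merged["pair_class_true"]).mean()
        assert len(merged) >= 0.9 * len(ds.truth.pairs)
        assert agree >= 0.9
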