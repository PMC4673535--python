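import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtarnet.expression import (
    ExpressionMatrix,
    apply_high_tier,
    apply_main_filter,
    differential_table,
    log2_fold_change,
    presence_calls,
    relative_quantification_ddct,
    two_sample_t,
)


def make_matrix(values: dict, channel="miRNA"):
    df = pd.DataFrame(values)
    df.index = [f"p{i}" for i in range(len(df))]
    return ExpressionMatrix(df, channel=channel)


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        ("a", "b", "expected"),
        [
            (100.0, 400.0, 2.0),
            (250.0, 250.0, 0.0),
            (100.0, 100.0 * 2**1.327, 1.327),  # the top inflamed small-IEC induction
        ],
    )
    def test_examples(self, a, b, expected):
        assert log2_fold_change(a, b) == pytest.approx(expected)

    @given(
        a=st.floats(0.1, 1e6, allow_nan=False),
        b=st.floats(0.1, 1e6, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a))

    def test_floor_clamps_background(self):
        assert log2_fold_change(0.0, 8.0, floor=1.0) == 3.0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            log2_fold_change(float("nan"), 1.0)
        with pytest.raises(ValueError):
            log2_fold_change(1.0, 1.0, floor=0.0)


def records(rows):
    return pd.DataFrame(
        rows, columns=["probe_id", "intensity_a", "intensity_b", "log2_fc"]
    )


class TestFilters:
    def test_strict_boundaries(self):
        rec = records(
            [
                ("exact_2fold", 200.0, 400.0, 1.0),  # |fc| exactly 1 -> excluded
                ("dim_but_big_fold", 12.0, 99.0, 3.0),  # peak 99 -> excluded
                ("passes", 50.0, 400.0, 3.0),
                ("down_passes", 400.0, 50.0, -3.0),
            ]
        )
        kept = apply_main_filter(rec)
        assert list(kept["probe_id"]) == ["passes", "down_passes"]
        assert list(kept["direction"]) == ["up", "down"]

    def test_intensity_gate_uses_higher_side(self):
        # a down-regulated probe is gated on its (higher) reference intensity
        rec = records([("down", 500.0, 40.0, -3.64)])
        assert len(apply_main_filter(rec)) == 1

    def test_high_tier_nests_in_main(self):
        rng = np.random.default_rng(5)
        rec = records(
            [
                (f"p{i}", a, b, math.log2(max(b, 1) / max(a, 1)))
                for i, (a, b) in enumerate(
                    zip(rng.uniform(1, 30000, 300), rng.uniform(1, 30000, 300))
                )
            ]
        )
        main = set(apply_main_filter(rec)["probe_id"])
        high = set(apply_high_tier(rec)["probe_id"])
        assert high <= main

    def test_raising_thresholds_never_adds(self):
        rng = np.random.default_rng(6)
        rec = records(
            [
                (f"p{i}", a, b, math.log2(max(b, 1) / max(a, 1)))
                for i, (a, b) in enumerate(
                    zip(rng.uniform(1, 5000, 200), rng.uniform(1, 5000, 200))
                )
            ]
        )
        base = set(apply_main_filter(rec)["probe_id"])
        for fold, inten in [(2.5, 100.0), (2.0, 500.0), (4.0, 1000.0)]:
            tighter = set(
                apply_main_filter(rec, fold_threshold=fold, intensity_threshold=inten)[
                    "probe_id"
                ]
            )
            assert tighter <= base

    def test_empty_input(self):
        assert apply_high_tier(records([])).empty


class TestPresenceCalls:
    def test_forced_by_definition(self):
        m = make_matrix({"g": [1.0, 2.0, 3.0, 4.0]})
        calls = presence_calls(m)
        assert calls["threshold_used"].iloc[0] == 2.5
        assert set(calls.loc[calls["expressed"], "probe_id"]) == {"p2", "p3"}

    def test_all_equal_means_none_expressed(self):
        m = make_matrix({"g1": [7.0] * 5, "g2": [7.0] * 5})
        assert not presence_calls(m)["expressed"].any()

    def test_planted_above_median_counts_recovered(self):
        # plant the per-group expressed-set sizes reported for the four arrays
        planted = {"ns": 648, "nl": 844, "is": 541, "il": 514}
        n = 1900
        rng = np.random.default_rng(0)
        cols = {}
        for g, k in planted.items():
            vals = np.full(n, 10.0)  # majority mass pins the pooled median at 10
            vals[:k] = rng.uniform(11.0, 1000.0, size=k)
            cols[g] = rng.permutation(vals)
        m = make_matrix(cols)
        calls = presence_calls(m)
        counts = calls.groupby("group")["expressed"].sum().to_dict()
        assert counts == planted

    def test_invariant_under_uniform_rescaling(self):
        rng = np.random.default_rng(1)
        vals = {"a": rng.uniform(1, 1000, 50), "b": rng.uniform(1, 1000, 50)}
        before = presence_calls(make_matrix(vals))["expressed"]
        scaled = {g: v * 37.5 for g, v in vals.items()}
        after = presence_calls(make_matrix(scaled))["expressed"]
        assert before.equals(after)

    def test_all_invalid_is_an_error(self):
        m = make_matrix({"g": [1.0, 2.0]})
        m.valid[:] = False
        with pytest.raises(ValueError):
            presence_calls(m)


class TestDifferentialTable:
    def test_orientation_and_verdicts(self, small_dataset):
        mirna, _, truth = small_dataset
        rec = differential_table(mirna, "normal_large", "inflamed_large")
        assert (rec["group_a"] == "normal_large").all()
        up = set(rec.loc[rec["direction"] == "up", "probe_id"])
        planted = {
            p
            for p in truth.de_up[("normal_large", "inflamed_large")]
            if p.startswith("mir-")
        }
        assert len(up & planted) / len(planted) >= 0.9
        assert rec.loc[rec["passes_high_tier"], "passes_main_filter"].all()

    def test_unknown_group(self, small_dataset):
        mirna, _, _ = small_dataset
        with pytest.raises(KeyError):
            differential_table(mirna, "normal_large", "nope")


class TestQpcrAndTtest:
    @pytest.mark.parametrize(
        ("cts", "expected"),
        [
            ((20.0, 15.0, 22.0, 17.0), 1.0),  # identical delta-Ct
            ((19.0, 15.0, 22.0, 17.0), 2.0),  # one cycle lower -> one doubling
            ((17.0, 15.0, 22.0, 17.0), 8.0),  # delta-delta-Ct of -3
        ],
    )
    def test_ddct(self, cts, expected):
        assert relative_quantification_ddct(*cts) == pytest.approx(expected)

    def test_identical_groups(self):
        assert two_sample_t([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]) == (0.0, 1.0)

    def test_clear_separation(self):
        t, p = two_sample_t([0.0, 0.01, -0.01], [1.0, 1.01, 0.99])
        assert p < 0.01

    def test_symmetry(self):
        t1, p1 = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 7.0])
        t2, p2 = two_sample_t([4.0, 5.0, 7.0], [1.0, 2.0, 3.0])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_textbook_value(self):
        # classical pooled t: means 2 vs 4, s_p^2 = 1, n = 3 each -> t = -2.449
        t, p = two_sample_t([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert t == pytest.approx(-2.449, abs=1e-3)

    def test_too_small(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])
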