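"""Risk index P x S, direct-weighted aggregation and summary tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vegrisk import (
    ConfigError,
    ThresholdConfig,
    aggregate,
    classify,
    composition_stats,
    descriptive_stats,
    risk_index,
    round_half_up,
    stratum_risk,
    top_share,
)
from vegrisk.risk import HIGH, LOW, S_ALL, W_NONCOMPLIANT, render_risk_table


def make_assessments(groups):
    """groups: list of (province, vegetable, hazards) with hazard 0 = compliant."""
    rows = []
    i = 0
    for prov, veg, hazards in groups:
        for h in hazards:
            i += 1
            rows.append((f"b{i}", prov, veg, 2021, h == 0, float(h),
                         "" if h == 0 else "px", "none" if h == 0 else "over-limit"))
    return pd.DataFrame(
        rows, columns=["batch_id", "province", "vegetable", "year", "compliant",
                       "hazard", "trigger_pesticide", "trigger_kind"])


class TestStratumRisk:
    def test_all_compliant_stratum_is_zero(self):
        df = make_assessments([("Jiangsu", "celery", [0] * 100)])
        (row,) = stratum_risk(df).to_dict("records")
        assert (row["n"], row["m"]) == (100, 0)
        assert row["p"] == row["s"] == row["ir"] == 0.0

    def test_hand_evaluated_stratum(self):
        """10 batches, 2 non-compliant with hazards {3, 5}: P=0.2, S=4, IR=0.8."""
        df = make_assessments([("Jiangsu", "celery", [0] * 8 + [3, 5])])
        (row,) = stratum_risk(df).to_dict("records")
        assert row["p"] == pytest.approx(0.2)
        assert row["s"] == pytest.approx(4.0)
        assert row["ir"] == pytest.approx(0.8)

    def test_all_sample_denominator_option(self):
        df = make_assessments([("Jiangsu", "celery", [0] * 8 + [3, 5])])
        (row,) = stratum_risk(df, s_denominator=S_ALL).to_dict("records")
        assert row["s"] == pytest.approx(0.8)  # 8 / 10
        assert row["ir"] == pytest.approx(0.16)

    def test_ir_identity_and_small_sample_flag(self):
        df = make_assessments(
            [("Jiangsu", "celery", [0, 2.0]), ("Yunnan", "leek", [0] * 50 + [4.0])]
        )
        out = stratum_risk(df, min_n_flag=10)
        assert np.allclose(out["ir"], out["p"] * out["s"])
        flags = dict(zip(out["province"], out["small_sample"]))
        assert flags == {"Jiangsu": True, "Yunnan": False}

    def test_empty_input_empty_output(self):
        out = stratum_risk(make_assessments([]))
        assert out.empty


class TestAggregate:
    def test_single_stratum_group_equals_stratum(self):
        df = make_assessments([("Jiangsu", "celery", [0] * 8 + [3, 5])])
        strata = stratum_risk(df)
        (row,) = aggregate(strata, "vegetable").to_dict("records")
        assert row["p"] == pytest.approx(0.2)
        assert row["s"] == pytest.approx(4.0)
        assert row["ir"] == pytest.approx(0.8)
        assert row["group_count"] == 1

    def test_two_strata_direct_weighting(self):
        """{N=100,M=2,S=3} + {N=300,M=6,S=5}: P=0.02, S=4.5, IR=0.09."""
        strata = pd.DataFrame(
            {
                "province": ["A", "B"], "vegetable": ["celery", "celery"],
                "n": [100, 300], "m": [2, 6],
                "p": [0.02, 0.02], "s": [3.0, 5.0], "ir": [0.06, 0.10],
                "small_sample": [False, False],
            }
        )
        (row,) = aggregate(strata, "vegetable").to_dict("records")
        assert row["p"] == pytest.approx(8 / 400)
        assert row["s"] == pytest.approx((3 * 100 + 5 * 300) / 400)
        assert row["ir"] == pytest.approx(0.02 * 4.5)

    @pytest.mark.parametrize("level", ["vegetable", "province"])
    def test_pooling_identity_against_concatenated_recomputation(self, level):
        """Direct weighting equals recomputing from the pooled assessment table.

        Exact for the two self-consistent pairings: all-sample stratum means
        with batch-count weights, and non-compliant means with
        non-compliant-count weights.
        """
        rng = np.random.default_rng(3)
        groups = []
        for prov in ["A", "B", "C", "D"]:
            for veg in ["celery", "leek", "ginger"]:
                n = int(rng.integers(5, 60))
                hazards = [0.0] * n
                for k in range(int(rng.integers(0, 5))):
                    if k < n:
                        hazards[k] = float(rng.uniform(1.001, 30))
                groups.append((prov, veg, hazards))
        df = make_assessments(groups)

        for s_den, s_w in [(S_ALL, "batches"), ("noncompliant", W_NONCOMPLIANT)]:
            strata = stratum_risk(df, s_denominator=s_den)
            agg = aggregate(strata, level, s_weights=s_w).set_index(level)
            pooled = stratum_risk(df, s_denominator=s_den, by=(level,)).set_index(level)
            for key in pooled.index:
                assert agg.loc[key, "p"] == pytest.approx(pooled.loc[key, "p"], abs=1e-12)
                assert agg.loc[key, "s"] == pytest.approx(pooled.loc[key, "s"], abs=1e-9)
                assert agg.loc[key, "ir"] == pytest.approx(pooled.loc[key, "ir"], abs=1e-9)

    def test_ranking_ties_broken_by_n_then_key(self):
        strata = pd.DataFrame(
            {
                "province": ["A", "A", "A"], "vegetable": ["x", "y", "z"],
                "n": [50, 200, 200], "m": [0, 0, 0],
                "p": [0.0, 0.0, 0.0], "s": [0.0, 0.0, 0.0], "ir": [0.0, 0.0, 0.0],
                "small_sample": [False] * 3,
            }
        )
        out = aggregate(strata, "vegetable")
        assert list(out["vegetable"]) == ["y", "z", "x"]


class TestClassify:
    def test_threshold_product(self):
        assert ThresholdConfig().ir0 == pytest.approx(0.02)
        assert ThresholdConfig(p_max=0.05, s_max=2.0).ir0 == pytest.approx(0.1)

    @pytest.mark.parametrize("ir,expected", [(0.015, LOW), (0.02, HIGH), (0.023, HIGH)])
    def test_boundary_is_high(self, ir, expected):
        assert classify(ir) == expected

    def test_negative_ir_rejected(self):
        with pytest.raises(ValueError):
            classify(-0.01)

    def test_risk_index_product(self):
        assert risk_index(0.2, 4.0) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            risk_index(-0.1, 1.0)


class TestComposition:
    def test_single_category_is_everything(self):
        df = make_assessments([("Jiangsu", "celery", [0, 0, 2.0])])
        tables = composition_stats(df)
        assert tables["batch_share_vegetable"]["share"].iloc[0] == pytest.approx(1.0)
        assert tables["exceedance_by_pesticide"]["share"].iloc[0] == pytest.approx(1.0)

    def test_shares_sum_to_one(self):
        df = make_assessments(
            [("Jiangsu", "celery", [0, 0, 2.0]), ("Yunnan", "leek", [0, 3.0, 4.0])]
        )
        tables = composition_stats(df)
        for name in ["batch_share_vegetable", "batch_share_province",
                     "exceedance_by_pesticide", "exceedance_share_vegetable"]:
            assert tables[name]["share"].sum() == pytest.approx(1.0)

    def test_top_share(self):
        counts = pd.Series([50, 30, 10, 5, 5])
        assert top_share(counts, 2) == pytest.approx(0.8)
        assert top_share(pd.Series(dtype=float), 3) == 0.0


class TestDescriptiveStats:
    def test_single_stratum_degenerate(self):
        df = make_assessments([("Jiangsu", "celery", [0] * 8 + [3, 5])])
        out = descriptive_stats(stratum_risk(df)).set_index("variable")
        for var in ("p", "s", "ir"):
            row = out.loc[var]
            assert row["mean"] == row["min"] == row["max"]
            assert row["sd"] == 0.0

    def test_matches_two_pass_recomputation(self):
        rng = np.random.default_rng(9)
        groups = [
            (f"P{i}", "celery", [0.0] * int(rng.integers(3, 20)) + [float(rng.uniform(1, 20))])
            for i in range(12)
        ]
        strata = stratum_risk(make_assessments(groups))
        out = descriptive_stats(strata).set_index("variable")
        for var in ("p", "s", "ir"):
            x = strata[var].to_numpy()
            assert out.loc[var, "mean"] == pytest.approx(x.mean())
            assert out.loc[var, "sd"] == pytest.approx(x.std(ddof=1))
            assert out.loc[var, "min"] == pytest.approx(x.min())
            assert out.loc[var, "max"] == pytest.approx(x.max())

    def test_all_compliant_all_zero(self):
        df = make_assessments([("Jiangsu", "celery", [0] * 5), ("Yunnan", "leek", [0] * 5)])
        out = descriptive_stats(stratum_risk(df))
        assert (out[["mean", "sd", "min", "max"]].to_numpy() == 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            descriptive_stats(stratum_risk(make_assessments([])))


class TestRendering:
    def test_round_half_up_at_reporting_boundary(self):
        assert round_half_up(0.0745, 3) == 0.075  # bankers' rounding would give 0.074
        assert round_half_up(7.375, 2) == 7.38

    def test_render_percent_and_precision(self):
        df = make_assessments([("Jiangsu", "celery", [0] * 8 + [3, 5])])
        out = render_risk_table(aggregate(stratum_risk(df), "vegetable"), "vegetable")
        (row,) = out.to_dict("records")
        assert row["p_pct"] == 20.0 and row["s"] == 4.0 and row["ir"] == 0.8


@given(
    st.lists(
        st.tuples(st.integers(1, 40), st.integers(0, 6), st.floats(1.0, 40.0)),
        min_size=1, max_size=20,
    )
)
@settings(derandomize=True, max_examples=50, deadline=None)
def test_ir_identity_property(cells):
    """IR == P x S at stratum and aggregate level for arbitrary cell plans."""
    groups = []
    for i, (n, m, s) in enumerate(cells):
        m = min(m, n)
        hazards = [float(s)] * m + [0.0] * (n - m)
        groups.append((f"P{i % 4}", f"veg{i % 5}", hazards))
    strata = stratum_risk(make_assessments(groups))
    assert np.allclose(strata["ir"], strata["p"] * strata["s"])
    for level in ("vegetable", "province"):
        agg = aggregate(strata, level)
        assert np.allclose(agg["ir"], agg["p"] * agg["s"])
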