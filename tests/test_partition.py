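import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phyloassembly import PROCESSES, classify_pair, classify_pairs, partition_fractions
from phyloassembly.matrices import PairwiseMatrix


finite = st.floats(allow_nan=False, allow_infinity=False, min_value=-50, max_value=50)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (2.5, 0.1, "variable_selection"),
            (0.3, 0.97, "dispersal_limitation"),
            (0.0, 0.0, "undominated"),
            (-2.5, -0.99, "homogeneous_selection"),  # selection outranks rc
            (0.0, -0.99, "homogenizing_dispersal"),
            (-3.1, 0.99, "homogeneous_selection"),
        ],
    )
    def test_rule_table(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (2.0, 0.99, "dispersal_limitation"),  # exactly 2 is stochastic
            (-2.0, 0.0, "undominated"),
            (0.0, 0.95, "undominated"),  # exactly 0.95 is drift
            (0.0, -0.95, "undominated"),
        ],
    )
    def test_boundary_values_fall_to_stochastic(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(float("nan"), 0.0)
        with pytest.raises(ValueError):
            classify_pair(0.0, float("inf"))

    @given(finite, finite)
    @settings(max_examples=200, deadline=None)
    def test_total_and_deterministic(self, bnti, rc):
        p = classify_pair(bnti, rc)
        assert p in PROCESSES
        assert classify_pair(bnti, rc) == p


def _mat(vals, name):
    ids = [f"s{i}" for i in range(len(vals))]
    return PairwiseMatrix.from_values(np.asarray(vals, float), ids, name)


class TestClassifyPairs:
    def test_long_form_and_flagging(self):
        bnti = _mat([[0, 3, np.nan], [3, 0, 0.5], [np.nan, 0.5, 0]], "beta_nti")
        rc = _mat([[0, 0.1, 0.2], [0.1, 0, 0.99], [0.2, 0.99, 0]], "rc_bray")
        df = classify_pairs(bnti, rc)
        assert len(df) == 3
        assert df.set_index(["sample_a", "sample_b"]).loc[("s0", "s1"), "process"] == "variable_selection"
        assert df.set_index(["sample_a", "sample_b"]).loc[("s1", "s2"), "process"] == "dispersal_limitation"
        assert df["flagged"].sum() == 1


class TestPartitionFractions:
    def make_pairs(self, procs, groups=None):
        rows = []
        for i, p in enumerate(procs):
            rows.append(
                {
                    "sample_a": f"a{i}",
                    "sample_b": f"b{i}",
                    "bnti": 0.0,
                    "rc": 0.0,
                    "process": p,
                    "flagged": p is None,
                }
            )
        return pd.DataFrame(rows)

    def test_all_undominated(self):
        pairs = self.make_pairs(["undominated"] * 4)
        out = partition_fractions(pairs, None, scheme="all_pairs")
        assert out.loc["all", "undominated_pct"] == pytest.approx(100.0)
        assert out.loc["all", "stochastic_pct"] == pytest.approx(100.0)

    def test_hand_count(self):
        pairs = self.make_pairs(["variable_selection", "dispersal_limitation", "undominated"])
        out = partition_fractions(pairs, None, scheme="all_pairs").loc["all"]
        assert out["variable_selection_pct"] == pytest.approx(100 / 3)
        assert out["dispersal_limitation_pct"] == pytest.approx(100 / 3)
        assert out["stochastic_pct"] == pytest.approx(200 / 3)

    def test_percentages_sum_to_100_and_flagged_excluded(self):
        pairs = self.make_pairs(
            ["variable_selection", "homogenizing_dispersal", None, "undominated", "undominated"]
        )
        out = partition_fractions(pairs, None, scheme="all_pairs").loc["all"]
        assert out["n_excluded"] == 1
        assert out["n_pairs"] == 4
        total = sum(out[f"{p}_pct"] for p in PROCESSES)
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_within_group_scheme(self):
        pairs = pd.DataFrame(
            [
                {"sample_a": "x1", "sample_b": "x2", "bnti": 0, "rc": 0, "process": "undominated", "flagged": False},
                {"sample_a": "x1", "sample_b": "y1", "bnti": 0, "rc": 0, "process": "dispersal_limitation", "flagged": False},
                {"sample_a": "y1", "sample_b": "y2", "bnti": 3, "rc": 0, "process": "variable_selection", "flagged": False},
            ]
        )
        grouping = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
        out = partition_fractions(pairs, grouping, scheme="within_group")
        assert out.loc["X", "undominated_pct"] == pytest.approx(100.0)
        assert out.loc["Y", "variable_selection_pct"] == pytest.approx(100.0)
        assert out.loc["X", "n_pairs"] == 1  # cross-group pair excluded

    def test_pair_order_invariance(self):
        procs = ["variable_selection", "undominated", "dispersal_limitation", "undominated"]
        a = partition_fractions(self.make_pairs(procs), None, scheme="all_pairs")
        b = partition_fractions(self.make_pairs(procs[::-1]), None, scheme="all_pairs")
        pd.testing.assert_frame_equal(
            a.drop(columns=[]), b.drop(columns=[]), check_like=True
        )

    def test_missing_sample_in_grouping_rejected(self):
        pairs = self.make_pairs(["undominated"])
        with pytest.raises(ValueError, match="missing"):
            partition_fractions(pairs, {"a0": "g"}, scheme="within_group")
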