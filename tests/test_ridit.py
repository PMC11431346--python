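"""Ridit scoring: worked examples, algebraic identities, property tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socineq.datasets import pns_sroh_distribution
from socineq.ridit import (
    DegenerateDistributionError,
    GroupedDistribution,
    attach_scores,
    compute_ridit_scores,
    score_table,
)
from socineq.simulate import SimulationDesign, generate


def shares_strategy(min_k=2, max_k=6):
    return (
        st.lists(st.floats(0.01, 1.0), min_size=min_k, max_size=max_k)
        .map(lambda xs: tuple(x / sum(xs) for x in xs))
    )


class TestComputeRiditScores:
    def test_symmetric_two_group(self):
        d = GroupedDistribution(("a", "b"), (0.5, 0.5))
        assert compute_ridit_scores(d).midpoints == (0.25, 0.75)

    def test_published_education_2013_shares(self):
        # hand cumulative-sum oracle on the printed 2013 education shares
        d = GroupedDistribution(
            ("0-4", "5-8", "9-11", "12+"), (0.2143, 0.2509, 0.3430, 0.1918)
        )
        got = compute_ridit_scores(d).midpoints
        np.testing.assert_allclose(
            got, (0.10715, 0.33975, 0.63670, 0.90410), atol=1e-12
        )

    @given(shares=shares_strategy())
    @settings(max_examples=100, deadline=None)
    def test_weighted_mean_is_half(self, shares):
        sc = compute_ridit_scores(GroupedDistribution(
            tuple(f"g{i}" for i in range(len(shares))), shares))
        mean = np.dot(sc.shares, sc.midpoints)
        assert mean == pytest.approx(0.5, abs=1e-12)

    @given(shares=shares_strategy())
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_unit_interval(self, shares):
        m = np.array(compute_ridit_scores(GroupedDistribution(
            tuple(f"g{i}" for i in range(len(shares))), shares)).midpoints)
        assert (np.diff(m) > 0).all()
        assert (m > 0).all() and (m < 1).all()

    @given(shares=shares_strategy())
    @settings(max_examples=100, deadline=None)
    def test_reversal_reflects_midpoints(self, shares):
        labels = tuple(f"g{i}" for i in range(len(shares)))
        fwd = compute_ridit_scores(GroupedDistribution(labels, shares))
        rev = compute_ridit_scores(
            GroupedDistribution(labels[::-1], shares[::-1]))
        np.testing.assert_allclose(
            np.array(rev.midpoints)[::-1], 1.0 - np.array(fwd.midpoints),
            atol=1e-12,
        )

    @given(shares=shares_strategy(min_k=3))
    @settings(max_examples=50, deadline=None)
    def test_merging_adjacent_preserves_mean(self, shares):
        merged = (shares[0] + shares[1],) + tuple(shares[2:])
        sc = compute_ridit_scores(GroupedDistribution(
            tuple(f"m{i}" for i in range(len(merged))), merged))
        assert np.dot(sc.shares, sc.midpoints) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_distribution_raises(self):
        with pytest.raises(DegenerateDistributionError):
            compute_ridit_scores(
                GroupedDistribution(("a", "b"), (1.0, 0.0)))

    def test_zero_share_category_dropped_with_warning(self):
        d = GroupedDistribution(("a", "b", "c"), (0.5, 0.0, 0.5))
        with pytest.warns(UserWarning, match="zero-share"):
            sc = compute_ridit_scores(d)
        assert sc.labels == ("a", "c")
        assert sc.midpoints == (0.25, 0.75)


class TestDistributionValidation:
    @pytest.mark.parametrize(
        "shares", [(0.5, 0.6), (-0.1, 1.1), (0.5,)],
        ids=["not-normalized", "negative", "single-group"],
    )
    def test_invalid_shares_rejected(self, shares):
        with pytest.raises(ValueError):
            GroupedDistribution(tuple(f"g{i}" for i in range(len(shares))),
                                shares)

    def test_prevalence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GroupedDistribution(("a", "b"), (0.5, 0.5), (0.4, 1.2))


class TestAttachScores:
    def test_single_wave_matches_pooled_scores(self, ):
        design = SimulationDesign(n=2000, shares={"w": (0.3, 0.3, 0.4)},
                                  truth={"w": ("linear", 0.4, 0.2)})
        df = generate(design, seed=0)
        scored = attach_scores(df, "group")
        from socineq.ridit import weighted_shares
        shares = weighted_shares(df["group"], df["weight"],
                                 df["group"].cat.categories)
        sc = compute_ridit_scores(GroupedDistribution(
            tuple(df["group"].cat.categories), tuple(shares)))
        expect = dict(zip(sc.labels, sc.midpoints))
        for lab, sub in scored.groupby("group", observed=True):
            assert sub["ridit"].unique() == pytest.approx(expect[lab])

    def test_per_wave_scores_differ_and_each_mean_half(self):
        design = SimulationDesign(
            n=4000,
            shares={"w1": (0.4, 0.3, 0.2, 0.1), "w2": (0.1, 0.2, 0.3, 0.4)},
            truth={"w1": ("linear", 0.4, 0.2), "w2": ("linear", 0.4, 0.2)},
        )
        scored = attach_scores(generate(design, seed=1), "group", wave="wave")
        per_wave = {
            w: sub.groupby("group", observed=True)["ridit"].first()
            for w, sub in scored.groupby("wave")
        }
        assert not np.allclose(per_wave["w1"], per_wave["w2"])
        for w, sub in scored.groupby("wave"):
            mean = np.average(sub["ridit"], weights=sub["weight"])
            assert mean == pytest.approx(0.5, abs=1e-10)

    def test_uniform_weights_reduce_to_frequencies(self):
        df = pd.DataFrame({
            "group": pd.Categorical(["a"] * 3 + ["b"] * 1,
                                    categories=["a", "b"], ordered=True),
            "weight": 1.0,
        })
        tab = score_table(df, "group", per_wave=False)
        assert tab.set_index("label")["share"].to_dict() == {
            "a": 0.75, "b": 0.25}

    def test_weight_rescaling_invariance(self, scored_single_wave):
        df = scored_single_wave.drop(columns="ridit")
        a = attach_scores(df, "group")
        df2 = df.assign(weight=df["weight"] * 17.3)
        b = attach_scores(df2, "group")
        np.testing.assert_allclose(a["ridit"], b["ridit"], atol=1e-12)

    def test_unordered_group_column_rejected(self):
        df = pd.DataFrame({"group": ["a", "b"], "weight": [1.0, 1.0]})
        with pytest.raises(ValueError, match="ordered categorical"):
            score_table(df, "group", per_wave=False)


class TestReferenceDistributions:
    @pytest.mark.parametrize(
        "group,wave,expected",
        [("education", "2013", 67.50), ("education", "2019", 69.68),
         ("income", "2019", 69.68)],
    )
    def test_share_weighted_mean_prevalence(self, group, wave, expected):
        d = pns_sroh_distribution(group, wave)
        assert d.mean_prevalence * 100 == pytest.approx(expected, abs=0.02)

    def test_income_2013_carries_quality_flag(self):
        d = pns_sroh_distribution("income", 2013)
        assert d.flags and "90.38" in d.flags[0]
        assert sum(d.shares) == pytest.approx(1.0, abs=1e-12)
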