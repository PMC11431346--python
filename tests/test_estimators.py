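"""SII/RII estimation: closed forms, oracle equivalence, invariances, and an
independent cross-check against statsmodels' GLM."""

import numpy as np
import pandas as pd
import pytest

from socineq.estimators import (
    DegenerateOutcomeError,
    estimate_rii,
    estimate_sii,
    expand_grouped,
    fit_weighted_binomial,
    grouped_oracle,
)
from socineq.ridit import GroupedDistribution, attach_scores
from socineq.simulate import SimulationDesign, generate
from tests.conftest import random_grouped_distribution


def microdata_from_grouped(dist, reps_per_cell=1):
    """Microdata whose group aggregates equal the grouped distribution.

    Each (group, outcome) cell becomes ``reps_per_cell`` records splitting
    the cell weight equally, so weighted aggregates are identical.
    """
    base = expand_grouped(dist)
    rows = []
    for _, r in base.iterrows():
        for _ in range(reps_per_cell):
            rows.append({**r, "weight": r["weight"] / reps_per_cell})
    return pd.DataFrame(rows)


class TestClosedForms:
    def test_two_group_sii_exact(self, two_group_even):
        # slope of the exact interpolation through (0.25, 0.40), (0.75, 0.60)
        assert grouped_oracle(two_group_even, "SII") == pytest.approx(
            0.40, abs=1e-9)

    def test_two_group_rii_exact(self, two_group_even):
        # exp(slope) with slope = 2 ln(0.6/0.4)
        assert grouped_oracle(two_group_even, "RII") == pytest.approx(
            2.25, abs=1e-9)
        assert 2 * np.log(1.5) == pytest.approx(np.log(2.25), abs=1e-12)

    def test_wls_variant_matches_glm_on_two_groups(self, two_group_even):
        # two points: any weighted regression interpolates exactly
        assert grouped_oracle(two_group_even, "SII", "wls") == pytest.approx(
            grouped_oracle(two_group_even, "SII"), abs=1e-9)

    def test_equal_prevalences_give_null_indices(self):
        d = GroupedDistribution(("a", "b", "c"), (0.2, 0.5, 0.3),
                                (0.55, 0.55, 0.55))
        assert grouped_oracle(d, "SII") == pytest.approx(0.0, abs=1e-9)
        assert grouped_oracle(d, "RII") == pytest.approx(1.0, abs=1e-9)


class TestGroupedOracleEquivalence:
    @pytest.mark.parametrize("index", ["SII", "RII"])
    def test_grouped_equals_microdata_fits(self, index):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            dist = random_grouped_distribution(rng)
            oracle = grouped_oracle(dist, index)
            micro = microdata_from_grouped(dist, reps_per_cell=3)
            fn = estimate_sii if index == "SII" else estimate_rii
            est = fn(micro, "group_label", adjusters=(),
                     psu=None, stratum=None)
            assert est.estimate == pytest.approx(oracle, abs=1e-6)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(5)
        dist = random_grouped_distribution(rng, k=4)
        rev = GroupedDistribution(dist.labels[::-1], dist.shares[::-1],
                                  dist.prevalences[::-1])
        assert grouped_oracle(rev, "SII") == pytest.approx(
            -grouped_oracle(dist, "SII"), abs=1e-8)
        assert grouped_oracle(rev, "RII") == pytest.approx(
            1.0 / grouped_oracle(dist, "RII"), rel=1e-7)

    def test_sii_rii_sign_coherence(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            dist = random_grouped_distribution(rng)
            sii = grouped_oracle(dist, "SII")
            rii = grouped_oracle(dist, "RII")
            assert np.sign(sii) == np.sign(rii - 1.0)


class TestFitWeightedBinomial:
    def test_degenerate_outcome_raises(self):
        df = pd.DataFrame({"outcome": [1, 1, 1], "x": [0.1, 0.5, 0.9],
                           "weight": 1.0})
        with pytest.raises(DegenerateOutcomeError):
            fit_weighted_binomial(df, ["x"], link="identity",
                                  psu=None, stratum=None)

    def test_nonbinary_outcome_rejected(self):
        df = pd.DataFrame({"outcome": [0.0, 0.5], "x": [0, 1], "weight": 1.0})
        with pytest.raises(ValueError, match="binary"):
            fit_weighted_binomial(df, ["x"], link="identity", psu=None)

    @pytest.mark.parametrize("link", ["log", "logit"])
    def test_matches_statsmodels_glm(self, scored_single_wave, link):
        """Independent cross-check: coefficients against statsmodels."""
        sm = pytest.importorskip("statsmodels.api")
        df = scored_single_wave
        fit = fit_weighted_binomial(df, ["ridit"], link=link,
                                    psu=None, stratum=None)
        links = {"log": sm.families.links.Log(),
                 "logit": sm.families.links.Logit()}
        X = np.column_stack([np.ones(len(df)), df["ridit"]])
        ref = sm.GLM(df["outcome"].to_numpy(), X,
                     family=sm.families.Binomial(links[link]),
                     freq_weights=df["weight"].to_numpy()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params,
                                   rtol=1e-6, atol=1e-8)

    def test_covariance_symmetric_psd(self, scored_single_wave):
        fit = fit_weighted_binomial(scored_single_wave, ["ridit", "sex"],
                                    link="identity")
        V = fit.cov.to_numpy()
        np.testing.assert_allclose(V, V.T, atol=1e-14)
        assert np.linalg.eigvalsh(V).min() > -1e-14

    def test_cluster_robust_se_larger_under_clustering(self):
        """Positive intra-PSU correlation inflates the cluster-robust SE
        relative to ignoring clustering (design-effect direction)."""
        design = SimulationDesign(
            n=6000, shares={"w": (0.25,) * 4},
            truth={"w": ("linear", 0.45, 0.25)}, n_psu=60, icc=0.10,
            psu_segregation=0.4)
        ratios = []
        for seed in range(8):
            df = attach_scores(generate(design, seed=seed), "group")
            clustered = fit_weighted_binomial(df, ["ridit"], link="identity")
            iid = fit_weighted_binomial(df, ["ridit"], link="identity",
                                        psu=None, stratum=None)
            ratios.append(clustered.bse["ridit"] / iid.bse["ridit"])
        assert np.mean(ratios) > 1.1


class TestInequalityEstimates:
    def test_weight_scale_invariance(self, scored_single_wave):
        df = scored_single_wave
        a = estimate_sii(df, "group")
        b = estimate_sii(df.assign(weight=df["weight"] * 250.0), "group")
        assert a.estimate == pytest.approx(b.estimate, abs=1e-8)
        r1 = estimate_rii(df, "group")
        r2 = estimate_rii(df.assign(weight=df["weight"] * 0.004), "group")
        assert r1.estimate == pytest.approx(r2.estimate, rel=1e-7)

    def test_reversed_order_negates_sii_and_inverts_rii(self,
                                                        scored_single_wave):
        df = scored_single_wave.copy()
        rev = df.assign(ridit=1.0 - df["ridit"])
        s, s_rev = (estimate_sii(d, "group", adjusters=())
                    for d in (df, rev))
        assert s_rev.estimate == pytest.approx(-s.estimate, abs=1e-7)
        r, r_rev = (estimate_rii(d, "group", adjusters=())
                    for d in (df, rev))
        assert r_rev.estimate == pytest.approx(1.0 / r.estimate, rel=1e-5)

    def test_estimate_metadata_and_ci(self, scored_single_wave):
        est = estimate_sii(scored_single_wave, "group")
        assert est.index == "SII"
        assert est.ci_low <= est.estimate <= est.ci_high
        assert est.adjusted_for == ("sex", "age_group")
        assert est.n == len(scored_single_wave)
        assert est.converged
        rii = estimate_rii(scored_single_wave, "group")
        assert rii.ci_low > 0

    def test_missing_ridit_column_is_an_error(self, scored_single_wave):
        with pytest.raises(ValueError, match="ridit"):
            estimate_sii(scored_single_wave.drop(columns="ridit"), "group")
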