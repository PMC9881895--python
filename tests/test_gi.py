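"""SMF/DMF/dLFC, modified Cohen's D, interaction calling, PR curves."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadscreen.gi import (
    GIError,
    GIResult,
    GroupStats,
    call_interactions,
    cohens_d,
    delta_lfc,
    expected_double_mutant_fitness,
    gene_level_essentiality,
    precision_recall,
    score_pair,
    single_mutant_fitness,
)
from quadscreen.screens import ReferenceGeneSets
from quadscreen.simulate import simulate_pair_lfc


def _constructs(rows):
    return pd.DataFrame(rows, columns=["construct_id", "gene1", "gene2", "group", "lfc"])


class TestSingleMutantFitness:
    def test_mean_over_gene_control_constructs(self):
        tbl = _constructs(
            [("a", "G", "control", "gene_N", -1.0),
             ("b", "G", "control", "gene_N", -0.5),
             ("c", "control", "G", "N_gene", -1.5)]
        )
        assert single_mutant_fitness(tbl, "G") == pytest.approx(-1.0)

    def test_orientation_pooling_symmetry(self):
        fwd = _constructs(
            [("a", "G", "control", "gene_N", -2.0),
             ("b", "control", "G", "N_gene", -1.0)]
        )
        swapped = _constructs(
            [("a", "control", "G", "N_gene", -2.0),
             ("b", "G", "control", "gene_N", -1.0)]
        )
        assert single_mutant_fitness(fwd, "G") == single_mutant_fitness(swapped, "G")

    def test_missing_gene_named_in_error(self):
        with pytest.raises(GIError, match="NOPE"):
            single_mutant_fitness(_constructs([]), "NOPE")


class TestExpectedAndDelta:
    @pytest.mark.parametrize(
        "smf1, smf2, expected", [(-1.0, -1.2, -2.2), (0.0, 3.3, 3.3), (-1.2, -1.0, -2.2)]
    )
    def test_additive_expectation(self, smf1, smf2, expected):
        assert expected_double_mutant_fitness(smf1, smf2) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "obs, exp, d", [(-3.2, -2.2, -1.0), (-2.2, -2.2, 0.0), (-1.0, -2.2, 1.2)]
    )
    def test_delta_sign_convention(self, obs, exp, d):
        assert delta_lfc(obs, exp) == pytest.approx(d)


def _chain_oracle(mu1, mu2, s1, s2, obs_mean, obs_std):
    """Independent step-by-step evaluation of the printed formula chain."""
    expected_mean = mu1 + mu2
    expected_std = (s1**2 + s2**2) ** 0.5
    spooled = ((expected_std**2 + obs_std**2) / 2) ** 0.5
    return (expected_mean - obs_mean) / spooled


class TestCohensD:
    def test_hand_arithmetic_sqrt2(self):
        d = cohens_d(
            GroupStats(-1, 1, 3), GroupStats(-1, 1, 3),
            GroupStats(-4, math.sqrt(2), 3),
        )
        assert d == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_hand_arithmetic_three_four_five(self):
        d = cohens_d(GroupStats(0, 3, 3), GroupStats(0, 4, 3), GroupStats(-1, 5, 3))
        assert d == pytest.approx(0.2, abs=1e-12)

    def test_null_case(self):
        d = cohens_d(GroupStats(-1, 1, 3), GroupStats(-1, 1, 3), GroupStats(-2, 1, 3))
        assert d == pytest.approx(0.0)

    def test_degenerate_spread_rejected(self):
        with pytest.raises(GIError, match="Spooled"):
            cohens_d(GroupStats(0, 0, 3), GroupStats(0, 0, 3), GroupStats(-1, 0, 3))

    @given(
        mu1=st.floats(-5, 5), mu2=st.floats(-5, 5),
        s1=st.floats(0.01, 4), s2=st.floats(0.01, 4),
        om=st.floats(-10, 5), os_=st.floats(0.01, 4),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_independent_chain(self, mu1, mu2, s1, s2, om, os_):
        ours = cohens_d(GroupStats(mu1, s1, 3), GroupStats(mu2, s2, 3),
                        GroupStats(om, os_, 3))
        assert ours == pytest.approx(_chain_oracle(mu1, mu2, s1, s2, om, os_), abs=1e-12)

    def test_symmetric_in_gene_labels(self, rng):
        g1, g2 = GroupStats(-1.2, 0.4, 5), GroupStats(-0.3, 0.7, 5)
        obs = GroupStats(-2.5, 0.5, 6)
        assert cohens_d(g1, g2, obs) == pytest.approx(cohens_d(g2, g1, obs))


class TestScorePair:
    def test_dlfc_invariant_to_gene_order(self):
        tbl = simulate_pair_lfc(-1.0, -0.5, gi_effect=-1.5, seed=11)
        r12 = score_pair(tbl, "GENE1", "GENE2")
        r21 = score_pair(tbl, "GENE2", "GENE1")
        assert r12.dlfc == pytest.approx(r21.dlfc)
        assert r12.cohens_d == pytest.approx(r21.cohens_d)

    def test_recovers_injected_effect_without_noise(self):
        tbl = simulate_pair_lfc(-1.0, -0.5, gi_effect=-1.5, sigma=0.0, seed=0)
        res = score_pair(tbl, "GENE1", "GENE2")
        assert res.expected_dmf == pytest.approx(-1.5)
        assert res.observed_dmf == pytest.approx(-3.0)
        assert res.dlfc == pytest.approx(-1.5)

    def test_missing_pair_constructs_rejected(self):
        tbl = simulate_pair_lfc(-1.0, -0.5, seed=0)
        with pytest.raises(GIError, match="double-targeting"):
            score_pair(tbl[tbl["group"] != "A_B"], "GENE1", "GENE2")


class TestCallInteractions:
    def _res(self, dlfc, d=None):
        return GIResult(genes=("A", "B"), smf={"A": 0, "B": 0}, expected_dmf=0,
                        observed_dmf=dlfc, dlfc=dlfc, cohens_d=d)

    @pytest.mark.parametrize(
        "dlfc, d, hit",
        [(-1.5, 1.0, True), (-1.5, 0.5, False), (-0.5, 2.0, False),
         (-1.0, 1.0, False)],  # boundary: strict inequality
    )
    def test_pair_mode_thresholds(self, dlfc, d, hit):
        (out,) = call_interactions([self._res(dlfc, d)])
        assert out.hit is hit

    @pytest.mark.parametrize(
        "dlfc, cls",
        [(-1.5, "synthetic_lethal"), (1.2, "masking"), (0.0, "none"),
         (1.0, "none")],  # boundary
    )
    def test_threshold_mode(self, dlfc, cls):
        (out,) = call_interactions([self._res(dlfc)], mode="threshold")
        assert out.classification == cls


class TestEssentialityAndPR:
    def test_mean_fc_threshold(self):
        arrays = pd.DataFrame(
            {"target": ["g1", "g1", "g2", "g2", "g3", "g3"],
             "lfc": [-2.4, -1.8, 0.1, -0.3, -1.0, -1.0]}
        )
        out = gene_level_essentiality(arrays).set_index("target")
        assert out.loc["g1", "mean_fc"] == pytest.approx(-2.1)
        assert bool(out.loc["g1", "essential"])
        assert not bool(out.loc["g2", "essential"])
        # exactly -1 is not essential: strict inequality
        assert not bool(out.loc["g3", "essential"])

    def test_pr_perfect_separation(self):
        scores = pd.Series({"e1": -3, "e2": -2.5, "n1": 0.0, "n2": 0.2})
        refs = ReferenceGeneSets({"e1", "e2"}, {"n1", "n2"})
        pr = precision_recall(scores, refs)
        at_full = pr[pr["recall"] == 1.0].iloc[0]
        assert at_full["precision"] == pytest.approx(1.0)

    def test_pr_reversed_separation(self):
        scores = pd.Series({"e1": 0.0, "e2": 0.5, "n1": -2.0, "n2": -3.0})
        refs = ReferenceGeneSets({"e1", "e2"}, {"n1", "n2"})
        pr = precision_recall(scores, refs)
        at_full = pr[pr["recall"] == 1.0]["precision"].max()
        assert at_full == pytest.approx(2 / 4)

    def test_pr_enumerated_ranks(self):
        # essentials at ranks 1 and 3, nonessential at rank 2
        scores = pd.Series({"e1": -3.0, "n1": -2.0, "e2": -1.0, "x": -5.0})
        refs = ReferenceGeneSets({"e1", "e2"}, {"n1"})
        pr = precision_recall(scores, refs)  # "x" is ignored (not a reference)
        points = list(zip(pr["recall"].round(6), pr["precision"].round(6)))
        assert points == [(0.5, 1.0), (0.5, 0.5), (1.0, pytest.approx(2 / 3))]

    def test_pr_average_precision_matches_sklearn(self, rng):
        """Independent cross-check: average precision derived from our
        rank-based curve equals sklearn's on distinct scores."""
        from sklearn.metrics import average_precision_score

        ess = [f"e{i}" for i in range(20)]
        non = [f"n{i}" for i in range(30)]
        scores = pd.Series(rng.normal(size=50), index=ess + non)
        scores[ess] -= 1.0  # essentials somewhat depleted
        refs = ReferenceGeneSets(set(ess), set(non))
        pr = precision_recall(scores, refs)
        recall_steps = np.diff(np.concatenate([[0.0], pr["recall"]]))
        ours = float((recall_steps * pr["precision"]).sum())
        theirs = average_precision_score(
            scores.index.isin(ess).astype(int), -scores.to_numpy()
        )
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_pr_requires_both_reference_classes(self):
        scores = pd.Series({"e1": -3.0})
        refs = ReferenceGeneSets({"e1"}, {"n1"})
        with pytest.raises(GIError, match="nonessential"):
            precision_recall(scores, refs)


class TestNullAndRecoveryProperties:
    def test_null_hit_rate_small(self):
        """No-interaction pairs are almost never called at default thresholds."""
        hits = 0
        n = 200
        for seed in range(n):
            tbl = simulate_pair_lfc(-1.0, -0.5, gi_effect=0.0, sigma=0.3, seed=seed)
            res = call_interactions([score_pair(tbl, "GENE1", "GENE2")])[0]
            hits += res.hit
        assert hits / n <= 0.02

    def test_groupstats_needs_two_values(self):
        with pytest.raises(GIError):
            GroupStats.from_values([1.0])
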