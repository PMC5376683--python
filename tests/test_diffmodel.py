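"""Pseudo-temporal profiles, marker-rule state labelling and gene clustering."""

import numpy as np
import pandas as pd
import pytest

from scfib import (
    STATE_LABELS,
    cluster_profiles,
    label_states,
    order_states,
    pseudotemporal_profile,
)
from scfib.diffmodel import PseudoTemporalProfile
from scfib.simulate import STATE_CONDITION


def summary_from(freq: pd.DataFrame, level: pd.DataFrame) -> pd.DataFrame:
    """Assemble a (gene, group) summary table from frequency/level frames."""
    rows = []
    for gene in freq.index:
        for state in freq.columns:
            rows.append(
                (gene, state, freq.loc[gene, state], level.loc[gene, state],
                 np.nan, 0, 1)
            )
    return pd.DataFrame(
        rows, columns=["gene", "group", "frequency", "level", "sem", "n_pos", "n_total"]
    ).set_index(["gene", "group"])


class TestPseudoTemporalProfile:
    def test_score_is_frequency_times_level(self):
        freq = pd.DataFrame({"s1": [0.5]}, index=["ACTA2"])
        level = pd.DataFrame({"s1": [4.0]}, index=["ACTA2"])
        prof = pseudotemporal_profile(summary_from(freq, level), ["s1"])
        assert prof.score.loc["ACTA2", "s1"] == pytest.approx(2.0)

    def test_zero_frequency_forces_zero_score(self):
        freq = pd.DataFrame({"s1": [0.0]}, index=["HGF"])
        level = pd.DataFrame({"s1": [np.nan]}, index=["HGF"])
        prof = pseudotemporal_profile(summary_from(freq, level), ["s1"])
        assert prof.score.loc["HGF", "s1"] == 0.0

    def test_negative_levels_floored(self):
        freq = pd.DataFrame({"s1": [0.8]}, index=["CD24"])
        level = pd.DataFrame({"s1": [-2.0]}, index=["CD24"])
        prof = pseudotemporal_profile(summary_from(freq, level), ["s1"])
        assert prof.score.loc["CD24", "s1"] == 0.0

    def test_matches_two_loop_recomputation(self, log2_unimputed):
        from scfib import summarize_groups

        summary = summarize_groups(log2_unimputed, "cell_class")
        states = list(log2_unimputed.cells["cell_class"].unique())
        prof = pseudotemporal_profile(summary, states)
        for gene in log2_unimputed.genes:
            for state in states:
                f = summary.loc[(gene, state), "frequency"]
                lvl = summary.loc[(gene, state), "level"]
                expected = 0.0 if f == 0 else f * max(0.0, 0.0 if np.isnan(lvl) else lvl)
                assert abs(prof.score.loc[gene, state] - expected) < 1e-12

    def test_missing_state_rejected(self):
        freq = pd.DataFrame({"s1": [0.5]}, index=["ACTA2"])
        level = pd.DataFrame({"s1": [4.0]}, index=["ACTA2"])
        with pytest.raises(ValueError, match="s2"):
            pseudotemporal_profile(summary_from(freq, level), ["s1", "s2"])

    def test_linearity_doubling_levels_doubles_scores(self):
        rng = np.random.default_rng(0)
        freq = pd.DataFrame(rng.uniform(0.1, 1, (4, 2)), index=list("ABCD"),
                            columns=["s1", "s2"])
        freq.index = ["ACTA2", "TNC", "HGF", "CCL5"]
        level = pd.DataFrame(rng.uniform(1, 8, (4, 2)), index=freq.index,
                             columns=["s1", "s2"])
        p1 = pseudotemporal_profile(summary_from(freq, level), ["s1", "s2"])
        p2 = pseudotemporal_profile(summary_from(freq, 2 * level), ["s1", "s2"])
        np.testing.assert_allclose(p2.score.to_numpy(), 2 * p1.score.to_numpy())


def planted_profile(panel):
    """A six-state profile where each label's defining criterion is planted."""
    states = [f"state{i}" for i in range(1, 7)]
    score = pd.DataFrame(1.0, index=panel.genes, columns=states)
    for g in panel.genes_in_group("pluripotency"):
        score.loc[g] = [8, 0.2, 0.2, 0.2, 0.2, 0.2]
    for g in ["ACTA2", "COL1A1", "TNC", "FN1", "FAP", "MMP2"]:
        score.loc[g] = [2.0, 0.5, 4.0, 5.0, 7.0, 5.0]
    for g in ["CXCL12", "PDGFA", "VEGFA", "HGF"]:
        score.loc[g] = [1, 1, 2, 3, 4, 9]
    score.loc["COL1A1"] = [2, 0.5, 5, 6, 10, 5]
    score.loc["FN1"] = [2, 0.5, 5, 6, 10, 5]
    return PseudoTemporalProfile(score=score, states=states)


class TestLabelStates:
    def test_planted_criteria_recovered(self, panel):
        model = label_states(planted_profile(panel), panel, STATE_CONDITION)
        assert model.labels["state1"] == "stem_like"
        assert model.labels["state2"] == "naive"
        assert model.labels["state3"] == "primed"
        assert model.labels["state4"] == "proto_myofibroblast"
        assert model.labels["state5"] == "ecm_myofibroblast"
        assert model.labels["state6"] == "secretory_myofibroblast"

    def test_input_order_invariance(self, panel):
        prof = planted_profile(panel)
        rev = PseudoTemporalProfile(
            score=prof.score[prof.states[::-1]], states=prof.states[::-1]
        )
        a = label_states(prof, panel, STATE_CONDITION)
        b = label_states(rev, panel, STATE_CONDITION)
        assert a.labels == b.labels

    def test_tie_breaks_to_lower_state_id(self, panel):
        prof = planted_profile(panel)
        # make the two normal non-stem states identical on activation markers
        for g in ["ACTA2", "COL1A1", "TNC", "FN1", "FAP", "MMP2"]:
            prof.score.loc[g, "state3"] = prof.score.loc[g, "state2"]
        model = label_states(prof, panel, STATE_CONDITION)
        assert model.labels["state2"] == "naive"  # lower id wins the tie

    def test_unknown_rule_gene_rejected(self, panel):
        with pytest.raises((ValueError, KeyError)):
            label_states(
                planted_profile(panel), panel, STATE_CONDITION,
                rules={"activation_markers": ["NOT_A_GENE"]},
            )

    def test_missing_condition_rejected(self, panel):
        with pytest.raises(ValueError, match="condition"):
            label_states(planted_profile(panel), panel, {"state1": "normal"})


class TestOrderStates:
    def test_shuffled_input_reaches_canonical_order(self, panel):
        model = label_states(planted_profile(panel), panel, STATE_CONDITION)
        ordered = order_states(model)
        assert ordered.label_order() == list(STATE_LABELS)
        assert ordered.states == [f"state{i}" for i in range(1, 7)]

    def test_already_ordered_unchanged(self, panel):
        model = order_states(label_states(planted_profile(panel), panel, STATE_CONDITION))
        again = order_states(model)
        assert again.states == model.states

    def test_normal_only_subset_keeps_relative_order(self, panel):
        prof = planted_profile(panel)
        sub = PseudoTemporalProfile(
            score=prof.score[["state1", "state2", "state3"]],
            states=["state1", "state2", "state3"],
        )
        conditions = {s: "normal" for s in sub.states}
        model = order_states(label_states(sub, panel, conditions))
        assert model.label_order() == ["stem_like", "naive", "primed"]


class TestClusterProfiles:
    def test_two_archetypes_separate_at_two_cut(self):
        states = ["s1", "s2", "s3", "s4"]
        up = np.array([1.0, 2.0, 3.0, 4.0])
        off = np.array([4.0, 3.0, 1.0, 0.0])
        rows, names = [], []
        for i in range(3):
            rows.append(up + 0.1 * i)
            names.append(f"up{i}")
        for i in range(3):
            rows.append(off + 0.1 * i)
            names.append(f"off{i}")
        prof = PseudoTemporalProfile(
            score=pd.DataFrame(rows, index=names, columns=states), states=states
        )
        out = cluster_profiles(prof, n_clusters=2)
        up_clusters = set(out.loc[[f"up{i}" for i in range(3)], "cluster"])
        off_clusters = set(out.loc[[f"off{i}" for i in range(3)], "cluster"])
        assert len(up_clusters) == 1 and len(off_clusters) == 1
        assert up_clusters != off_clusters

    def test_single_gene_is_singleton(self):
        prof = PseudoTemporalProfile(
            score=pd.DataFrame([[1.0, 2.0]], index=["ACTA2"], columns=["s1", "s2"]),
            states=["s1", "s2"],
        )
        out = cluster_profiles(prof)
        assert len(out) == 1

    def test_duplicated_rows_share_cluster(self):
        score = pd.DataFrame(
            [[1.0, 5.0], [1.0, 5.0], [9.0, 0.0]],
            index=["A", "B", "C"], columns=["s1", "s2"],
        )
        prof = PseudoTemporalProfile(score=score, states=["s1", "s2"])
        out = cluster_profiles(prof, n_clusters=2)
        assert out.loc["A", "cluster"] == out.loc["B", "cluster"]

    def test_extreme_range_gene_flagged(self):
        score = pd.DataFrame(
            {"s1": [0.0, 0.0, 0.0], "s2": [1.0, 1.2, 50.0]},
            index=["A", "B", "WILD"],
        )
        prof = PseudoTemporalProfile(score=score, states=["s1", "s2"])
        out = cluster_profiles(prof)
        assert out.loc["WILD", "extreme"]
        assert not out.loc["A", "extreme"]
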