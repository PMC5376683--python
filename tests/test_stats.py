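"""Group summaries, differential tests, significance area and bimodality."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from scfib import (
    differential_expression,
    fit_bimodal,
    stratified_mean_scatter,
    stratify_by_gene,
    summarize_groups,
)
from scfib.stats import SD_FLOOR

from conftest import make_matrix


def _series(matrix, value="g"):
    return pd.Series(value, index=matrix.values.index)


class TestSummarizeGroups:
    def test_hand_computed_example(self):
        m = make_matrix(
            [[2.0], [4.0], [6.0], [0.0]],
            genes=["ACTA2"],
            scale="log2_rq",
            detected=[[True], [True], [True], [False]],
        )
        out = summarize_groups(m, _series(m))
        row = out.loc[("ACTA2", "g")]
        assert row["frequency"] == pytest.approx(0.75)
        assert row["level"] == pytest.approx(4.0)
        assert row["sem"] == pytest.approx(2.0 / np.sqrt(3))
        assert row["n_pos"] == 3 and row["n_total"] == 4

    def test_never_detected_gene_has_missing_level(self):
        m = make_matrix(
            [[0.0], [0.0]], genes=["HGF"], scale="log2_rq", detected=[[False], [False]]
        )
        out = summarize_groups(m, _series(m))
        row = out.loc[("HGF", "g")]
        assert row["frequency"] == 0.0 and np.isnan(row["level"])

    def test_brute_force_oracle_on_reference(self, log2_unimputed):
        groups = log2_unimputed.cells["cell_class"]
        out = summarize_groups(log2_unimputed, "cell_class")
        for gene in log2_unimputed.genes[::7]:
            for grp in groups.unique():
                idx = groups.index[groups == grp]
                det = log2_unimputed.detected.loc[idx, gene]
                vals = log2_unimputed.values.loc[idx, gene][det]
                row = out.loc[(gene, grp)]
                assert row["frequency"] == pytest.approx(det.mean(), abs=1e-12)
                if len(vals):
                    assert row["level"] == pytest.approx(vals.mean(), abs=1e-12)

    def test_cell_order_invariance(self, log2_unimputed):
        out1 = summarize_groups(log2_unimputed, "cell_class")
        perm = np.random.default_rng(0).permutation(log2_unimputed.n_cells)
        shuffled = log2_unimputed.subset_cells(
            [log2_unimputed.cell_ids[i] for i in perm]
        )
        out2 = summarize_groups(shuffled, "cell_class")
        pd.testing.assert_frame_equal(out1.sort_index(), out2.sort_index())

    def test_linear_scale_rejected(self):
        m = make_matrix([[1.0]], scale="linear_rq", detected=[[True]])
        with pytest.raises(ValueError):
            summarize_groups(m, _series(m))


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        m = make_matrix([[1.0], [2.0], [3.0]], genes=["ACTA2"], scale="log2_rq")
        out = differential_expression(m, m)
        assert out.loc["ACTA2", "delta_level"] == 0.0
        assert out.loc["ACTA2", "p_value"] == pytest.approx(1.0)
        assert not out.loc["ACTA2", "significant"]

    def test_textbook_t_statistic(self):
        a = make_matrix([[1.0], [2.0], [3.0]], genes=["G"], scale="log2_rq")
        b = make_matrix([[4.0], [5.0], [6.0]], genes=["G"], scale="log2_rq")
        out = differential_expression(a, b, test="student_t")
        # closed form: pooled SD = 1, t = -3/sqrt(2/3), df = 4
        t = -3.0 / np.sqrt(2.0 / 3.0)
        p = 2 * sps.t.sf(abs(t), df=4)
        assert out.loc["G", "p_value"] == pytest.approx(p, abs=1e-10)
        assert out.loc["G", "delta_level"] == pytest.approx(-3.0)

    def test_anova_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(1)
        a = make_matrix(rng.normal(0, 1, (8, 1)), genes=["G"], scale="log2_rq")
        b = make_matrix(rng.normal(1, 1, (9, 1)), genes=["G"], scale="log2_rq")
        p_t = differential_expression(a, b, test="student_t").loc["G", "p_value"]
        p_f = differential_expression(a, b, test="anova").loc["G", "p_value"]
        assert p_t == pytest.approx(p_f, rel=1e-10)

    def test_minimum_detected_cells_rule(self):
        a = make_matrix(
            [[1.0], [0.0]], genes=["G"], scale="log2_rq", detected=[[True], [False]]
        )
        b = make_matrix([[1.0], [2.0]], genes=["G"], scale="log2_rq")
        out = differential_expression(a, b)
        assert np.isnan(out.loc["G", "p_value"])

    def test_unknown_test_rejected(self):
        m = make_matrix([[1.0]], genes=["G"], scale="log2_rq")
        with pytest.raises(ValueError):
            differential_expression(m, m, test="bogus")

    def test_bh_adjustment_is_monotone_weaker(self):
        rng = np.random.default_rng(2)
        a = make_matrix(rng.normal(0, 1, (10, 4)), scale="log2_rq")
        b = make_matrix(rng.normal(0.5, 1, (10, 4)), scale="log2_rq")
        plain = differential_expression(a, b)
        adj = differential_expression(a, b, adjust="bh")
        assert (adj["p_adjusted"] >= plain["p_value"] - 1e-15).all()


class TestStratifiedScatter:
    def test_identical_stratum_nothing_outside(self):
        rng = np.random.default_rng(3)
        ref = make_matrix(rng.normal(0, 1, (20, 3)), scale="log2_rq")
        out = stratified_mean_scatter(ref, {"same": ref})
        assert not out["outside_significance_area"].any()

    def test_large_shift_flagged_outside(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, (20, 3))
        shifted = base.copy() + 0.0
        shifted[:, 0] += 10.0  # ten SDs on the first gene
        ref = make_matrix(base, scale="log2_rq")
        stratum = make_matrix(shifted, scale="log2_rq")
        out = stratified_mean_scatter(ref, {"hi": stratum})
        assert out.loc["G0", "outside_significance_area"]
        assert not out.loc["G2", "outside_significance_area"]

    def test_flags_agree_with_differential_expression(self):
        rng = np.random.default_rng(5)
        ref = make_matrix(rng.normal(0, 1, (15, 4)), scale="log2_rq")
        stratum = make_matrix(rng.normal(0.8, 1, (15, 4)), scale="log2_rq")
        scatter = stratified_mean_scatter(ref, {"s": stratum})
        de = differential_expression(stratum, ref)
        assert (
            scatter["outside_significance_area"]
            == de["significant"].fillna(False)
        ).all()

    def test_tiny_stratum_rejected(self):
        ref = make_matrix(np.zeros((5, 2)), scale="log2_rq")
        one = make_matrix(np.zeros((1, 2)), scale="log2_rq")
        with pytest.raises(ValueError):
            stratified_mean_scatter(ref, {"tiny": one})


class TestBimodalFit:
    def test_recovers_two_well_separated_components(self):
        rng = np.random.default_rng(10)
        x = np.concatenate(
            [rng.normal(2.0, 0.5, 100), rng.normal(6.0, 0.5, 100)]
        )
        fit = fit_bimodal(x, seed=0)
        assert fit.k == 2
        assert fit.means[0] == pytest.approx(2.0, abs=0.3)
        assert fit.means[1] == pytest.approx(6.0, abs=0.3)
        assert 2.0 < fit.boundary < 6.0

    def test_single_gaussian_selects_one_component(self):
        rng = np.random.default_rng(11)
        fit = fit_bimodal(rng.normal(4.0, 1.0, 200), seed=0)
        assert fit.k == 1
        assert fit.means[0] == pytest.approx(4.0, abs=0.3)

    def test_degenerate_identical_values(self):
        fit = fit_bimodal(np.full(20, 3.0), seed=0)
        assert fit.k == 1
        assert fit.sds[0] == pytest.approx(SD_FLOOR)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_bimodal(np.arange(5.0), seed=0)

    def test_detection_of_bimodality_monotone_in_separation(self):
        # at fixed n the two-component model wins more often as separation grows
        rng = np.random.default_rng(12)
        rates = []
        for sep in (1.0, 4.0, 8.0):
            wins = 0
            for rep in range(10):
                x = np.concatenate(
                    [rng.normal(0.0, 1.0, 60), rng.normal(sep, 1.0, 60)]
                )
                wins += fit_bimodal(x, seed=rep).k == 2
            rates.append(wins / 10)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] == 1.0


class TestStratifyByGene:
    @pytest.fixture()
    def mixture_matrix(self):
        rng = np.random.default_rng(13)
        comp = rng.integers(0, 2, 120)
        vals = np.where(comp == 0, rng.normal(2, 0.5, 120), rng.normal(6, 0.5, 120))
        det = np.ones((120, 1), dtype=bool)
        det[:3, 0] = False
        m = make_matrix(vals[:, None], genes=["ACTA2"], scale="log2_rq", detected=det)
        return m, comp

    def test_component_means_assign_to_their_side(self, mixture_matrix):
        m, comp = mixture_matrix
        fit = fit_bimodal(m.values["ACTA2"][m.detected["ACTA2"]].to_numpy(), seed=0)
        strat = stratify_by_gene(m, "ACTA2", fit)
        detected = m.values["ACTA2"][m.detected["ACTA2"]]
        nearest_low = (detected - 2.0).abs().idxmin()
        nearest_high = (detected - 6.0).abs().idxmin()
        assert strat.labels[nearest_low] == "low"
        assert strat.labels[nearest_high] == "high"

    def test_non_detects_assigned_low(self, mixture_matrix):
        m, _ = mixture_matrix
        fit = fit_bimodal(m.values["ACTA2"][m.detected["ACTA2"]].to_numpy(), seed=0)
        strat = stratify_by_gene(m, "ACTA2", fit)
        assert (strat.labels[~m.detected["ACTA2"]] == "low").all()

    def test_accuracy_against_simulated_components(self, mixture_matrix):
        m, comp = mixture_matrix
        det = m.detected["ACTA2"].to_numpy()
        fit = fit_bimodal(m.values["ACTA2"][m.detected["ACTA2"]].to_numpy(), seed=0)
        strat = stratify_by_gene(m, "ACTA2", fit)
        pred = (strat.labels == "high").to_numpy()[det]
        truth = comp[det] == 1
        assert (pred == truth).mean() >= 0.95

    def test_unimodal_fit_rejected(self):
        rng = np.random.default_rng(14)
        m = make_matrix(rng.normal(4, 1, (200, 1)), genes=["ACTA2"], scale="log2_rq")
        fit = fit_bimodal(m.values["ACTA2"].to_numpy(), seed=0)
        with pytest.raises(ValueError, match="bimodal"):
            stratify_by_gene(m, "ACTA2", fit)
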