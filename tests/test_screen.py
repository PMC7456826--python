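"""Panel intersection, pair correlation, hit calling and drug ranking."""

import numpy as np
import pandas as pd
import pytest

from tkiscreen import screen, simulate


def _matrix(ids, columns, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(len(ids), len(columns))),
        index=pd.Index(ids), columns=pd.Index(columns),
    )


class TestIntersectPanel:
    def test_keeps_only_shared_cell_lines(self):
        expr = _matrix(["g1"], ["a", "b", "c"])
        auc = _matrix(["d1"], ["b", "c", "d"])
        panel = screen.intersect_panel(expr, auc)
        assert list(panel.cell_line_ids) == ["b", "c"]

    def test_disjoint_ids_rejected(self):
        with pytest.raises(ValueError):
            screen.intersect_panel(_matrix(["g"], ["a"]), _matrix(["d"], ["b"]))

    def test_column_order_irrelevant(self):
        expr = _matrix(["g1", "g2"], ["a", "b", "c", "d"], seed=1)
        auc = _matrix(["d1"], ["a", "b", "c", "d"], seed=2)
        p1 = screen.intersect_panel(expr, auc)
        p2 = screen.intersect_panel(expr[["d", "b", "a", "c"]], auc[["c", "a", "d", "b"]])
        r1 = screen.run_screen(["g1", "g2"], p1)
        r2 = screen.run_screen(["g1", "g2"], p2)
        pd.testing.assert_frame_equal(r1, r2)


class TestSelectCandidates:
    def _deg_table(self, rows):
        return pd.DataFrame(
            rows, columns=["is_deg", "direction"],
            index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id"),
        )

    def test_all_down_degs_give_empty_output(self):
        table = self._deg_table([(True, "down"), (True, "down")])
        targets = pd.DataFrame({"gene_id": ["g0", "g1"], "drug_id": ["d", "d"]})
        assert screen.select_candidates(table, targets) == []

    def test_only_annotated_up_degs_kept_sorted(self):
        table = self._deg_table(
            [(True, "up"), (True, "up"), (True, "up"), (False, "up"), (True, "down")]
        )
        targets = pd.DataFrame({"gene_id": ["g2", "g0"], "drug_id": ["d1", "d2"]})
        assert screen.select_candidates(table, targets) == ["g0", "g2"]

    def test_matches_simulation_truth_exactly(self):
        cm, truth = simulate.gen_two_condition_counts(
            300, 3, frac_up=0.1, frac_down=0.1, lfc=2.0, seed=17
        )
        # treat the planted truth as a perfect DEG table
        table = pd.DataFrame(
            {"is_deg": truth["is_deg"], "direction": truth["direction"]},
            index=truth.index,
        )
        up = sorted(truth.index[truth["direction"] == "up"])
        annotated = up[::2] + sorted(truth.index[truth["direction"] == "down"])[:3]
        targets = pd.DataFrame({"gene_id": annotated, "drug_id": "d1"})
        assert screen.select_candidates(table, targets) == sorted(up[::2])


class TestCorrelatePair:
    def test_exact_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        n, r, p = screen.correlate_pair(x, -x)
        assert (n, r, p) == (4, -1.0, 0.0)

    def test_hand_computed_r(self):
        # r = -10.5 / sqrt(5 * 22.75) = -0.9845
        n, r, p = screen.correlate_pair([1, 2, 3, 4], [10, 8, 5, 4])
        assert r == pytest.approx(-0.9845, abs=5e-5)
        assert n == 4

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(size=20)
        _, r1, p1 = screen.correlate_pair(x, y)
        _, r2, p2 = screen.correlate_pair(2.0 * x, y + 100.0)
        assert r2 == pytest.approx(r1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_missing_entries_dropped_pairwise(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
        n, r, _ = screen.correlate_pair(x, y)
        assert n == 3
        assert r == pytest.approx(1.0)

    def test_degenerate_inputs_flagged_undefined(self):
        n, r, p = screen.correlate_pair([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(r) and np.isnan(p)
        n, r, p = screen.correlate_pair([1.0, 2.0], [3.0, 4.0])
        assert n == 2 and np.isnan(r)

    def test_p_value_matches_scipy_pearsonr(self):
        from scipy import stats

        rng = np.random.default_rng(9)
        x, y = rng.normal(size=30), rng.normal(size=30)
        _, r, p = screen.correlate_pair(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_spearman_option_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(10)
        x, y = rng.normal(size=25), rng.normal(size=25)
        _, r, _ = screen.correlate_pair(x, y, method="spearman")
        assert r == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)


def _pair_with_exact_r(target_r, n=144, seed=0):
    """Vectors whose sample Pearson r equals target_r exactly."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    xs = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= xs * (z @ xs) / n
    zs = z / np.sqrt((z**2).mean())
    y = target_r * xs + np.sqrt(1 - target_r**2) * zs
    return x, y


class TestRunScreen:
    def test_strict_threshold_boundaries(self):
        x_in, y_in = _pair_with_exact_r(-0.31)
        x_on, y_on = _pair_with_exact_r(-0.30, seed=1)
        expr = pd.DataFrame([x_in, x_on], index=["g_in", "g_on"],
                            columns=[f"c{i}" for i in range(144)])
        auc = pd.DataFrame([y_in, y_on], index=["d_in", "d_on"],
                           columns=expr.columns)
        panel = screen.intersect_panel(expr, auc)
        pairs = screen.run_screen(["g_in", "g_on"], panel).set_index(
            ["gene_id", "drug_id"]
        )
        # r = -0.31 with n=144 gives p ~ 1.5e-4 < 1e-3: a hit
        assert pairs.loc[("g_in", "d_in"), "hit"]
        # r = -0.30 exactly fails the strict r < -0.3 bound
        assert not pairs.loc[("g_on", "d_on"), "hit"]
        assert pairs.loc[("g_on", "d_on"), "r"] == pytest.approx(-0.30, abs=1e-12)

    def test_full_table_retained_with_hit_flags(self, strong_panel):
        panel, _, genes, drugs = strong_panel
        pairs = screen.run_screen(genes, panel)
        assert len(pairs) == len(genes) * len(drugs)
        assert pairs["hit"].sum() > 0

    def test_missing_candidate_skipped_with_warning(self, strong_panel, caplog):
        panel, _, genes, _ = strong_panel
        with caplog.at_level("WARNING"):
            pairs = screen.run_screen(["absent_gene", genes[0]], panel)
        assert "absent_gene" in caplog.text
        assert set(pairs["gene_id"]) == {genes[0]}

    def test_rerun_is_deterministic(self, strong_panel):
        panel, _, genes, _ = strong_panel
        pd.testing.assert_frame_equal(
            screen.run_screen(genes, panel), screen.run_screen(genes, panel)
        )

    def test_pairwise_locality_under_unrelated_missingness(self, strong_panel):
        panel, _, genes, drugs = strong_panel
        base = screen.run_screen(genes, panel)
        auc2 = panel.auc.copy()
        auc2.loc[drugs[-1], auc2.columns[:10]] = np.nan
        panel2 = screen.intersect_panel(panel.expr, auc2)
        mod = screen.run_screen(genes, panel2)
        unrelated = base["drug_id"] != drugs[-1]
        pd.testing.assert_frame_equal(
            base[unrelated].reset_index(drop=True),
            mod[unrelated].reset_index(drop=True),
        )
        assert (mod.loc[mod["drug_id"] == drugs[-1], "n_used"] == 134).all()


class TestRankDrugs:
    def _pairs(self, hits_per_drug):
        rows = []
        for drug, n_hits in hits_per_drug.items():
            for i in range(6):
                rows.append((f"g{i}", drug, 144, -0.5, 1e-5, i < n_hits))
        return pd.DataFrame(
            rows, columns=["gene_id", "drug_id", "n_used", "r", "p", "hit"]
        )

    def test_kept_requires_at_least_four_hit_genes(self):
        ranking, _ = screen.rank_drugs(self._pairs({"d3": 3, "d4": 4}))
        kept = ranking.set_index("drug_id")["kept"]
        assert not kept["d3"]
        assert kept["d4"]

    def test_no_hits_keeps_nothing(self):
        ranking, _ = screen.rank_drugs(self._pairs({"d1": 0, "d2": 0}))
        assert not ranking["kept"].any()
        assert (ranking["n_hits"] == 0).all()

    def test_sorted_by_count_then_id(self):
        ranking, _ = screen.rank_drugs(self._pairs({"db": 5, "da": 5, "dc": 6}))
        assert list(ranking["drug_id"]) == ["dc", "da", "db"]

    def test_hit_matrix_consistent_with_pairs(self, strong_panel):
        panel, _, genes, _ = strong_panel
        pairs = screen.run_screen(genes, panel)
        ranking, matrix = screen.rank_drugs(pairs)
        for _, row in ranking.iterrows():
            assert matrix[row["drug_id"]].sum() == row["n_hits"]

    def test_planted_multi_gene_drug_ranked_first_and_kept(self):
        """The drug coupled to six genes tops the ranking with >=4 hits
        in >=95/100 seeds at coupling -5, noise 1, 144 lines."""
        genes = [f"G{i:05d}" for i in range(10)]
        drugs = [f"D{i:03d}" for i in range(5)]
        wins = 0
        for seed in range(100):
            planted = simulate.PanelSimTruth(
                pairs=[(genes[i], drugs[0], -5.0) for i in range(6)], noise_sd=1.0
            )
            panel, _ = simulate.gen_panel(144, genes, drugs, planted, seed=seed)
            pairs = screen.run_screen(genes, panel)
            ranking, _ = screen.rank_drugs(pairs)
            top = ranking.iloc[0]
            wins += top["drug_id"] == drugs[0] and top["kept"]
        assert wins >= 95

    def test_hit_sensitivity_and_specificity_on_planted_panels(self):
        """Per-pair hit calling: sensitivity > 0.9, specificity > 0.99 under
        the strong-signal settings (one coupled gene per planted drug)."""
        genes = [f"G{i:05d}" for i in range(8)]
        drugs = [f"D{i:03d}" for i in range(8)]
        tp = fn = fp = tn = 0
        for seed in range(20):
            planted = simulate.PanelSimTruth(
                pairs=[(genes[i], drugs[i], -5.0) for i in range(4)], noise_sd=1.0
            )
            panel, truth = simulate.gen_panel(144, genes, drugs, planted, seed=seed)
            pairs = screen.run_screen(genes, panel)
            truth_pairs = {(g, d) for g, d, _ in truth.pairs}
            for _, row in pairs.iterrows():
                is_true = (row["gene_id"], row["drug_id"]) in truth_pairs
                if is_true and row["hit"]:
                    tp += 1
                elif is_true:
                    fn += 1
                elif row["hit"]:
                    fp += 1
                else:
                    tn += 1
        assert tp / (tp + fn) > 0.9
        assert tn / (tn + fp) > 0.99
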