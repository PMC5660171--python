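"""Marker-rule classification, EMT trichotomy, side tables, clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nx1seq.annotate import (
    EA,
    EA_EMT,
    EA_INT_EMT,
    EMT_NONE,
    E_OVER_M,
    M_OVER_E,
    UNASSIGNED_CLASS,
    MarkerRule,
    MarkerRuleSet,
    annotations_to_frame,
    chemokine_positive_counts,
    classify_cells,
    classify_emt,
    cluster_cells,
    fold_ratio,
    is_positive,
    percent,
    side_table,
    side_table_from_counts,
)
from nx1seq.datasets import SIDE_TOTAL_E, SIDE_TOTAL_M, load_side_distribution

from conftest import make_matrix

IMMUNE_RULES = MarkerRuleSet(
    class_rules={
        "T": MarkerRule(("CD3D",)),
        "macrophage": MarkerRule(("CD68",)),
        "cancer": MarkerRule(("EPCAM", "CDH1")),
    }
)


class TestIsPositive:
    def test_below_threshold_negative(self):
        assert not is_positive(0.0, 1.0)

    def test_boundary_inclusive(self):
        assert is_positive(1.0, 1.0)

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            is_positive(-0.1, 1.0)


class TestClassifyCells:
    def test_t_cell_by_cd3d(self):
        m = make_matrix([[5, 0, 0, 0]], genes=["CD3D", "CD68", "EPCAM", "CDH1"])
        (ann,) = classify_cells(m, IMMUNE_RULES)
        assert ann.cell_class == "T"

    def test_conflict_resolved_by_priority_and_logged(self, caplog):
        m = make_matrix([[5, 5, 0, 0]], genes=["CD3D", "CD68", "EPCAM", "CDH1"])
        import logging

        with caplog.at_level(logging.INFO, logger="nx1seq.annotate"):
            (ann,) = classify_cells(m, IMMUNE_RULES)
        assert ann.cell_class == "T"
        assert any("matches classes" in r.message for r in caplog.records)

    def test_unmatched_cell_unassigned(self):
        m = make_matrix([[0, 0, 0, 0]], genes=["CD3D", "CD68", "EPCAM", "CDH1"])
        (ann,) = classify_cells(m, IMMUNE_RULES)
        assert ann.cell_class == UNASSIGNED_CLASS

    def test_invariant_to_gene_order(self):
        genes = ["CD3D", "CD68", "EPCAM", "CDH1"]
        rows = np.array([[3, 0, 0, 2], [0, 4, 0, 0], [0, 0, 2, 2]])
        m1 = make_matrix(rows, genes=genes)
        perm = [2, 0, 3, 1]
        m2 = make_matrix(rows[:, perm], genes=[genes[i] for i in perm])
        c1 = [a.cell_class for a in classify_cells(m1, IMMUNE_RULES)]
        c2 = [a.cell_class for a in classify_cells(m2, IMMUNE_RULES)]
        assert c1 == c2

    def test_missing_rule_gene_warns_and_counts_negative(self, caplog):
        m = make_matrix([[5]], genes=["CD3D"])
        import logging

        with caplog.at_level(logging.WARNING, logger="nx1seq.annotate"):
            (ann,) = classify_cells(m, IMMUNE_RULES)
        assert ann.cell_class == "T"
        assert any("absent" in r.message for r in caplog.records)

    def test_recovers_simulated_classes(self):
        rng = np.random.default_rng(5)
        genes = ["CD3D", "CD68", "EPCAM", "CDH1"]
        rows, want = [], []
        for _ in range(300):
            cls = rng.choice(["T", "macrophage", "cancer"])
            row = [0, 0, 0, 0]
            if cls == "T":
                row[0] = 1 + rng.poisson(4)
            elif cls == "macrophage":
                row[1] = 1 + rng.poisson(4)
            else:
                row[2] = 1 + rng.poisson(4)
            rows.append(row)
            want.append(cls)
        m = make_matrix(rows, genes=genes)
        got = [a.cell_class for a in classify_cells(m, IMMUNE_RULES)]
        assert got == want  # no dropout simulated, so diagonal is perfect


class TestClassifyEmt:
    GENES = ["EPCAM", "CDH1", "ACTA2", "VIM", "FN1", "ZEB1", "THY1", "CD44"]

    def _classify(self, rows):
        m = make_matrix(rows, genes=self.GENES)
        cancer_rules = MarkerRuleSet(class_rules={"cancer": MarkerRule(tuple(self.GENES))})
        ann = [a for a in classify_cells(m, cancer_rules)]
        return classify_emt(ann, m, cancer_rules)

    def test_epithelial_only_is_ea(self):
        (ann,) = self._classify([[5, 0, 0, 0, 0, 0, 0, 0]])
        assert ann.emt_class == EA

    def test_both_kinds_is_intermediate(self):
        (ann,) = self._classify([[5, 0, 0, 3, 0, 0, 0, 0]])
        assert ann.emt_class == EA_INT_EMT

    def test_mesenchymal_only_is_emt(self):
        (ann,) = self._classify([[0, 0, 0, 3, 0, 0, 0, 0]])
        assert ann.emt_class == EA_EMT

    def test_non_cancer_cells_keep_none(self):
        m = make_matrix([[5, 0, 0, 0]], genes=["CD3D", "CD68", "EPCAM", "CDH1"])
        ann = classify_emt(classify_cells(m, IMMUNE_RULES), m, IMMUNE_RULES)
        assert ann[0].cell_class == "T"
        assert ann[0].emt_class is None

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.lists(st.integers(0, 3), min_size=8, max_size=8),
                    min_size=1, max_size=25))
    def test_partition_is_exhaustive_and_disjoint(self, rows):
        anns = self._classify(rows)
        # every cancer cell gets exactly one of the four labels; others None
        for a, row in zip(anns, rows):
            if a.cell_class != "cancer":
                assert a.emt_class is None
                continue
            assert a.emt_class in {EA, EA_INT_EMT, EA_EMT, EMT_NONE}
            e = any(v >= 1 for v in row[:2])
            m = any(v >= 1 for v in row[2:])
            want = EA_INT_EMT if (e and m) else EA if e else EA_EMT if m else EMT_NONE
            assert a.emt_class == want


class TestSideTableArithmetic:
    def test_template_row_fold(self):
        assert fold_ratio(147, 305, 55, 180, E_OVER_M) == 1.6

    def test_large_fold(self):
        assert fold_ratio(61, 305, 3, 180, E_OVER_M) == 12.0

    def test_reverse_direction(self):
        assert fold_ratio(5, 305, 18, 180, M_OVER_E) == 6.1

    def test_equal_proportions_fold_one(self):
        assert fold_ratio(30, 100, 30, 100, E_OVER_M) == 1.0

    def test_zero_denominator_is_nan(self):
        assert math.isnan(fold_ratio(2, 305, 0, 180, E_OVER_M))

    def test_percent_rounding(self):
        assert percent(205, 305) == 67
        assert percent(1, 305) == 0
        assert percent(1, 180) == 1

    def test_printed_table_reproduced(self):
        """Published counts reproduce every printed % and defined fold."""
        table = load_side_distribution()
        result = side_table_from_counts(
            table.rename(columns={"fold_printed": "fold_expected"}),
            SIDE_TOTAL_E, SIDE_TOTAL_M,
        )
        assert (result["pct_E"] == table["pct_E"]).all()
        assert (result["pct_M"] == table["pct_M"]).all()
        defined = table["fold_defined"]
        assert (result.loc[defined, "fold"] == table.loc[defined, "fold_printed"]).all()
        assert result.loc[~defined, "fold"].isna().all()

    def test_side_table_counts_positive_cells(self):
        e = make_matrix([[2, 0], [1, 0], [0, 5]], genes=["FADS2", "SOX2"])
        m = make_matrix([[0, 0], [3, 0]], genes=["FADS2", "SOX2"])
        out = side_table(e, m, ["FADS2", "SOX2"], threshold=1.0, direction=E_OVER_M)
        assert out.loc["FADS2", ["count_E", "count_M"]].tolist() == [2, 1]
        assert out.loc["FADS2", "fold"] == pytest.approx(
            round((2 / 3) / (1 / 2), 1)
        )
        assert out.loc["SOX2", "count_M"] == 0

    def test_empty_side_rejected(self):
        e = make_matrix([[1]], genes=["g"])
        empty = make_matrix(np.empty((0, 1), dtype=int), barcodes=[], genes=["g"])
        with pytest.raises(ValueError):
            side_table(e, empty, ["g"])


class TestChemokineCounts:
    def _setup(self):
        genes = ["CD3D", "CD68", "CCL4", "CCL20"]
        rows = [
            [5, 0, 2, 0],  # T cell, CCL4+
            [5, 0, 0, 0],  # T cell, negative
            [0, 5, 2, 2],  # macrophage, CCL4+ CCL20+
        ]
        m = make_matrix(rows, genes=genes)
        ann = classify_cells(m, IMMUNE_RULES, side="E")
        return m, ann

    def test_counts_stratified_by_class(self):
        m, ann = self._setup()
        out = chemokine_positive_counts(m, ["CCL4", "CCL20"], ann)
        t_ccl4 = out.query("gene == 'CCL4' and cell_class == 'T'")["positive_cells"].sum()
        mac_ccl20 = out.query("gene == 'CCL20' and cell_class == 'macrophage'")["positive_cells"].sum()
        assert t_ccl4 == 1 and mac_ccl20 == 1

    def test_class_sums_match_unstratified_totals(self):
        m, ann = self._setup()
        out = chemokine_positive_counts(m, ["CCL4", "CCL20"], ann)
        for g in ("CCL4", "CCL20"):
            total = out.query("gene == @g")["positive_cells"].sum()
            assert total == int((m.data[g] >= 1).sum())

    def test_all_zero_gene_counts_zero_everywhere(self):
        m, ann = self._setup()
        m2 = make_matrix(np.c_[m.data.to_numpy(), np.zeros(3, int)],
                         genes=m.genes + ["CCL3"])
        out = chemokine_positive_counts(m2, ["CCL3"], ann)
        assert (out["positive_cells"] == 0).all()

    def test_recovers_simulated_positivity(self):
        rng = np.random.default_rng(8)
        n = 500
        rows = np.zeros((n, 2), dtype=int)
        rows[:, 0] = 5  # every cell CD3D+ -> T
        positive = rng.random(n) < 0.30
        rows[positive, 1] = 1 + rng.poisson(3, positive.sum())
        m = make_matrix(rows, genes=["CD3D", "CCL4"])
        ann = classify_cells(m, MarkerRuleSet(class_rules={"T": MarkerRule(("CD3D",))}),
                             side="M")
        out = chemokine_positive_counts(m, ["CCL4"], ann)
        frac = out["positive_cells"].sum() / n
        se = math.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.30) <= 3 * se


class TestClusterCells:
    def test_identical_cells_have_zero_distance(self):
        m = make_matrix([[3, 1, 0], [3, 1, 0]])
        linkage, _, _ = cluster_cells(m)
        assert linkage[0, 2] == 0.0

    def test_two_separated_classes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(9)
        a = rng.poisson(50, size=(15, 10))
        b = np.hstack([np.zeros((15, 5), int), rng.poisson(50, size=(15, 5))])
        b[:, :5] = 0
        a[:, 5:] = 0
        m = make_matrix(np.vstack([a, b]))
        _, labels, _ = cluster_cells(m, n_clusters=2)
        truth = [0] * 15 + [1] * 15
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_order_permutation_gives_same_partition(self):
        rng = np.random.default_rng(10)
        rows = rng.poisson(5, size=(12, 8))
        m1 = make_matrix(rows)
        perm = rng.permutation(12)
        m2 = make_matrix(rows[perm], barcodes=[f"BC{i:03d}" for i in perm])
        _, l1, _ = cluster_cells(m1, n_clusters=3)
        _, l2, _ = cluster_cells(m2, n_clusters=3)
        lab1 = {bc: l for bc, l in zip(m1.barcodes, l1)}
        lab2 = {bc: l for bc, l in zip(m2.barcodes, l2)}
        from sklearn.metrics import adjusted_rand_score

        common = sorted(lab1)
        assert adjusted_rand_score([lab1[b] for b in common],
                                   [lab2[b] for b in common]) == 1.0

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            cluster_cells(make_matrix([[1, 2]]))


class TestRuleSetConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "rules.yaml"
        IMMUNE_RULES.to_yaml(path)
        back = MarkerRuleSet.from_yaml(path)
        assert back == IMMUNE_RULES

    def test_overlapping_emt_partition_rejected(self):
        with pytest.raises(ValueError):
            MarkerRuleSet(class_rules={"c": MarkerRule(("EPCAM",))},
                          epithelial_genes=("EPCAM",), mesenchymal_genes=("EPCAM",))

    def test_empty_rule_set_rejected(self):
        with pytest.raises(ValueError):
            MarkerRuleSet(class_rules={})
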