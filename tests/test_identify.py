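"""Stage naming, confusion matrices, and identification metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import camgrade as cg
from camgrade.identify import ConfusionMatrix, map_clusters_to_stages
from camgrade.synthetic import STAGES
from conftest import STAGE_INDEX


def expand(cm_counts):
    """Turn a counts matrix into (true, predicted) label lists."""
    true, pred = [], []
    for i, row in enumerate(cm_counts):
        for j, c in enumerate(row):
            true += [STAGES[i]] * c
            pred += [STAGES[j]] * c
    return true, pred


PAPER_COUNTS = [[48, 2, 0], [3, 52, 5], [0, 4, 46]]


class TestMoistureContent:
    def test_basic_values(self):
        assert cg.moisture_content(10.0, 10.0) == 0.0
        assert cg.moisture_content(10.0, 4.0) == pytest.approx(60.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cg.moisture_content(4.0, 10.0)
        with pytest.raises(ValueError):
            cg.moisture_content(0.0, 0.0)
        with pytest.raises(ValueError):
            cg.moisture_content(10.0, -1.0)

    def test_generator_round_trip(self):
        records = cg.generate_property_table(5, rng_seed=0)
        for r in records:
            assert cg.moisture_content(r.fresh_seed_weight_g,
                                       r.dry_seed_weight_g) == pytest.approx(
                r.moisture_pct)


class TestBuildConfusion:
    def test_perfect_prediction_is_diagonal(self):
        labels = ["unripe"] * 3 + ["ripe"] * 2 + ["overripe"] * 4
        cm = cg.build_confusion(labels, labels)
        assert np.array_equal(cm.counts, np.diag([3, 2, 4]))

    def test_published_counts_sum_correctly(self):
        cm = cg.build_confusion(*expand(PAPER_COUNTS))
        assert cm.n == 160
        assert cm.n_correct == 146

    def test_row_sums_preserved_for_random_predictions(self):
        rng = np.random.default_rng(0)
        true = [STAGES[i] for i in rng.integers(0, 3, 100)]
        pred = [STAGES[i] for i in rng.integers(0, 3, 100)]
        cm = cg.build_confusion(true, pred)
        for i, stage in enumerate(STAGES):
            assert cm.counts[i].sum() == true.count(stage)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            cg.build_confusion(["unripe"], ["rotten"])
        with pytest.raises(ValueError):
            cg.build_confusion(["unripe", "ripe"], ["unripe"])


class TestComputeMetrics:
    def test_diagonal_matrix_scores_100_everywhere(self):
        m = cg.compute_metrics(ConfusionMatrix(np.diag([5, 6, 7])))
        assert m.precision == pytest.approx([100, 100, 100])
        assert m.recall == pytest.approx([100, 100, 100])
        assert m.f1 == pytest.approx([100, 100, 100])
        assert m.overall_accuracy == 100

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.integers(0, 30), min_size=9, max_size=9))
    def test_micro_recall_equals_overall_accuracy(self, flat):
        counts = np.array(flat).reshape(3, 3)
        if (counts.sum(axis=1) == 0).any():
            return
        cm = ConfusionMatrix(counts)
        m = cg.compute_metrics(cm)
        micro = 100.0 * sum(cm.one_vs_rest(i)["TP"] for i in range(3)) / cm.n
        assert m.overall_accuracy == pytest.approx(micro)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(1, 30, (3, 3))
            m = cg.compute_metrics(ConfusionMatrix(counts))
            for i in range(3):
                assert min(m.precision[i], m.recall[i]) - 1e-9 <= m.f1[i]
                assert m.f1[i] <= max(m.precision[i], m.recall[i]) + 1e-9

    def test_invariant_to_consistent_stage_permutation(self):
        cm = ConfusionMatrix(np.array(PAPER_COUNTS))
        m = cg.compute_metrics(cm)
        perm = [2, 0, 1]
        permuted = ConfusionMatrix(
            np.array(PAPER_COUNTS)[np.ix_(perm, perm)],
            stage_names=tuple(STAGES[i] for i in perm))
        mp = cg.compute_metrics(permuted)
        for new_pos, old_pos in enumerate(perm):
            assert mp.precision[new_pos] == pytest.approx(m.precision[old_pos])
        assert mp.overall_accuracy == pytest.approx(m.overall_accuracy)

    def test_never_predicted_stage_flagged_undefined(self):
        counts = np.array([[5, 0, 0], [4, 0, 1], [0, 0, 6]])
        m = cg.compute_metrics(ConfusionMatrix(counts))
        assert m.undefined == ("ripe",)
        assert np.isnan(m.precision[1])
        assert m.rounded()["ripe"]["precision"] is None

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cg.compute_metrics(ConfusionMatrix(np.zeros((3, 3), dtype=int)))


class TestMapClustersToStages:
    def test_pure_anchors_give_bijective_naming(self):
        assignments = [0, 0, 1, 1, 2, 2]
        anchors = ["ripe", "ripe", "overripe", "overripe", "unripe", "unripe"]
        naming = map_clusters_to_stages(assignments, anchor_stages=anchors)
        assert naming.mapping == {0: "ripe", 1: "overripe", 2: "unripe"}
        assert naming.apply(assignments) == anchors

    def test_invariant_to_cluster_id_permutation(self):
        assignments = np.array([0, 0, 1, 1, 2, 2])
        anchors = ["ripe", "ripe", "overripe", "overripe", "unripe", "unripe"]
        a = map_clusters_to_stages(assignments, anchor_stages=anchors)
        swap = {0: 2, 1: 0, 2: 1}
        remapped = np.array([swap[i] for i in assignments])
        b = map_clusters_to_stages(remapped, anchor_stages=anchors)
        assert a.apply(assignments) == b.apply(remapped)

    def test_crack_proxy_orders_clusters_monotonically(self):
        assignments = np.array([2, 2, 0, 0, 1, 1])
        proxy = np.array([0.0, 0.01, 0.3, 0.28, 0.1, 0.12])
        naming = map_clusters_to_stages(assignments, proxy_values=proxy)
        assert naming.mapping == {2: "unripe", 1: "ripe", 0: "overripe"}
        assert not naming.flagged

    def test_oil_proxy_uses_low_high_mid_trajectory_and_flags(self):
        assignments = np.array([0, 0, 1, 1, 2, 2])
        oil = np.array([39.0, 39.2, 46.0, 46.1, 44.4, 44.5])
        naming = map_clusters_to_stages(assignments, proxy_values=oil,
                                        proxy_kind="oil")
        assert naming.mapping == {0: "unripe", 1: "ripe", 2: "overripe"}
        assert naming.flagged

    def test_evidence_required(self):
        with pytest.raises(ValueError):
            map_clusters_to_stages([0, 1, 2])
        with pytest.raises(ValueError):
            map_clusters_to_stages([0, 1], proxy_values=[1.0, 2.0])

    def test_proxy_naming_matches_truth_matching_on_recovery_run(
            self, recovery_run):
        images, truth, results = recovery_run
        anchors = [img.truth_stage for img in images]
        by_truth = map_clusters_to_stages(results.assignments,
                                          anchor_stages=anchors)
        bbox_area = [0.0 if img.crack_bbox is None else
                     (img.crack_bbox[2] - img.crack_bbox[0])
                     * (img.crack_bbox[3] - img.crack_bbox[1])
                     for img in images]
        by_proxy = map_clusters_to_stages(results.assignments,
                                          proxy_values=bbox_area)
        assert by_truth.mapping == by_proxy.mapping
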