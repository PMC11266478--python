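"""Metrics, split protocols, cross-validation, ablation table, maps."""

import numpy as np
import pytest

from canopyhsi.evaluate import (ABLATION_CASES, ConfusionMatrix, SplitSpec,
                                average_accuracy, classification_map, confusion,
                                cross_validate, kappa, overall_accuracy, split,
                                split_indices)
from canopyhsi.superpca import PatchSet


def make_patchset(labels, s=3, b=2, seed=0):
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = labels.size
    return PatchSet(rng.random((n, s, s, b)).astype(np.float32),
                    np.stack([np.arange(n), np.arange(n)], axis=1),
                    labels.astype(np.int64), s)


class TestConfusion:
    def test_perfect_prediction_diagonal(self):
        cm = confusion([1, 2, 3, 1], [1, 2, 3, 1], 3)
        assert np.trace(cm.counts) == 4
        assert cm.counts.sum() == 4

    def test_enumerated_example(self):
        cm = confusion([1, 1, 2], [1, 2, 2], 2)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_row_sums_equal_true_counts(self, rng):
        y_true = rng.integers(1, 5, 100)
        y_pred = rng.integers(1, 5, 100)
        cm = confusion(y_true, y_pred, 4)
        np.testing.assert_array_equal(cm.counts.sum(axis=1),
                                      np.bincount(y_true, minlength=5)[1:])

    def test_out_of_range_label(self):
        with pytest.raises(ValueError, match="out of range"):
            confusion([1, 5], [1, 1], 4)


class TestMetrics:
    def test_overall_accuracy_hand_values(self):
        assert overall_accuracy(ConfusionMatrix(np.diag([3, 4]))) == 1.0
        assert overall_accuracy(ConfusionMatrix([[45, 5], [10, 40]])) == pytest.approx(0.85)
        uniform = ConfusionMatrix(np.full((4, 4), 2))
        assert overall_accuracy(uniform) == pytest.approx(0.25)

    def test_average_accuracy_hand_values(self):
        assert average_accuracy(ConfusionMatrix(np.diag([3, 4]))) == 1.0
        assert average_accuracy(ConfusionMatrix([[8, 2], [5, 5]])) == pytest.approx(0.65)

    def test_aa_equals_oa_under_symmetry(self):
        cm = ConfusionMatrix([[8, 2], [2, 8]])
        assert average_accuracy(cm) == pytest.approx(overall_accuracy(cm))

    def test_empty_class_errors(self):
        with pytest.raises(ValueError, match="no true samples"):
            average_accuracy(ConfusionMatrix([[3, 0], [0, 0]]))

    def test_kappa_hand_values(self):
        assert kappa(ConfusionMatrix(np.diag([5, 5]))) == pytest.approx(1.0)
        assert kappa(ConfusionMatrix([[45, 5], [10, 40]])) == pytest.approx(0.70)

    def test_kappa_chance_level_near_zero(self, rng):
        values = []
        for _ in range(50):
            y_true = rng.integers(1, 4, 300)
            y_pred = rng.integers(1, 4, 300)  # independent of truth
            values.append(kappa(confusion(y_true, y_pred, 3)))
        assert abs(np.mean(values)) < 0.02

    def test_kappa_equals_expanded_form(self, rng):
        """The (p_o, p_e) form is algebraically the printed expanded ratio:
        (N * sum x_ii - sum row_i col_i) / (N^2 - sum row_i col_i)."""
        for _ in range(20):
            counts = rng.integers(0, 30, (4, 4))
            counts[0, 0] += 1  # nonempty
            cm = ConfusionMatrix(counts)
            total = counts.sum()
            rc = (counts.sum(axis=1) * counts.sum(axis=0)).sum()
            expanded = (total * np.trace(counts) - rc) / (total**2 - rc)
            assert kappa(cm) == pytest.approx(expanded, rel=1e-12)

    def test_degenerate_single_cell_flagged(self):
        assert np.isnan(kappa(ConfusionMatrix([[7]])))

    def test_permutation_invariance(self, rng):
        y_true = rng.integers(1, 5, 200)
        y_pred = rng.integers(1, 5, 200)
        perm = np.array([0, 3, 1, 4, 2])  # permutation of 1..4 at indices 1..4
        cm1 = confusion(y_true, y_pred, 4)
        cm2 = confusion(perm[y_true], perm[y_pred], 4)
        assert overall_accuracy(cm1) == pytest.approx(overall_accuracy(cm2))
        assert average_accuracy(cm1) == pytest.approx(average_accuracy(cm2))
        assert kappa(cm1) == pytest.approx(kappa(cm2))

    def test_kappa_one_iff_diagonal(self, rng):
        counts = rng.integers(1, 10, (3, 3))
        assert kappa(ConfusionMatrix(counts)) < 1.0
        assert kappa(ConfusionMatrix(np.diag([1, 2, 3]))) == pytest.approx(1.0)


class TestSplits:
    def test_70_30_counts(self):
        labels = np.repeat(np.arange(1, 4), 100)
        spec = SplitSpec(0.70, seed=1)
        train, test = split_indices(labels, spec)
        for cls in (1, 2, 3):
            assert abs((labels[train] == cls).sum() - 70) <= 1
        assert train.size + test.size == 300
        assert np.intersect1d(train, test).size == 0

    def test_5_95_counts(self):
        labels = np.repeat(np.arange(1, 3), 1000)
        train, _ = split_indices(labels, SplitSpec(0.05, seed=2))
        assert (labels[train] == 1).sum() == 50
        assert (labels[train] == 2).sum() == 50

    def test_deterministic(self):
        labels = np.repeat([1, 2], 50)
        a = split_indices(labels, SplitSpec(0.7, seed=9))
        b = split_indices(labels, SplitSpec(0.7, seed=9))
        np.testing.assert_array_equal(a[0], b[0])

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            split_indices(np.array([1, 1, 2]), SplitSpec(0.5))

    def test_patchset_split_partitions(self):
        ps = make_patchset(np.repeat([1, 2, 3], 20))
        train, test = split(ps, SplitSpec(0.70, seed=0))
        assert len(train) + len(test) == 60
        combined = sorted(np.concatenate([train.centers[:, 0], test.centers[:, 0]]))
        assert combined == list(range(60))  # disjoint and exhaustive


class TestCrossValidate:
    class MajorityModel:
        def __init__(self, patchset, seed):
            values, counts = np.unique(patchset.labels, return_counts=True)
            self.majority = values[np.argmax(counts)]

        def predict(self, patches):
            return np.full(patches.shape[0], self.majority)

    def test_folds_partition_and_constant_model_oa(self):
        labels = np.repeat([1, 2], [60, 40])
        ps = make_patchset(labels)
        result = cross_validate(ps, 10, self.MajorityModel, seed=0)
        assert len(result["folds"]) == 10
        # constant majority-class prediction scores the majority frequency
        assert result["summary"]["OA"]["mean"] == pytest.approx(0.6, abs=1e-9)

    def test_reproducible(self):
        ps = make_patchset(np.repeat([1, 2, 3], 20))
        a = cross_validate(ps, 5, self.MajorityModel, seed=4)
        b = cross_validate(ps, 5, self.MajorityModel, seed=4)
        assert a["folds"] == b["folds"]

    def test_small_class_rejected(self):
        ps = make_patchset(np.array([1] * 20 + [2] * 3))
        with pytest.raises(ValueError, match="smaller than k"):
            cross_validate(ps, 5, self.MajorityModel)


class TestAblationTable:
    def test_seven_cases_match_design(self):
        flags = {c.name: (c.use_superpca, c.use_cbam, c.use_cnn, c.use_tokenizer_te)
                 for c in ABLATION_CASES}
        assert flags["Case 1"] == (True, False, True, True)
        assert flags["Case 2"] == (False, True, True, True)
        assert flags["Case 3"] == (False, False, True, True)
        assert flags["Case 4"] == (True, False, True, False)
        assert flags["Case 5"] == (True, True, True, False)
        assert flags["Case 6"] == (True, False, False, True)
        assert flags["SHCFTT"] == (True, True, True, True)
        assert len(ABLATION_CASES) == 7


class TestClassificationMap:
    class LookupModel:
        """Stands in for a trained network: predicts from a lookup table."""

        def __init__(self, table, config):
            self.table = table
            self.model = type("M", (), {"config": config})()

        def predict(self, patches):
            keys = patches[:, patches.shape[1] // 2,
                           patches.shape[2] // 2, 0].astype(int)
            return np.array([self.table[k] for k in keys])

    def test_map_matches_labels_and_background_zero(self):
        from canopyhsi.io import LabelMap
        from canopyhsi.nn import ModelConfig
        from canopyhsi.superpca import ReducedCube, extract_patches
        from canopyhsi.evaluate import confusion as build_confusion

        rng = np.random.default_rng(0)
        # integer-valued features survive the float32 patch cast exactly
        values = rng.integers(1, 1000, (6, 6, 2)).astype(float)
        lab = rng.integers(0, 3, (6, 6)).astype(np.int32)
        reduced = ReducedCube(values, 2)
        labels = LabelMap(lab, ["a", "b"])
        table = {int(values[r, c, 0]): lab[r, c] for r in range(6) for c in range(6)}
        model = self.LookupModel(table, ModelConfig(s=3, b=2))
        mapped = classification_map(model, reduced, labels, s=3)
        np.testing.assert_array_equal(mapped[lab > 0], lab[lab > 0])
        assert np.all(mapped[lab == 0] == 0)

        # map-derived confusion equals patchwise confusion
        patches = extract_patches(reduced, labels, 3)
        patch_pred = model.predict(patches.patches)
        cm_patch = build_confusion(patches.labels, patch_pred, 2)
        cm_map = build_confusion(lab[lab > 0], mapped[lab > 0], 2)
        np.testing.assert_array_equal(cm_patch.counts, cm_map.counts)
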