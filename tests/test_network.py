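"""Correlation matrices, binarization sweep, and sign-test backbone."""

import numpy as np
import pandas as pd
import pytest

from metabnet.errors import InsufficientDataError, InvalidParameterError
from metabnet.network import (CorrelationMatrix, DEFAULT_THRESHOLDS, backbone,
                              binarize, read_edge_list, read_matrix_csv,
                              spearman_matrix, threshold_sweep,
                              write_edge_list, write_matrix_csv)
from metabnet.panel import DEFAULT_PANEL, MetabolitePanel
from metabnet.synthetic import default_cohort_config, generate_cohort

from conftest import make_table


def corr_matrix(values, group="g", time_point=1):
    m = values.shape[0]
    panel = MetabolitePanel(tuple(f"m{i}" for i in range(m)))
    return CorrelationMatrix(values=values, panel=panel, group=group,
                             time_point=time_point)


def random_corr(rng, m=11):
    v = rng.uniform(0, 1, size=(m, m))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return corr_matrix(v)


class TestSpearmanMatrix:
    def test_toy_rank_formula_oracle(self):
        # x = (1..5), y = (2,1,4,3,5): sum d^2 = 4 so
        # rho = 1 - 6*4/(5*24) = 0.8
        table = make_table({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        mat = spearman_matrix(table, "g", 1)
        assert mat.values[0, 1] == pytest.approx(0.8)

    def test_identical_and_reversed_rankings_give_one(self):
        table = make_table({"x": [1, 2, 3, 4, 5], "up": [10, 20, 30, 40, 50],
                            "down": [5, 4, 3, 2, 1]})
        mat = spearman_matrix(table, "g", 1)
        i, j, k = (mat.panel.index(n) for n in ("x", "up", "down"))
        assert mat.values[i, j] == pytest.approx(1.0)
        assert mat.values[i, k] == pytest.approx(1.0)  # |rho| drops the sign

    def test_default_panel_gives_11x11(self):
        table = generate_cohort(default_cohort_config(seed=2))
        mat = spearman_matrix(table, "control", 1, DEFAULT_PANEL)
        assert mat.values.shape == (11, 11)
        assert np.all(np.diag(mat.values) == 0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        data = {f"m{i}": rng.lognormal(size=9).tolist() for i in range(4)}
        base = spearman_matrix(make_table(data), "g", 1)
        warped = {k: (np.exp(v) if i % 2 else np.asarray(v) ** 3)
                  for i, (k, v) in enumerate(data.items())}
        trans = spearman_matrix(make_table(warped), "g", 1)
        np.testing.assert_allclose(base.values, trans.values, atol=1e-12)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(1)
        data = {f"m{i}": rng.normal(size=8).tolist() for i in range(3)}
        table = make_table(data)
        panel = MetabolitePanel(("m0", "m1", "m2"))
        shuffled = table.sample(frac=1.0, random_state=4).reset_index(drop=True)
        np.testing.assert_allclose(
            spearman_matrix(table, "g", 1, panel).values,
            spearman_matrix(shuffled, "g", 1, panel).values, atol=1e-12)

    def test_insufficient_subjects(self):
        table = make_table({"x": [1, 2], "y": [2, 1]})
        with pytest.raises(InsufficientDataError):
            spearman_matrix(table, "g", 1)

    def test_zero_variance_metabolite_warns_and_zeroes(self):
        table = make_table({"x": [1, 2, 3, 4], "const": [5, 5, 5, 5]})
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            mat = spearman_matrix(table, "g", 1)
        assert mat.values[0, 1] == 0.0


class TestBinarize:
    def test_strictly_above_threshold(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.45
        v[1, 2] = v[2, 1] = 0.41  # exactly at threshold: no edge
        net = binarize(corr_matrix(v), 0.41)
        assert net.adjacency[0, 1]
        assert not net.adjacency[1, 2]

    def test_all_below_gives_edgeless(self):
        net = binarize(corr_matrix(np.zeros((4, 4))), 0.41)
        assert net.n_edges == 0

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(InvalidParameterError):
            binarize(corr_matrix(np.zeros((3, 3))), bad)


class TestThresholdSweep:
    def test_default_sweep_has_9_networks(self):
        nets = threshold_sweep(random_corr(np.random.default_rng(3)))
        assert len(nets) == 9
        assert [n.threshold for n in nets] == pytest.approx(
            [0.41, 0.42, 0.43, 0.44, 0.45, 0.46, 0.47, 0.48, 0.49])

    def test_nested_edges_match_elementwise_oracle(self):
        rng = np.random.default_rng(5)
        mat = random_corr(rng)
        nets = threshold_sweep(mat, DEFAULT_THRESHOLDS)
        for t, net in zip(DEFAULT_THRESHOLDS, nets):
            np.testing.assert_array_equal(net.adjacency, mat.values > t)
        for lo, hi in zip(nets, nets[1:]):
            assert np.all(hi.adjacency <= lo.adjacency)  # edge sets nested

    def test_empty_threshold_list(self):
        with pytest.raises(InvalidParameterError):
            threshold_sweep(random_corr(np.random.default_rng(0)), [])

    def test_non_increasing_thresholds(self):
        with pytest.raises(InvalidParameterError):
            threshold_sweep(random_corr(np.random.default_rng(0)), [0.45, 0.41])


class TestBackbone:
    def _matrices(self, consistent_value=0.6, n_t=8, weak_at=()):
        """One pair (0,1) present at all time points except ``weak_at``."""
        mats = []
        for tp in range(1, n_t + 1):
            v = np.zeros((3, 3))
            if tp not in weak_at:
                v[0, 1] = v[1, 0] = consistent_value
            mats.append(corr_matrix(v, time_point=tp))
        return mats

    def test_eight_of_eight_eligible(self):
        # p = 0.5^8 = 0.00390625 < 0.025
        bb = backbone(self._matrices())
        assert bb.sign_test_p[0, 1] == pytest.approx(0.00390625)
        assert bb.eligible[0, 1]
        assert bb.matrix.values[0, 1] == pytest.approx(0.6)

    def test_seven_of_eight_not_eligible(self):
        # p = 9/256 ~ 0.03516 > 0.025
        bb = backbone(self._matrices(weak_at={3}))
        assert bb.sign_test_p[0, 1] == pytest.approx(9 / 256)
        assert not bb.eligible[0, 1]
        assert bb.matrix.values[0, 1] == 0.0

    def test_default_alpha(self):
        assert backbone(self._matrices()).alpha == 0.025

    def test_min_aggregation(self):
        mats = self._matrices()
        mats[4].values[0, 1] = mats[4].values[1, 0] = 0.45
        bb = backbone(mats, aggregate="min")
        assert bb.matrix.values[0, 1] == pytest.approx(0.45)
        bb_med = backbone(mats, aggregate="median")
        assert bb_med.matrix.values[0, 1] == pytest.approx(0.6)

    def test_backbone_edges_subset_of_per_time_intersection(self):
        rng = np.random.default_rng(8)
        mats = []
        for tp in range(1, 9):
            v = rng.uniform(0, 1, size=(6, 6))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            mats.append(corr_matrix(v, time_point=tp))
        bb = backbone(mats)
        for t in (0.41, 0.45, 0.49):
            bb_adj = binarize(bb.matrix, t).adjacency
            inter = np.logical_and.reduce([binarize(m, t).adjacency
                                           for m in mats])
            assert np.all(bb_adj <= inter)

    def test_strict_mode_counts_above_threshold(self):
        # |rho| = 0.3 everywhere is a "presence" in raw mode but not in
        # strict mode at 0.41
        mats = self._matrices(consistent_value=0.3)
        assert backbone(mats, count_mode="raw").eligible[0, 1]
        assert not backbone(mats, count_mode="strict",
                            count_threshold=0.41).eligible[0, 1]

    def test_mismatched_panels_rejected(self):
        a = corr_matrix(np.zeros((3, 3)), time_point=1)
        v = np.zeros((4, 4))
        b = CorrelationMatrix(values=v,
                              panel=MetabolitePanel(("a", "b", "c", "d")),
                              group="g", time_point=2)
        with pytest.raises(InvalidParameterError):
            backbone([a, b])

    def test_fewer_than_two_time_points(self):
        with pytest.raises(InvalidParameterError):
            backbone(self._matrices()[:1])


class TestSerialization:
    def test_matrix_csv_round_trip(self, tmp_path):
        mat = random_corr(np.random.default_rng(9))
        path = tmp_path / "m.csv"
        write_matrix_csv(mat, path)
        back = read_matrix_csv(path)
        np.testing.assert_allclose(back.values, mat.values, atol=1e-12)
        assert back.panel.names == mat.panel.names

    def test_edge_list_round_trip_keeps_isolated_nodes(self, tmp_path):
        mat = random_corr(np.random.default_rng(10), m=5)
        net = binarize(mat, 0.8)
        path = tmp_path / "e.tsv"
        write_edge_list(net, path, weights=mat)
        back = read_edge_list(path)
        assert back.panel.names == net.panel.names
        np.testing.assert_array_equal(back.adjacency, net.adjacency)
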