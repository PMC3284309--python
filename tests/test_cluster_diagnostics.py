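"""Boxplot summaries, per-cluster statistics, and state classification."""

import numpy as np
import pytest

from conftest import rand_index
from polyclust.analytic_models import (AnalyticModelParams,
                                       linear_dissimilarity,
                                       sinusoid_state_centers)
from polyclust.cluster_diagnostics import (BoxplotSummary, InsufficientDataError,
                                           META_STABLE, TRANSITION,
                                           INTERMEDIATE, boxplot_summary,
                                           classify_states, compute_diagnostics,
                                           representative_structure)
from polyclust.containers import InvalidInputError, InvalidParameterError
from polyclust.spectral_clustering import (ClusterResult, ScalingVector,
                                           spectral_cluster)


class TestBoxplotSummary:
    def test_hand_computed_nine_values(self):
        b = boxplot_summary(range(1, 10))
        assert (b.q1, b.median, b.q3) == (3, 5, 7)
        assert b.notch_halfwidth == pytest.approx(1.58 * 4 / 3)

    def test_constant_sample(self):
        b = boxplot_summary([2.5] * 8)
        assert b.q1 == b.median == b.q3 == 2.5
        assert b.notch_halfwidth == 0
        assert b.outliers.size == 0
        assert b.whisker_low == b.whisker_high == 2.5

    def test_extreme_value_is_outlier(self):
        b = boxplot_summary([0.0] * 10 + [100.0])
        assert list(b.outliers) == [100.0]
        assert b.whisker_high == 0.0

    def test_whiskers_truncate_to_data_extremes(self):
        values = [1, 2, 3, 4, 5]
        b = boxplot_summary(values)
        assert b.whisker_low == 1
        assert b.whisker_high == 5
        assert b.outliers.size == 0

    def test_against_independent_quantile_oracle(self):
        # sorted-array linear interpolation, written out by hand
        def quantile_oracle(sorted_vals, p):
            pos = p * (len(sorted_vals) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(sorted_vals) - 1)
            frac = pos - lo
            return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac

        rng = np.random.default_rng(0)
        for _ in range(1000):
            vals = rng.normal(size=rng.integers(2, 40))
            b = boxplot_summary(vals)
            s = np.sort(vals)
            assert b.q1 == pytest.approx(quantile_oracle(s, 0.25), abs=1e-12)
            assert b.median == pytest.approx(quantile_oracle(s, 0.5), abs=1e-12)
            assert b.q3 == pytest.approx(quantile_oracle(s, 0.75), abs=1e-12)

    def test_tukey_style_differs_for_skewed_data(self):
        # median close to q1: the median-to-quartile rule gives a much
        # shorter upper reach than the conventional 1.5*IQR rule
        vals = [0.0, 0.0, 0.0, 1.0, 2.0, 3.0, 5.5]
        default = boxplot_summary(vals)
        tukey = boxplot_summary(vals, style="tukey")
        assert default.q1 == tukey.q1  # quartiles unaffected
        assert len(default.outliers) == 1  # 5.5 beyond q3 + 1.5*(q3 - med)
        assert len(tukey.outliers) == 0

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            boxplot_summary([1.0])


def make_result(labels, sigma=None):
    labels = np.asarray(labels)
    k = labels.max()
    return ClusterResult(
        labels=labels, k=int(k), objective=0.0,
        centroids=np.zeros((k, 1)),
        sigma=None if sigma is None else ScalingVector(np.asarray(sigma, float), 1))


class TestComputeDiagnostics:
    def test_linear_model_edge_clusters_show_sigma_outliers(self, linear_X):
        res = spectral_cluster(linear_X, 5, seed=0)
        diags = compute_diagnostics(linear_X, res)
        assert sum(d.size for d in diags) == 1000
        medians = [d.intra_sigma.median for d in diags]
        # interior medians all close; edge clusters contain high-sigma outliers
        assert max(medians) / min(medians) < 1.2
        assert len(diags[0].intra_sigma.outliers) > 0
        assert len(diags[-1].intra_sigma.outliers) > 0

    def test_singleton_cluster_flagged(self):
        X = np.array([[0, 1, 2, 9], [1, 0, 1, 9], [2, 1, 0, 9], [9, 9, 9, 0]],
                     float)
        res = make_result([1, 1, 1, 2], sigma=[1, 1, 1, 9])
        diags = compute_diagnostics(X, res)
        assert diags[0].intra_rmsd is not None
        assert diags[1].size == 1
        assert diags[1].intra_rmsd is None

    def test_sinusoid_gap_clusters_have_largest_sigma(self, sinusoid_X):
        res = spectral_cluster(sinusoid_X, 10, seed=0)
        diags = compute_diagnostics(sinusoid_X, res)
        medians = np.array([d.intra_sigma.median for d in diags])
        centers = sinusoid_state_centers(sinusoid_X)
        gaps = np.array([(centers[0] + centers[1]) // 2,
                         (centers[1] + centers[2]) // 2])
        gap_clusters = {int(res.labels[g - 1]) for g in gaps}
        # the two interior maxima of median sigma are the gap clusters
        interior = medians[1:-1]
        top_two = set(np.argsort(interior)[-2:] + 2)  # 1-based cluster ids
        assert top_two == gap_clusters

    def test_size_mismatch_raises(self):
        X = np.zeros((4, 4))
        res = make_result([1, 1, 2])
        with pytest.raises(InvalidInputError):
            compute_diagnostics(X, res)


class TestRepresentativeStructure:
    def test_medoid_of_three_collinear(self):
        X = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        res = make_result([1, 1, 1])
        assert representative_structure(X, res, 1) == 2  # middle frame

    def test_singleton_and_membership(self, linear_X):
        res = spectral_cluster(linear_X, 5, seed=0)
        for cid in range(1, 6):
            rep = representative_structure(linear_X, res, cid)
            assert res.labels[rep - 1] == cid

    def test_unknown_cluster(self):
        X = np.zeros((3, 3))
        res = make_result([1, 1, 1])
        with pytest.raises(InvalidParameterError):
            representative_structure(X, res, 7)


def diag_stub(cluster_id, sigma_values):
    b = boxplot_summary(sigma_values)
    from polyclust.cluster_diagnostics import ClusterDiagnostics

    return ClusterDiagnostics(cluster_id=cluster_id, size=len(sigma_values),
                              median_time=float(cluster_id), intra_rmsd=None,
                              intra_sigma=b)


class TestClassifyStates:
    def test_sharp_middle_peak_is_transition(self):
        diags = [diag_stub(1, [1.0, 1.01, 0.99]),
                 diag_stub(2, [5.0, 5.01, 4.99]),
                 diag_stub(3, [1.0, 1.02, 0.98])]
        classify_states(diags)
        assert diags[1].state == TRANSITION
        assert diags[0].state == META_STABLE  # endpoint below its neighbor

    def test_identical_distributions_all_intermediate(self):
        diags = [diag_stub(i, [1.0, 1.0, 1.0]) for i in range(1, 5)]
        classify_states(diags)
        assert all(d.state == INTERMEDIATE for d in diags)

    def test_overlapping_notches_block_classification(self):
        diags = [diag_stub(1, [1.0, 3.0]), diag_stub(2, [1.5, 3.5]),
                 diag_stub(3, [1.1, 3.1])]
        classify_states(diags)  # wide notches overlap everywhere
        assert all(d.state == INTERMEDIATE for d in diags)

    def test_fewer_than_three_clusters_warns(self):
        diags = [diag_stub(1, [1, 2]), diag_stub(2, [3, 4])]
        with pytest.warns(UserWarning):
            classify_states(diags)
        assert all(d.state == INTERMEDIATE for d in diags)

    def test_sinusoid_centers_become_meta_stable_at_k15(self, sinusoid_X):
        res = spectral_cluster(sinusoid_X, 15, seed=0)
        diags = compute_diagnostics(sinusoid_X, res)
        centers = sinusoid_state_centers(sinusoid_X)
        center_clusters = {int(res.labels[c - 1]) for c in centers}
        meta = {d.cluster_id for d in diags if d.state == META_STABLE}
        assert center_clusters == meta

    def test_invariant_under_relabeling(self, sinusoid_X):
        # classification depends only on the temporally ordered statistics
        res = spectral_cluster(sinusoid_X, 10, seed=0)
        diags = compute_diagnostics(sinusoid_X, res)
        states_a = [d.state for d in diags]
        res2 = spectral_cluster(sinusoid_X, 10, seed=99)
        diags2 = compute_diagnostics(sinusoid_X, res2)
        if rand_index(res.labels, res2.labels) == 1.0:
            assert [d.state for d in diags2] == states_a


class TestDynamicModelDiagnostics:
    @pytest.mark.parametrize("k", [10, 15])
    def test_folded_state_cluster_is_structurally_homogeneous(
            self, k, dynamic_runs, helix_rmsd_series):
        from polyclust.structure_metrics import pairwise_rmsd_matrix

        for seed, (_, _, concat) in dynamic_runs.items():
            X = pairwise_rmsd_matrix(concat)
            res = spectral_cluster(X, k, seed=seed)
            folded_frame = int(np.argmin(helix_rmsd_series[seed]))
            folded_cluster = res.labels[folded_frame]
            members = np.flatnonzero(res.labels == folded_cluster)
            sigma = res.sigma.sigma
            assert np.median(sigma[members]) < np.median(sigma)
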