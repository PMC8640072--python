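"""Neighbor graphs, permutation/bootstrap statistics, module scores and scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepazone import (
    SimulationConfig,
    bootstrap_pearson,
    cluster_interaction,
    distance_correlation_screen,
    generate_frame,
    holm_sidak,
    module_score,
    neighbor_graph,
    quantile_scale,
    quantile_scale_proportions,
    spatial_autocorrelation,
)


@pytest.fixture(scope="module")
def lattice_frame():
    return generate_frame(SimulationConfig(frame_extent=(1700.0, 1700.0)))


class TestNeighborGraph:
    def test_interior_spot_has_four_neighbors_at_pitch(self, lattice_frame):
        graph = neighbor_graph(lattice_frame, k=4, max_dist_um=155.0)
        xy = lattice_frame.coords_um()
        center_idx = int(np.argmin(((xy - xy.mean(axis=0)) ** 2).sum(axis=1)))
        sid = lattice_frame.spot_ids.iloc[center_idx]
        nbrs = graph.neighbors[sid]
        assert len(nbrs) == 4
        assert all(d == pytest.approx(150.0, abs=1e-6) for _, d in nbrs)

    def test_threshold_below_pitch_gives_empty_lists(self, lattice_frame):
        graph = neighbor_graph(lattice_frame, max_dist_um=100.0)
        assert all(len(v) == 0 for v in graph.neighbors.values())

    def test_corner_spot_has_at_most_two(self, lattice_frame):
        graph = neighbor_graph(lattice_frame, max_dist_um=155.0)
        xy = lattice_frame.coords_um()
        corner_idx = int(np.argmin(xy.sum(axis=1)))
        sid = lattice_frame.spot_ids.iloc[corner_idx]
        assert len(graph.neighbors[sid]) <= 2

    def test_no_cross_section_neighbors(self, small_dataset):
        graph = neighbor_graph(small_dataset.spots, max_dist_um=155.0)
        sections = small_dataset.spots.spots.set_index("spot_id")["section_id"]
        for sid, nbrs in graph.neighbors.items():
            for nid, _ in nbrs:
                assert sections[nid] == sections[sid]


class TestClusterInteraction:
    def test_single_cluster_fraction_one(self, lattice_frame):
        labels = pd.Series("a", index=lattice_frame.spot_ids.tolist())
        graph = neighbor_graph(lattice_frame, max_dist_um=155.0)
        report = cluster_interaction(labels, graph, n_perm=10, rng=np.random.default_rng(0))
        row = report.fractions.loc[("a", "a")]
        assert row["observed"] == 1.0
        assert row["null_mean"] == 1.0
        assert row["null_sd"] == 0.0

    def test_fractions_sum_to_one(self, lattice_frame):
        rng = np.random.default_rng(1)
        labels = pd.Series(rng.choice(["a", "b", "c"], size=len(lattice_frame)),
                           index=lattice_frame.spot_ids.tolist())
        graph = neighbor_graph(lattice_frame, max_dist_um=155.0)
        report = cluster_interaction(labels, graph, n_perm=5, rng=rng)
        sums = report.fractions["observed"].groupby(level="cluster_a").sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)

    def test_null_mean_matches_label_frequency(self, lattice_frame):
        rng = np.random.default_rng(2)
        labels = pd.Series(rng.choice(["a", "b"], size=len(lattice_frame), p=[0.3, 0.7]),
                           index=lattice_frame.spot_ids.tolist())
        graph = neighbor_graph(lattice_frame, max_dist_um=155.0)
        report = cluster_interaction(labels, graph, n_perm=100, rng=rng)
        freq_b = (labels == "b").mean()
        row = report.fractions.loc[("a", "b")]
        assert abs(row["null_mean"] - freq_b) < 3 * max(row["null_sd"], 1e-3)

    def test_exchangeable_labels_within_null_envelope(self, lattice_frame):
        rng = np.random.default_rng(3)
        labels = pd.Series(rng.permutation(["a", "b"] * (len(lattice_frame) // 2 + 1))[: len(lattice_frame)],
                           index=lattice_frame.spot_ids.tolist())
        graph = neighbor_graph(lattice_frame, max_dist_um=155.0)
        report = cluster_interaction(labels, graph, n_perm=100, rng=rng)
        z = (report.fractions["observed"] - report.fractions["null_mean"]) / report.fractions["null_sd"]
        assert np.all(np.abs(z.to_numpy()) < 4.0)


class TestAutocorrelation:
    def test_smooth_gradient_scores_high(self):
        frame = generate_frame(SimulationConfig(frame_extent=(5000.0, 5000.0)))
        xy = frame.coords_um()
        feature = xy[:, 0] + xy[:, 1]
        expr = pd.DataFrame([feature], index=["grad"], columns=frame.spot_ids.tolist())
        graph = neighbor_graph(frame, max_dist_um=150.0)
        scores = spatial_autocorrelation(expr, graph)
        assert scores.loc["grad", "score"] > 0.9

    def test_permuted_feature_scores_near_zero(self):
        frame = generate_frame(SimulationConfig(frame_extent=(5000.0, 5000.0)))
        rng = np.random.default_rng(4)
        xy = frame.coords_um()
        feature = rng.permutation(xy[:, 0] + xy[:, 1])
        expr = pd.DataFrame([feature], index=["perm"], columns=frame.spot_ids.tolist())
        graph = neighbor_graph(frame, max_dist_um=150.0)
        scores = spatial_autocorrelation(expr, graph)
        assert abs(scores.loc["perm", "score"]) < 0.1

    def test_constant_feature_reported_missing(self, lattice_frame):
        expr = pd.DataFrame([np.ones(len(lattice_frame))], index=["const"],
                            columns=lattice_frame.spot_ids.tolist())
        graph = neighbor_graph(lattice_frame, max_dist_um=155.0)
        scores = spatial_autocorrelation(expr, graph)
        assert np.isnan(scores.loc["const", "score"])
        assert "zero-variance" in scores.loc["const", "reason"]

    def test_affine_rescaling_invariance(self, lattice_frame):
        rng = np.random.default_rng(5)
        xy = lattice_frame.coords_um()
        feature = np.sin(xy[:, 0] / 400) + rng.normal(0, 0.1, len(xy))
        cols = lattice_frame.spot_ids.tolist()
        expr = pd.DataFrame([feature, 5.0 * feature + 2.0], index=["f", "af"], columns=cols)
        graph = neighbor_graph(lattice_frame, max_dist_um=155.0)
        scores = spatial_autocorrelation(expr, graph)
        assert scores.loc["f", "score"] == pytest.approx(scores.loc["af", "score"], abs=1e-12)


class TestModuleScore:
    def test_identical_genes_score_zero(self):
        expr = pd.DataFrame(np.ones((30, 10)), index=[f"g{i}" for i in range(30)])
        s = module_score(expr, ["g0", "g1"], n_bins=5, n_ctrl=10, rng=np.random.default_rng(0))
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_per_spot_shift_invariance(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(40, 15)), index=[f"g{i}" for i in range(40)])
        shift = rng.normal(size=15)
        shifted = expr + shift[None, :]
        s1 = module_score(expr, ["g3", "g7"], n_bins=8, n_ctrl=20, rng=np.random.default_rng(9))
        s2 = module_score(shifted, ["g3", "g7"], n_bins=8, n_ctrl=20, rng=np.random.default_rng(9))
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)

    def test_exchangeable_gene_set_null(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(120, 50)), index=[f"g{i}" for i in range(120)])
        means = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            genes = r.choice(expr.index, size=8, replace=False)
            s = module_score(expr, genes, n_bins=12, n_ctrl=30, rng=r)
            means.append(s.mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se + 1e-3

    def test_pericentral_program_localizes(self, small_dataset):
        ds = small_dataset
        program = [g.gene_id for g in ds.config.gene_panel if g.archetype == "gradient-central"]
        s = module_score(ds.expression.layer("normalized"), program,
                         rng=np.random.default_rng(3))
        d_c = ds.truth.true_distances["central"]
        near = s[d_c[d_c <= 100.0].index].mean()
        far = s[d_c[d_c >= 300.0].index].mean()
        assert near > far

    def test_missing_gene_set_errors(self):
        expr = pd.DataFrame(np.ones((30, 5)), index=[f"g{i}" for i in range(30)])
        with pytest.raises(ValueError):
            module_score(expr, ["absent"], n_bins=5, rng=np.random.default_rng(0))


class TestQuantileScale:
    def test_equal_values_map_to_one(self):
        out, flagged = quantile_scale(np.full(10, 3.7))
        np.testing.assert_allclose(out, 1.0)
        assert not flagged

    def test_clip_then_rescale(self):
        vals = np.arange(1.0, 101.0)
        out, _ = quantile_scale(vals, q=0.95)
        assert out.max() == 1.0
        # everything at/above the 0.95 quantile shares the maximum
        hi = np.quantile(vals, 0.95)
        assert np.all(out[vals >= hi] == 1.0)
        assert np.all(out[vals < hi] < 1.0)

    def test_all_zero_flagged(self):
        out, flagged = quantile_scale(np.zeros(5))
        np.testing.assert_array_equal(out, 0.0)
        assert flagged

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            quantile_scale(np.array([1.0, -0.1]))

    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=3, max_size=40))
    @settings(deadline=None, derandomize=True)
    def test_idempotent(self, values):
        once, _ = quantile_scale(np.asarray(values))
        twice, _ = quantile_scale(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_groupwise_application(self, small_dataset):
        ds = small_dataset
        sections = ds.spots.spots.set_index("spot_id")["section_id"]
        scaled = quantile_scale_proportions(ds.proportions, sections)
        assert float(scaled.to_numpy().max()) <= 1.0
        for sec in sections.unique():
            block = scaled.loc[sections[sections == sec].index]
            np.testing.assert_allclose(block.max(axis=0).to_numpy(), 1.0, atol=1e-12)


class TestBootstrapPearson:
    def test_perfect_correlation_degenerate_ci(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": x})
        out = bootstrap_pearson(df, n_boot=200, rng=np.random.default_rng(0))
        row = out.iloc[0]
        assert row["mean_r"] == pytest.approx(1.0)
        assert row["ci_low"] == pytest.approx(1.0)
        assert row["ci_high"] == pytest.approx(1.0)
        assert row["significant"]

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        out = bootstrap_pearson(df, n_boot=50, rng=np.random.default_rng(1))
        assert np.isnan(out.iloc[0]["mean_r"])
        assert not out.iloc[0]["significant"]

    def test_planted_anticorrelation_significant(self, small_dataset):
        out = bootstrap_pearson(small_dataset.proportions, n_boot=500,
                                rng=np.random.default_rng(2))
        out = out.set_index(["type_a", "type_b"])
        row = out.loc[("pericentral-hepatocyte", "periportal-hepatocyte")]
        assert row["mean_r"] < 0
        assert row["significant"]
        assert row["ci_high"] < 0

    def test_too_few_spots_errors(self):
        with pytest.raises(ValueError):
            bootstrap_pearson(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))


class TestDistanceScreen:
    def _screen_inputs(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        dist = pd.Series(rng.uniform(0, 700, n), index=[f"s{i}" for i in range(n)])
        return dist

    def test_perfect_monotone_decrease(self):
        dist = self._screen_inputs()
        expr = pd.DataFrame([1000.0 - dist.to_numpy()], index=["g"], columns=dist.index)
        out = distance_correlation_screen(expr, dist)
        assert out.loc["g", "rho"] == pytest.approx(-1.0)
        assert out.loc["g", "significant"]
        assert out.loc["g", "direction"] == "down-with-distance"

    def test_single_gene_adjusted_equals_raw(self):
        dist = self._screen_inputs(seed=1)
        rng = np.random.default_rng(2)
        expr = pd.DataFrame([rng.normal(size=len(dist))], index=["g"], columns=dist.index)
        out = distance_correlation_screen(expr, dist)
        assert out.loc["g", "p_adjusted"] == pytest.approx(out.loc["g", "p_value"], rel=1e-9)

    def test_max_dist_filter(self):
        dist = pd.Series([100.0, 700.0, 900.0, 300.0, 200.0],
                         index=[f"s{i}" for i in range(5)])
        expr = pd.DataFrame(np.ones((1, 5)) * np.arange(5), index=["g"], columns=dist.index)
        # only 4 spots lie within 800 um; the screen should not see s2
        out = distance_correlation_screen(expr, dist, max_dist_um=800.0)
        assert not np.isnan(out.loc["g", "rho"])

    def test_too_few_spots_errors(self):
        dist = pd.Series([900.0, 950.0, 100.0], index=["a", "b", "c"])
        expr = pd.DataFrame(np.ones((1, 3)), index=["g"], columns=dist.index)
        with pytest.raises(ValueError, match="fewer than 3"):
            distance_correlation_screen(expr, dist, max_dist_um=800.0)

    def test_holm_sidak_matches_stepdown_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, size=20)
        got = holm_sidak(p)
        order = np.argsort(p)
        m = len(p)
        adj_sorted = np.maximum.accumulate(
            [1.0 - (1.0 - p[order][k]) ** (m - k) for k in range(m)]
        )
        want = np.empty(m)
        want[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(got, want, atol=1e-12)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=25))
    @settings(deadline=None, derandomize=True)
    def test_adjusted_never_below_raw_and_monotone(self, p_list):
        p = np.asarray(p_list)
        adj = holm_sidak(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
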