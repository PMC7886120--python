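from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from claimsmapper import (
    MapperConfig,
    RuleIndexMatrix,
    build_cover,
    build_nerve,
    cluster_preimage,
    distance_matrix,
    filter_values,
    run_mapper,
    standardize,
)
from claimsmapper.mapper import DistanceMatrix


def _matrix(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = tuple(ids or (f"r{i}" for i in range(len(values))))
    return RuleIndexMatrix(rule_ids=ids, values=values)


def _line_matrix(n=200, lo=0.0, hi=10.0):
    """n points on a 1-D segment embedded in 3-D."""
    t = np.linspace(lo, hi, n)
    return _matrix(np.column_stack([t, 2 * t, -0.5 * t]))


def _two_blob_matrix(separation=10.0):
    """Two 27-point lattice blobs of unit side, centres ``separation`` apart
    per axis: inter-blob distance ~ 10x the intra-blob spread."""
    axis = np.linspace(0.0, 1.0, 3)
    blob = np.array([[x, y, z] for x in axis for y in axis for z in axis])
    return _matrix(np.vstack([blob, blob + separation]))


class TestStandardize:
    def test_hand_zscores(self):
        m = standardize(_matrix([[1, 4, 7], [2, 5, 8], [3, 6, 9]]))
        assert np.allclose(m.standardized, np.tile([[-1], [0], [1]], (1, 3)))

    def test_constant_column_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            m = standardize(_matrix([[5, 1, 2], [5, 2, 4], [5, 3, 6]]))
        assert np.all(m.standardized[:, 0] == 0)

    def test_idempotent_up_to_tolerance(self):
        m1 = standardize(_matrix([[1, 2, 4], [3, 1, 9], [7, 5, 2], [2, 8, 6]]))
        m2 = standardize(_matrix(m1.standardized))
        assert np.allclose(m1.standardized, m2.standardized)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            standardize(_matrix([[1, 2, 3]]))


class TestDistanceMatrix:
    def test_three_four_five(self):
        d = distance_matrix(_matrix([[0, 0, 0], [3, 4, 0]]))
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_identical_rows_zero(self):
        d = distance_matrix(_matrix([[1, 2, 3], [1, 2, 3]]))
        assert d.values[0, 1] == 0.0

    def test_matches_double_loop(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 3))
        d = distance_matrix(_matrix(pts))
        for i in range(20):
            for j in range(20):
                assert d.values[i, j] == pytest.approx(
                    np.sqrt(((pts[i] - pts[j]) ** 2).sum())
                )


class TestFilterValues:
    def test_eccentricity_collinear(self):
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float))
        assert filter_values(d, "eccentricity") == pytest.approx([1.0, 2 / 3, 1.0])

    def test_coordinate_returns_column(self):
        m = _matrix([[1, 9, 0], [2, 8, 0], [3, 7, 0]])
        d = distance_matrix(m)
        got = filter_values(d, "coordinate", matrix=m, coordinate_index=0)
        assert got == pytest.approx([1, 2, 3])

    def test_coordinate_out_of_range(self):
        m = _matrix([[1, 2, 3], [4, 5, 6]])
        d = distance_matrix(m)
        with pytest.raises(IndexError):
            filter_values(d, "coordinate", matrix=m, coordinate_index=3)

    def test_max_variance_projection_orders_a_line(self):
        m = _line_matrix(50)
        d = distance_matrix(m)
        proj = filter_values(d, "max_variance_projection", matrix=m)
        assert np.all(np.diff(proj) > 0) or np.all(np.diff(proj) < 0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 3))
        perm = rng.permutation(15)
        f1 = filter_values(distance_matrix(_matrix(pts)), "eccentricity")
        f2 = filter_values(distance_matrix(_matrix(pts[perm])), "eccentricity")
        assert f2 == pytest.approx(f1[perm])


class TestBuildCover:
    def test_zero_overlap_partition(self):
        cover = build_cover(np.array([0.0, 10.0]), 5, 0.0)
        got = [(iv.lo, iv.hi) for iv in cover.intervals]
        assert got == pytest.approx(
            [(0, 2), (2, 4), (4, 6), (6, 8), (8, 10)]
        )

    def test_half_overlap_hand_values(self):
        cover = build_cover(np.array([0.0, 10.0]), 5, 0.5)
        L = 10 / 3
        starts = [iv.lo for iv in cover.intervals]
        assert starts == pytest.approx([0, 5 / 3, 10 / 3, 5, 20 / 3])
        assert all(iv.hi - iv.lo == pytest.approx(L) for iv in cover.intervals)
        assert cover.intervals[-1].hi == pytest.approx(10.0)

    def test_constant_values_single_interval(self):
        cover = build_cover(np.full(4, 2.5), 5, 0.5)
        assert len(cover.intervals) == 1
        (members,) = cover.assign(np.full(4, 2.5))
        assert members.tolist() == [0, 1, 2, 3]

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        n_intervals=st.integers(1, 20),
        overlap=st.floats(0.0, 0.89),
    )
    def test_random_configs_cover_everything(self, seed, n_intervals, overlap):
        rng = np.random.default_rng(seed)
        fvals = rng.uniform(-100, 100, size=40)
        cover = build_cover(fvals, n_intervals, overlap)
        assigned = np.zeros(fvals.size, dtype=int)
        for members in cover.assign(fvals):
            assigned[members] += 1
        assert np.all(assigned >= 1)
        # coverage multiplicity: at most ceil(1/(1-overlap)) intervals deep,
        # which is <= 2 for overlap <= 0.5
        if 0 < overlap <= 0.5:
            interior = (fvals > fvals.min()) & (fvals < fvals.max())
            assert np.all(assigned[interior] <= 2)

    def test_overlap_one_rejected(self):
        with pytest.raises(Exception):
            build_cover(np.array([0.0, 1.0]), 3, 1.0)


class TestClusterPreimage:
    def _dist_1d(self, xs):
        xs = np.asarray(xs, dtype=float)
        return DistanceMatrix(np.abs(xs[:, None] - xs[None, :]))

    def test_singleton(self):
        d = self._dist_1d([0.0, 1.0])
        assert cluster_preimage([1], d) == [[1]]

    def test_histogram_gap_splits_two_groups(self):
        d = self._dist_1d([0.0, 0.1, 0.2, 5.0, 5.1])
        clusters = cluster_preimage([0, 1, 2, 3, 4], d, num_bins=10)
        assert sorted(map(sorted, clusters)) == [[0, 1, 2], [3, 4]]

    def test_equal_distances_one_cluster(self):
        # equilateral configuration: all merge heights identical
        pts = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        d = distance_matrix(_matrix(pts))
        assert cluster_preimage([0, 1, 2], d) == [[0, 1, 2]]


class TestBuildNerve:
    def test_shared_member_edge(self):
        m = _matrix(np.arange(15).reshape(5, 3))
        g = build_nerve([[[0, 1, 2]], [[2, 3]]], m)
        assert len(g.nodes) == 2
        assert g.edges == ((("i0c0"), ("i1c0"), 1),)

    def test_disjoint_no_edge(self):
        m = _matrix(np.arange(12).reshape(4, 3))
        g = build_nerve([[[0, 1]], [[2, 3]]], m)
        assert g.edges == ()

    def test_no_same_interval_edges_and_metadata(self):
        m = _matrix([[1, 2, 3], [3, 4, 5], [5, 6, 7]])
        g = build_nerve([[[0, 1], [1, 2]]], m)
        assert g.edges == ()
        node = {n.node_id: n for n in g.nodes}["i0c0"]
        assert node.size == 2
        assert node.mean_support == pytest.approx(2.0)
        assert node.mean_lift == pytest.approx(4.0)


class TestRunMapper:
    def test_segment_gives_connected_path(self):
        import networkx as nx

        cfg = MapperConfig(n_intervals=5, overlap=0.5, filter_kind="coordinate")
        g = run_mapper(_line_matrix(200), cfg)
        nxg = g.to_networkx()
        assert nx.number_connected_components(nxg) == 1
        assert nx.is_forest(nxg)  # path-like: connected and acyclic

    def test_two_blobs_two_components(self):
        # projection lens separates the blobs along the max-variance axis
        cfg = MapperConfig(filter_kind="max_variance_projection")
        g = run_mapper(_two_blob_matrix(), cfg)
        assert len(g.connected_components()) == 2

    def test_two_blobs_stable_under_small_perturbation(self):
        cfg = MapperConfig(filter_kind="max_variance_projection")
        m = _two_blob_matrix()
        rng = np.random.default_rng(42)
        perturbed = _matrix(m.values * (1 + rng.uniform(-0.01, 0.01, m.values.shape)))
        assert len(run_mapper(perturbed, cfg).connected_components()) == 2

    def test_zero_overlap_single_cluster_partition_has_no_edges(self):
        m = _line_matrix(100)
        sm = standardize(m)
        d = distance_matrix(sm)
        fvals = filter_values(d, "coordinate", matrix=sm)
        cover = build_cover(fvals, 5, 0.0)
        # one-cluster-per-preimage clusterer: the limit case
        clusters = [[members.tolist()] for members in cover.assign(fvals)]
        g = build_nerve(clusters, sm)
        assert len(g.nodes) == 5
        assert g.edges == ()

    def test_duplicated_point_cloud_degenerate(self):
        vals = np.tile([[0.2, 0.6, 1.5]], (10, 1))
        vals[0] = [0.1, 0.5, 1.4]  # one distinct point so SD > 0
        g = run_mapper(_matrix(vals), MapperConfig(n_intervals=3, overlap=0.5))
        assert all(n.size >= 1 for n in g.nodes)

    def test_determinism(self):
        m = _two_blob_matrix()
        cfg = MapperConfig(n_intervals=6, overlap=0.4)
        assert run_mapper(m, cfg) == run_mapper(m, cfg)

    def test_nerve_soundness_on_random_cloud(self):
        rng = np.random.default_rng(11)
        m = _matrix(rng.normal(size=(80, 3)))
        g = run_mapper(m, MapperConfig())
        members = {n.node_id: n.member_rule_ids for n in g.nodes}
        interval = {n.node_id: n.interval_index for n in g.nodes}
        for u, v, shared in g.edges:
            assert interval[u] != interval[v]
            assert len(members[u] & members[v]) == shared >= 1

    def test_partition_within_interval(self):
        """Each interval's preimage is exactly partitioned by its clusters."""
        rng = np.random.default_rng(9)
        m = _matrix(rng.normal(size=(60, 3)))
        sm = standardize(m)
        d = distance_matrix(sm)
        fvals = filter_values(d, "eccentricity")
        cover = build_cover(fvals, 5, 0.5)
        for members in cover.assign(fvals):
            if members.size == 0:
                continue
            clusters = cluster_preimage(members.tolist(), d)
            flat = sorted(x for c in clusters for x in c)
            assert flat == sorted(members.tolist())


def test_graph_writers(tmp_path):
    import networkx as nx

    g = run_mapper(_two_blob_matrix(), MapperConfig())
    g.write_graphml(tmp_path / "g.graphml")
    g.write_dot(tmp_path / "g.dot")
    g.write_memberships_csv(tmp_path / "g_nodes.csv")
    back = nx.read_graphml(tmp_path / "g.graphml")
    assert set(back.nodes) == {n.node_id for n in g.nodes}
    dot = (tmp_path / "g.dot").read_text()
    assert dot.startswith("graph mapper {") and "--" in dot
    lines = (tmp_path / "g_nodes.csv").read_text().strip().splitlines()
    assert lines[0] == "node_id,rule_id"
    assert len(lines) - 1 == sum(n.size for n in g.nodes)
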