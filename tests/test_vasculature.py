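"""Vascular tree generation, hierarchy labels, compartments, blockage, I/O."""

import numpy as np
import pytest

import poroperf as pp
from poroperf.vasculature import (Box, HierarchyLabels, NetworkParseError,
                                  VascularNetwork, apply_blockage,
                                  assign_compartments, generate_cco_tree,
                                  hierarchy_parameters, partition_compartments,
                                  read_segment_table, write_segment_table,
                                  write_vtk_polylines)


def murray_violation(net, gamma=3.0):
    """Max relative Murray-law violation over all bifurcations."""
    worst = 0.0
    for i, kids in enumerate(net.children_lists()):
        if len(kids) >= 2:
            lhs = net.radius[i] ** gamma
            rhs = sum(net.radius[j] ** gamma for j in kids)
            worst = max(worst, abs(lhs - rhs) / lhs)
    return worst


class TestCCOGeneration:
    def test_single_terminal_degenerate(self):
        net = generate_cco_tree(Box.cube(100.0), 1, 3.0, seed=0)
        assert net.n_segments == 1
        assert net.n_terminals == 1
        assert net.radius[0] == pytest.approx(3.0)
        assert Box.cube(100.0).contains(net.midpoints).all()

    def test_determinism_bitwise(self):
        a = generate_cco_tree(Box.cube(100.0), 50, 3.0, seed=7)
        b = generate_cco_tree(Box.cube(100.0), 50, 3.0, seed=7)
        assert np.array_equal(a.proximal, b.proximal)
        assert np.array_equal(a.distal, b.distal)
        assert np.array_equal(a.radius, b.radius)
        assert np.array_equal(a.parent, b.parent)

    def test_murray_law_all_junctions(self, cco200):
        # direct summation over every bifurcation
        assert murray_violation(cco200, gamma=3.0) < 1e-6

    def test_terminal_count_and_geometry(self, cco200):
        assert cco200.n_terminals == 200
        assert Box.cube(100.0).contains(cco200.midpoints).all()
        # radii non-increasing root->leaf
        pos = cco200.parent >= 0
        assert np.all(cco200.radius[pos] <= cco200.radius[cco200.parent[pos]] + 1e-12)

    def test_custom_gamma(self):
        net = generate_cco_tree(Box.cube(50.0), 40, 1.5, seed=3, gamma=2.55)
        assert murray_violation(net, gamma=2.55) < 1e-6

    def test_invalid_inputs(self):
        box = Box.cube(100.0)
        with pytest.raises(ValueError):
            generate_cco_tree(box, 0, 3.0)
        with pytest.raises(ValueError):
            generate_cco_tree(box, 5, -1.0)
        with pytest.raises(ValueError):
            generate_cco_tree(box, 5, 3.0, inlet_point=(50.0, 50.0, 50.0))


class TestHierarchyParameter:
    def test_y_tree_hand_enumeration(self, y3):
        lab = hierarchy_parameters(y3)
        # root: distal lengths 1 + 1 of total 4
        assert lab.zeta[0] == pytest.approx(0.5)
        assert lab.zeta[1] == 0.0 and lab.zeta[2] == 0.0
        assert lab.total_length == pytest.approx(4.0)

    def test_terminals_exactly_zero(self, cco200):
        lab = hierarchy_parameters(cco200)
        assert np.all(lab.zeta[cco200.is_terminal] == 0.0)

    def test_chain_closed_form(self):
        # chain of n equal segments: k-th from root has zeta = (n-1-k)/n
        n = 7
        zs = np.arange(n + 1, dtype=float)
        prox = np.stack([np.zeros(n), np.zeros(n), zs[:-1]], axis=1)
        dist = np.stack([np.zeros(n), np.zeros(n), zs[1:]], axis=1)
        net = VascularNetwork(prox, dist, np.linspace(1, 0.5, n),
                              np.arange(-1, n - 1))
        lab = hierarchy_parameters(net)
        expect = (n - 1 - np.arange(n)) / n
        np.testing.assert_allclose(lab.zeta, expect, atol=1e-14)
        assert np.all(np.diff(lab.zeta) < 0)

    def test_strictly_decreasing_root_to_leaf(self, cco200):
        lab = hierarchy_parameters(cco200)
        pos = cco200.parent >= 0
        assert np.all(lab.zeta[np.flatnonzero(pos)]
                      < lab.zeta[cco200.parent[pos]])

    def test_root_bound(self, cco200):
        lab = hierarchy_parameters(cco200)
        root = cco200.root_id
        l_root = cco200.lengths[root]
        assert lab.zeta[root] >= 1.0 - l_root / lab.total_length - 1e-12


def _sse(groups):
    return sum(((g - g.mean()) ** 2).sum() for g in groups if len(g))


def exhaustive_two_way_split(zeta, radii):
    """Oracle: scan all candidate thresholds for the best 2-leaf split."""
    uz = np.unique(zeta)
    best = (np.inf, None)
    for k in range(1, len(uz)):
        thr = (uz[k - 1] + uz[k]) / 2.0
        sse = _sse([radii[zeta < thr], radii[zeta >= thr]])
        if sse < best[0]:
            best = (sse, thr)
    return best


def dp_optimal_partition(zeta, radii, nc):
    """Exact contiguous-partition SSE by dynamic programming (oracle)."""
    order = np.argsort(zeta)
    z, r = zeta[order], radii[order]
    uz, idx = np.unique(z, return_inverse=True)
    K = len(uz)
    cnt = np.bincount(idx).astype(float)
    s1 = np.bincount(idx, weights=r)
    s2 = np.bincount(idx, weights=r * r)
    C1, S1, S2 = (np.concatenate([[0.0], np.cumsum(a)]) for a in (cnt, s1, s2))

    def sse(i, j):
        n = C1[j] - C1[i]
        return (S2[j] - S2[i]) - (S1[j] - S1[i]) ** 2 / n if n else 0.0

    INF = np.inf
    dp = np.full((nc + 1, K + 1), INF)
    dp[0, 0] = 0.0
    for g in range(1, nc + 1):
        for j in range(1, K + 1):
            for i in range(g - 1, j):
                dp[g, j] = min(dp[g, j], dp[g - 1, i] + sse(i, j))
    return dp[nc, K]


class TestPartition:
    def test_two_level_radii_split_matches_oracle(self):
        rng = np.random.default_rng(0)
        zeta = rng.random(200)
        radii = np.where(zeta >= 0.5, 1.0, 0.1)
        lab = HierarchyLabels(zeta=zeta, total_length=1.0)
        scheme = partition_compartments(lab, radii, 2)
        _, thr = exhaustive_two_way_split(zeta, radii)
        assert scheme.zeta_crit[1] == pytest.approx(thr)
        below = zeta[zeta < 0.5].max()
        above = zeta[zeta >= 0.5].min()
        assert scheme.zeta_crit[1] == pytest.approx((below + above) / 2)

    def test_constant_radii_median_tiebreak(self):
        zeta = np.linspace(0, 1, 11)
        lab = HierarchyLabels(zeta=zeta, total_length=1.0)
        scheme = partition_compartments(lab, np.ones(11), 2)
        # split at the median zeta of the (single) leaf
        assert 0.3 < scheme.zeta_crit[1] < 0.7

    def test_monotone_sse_refinement(self, cco200):
        lab = hierarchy_parameters(cco200)
        sses = []
        for nc in (2, 3, 4, 5):
            _, sse = partition_compartments(lab, cco200.radius, nc,
                                            return_sse=True)
            sses.append(sse)
        assert np.all(np.diff(sses) <= 1e-12)

    def test_greedy_vs_dp_oracle(self, cco200):
        lab = hierarchy_parameters(cco200)
        for nc in (2, 3):
            _, sse = partition_compartments(lab, cco200.radius, nc,
                                            return_sse=True)
            opt = dp_optimal_partition(lab.zeta, cco200.radius, nc)
            assert sse >= opt - 1e-9 * max(1.0, opt)
        # identical split on well-separated two-level data
        rng = np.random.default_rng(1)
        zeta = rng.random(300)
        radii = np.where(zeta >= 0.4, 2.0, 0.2)
        lab2 = HierarchyLabels(zeta=zeta, total_length=1.0)
        _, sse2 = partition_compartments(lab2, radii, 2, return_sse=True)
        assert sse2 == pytest.approx(dp_optimal_partition(zeta, radii, 2),
                                     abs=1e-10)

    def test_sklearn_cross_check(self, cco200):
        sklearn = pytest.importorskip("sklearn.tree")
        lab = hierarchy_parameters(cco200)
        scheme = partition_compartments(lab, cco200.radius, 2)
        t = sklearn.DecisionTreeRegressor(max_leaf_nodes=2, random_state=0)
        t.fit(lab.zeta[:, None], cco200.radius)
        thr = t.tree_.threshold[0]  # sklearn computes thresholds in float32
        assert scheme.zeta_crit[1] == pytest.approx(thr, rel=1e-6)

    def test_too_many_compartments_raises(self, y3):
        lab = hierarchy_parameters(y3)  # two distinct zeta values
        with pytest.raises(ValueError):
            partition_compartments(lab, y3.radius, 3)


class TestAssignment:
    def test_interval_conventions(self):
        scheme = pp.CompartmentScheme(nc=3, zeta_crit=np.array([1.0, 0.5, 0.2, 0.0]))
        comp = scheme.assign(np.array([1.0, 0.7, 0.5, 0.3, 0.2, 0.1, 0.0]))
        # top interval closed at 1; intervals closed at their lower zeta edge
        np.testing.assert_array_equal(comp, [1, 1, 1, 2, 2, 3, 3])

    def test_non_decreasing_along_paths(self, cco200):
        lab = hierarchy_parameters(cco200)
        scheme = partition_compartments(lab, cco200.radius, 3)
        comp = assign_compartments(cco200, scheme, lab)
        pos = cco200.parent >= 0
        assert np.all(comp[pos] >= comp[cco200.parent[pos]])

    def test_zeta_out_of_range_raises(self):
        scheme = pp.CompartmentScheme(nc=2, zeta_crit=np.array([1.0, 0.5, 0.0]))
        with pytest.raises(ValueError):
            scheme.assign(np.array([1.2]))


class TestBlockage:
    def test_block_terminal_single_segment(self, cco200):
        term = int(np.flatnonzero(cco200.is_terminal)[0])
        blocked = apply_blockage(cco200, int(cco200.ids[term]))
        assert blocked.blocked.sum() == 1

    def test_symmetric_tree_blocks_half(self, bin4):
        root_children = [i for i in range(bin4.n_segments)
                         if bin4.parent[i] == bin4.root_id]
        blocked = apply_blockage(bin4, int(bin4.ids[root_children[0]]))
        assert blocked.blocked.sum() == (bin4.n_segments - 1) // 2

    def test_blocked_root_raises(self, cco200):
        with pytest.raises(ValueError):
            apply_blockage(cco200, int(cco200.ids[cco200.root_id]))

    def test_unblocked_part_stays_connected(self, cco200):
        rng = np.random.default_rng(5)
        for sid in rng.choice(cco200.n_segments, 5, replace=False):
            if cco200.parent[sid] < 0:
                continue
            b = apply_blockage(cco200, int(cco200.ids[sid]))
            # every open segment has an open chain to the root
            for i in np.flatnonzero(~b.blocked):
                j = i
                while b.parent[j] >= 0:
                    j = b.parent[j]
                    assert not b.blocked[j]


class TestIO:
    def test_round_trip_identity(self, y3, tmp_path):
        path = tmp_path / "y3.csv"
        write_segment_table(y3, path)
        back = read_segment_table(path)
        np.testing.assert_array_equal(back.ids, y3.ids)
        np.testing.assert_array_equal(back.parent, y3.parent)
        np.testing.assert_allclose(back.radius, y3.radius, rtol=1e-15)

    def test_cco_round_trip_coordinates(self, cco200, tmp_path):
        path = tmp_path / "t.csv"
        write_segment_table(cco200, path)
        back = read_segment_table(path)
        assert np.max(np.abs(back.proximal - cco200.proximal)) < 1e-9
        assert np.max(np.abs(back.distal - cco200.distal)) < 1e-9

    def test_orphan_parent_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,parent_id,x0,y0,z0,x1,y1,z1,radius_mm,blocked\n"
                        "0,-1,0,0,0,0,0,1,1.0,0\n"
                        "1,99,0,0,1,0,0,2,0.5,0\n")
        with pytest.raises(NetworkParseError, match="99"):
            read_segment_table(path)

    def test_duplicate_id_raises(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("id,parent_id,x0,y0,z0,x1,y1,z1,radius_mm,blocked\n"
                        "0,-1,0,0,0,0,0,1,1.0,0\n"
                        "0,0,0,0,1,0,0,2,0.5,0\n")
        with pytest.raises(NetworkParseError):
            read_segment_table(path)

    def test_malformed_value_names_row(self, tmp_path):
        path = tmp_path / "mal.csv"
        path.write_text("id,parent_id,x0,y0,z0,x1,y1,z1,radius_mm,blocked\n"
                        "0,-1,0,0,0,0,0,oops,1.0,0\n")
        with pytest.raises(NetworkParseError, match="row 0"):
            read_segment_table(path)

    def test_vtk_polyline_export(self, y3, tmp_path):
        path = tmp_path / "y3.vtk"
        write_vtk_polylines(y3, path)
        text = path.read_text()
        assert "POLYDATA" in text and "LINES 3" in text
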