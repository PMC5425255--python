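"""Consensus state graph, Fisher clustering, paths and pseudotime."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from nmpgrn import preprocess, trajectory
from nmpgrn.errors import ConfigurationError

from conftest import toy_matrix


class TestDistances:
    def test_duplicates_and_pythagoras(self):
        vals = np.array([[0.0, 3.0, 0.0, 0.0], [0.0, 4.0, 8.0, 0.0]])
        m = toy_matrix(vals, layer="log_cpm")
        d = trajectory.cell_distance_matrix(m, m.genes)
        assert d.loc["c0", "c3"] == 0.0
        assert d.loc["c0", "c1"] == pytest.approx(5.0)
        assert d.loc["c1", "c2"] == pytest.approx(5.0)
        assert d.loc["c0", "c2"] == pytest.approx(8.0)

    def test_single_gene_absolute_difference(self):
        m = toy_matrix([[1.0, 4.0]], layer="log_cpm")
        d = trajectory.cell_distance_matrix(m, ["g0"])
        assert d.loc["c0", "c1"] == pytest.approx(3.0)

    def test_empty_gene_set_rejected(self):
        m = toy_matrix([[1.0, 2.0]], layer="log_cpm")
        with pytest.raises(ValueError):
            trajectory.cell_distance_matrix(m, [])


def _brute_force_mst_weight(d):
    """Minimum total weight over all spanning trees (n <= 6)."""
    n = d.shape[0]
    edges = list(itertools.combinations(range(n), 2))
    best = np.inf
    for subset in itertools.combinations(edges, n - 1):
        g = nx.Graph(subset)
        if g.number_of_nodes() == n and nx.is_connected(g):
            w = sum(d[i, j] for i, j in subset)
            best = min(best, w)
    return best


class TestPerturbedMST:
    @pytest.mark.parametrize("seed", range(5))
    def test_unperturbed_equals_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        pts = rng.uniform(0, 1, (n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        edges = trajectory.perturbed_mst(d, perturb_ratio=0.0)
        w = sum(d[i, j] for i, j in edges)
        assert w == pytest.approx(_brute_force_mst_weight(d), rel=1e-9)

    def test_two_nodes_single_edge(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        rng = np.random.default_rng(0)
        edges = trajectory.perturbed_mst(d, perturb_ratio=0.0, rng=rng)
        assert edges.tolist() == [[0, 1]]

    def test_collinear_points_give_path_graph(self):
        x = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        edges = trajectory.perturbed_mst(d, perturb_ratio=0.0)
        assert sorted(map(tuple, edges)) == [(0, 1), (1, 2), (2, 3), (3, 4)]

    def test_perturbation_changes_trees_but_keeps_size(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1, (20, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        e1 = trajectory.perturbed_mst(d, 0.2, np.random.default_rng(2))
        e2 = trajectory.perturbed_mst(d, 0.2, np.random.default_rng(3))
        assert len(e1) == len(e2) == 19
        assert set(map(tuple, e1)) != set(map(tuple, e2))


def _brute_force_fisher(values, k):
    """Best contiguous partition of the sorted values by total SSE."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size

    def sse(seg):
        return ((seg - seg.mean()) ** 2).sum()

    best, best_bounds = np.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        cost = sum(sse(x[bounds[i]:bounds[i + 1]]) for i in range(k))
        if cost < best - 1e-12:
            best, best_bounds = cost, bounds
    return best


class TestFisherClustering:
    def test_worked_example(self):
        labels = trajectory.fisher_1d_cluster([1, 1, 1, 10, 10], 2)
        assert labels.tolist() == [0, 0, 0, 1, 1]

    def test_single_class(self):
        labels = trajectory.fisher_1d_cluster([5, 5, 5], 1)
        assert labels.tolist() == [0, 0, 0]

    def test_too_many_classes_rejected(self):
        with pytest.raises(ConfigurationError):
            trajectory.fisher_1d_cluster([1, 1, 2], 3)

    @pytest.mark.parametrize("seed,k", [(s, k) for s in range(4)
                                        for k in (2, 3, 4)])
    def test_dp_equals_brute_force(self, seed, k):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(max(6, k + 1), 16))
        vals = rng.integers(1, 40, n)
        if np.unique(vals).size < k:
            vals = np.arange(1, n + 1)
        labels = trajectory.fisher_1d_cluster(vals, k)
        x = np.asarray(vals, dtype=float)
        cost = sum(((x[labels == c] - x[labels == c].mean()) ** 2).sum()
                   for c in range(k))
        assert cost == pytest.approx(_brute_force_fisher(vals, k), abs=1e-9)

    def test_classes_ordered_by_mean(self):
        labels = trajectory.fisher_1d_cluster([30, 1, 30, 2, 60], 3)
        assert labels.tolist() == [1, 0, 1, 0, 2]


class TestConsensus:
    def test_single_replicate_zero_ratio_is_plain_mst(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, (12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        g = trajectory.pmst_consensus(d, n_replicates=1, perturb_ratio=0.0,
                                      seed=1)
        mst = trajectory.perturbed_mst(d, 0.0)
        got = {(a, b) for a, b in g.edges[["cell_a", "cell_b"]].values}
        assert got == set(map(tuple, mst))

    def test_determinism(self, clean_branching):
        m, truth = clean_branching
        logcpm = preprocess.log_transform(preprocess.normalize_cpm(m))
        sub = logcpm.subset_cells(logcpm.cells[:60])
        d = trajectory.cell_distance_matrix(sub, sub.genes)
        g1 = trajectory.pmst_consensus(d, n_replicates=30, seed=5)
        g2 = trajectory.pmst_consensus(d, n_replicates=30, seed=5)
        pd.testing.assert_frame_equal(g1.edges, g2.edges)

    def test_connected_and_counts_bounded(self, clean_branching):
        m, truth = clean_branching
        logcpm = preprocess.log_transform(preprocess.normalize_cpm(m))
        sub = logcpm.subset_cells(logcpm.cells[:80])
        d = trajectory.cell_distance_matrix(sub, sub.genes)
        g = trajectory.pmst_consensus(d, n_replicates=40, seed=2)
        assert g.edges["occurrence"].max() <= 40
        assert nx.is_connected(g.to_networkx())

    def test_branch_edges_dominate(self, clean_branching):
        """Edges overwhelmingly join same-branch or trunk-adjacent cells."""
        m, truth = clean_branching
        logcpm = preprocess.log_transform(preprocess.normalize_cpm(m))
        d = trajectory.cell_distance_matrix(logcpm, logcpm.genes)
        g = trajectory.pmst_consensus(d, n_replicates=50, seed=3)
        branch = truth.cells["branch"]
        ok = 0
        for a, b in g.edges[["cell_a", "cell_b"]].values:
            ba, bb = branch[a], branch[b]
            if ba == bb or "nmp" in (ba, bb):
                ok += 1
        assert ok / len(g.edges) >= 0.9


class TestPaths:
    def _graph(self, edges):
        g = nx.Graph()
        for a, b, w in edges:
            g.add_edge(a, b, weight=w)
        return g

    def test_path_graph_single_path(self):
        g = self._graph([("a", "b", 1), ("b", "c", 1)])
        paths = trajectory.k_shortest_paths(g, "a", "c", 5)
        assert paths == [["a", "b", "c"]]

    def test_square_two_paths(self):
        g = self._graph([("a", "b", 1), ("b", "d", 1), ("a", "c", 1),
                         ("c", "d", 1)])
        paths = trajectory.k_shortest_paths(g, "a", "d", 2)
        assert len(paths) == 2
        assert all(len(p) == 3 for p in paths)

    def test_k_exceeding_path_count(self):
        g = self._graph([("a", "b", 1), ("b", "c", 1), ("a", "c", 5)])
        paths = trajectory.k_shortest_paths(g, "a", "c", 100)
        assert len(paths) == 2  # all simple paths


class TestPseudotimeProfiles:
    def _line_matrix(self, n=30):
        cells = [f"c{i}" for i in range(n)]
        rising = np.linspace(0, 5, n)
        flat = np.full(n, 2.0)
        vals = np.vstack([rising, flat])
        m = toy_matrix(vals, layer="log_cpm", cells=cells)
        return m, cells

    def test_monotone_gene_stays_monotone(self):
        m, cells = self._line_matrix()
        prof = trajectory.pseudotime_profiles([cells], m, n_bins=20)
        rho = spearmanr(np.arange(20), prof.profiles.loc["g0"].values).statistic
        assert rho > 0.99

    def test_constant_gene_flat(self):
        m, cells = self._line_matrix()
        prof = trajectory.pseudotime_profiles([cells], m, n_bins=20)
        np.testing.assert_allclose(prof.profiles.loc["g1"].values, 2.0,
                                   atol=1e-9)

    def test_duplicate_paths_idempotent(self):
        m, cells = self._line_matrix()
        one = trajectory.pseudotime_profiles([cells], m, n_bins=15)
        two = trajectory.pseudotime_profiles([cells, cells], m, n_bins=15)
        pd.testing.assert_frame_equal(one.profiles, two.profiles)

    def test_short_path_skipped(self):
        m, cells = self._line_matrix()
        with pytest.warns(UserWarning, match="fewer than 2"):
            prof = trajectory.pseudotime_profiles([cells, [cells[0]]], m,
                                                  n_bins=10)
        assert prof.n_paths == 1


class TestFractionalIdentity:
    def test_extremes_hit_bounds(self):
        vals = np.array([[0.0, 5.0, 10.0],   # increasing marker
                         [10.0, 5.0, 0.0]])  # decreasing marker
        m = toy_matrix(vals, layer="log_cpm")
        s = trajectory.fractional_identity(m, ["g1"], ["g0"])
        assert s["c0"] == 0.0 and s["c2"] == 1.0

    def test_role_swap_reflects_score(self):
        rng = np.random.default_rng(0)
        m = toy_matrix(rng.uniform(0, 5, (4, 10)), layer="log_cpm")
        s = trajectory.fractional_identity(m, ["g0", "g1"], ["g2", "g3"])
        swapped = trajectory.fractional_identity(m, ["g2", "g3"], ["g0", "g1"])
        np.testing.assert_allclose(s.values, 1.0 - swapped.values, atol=1e-12)

    def test_constant_gene_dropped(self):
        vals = np.array([[0.0, 1.0, 2.0], [3.0, 3.0, 3.0]])
        m = toy_matrix(vals, layer="log_cpm")
        with pytest.warns(UserWarning, match="constant"):
            s = trajectory.fractional_identity(m, [], ["g0", "g1"])
        assert s["c2"] == 1.0


def test_pseudotime_recovery_on_branch(clean_branching):
    """Inferred bin position correlates > 0.9 with latent pseudotime."""
    m, truth = clean_branching
    logcpm = preprocess.log_transform(preprocess.normalize_cpm(m))
    cells = truth.cells
    branch_cells = cells[cells.branch.isin(["nmp", "meso_branch"])]
    sub = logcpm.subset_cells(branch_cells.index)
    genes = truth.genes.query("program in ('nmp', 'mesoderm')").index
    d = trajectory.cell_distance_matrix(sub, genes)
    g = trajectory.pmst_consensus(d, n_replicates=50, seed=11)
    srt = branch_cells.sort_values("pseudotime")
    early = list(srt.index[:6])
    late = list(srt.index[-6:])
    paths = trajectory.paths_between_populations(g, early, late, k=10)
    # per-cell mean bin position across the paths that visit it
    n_bins = 50
    pos_sum, pos_n = {}, {}
    for p in paths:
        for r, c in enumerate(p):
            b = round(r / (len(p) - 1) * (n_bins - 1))
            pos_sum[c] = pos_sum.get(c, 0) + b
            pos_n[c] = pos_n.get(c, 0) + 1
    common = [c for c in branch_cells.index if c in pos_sum]
    inferred = [pos_sum[c] / pos_n[c] for c in common]
    latent = branch_cells.loc[common, "pseudotime"].values
    rho = abs(spearmanr(inferred, latent).statistic)
    assert rho > 0.9
    assert len(common) > 0.5 * len(branch_cells)


class TestTerminalSelection:
    def test_identity_extremes(self):
        s = pd.Series(np.linspace(0, 1, 30),
                      index=[f"c{i}" for i in range(30)])
        early, late = trajectory.terminal_cells_by_identity(s, n=12)
        assert len(early) == len(late) == 12
        assert s[early].max() < s[late].min()

    def test_cluster_labels(self):
        lab = pd.Series(["a"] * 8 + ["b"] * 8,
                        index=[f"c{i}" for i in range(16)])
        early, late = trajectory.terminal_cells_by_cluster(lab, "a", "b")
        assert set(lab[early]) == {"a"} and set(lab[late]) == {"b"}
        with pytest.raises(ConfigurationError):
            trajectory.terminal_cells_by_cluster(lab, "a", "z")


def test_consensus_stable_across_seeds(clean_branching):
    """Retained edge sets from independent replicate streams overlap strongly
    (Jaccard > 0.8 at 100 replicates)."""
    m, truth = clean_branching
    logcpm = preprocess.log_transform(preprocess.normalize_cpm(m))
    sub = logcpm.subset_cells(logcpm.cells[:120])
    d = trajectory.cell_distance_matrix(sub, sub.genes)
    sets = []
    for seed in (1, 2):
        g = trajectory.pmst_consensus(d, n_replicates=100, seed=seed)
        sets.append({tuple(sorted(e))
                     for e in g.edges[["cell_a", "cell_b"]].values})
    jaccard = len(sets[0] & sets[1]) / len(sets[0] | sets[1])
    assert jaccard > 0.8


def test_branch_separation_of_paths(clean_branching):
    """Paths from NMP-terminal to mesoderm-terminal cells avoid the neural
    branch (< 5% of visited cells)."""
    m, truth = clean_branching
    logcpm = preprocess.log_transform(preprocess.normalize_cpm(m))
    d = trajectory.cell_distance_matrix(logcpm, logcpm.genes)
    g = trajectory.pmst_consensus(d, n_replicates=100, seed=4)
    cells = truth.cells
    nmp = cells.query("branch == 'nmp'").sort_values("pseudotime")
    meso = cells.query("branch == 'meso_branch'").sort_values("pseudotime")
    paths = trajectory.paths_between_populations(
        g, list(nmp.index[:6]), list(meso.index[-6:]), k=5)
    visited = [c for p in paths for c in p]
    frac_neural = np.mean([cells.loc[c, "branch"] == "neural_branch"
                           for c in visited])
    assert frac_neural < 0.05
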