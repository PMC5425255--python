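"""Perturbed-MST consensus cell-state graph and pseudotemporal ordering.

A complete Euclidean distance graph over cells (log-CPM space, selected
genes) is summarised by a consensus of minimum spanning trees: each
replicate forbids a random 20% of the cell pairs (sets their distance to a
huge constant) before extracting an MST, replicate adjacencies are summed
into edge-occurrence counts, and rarely recruited edges are discarded by
1-D Fisher (Jenks) clustering of the non-zero occurrence distribution.
The procedure iterates until the retained edge count stops changing.

Pseudotime: K-shortest (Yen) paths between designated early and late
cells, rank-rebinned onto a fixed number of pseudotime bins, averaged and
loess-smoothed (local quadratic fit, tricube weights).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .containers import ExpressionMatrix
from .errors import ConfigurationError


@dataclasses.dataclass
class CellStateGraph:
    cells: list
    edges: pd.DataFrame  # columns: cell_a, cell_b, occurrence, distance
    converged: bool
    rounds: int

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.cells)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.cell_a, row.cell_b, weight=row.distance,
                       occurrence=row.occurrence)
        return g

    def write_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


@dataclasses.dataclass
class PseudotimeProfile:
    profiles: pd.DataFrame        # genes x n_bins smoothed levels
    raw_profiles: pd.DataFrame    # genes x n_bins before smoothing
    n_bins: int
    n_paths: int


# ---------------------------------------------------------------------------
# Distances and spanning trees
# ---------------------------------------------------------------------------

def cell_distance_matrix(m: ExpressionMatrix, genes) -> pd.DataFrame:
    """Pairwise Euclidean distance between cells over a gene subset."""
    m.require_layer("log_cpm")
    genes = pd.Index(genes)
    if len(genes) == 0:
        raise ValueError("empty gene set")
    d = squareform(pdist(m.values.loc[genes].values.T, metric="euclidean"))
    return pd.DataFrame(d, index=m.cells, columns=m.cells)


def _tie_broken(d: np.ndarray) -> np.ndarray:
    """Add a deterministic rank epsilon so every edge weight is unique.

    Makes the MST unique and reproducible (stable ordering by weight then
    node-pair position) without materially changing any distance.
    """
    n = d.shape[0]
    scale = max(d.max(), 1.0)
    eps = scale * 1e-12 * (np.arange(n)[:, None] * n + np.arange(n)[None, :])
    eps = np.triu(eps, 1)
    return d + eps + eps.T


def perturbed_mst(d: np.ndarray, perturb_ratio: float = 0.2,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """MST edge set after forbidding a random fraction of cell pairs.

    A symmetric ``perturb_ratio`` share of the off-diagonal pairs gets a
    forbidding constant (1e6 x max distance) before the MST is computed on
    the modified complete graph.  Returns an (n-1, 2) array of node index
    pairs (i < j).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2 or d.shape[0] != d.shape[1]:
        raise ValueError("need a square matrix over >= 2 cells")
    if not np.isfinite(d).all():
        raise ValueError("distances must be finite")
    if not 0.0 <= perturb_ratio < 1.0:
        raise ConfigurationError("perturb_ratio must lie in [0, 1)")
    work = _tie_broken(d)
    if perturb_ratio > 0:
        if rng is None:
            raise ValueError("perturbation requires an rng")
        iu, ju = np.triu_indices(n, k=1)
        n_forbid = int(round(perturb_ratio * iu.size))
        pick = rng.choice(iu.size, size=n_forbid, replace=False)
        big = 1e6 * max(d.max(), 1.0)
        work[iu[pick], ju[pick]] = big
        work[ju[pick], iu[pick]] = big
    tree = minimum_spanning_tree(scipy.sparse.csr_matrix(work))
    ii, jj = tree.nonzero()
    lo, hi = np.minimum(ii, jj), np.maximum(ii, jj)
    order = np.lexsort((hi, lo))
    return np.column_stack([lo[order], hi[order]])


def fisher_1d_cluster(values, n_classes: int = 2) -> np.ndarray:
    """Exact Fisher/Jenks 1-D clustering (minimal within-class SSE).

    Dynamic program over contiguous partitions of the sorted values;
    returned labels are ordered by class mean (0 = lowest).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    uniq = np.unique(values)
    if n_classes > uniq.size:
        raise ConfigurationError(
            f"{n_classes} classes requested but only {uniq.size} distinct values")
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def sse(i, j):  # cost of block x[i:j]
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / (j - i)

    inf = np.inf
    cost = np.full((n_classes + 1, n + 1), inf)
    back = np.zeros((n_classes + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, n_classes + 1):
        for j in range(k, n + 1):
            best, arg = inf, k - 1
            for i in range(k - 1, j):
                c = cost[k - 1, i] + sse(i, j)
                if c < best - 1e-15:
                    best, arg = c, i
            cost[k, j] = best
            back[k, j] = arg
    # reconstruct block boundaries
    bounds = [n]
    j = n
    for k in range(n_classes, 0, -1):
        j = back[k, j]
        bounds.append(j)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    for c in range(n_classes):
        labels_sorted[bounds[c]:bounds[c + 1]] = c
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def pmst_consensus(d: pd.DataFrame | np.ndarray, n_replicates: int = 100,
                   perturb_ratio: float = 0.2, max_rounds: int = 20,
                   seed: int = 0, n_classes: int = 2,
                   ensure_connected: bool = True) -> CellStateGraph:
    """Perturb-and-merge consensus graph over cells.

    Each round draws ``n_replicates`` perturbed MSTs from the full distance
    matrix, sums their adjacencies into occurrence counts and drops the
    lowest-occurrence Fisher class.  Convergence is declared when the
    retained edge count repeats between rounds.  If filtering disconnects
    the graph and ``ensure_connected`` is set, dropped edges are restored
    in decreasing-occurrence order until connectivity returns.
    """
    if isinstance(d, pd.DataFrame):
        cells = list(d.index)
        dm = d.values.astype(float)
    else:
        dm = np.asarray(d, dtype=float)
        cells = list(range(dm.shape[0]))
    n = dm.shape[0]
    rng = np.random.default_rng(seed)
    prev_count = -1
    converged = False
    rounds = 0
    retained = None
    occurrence = None
    for rounds in range(1, max_rounds + 1):
        counts: dict[tuple[int, int], int] = {}
        for _ in range(n_replicates):
            for i, j in perturbed_mst(dm, perturb_ratio, rng):
                counts[(int(i), int(j))] = counts.get((int(i), int(j)), 0) + 1
        pairs = list(counts)
        occ = np.array([counts[p] for p in pairs])
        if np.unique(occ).size >= n_classes:
            classes = fisher_1d_cluster(occ, n_classes)
            keep = classes > 0
        else:
            keep = np.ones(occ.size, dtype=bool)
        kept_pairs = [p for p, k in zip(pairs, keep) if k]
        kept_occ = occ[keep]
        if ensure_connected:
            kept_pairs, kept_occ = _reconnect(n, kept_pairs, kept_occ,
                                              pairs, occ)
        retained, occurrence = kept_pairs, kept_occ
        if len(kept_pairs) == prev_count:
            converged = True
            break
        prev_count = len(kept_pairs)
    edges = pd.DataFrame(
        {"cell_a": [cells[i] for i, _ in retained],
         "cell_b": [cells[j] for _, j in retained],
         "occurrence": occurrence,
         "distance": [dm[i, j] for i, j in retained]})
    return CellStateGraph(cells=cells, edges=edges, converged=converged,
                          rounds=rounds)


def _reconnect(n, kept_pairs, kept_occ, all_pairs, all_occ):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(kept_pairs)
    if nx.number_connected_components(g) == 1:
        return kept_pairs, kept_occ
    occ_of = dict(zip(all_pairs, all_occ))
    kept_set = set(kept_pairs)
    dropped = sorted((p for p in all_pairs if p not in kept_set),
                     key=lambda p: -occ_of[p])
    kept_pairs = list(kept_pairs)
    kept_occ = list(kept_occ)
    for p in dropped:
        if nx.number_connected_components(g) == 1:
            break
        i, j = p
        if nx.has_path(g, i, j):
            continue
        g.add_edge(i, j)
        kept_pairs.append(p)
        kept_occ.append(occ_of[p])
    return kept_pairs, np.asarray(kept_occ)


# ---------------------------------------------------------------------------
# Paths and pseudotime
# ---------------------------------------------------------------------------

def k_shortest_paths(g: CellStateGraph | nx.Graph, source, target,
                     k: int = 100) -> list[list]:
    """Up to K loopless shortest paths (Yen) by edge-distance weight."""
    graph = g.to_networkx() if isinstance(g, CellStateGraph) else g
    if source not in graph or target not in graph:
        raise ValueError("source/target not in graph")
    try:
        gen = nx.shortest_simple_paths(graph, source, target, weight="weight")
        return list(itertools.islice(gen, k))
    except nx.NetworkXNoPath:
        warnings.warn(f"no path between {source} and {target}", stacklevel=2)
        return []


def terminal_cells_by_identity(score: pd.Series, n: int = 12
                               ) -> tuple[list, list]:
    """Early/late terminal populations from the extremes of a fractional-
    identity score (n cells each, default 12)."""
    if 2 * n > len(score):
        raise ConfigurationError("fewer cells than requested terminals")
    ordered = score.sort_values(kind="stable")
    return list(ordered.index[:n]), list(ordered.index[-n:])


def terminal_cells_by_cluster(labels: pd.Series, early_label, late_label,
                              n: int | None = None) -> tuple[list, list]:
    """Early/late terminal populations from cell-cluster labels (optionally
    capped at the first n members per population)."""
    early = list(labels.index[labels == early_label])
    late = list(labels.index[labels == late_label])
    if not early or not late:
        raise ConfigurationError("empty terminal population")
    if n is not None:
        early, late = early[:n], late[:n]
    return early, late


def paths_between_populations(g: CellStateGraph, early, late, k: int = 100
                              ) -> list[list]:
    """All K-shortest paths for each (early, late) cell pair."""
    early, late = list(early), list(late)
    if set(early) & set(late):
        raise ConfigurationError("early and late populations must be disjoint")
    paths = []
    for s in early:
        for t in late:
            paths.extend(k_shortest_paths(g, s, t, k))
    return paths


def _loess_smooth(y: np.ndarray, span: float = 0.5) -> np.ndarray:
    """Local quadratic regression with tricube weights over a span fraction."""
    n = y.size
    x = np.arange(n, dtype=float)
    q = max(int(np.ceil(span * n)), 3)
    out = np.empty(n)
    for i in range(n):
        dist = np.abs(x - x[i])
        idx = np.argsort(dist, kind="stable")[:q]
        dmax = dist[idx].max()
        w = (1 - (dist[idx] / max(dmax, 1e-12)) ** 3) ** 3
        X = np.column_stack([np.ones(q), x[idx] - x[i], (x[idx] - x[i]) ** 2])
        W = np.sqrt(np.clip(w, 0, None))
        beta, *_ = np.linalg.lstsq(X * W[:, None], y[idx] * W, rcond=None)
        out[i] = beta[0]
    return out


def pseudotime_profiles(paths: list[list], m: ExpressionMatrix,
                        genes=None, n_bins: int = 50,
                        loess_span: float = 0.5) -> PseudotimeProfile:
    """Average gene expression along paths, rebinned by cell rank.

    Each path's cells map to ``n_bins`` pseudotime bins according to their
    rank along the path (no interpolation); per-gene bin averages over all
    paths are then loess-smoothed.
    """
    genes = pd.Index(genes) if genes is not None else m.genes
    vals = m.values.loc[genes]
    sums = np.zeros((len(genes), n_bins))
    counts = np.zeros(n_bins)
    used = 0
    for path in paths:
        if len(path) < 2:
            warnings.warn("skipping path with fewer than 2 cells", stacklevel=2)
            continue
        ranks = np.arange(len(path))
        bins = np.round(ranks / (len(path) - 1) * (n_bins - 1)).astype(int)
        pv = vals[list(path)].values  # genes x path cells
        for b, col in zip(bins, pv.T):
            sums[:, b] += col
            counts[b] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable paths")
    with np.errstate(invalid="ignore"):
        raw = sums / counts
    # fill bins never hit (possible for short paths) by linear interpolation
    for g in range(raw.shape[0]):
        row = raw[g]
        bad = ~np.isfinite(row)
        if bad.any():
            row[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(~bad),
                                 row[~bad])
    smooth = np.vstack([_loess_smooth(raw[g], loess_span)
                        for g in range(raw.shape[0])])
    idx = pd.Index(range(n_bins), name="bin")
    return PseudotimeProfile(
        profiles=pd.DataFrame(smooth, index=genes, columns=idx),
        raw_profiles=pd.DataFrame(raw, index=genes, columns=idx),
        n_bins=n_bins, n_paths=used)


def fractional_identity(m: ExpressionMatrix, decreasing_genes,
                        increasing_genes) -> pd.Series:
    """Signed linear combination of min-max-normalised marker levels in [0,1].

    Genes expected to fall along the trajectory enter with weight -1,
    rising genes with +1; the combined score is affinely rescaled across
    cells to [0, 1].  Constant genes are dropped with a warning.
    """
    dec, inc = list(decreasing_genes), list(increasing_genes)
    if set(dec) & set(inc):
        raise ConfigurationError("gene sets must be disjoint")
    if not dec and not inc:
        raise ConfigurationError("no marker genes given")
    score = np.zeros(m.shape[1])
    for gene_set, sign in ((inc, 1.0), (dec, -1.0)):
        for g in gene_set:
            v = m.values.loc[g].values.astype(float)
            rng_v = v.max() - v.min()
            if rng_v == 0:
                warnings.warn(f"constant gene {g!r} dropped", stacklevel=2)
                continue
            score += sign * (v - v.min()) / rng_v
    span = score.max() - score.min()
    if span == 0:
        return pd.Series(0.5, index=m.cells, name="fractional_identity")
    return pd.Series((score - score.min()) / span, index=m.cells,
                     name="fractional_identity")
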