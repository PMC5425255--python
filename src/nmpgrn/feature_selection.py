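"""Feature selection by mutual information over Bayesian-Blocks bins.

Each gene's expression distribution is discretised with the Bayesian
Blocks change-point dynamic program (events fitness, geometric prior with
false-alarm probability p0).  Pairwise mutual information between the
discretised genes (plug-in estimator, natural log) then defines a
co-expression network; a gene is selected when it exceeds the MI threshold
with at least ``min_partners`` distinct partners.

A binned dispersion z-score (variance/mean, z-normalised within 20
equal-frequency mean-expression bins) is provided to verify that selected
genes indeed vary more than their expression-matched peers.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .containers import ExpressionMatrix
from .errors import ConfigurationError


@dataclasses.dataclass
class DiscretizedGene:
    gene: str
    edges: np.ndarray   # strictly increasing bin edges, len = n_bins + 1
    labels: np.ndarray  # per-cell bin index

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1


@dataclasses.dataclass
class MINetwork:
    mi: pd.DataFrame          # symmetric gene x gene MI (nats)
    threshold: float
    min_partners: int
    selected: list[str]

    def edge_list(self) -> pd.DataFrame:
        genes = self.mi.index
        rows = [(a, b, self.mi.loc[a, b])
                for a, b in itertools.combinations(genes, 2)]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi"])

    def write_edges(self, path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)

    def write_selected(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.selected) + ("\n" if self.selected else ""))


def bayesian_blocks_edges(values: np.ndarray, p0: float = 0.05) -> np.ndarray:
    """Optimal change-point bin edges for a 1-D sample (events fitness).

    Dynamic program over the Voronoi cells of the sorted unique values;
    block fitness is N (log N - log T) with N the points and T the width of
    the block, penalised by the standard geometric prior
    ncp = 4 - log(73.53 p0 n^-0.478).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least two finite values")
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size == 1:
        return np.array([uniq[0] - 0.5, uniq[0] + 0.5])
    n_tot = values.size
    m = uniq.size
    # cell edges: midpoints, extended by half the end gaps
    mid = 0.5 * (uniq[1:] + uniq[:-1])
    edges = np.concatenate([[uniq[0] - 0.5 * (uniq[1] - uniq[0])], mid,
                            [uniq[-1] + 0.5 * (uniq[-1] - uniq[-2])]])
    block_len = edges[-1] - edges  # width from edge k to the end
    ncp_prior = 4.0 - np.log(73.53 * p0 * n_tot ** -0.478)

    best = np.zeros(m)
    last = np.zeros(m, dtype=int)
    cum = np.concatenate([[0], np.cumsum(counts)]).astype(float)
    for k in range(m):
        widths = block_len[: k + 1] - block_len[k + 1]
        n_in = cum[k + 1] - cum[: k + 1]
        fit = n_in * (np.log(n_in) - np.log(widths)) - ncp_prior
        fit[1:] += best[:k]
        idx = int(np.argmax(fit))
        best[k] = fit[idx]
        last[k] = idx
    change_points = []
    k = m
    while k > 0:
        change_points.append(last[k - 1])
        k = last[k - 1]
    change_points = np.array(change_points[::-1], dtype=int)
    return np.concatenate([edges[change_points], [edges[-1]]])


def bayesian_blocks_discretize(values, gene: str = "", p0: float = 0.05
                               ) -> DiscretizedGene:
    """Discretise a gene's values into Bayesian-Blocks bins.

    Labels by edge membership: half-open bins, last bin closed.  A constant
    vector yields a single bin (all labels 0), not an error.
    """
    values = np.asarray(values, dtype=float)
    edges = bayesian_blocks_edges(values, p0=p0)
    labels = np.clip(np.searchsorted(edges, values, side="right") - 1, 0,
                     edges.size - 2)
    return DiscretizedGene(gene=gene, edges=edges, labels=labels.astype(int))


def mutual_information(a: DiscretizedGene, b: DiscretizedGene) -> float:
    """Plug-in MI (nats): H(a) + H(b) - H(a,b) from empirical frequencies."""
    if a.labels.size != b.labels.size:
        raise ValueError("discretised genes cover different cell sets")
    return float(mutual_info_score(a.labels, b.labels))


def select_genes_by_mi(m: ExpressionMatrix, threshold: float = 0.25,
                       min_partners: int = 2, p0: float = 0.05,
                       min_mean: float | None = None) -> MINetwork:
    """Retain genes with MI > threshold (strict) to >= min_partners others.

    ``min_mean`` (off by default) prefilters genes by mean expression to
    bound the O(G^2) pair cost on large matrices.
    """
    m.require_layer("cpm", "log_cpm")
    if min_mean is not None:
        m = m.subset_genes(m.genes[m.values.mean(axis=1) >= min_mean])
    if m.shape[0] < 3:
        raise ValueError("need at least 3 genes for MI selection")
    disc = [bayesian_blocks_discretize(m.values.loc[g].values, gene=g, p0=p0)
            for g in m.genes]
    n = len(disc)
    mi = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mi[i, j] = mi[j, i] = mutual_information(disc[i], disc[j])
    mi_df = pd.DataFrame(mi, index=m.genes, columns=m.genes)
    partners = (mi > threshold).sum(axis=1)
    selected = list(m.genes[partners >= min_partners])
    return MINetwork(mi=mi_df, threshold=threshold, min_partners=min_partners,
                     selected=selected)


def dispersion_zscore(m: ExpressionMatrix, n_bins: int = 20) -> pd.Series:
    """Variance/mean dispersion, z-scored within mean-expression bins.

    Genes are assigned to ``n_bins`` equal-frequency bins of mean
    expression (ties broken by gene order) and the dispersion is
    z-normalised within each bin.
    """
    if m.shape[0] < n_bins:
        raise ValueError(f"need at least {n_bins} genes")
    means = m.values.mean(axis=1)
    var = m.values.var(axis=1, ddof=0)
    disp = np.zeros(len(means))
    nonzero = means.values > 0
    disp[nonzero] = var.values[nonzero] / means.values[nonzero]
    if (~nonzero).any():
        warnings.warn("zero-mean gene(s): dispersion set to 0", stacklevel=2)
    order = np.lexsort((np.arange(len(means)), means.values))
    bin_of = np.empty(len(means), dtype=int)
    bin_of[order] = np.floor(np.arange(len(means)) * n_bins / len(means)).astype(int)
    z = np.zeros(len(means))
    for b in range(n_bins):
        in_bin = bin_of == b
        if not in_bin.any():
            continue
        mu = disp[in_bin].mean()
        sd = disp[in_bin].std(ddof=0)
        z[in_bin] = 0.0 if sd == 0 else (disp[in_bin] - mu) / sd
    return pd.Series(z, index=m.genes, name="dispersion_z")


def top_dispersed_genes(z: pd.Series, k: int = 168) -> list[str]:
    """The k genes with the highest binned dispersion z-score."""
    if k <= 0:
        raise ConfigurationError("k must be positive")
    return list(z.sort_values(ascending=False).index[:k])
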