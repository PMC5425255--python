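"""Gene modules, cell populations, module activity and Tobit DE testing.

Gene modules come from hierarchical clustering (Ward criterion) of the
1 - Spearman-rho distance between genes; cell populations from the same
linkage over cell-cell Spearman distances of z-scored levels.  Differential
expression uses a likelihood-ratio test between left-censored Gaussian
(Tobit) fits: a common-mean null against group-specific means with a shared
scale, with the statistic referred to a chi-square with one degree of
freedom.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.optimize
import scipy.spatial.distance as ssd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import ConfigurationError


@dataclasses.dataclass
class GeneModuleSet:
    modules: dict[str, list[str]]  # ordered, pairwise disjoint
    mode: str
    params: dict

    def __post_init__(self):
        seen: set[str] = set()
        for name, genes in self.modules.items():
            dup = seen.intersection(genes)
            if dup:
                raise ValueError(f"modules overlap on {sorted(dup)[:5]}")
            seen.update(genes)

    def __len__(self) -> int:
        return len(self.modules)

    def write_tsv(self, path) -> None:
        rows = [(name, gene) for name, genes in self.modules.items()
                for gene in genes]
        pd.DataFrame(rows, columns=["module", "gene"]).to_csv(
            path, sep="\t", index=False)


@dataclasses.dataclass
class DEResult:
    table: pd.DataFrame  # index gene; columns lrt, df, p, converged
    detection_limit: float

    def significant(self, alpha: float = 5e-5) -> list[str]:
        return list(self.table.index[self.table["p"] < alpha])


# ---------------------------------------------------------------------------
# Correlation and clustering
# ---------------------------------------------------------------------------

def spearman_correlation_matrix(m: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """Symmetric gene x gene Spearman correlation (average ranks for ties).

    Constant genes get correlation 0 with everything (diagonal stays 1),
    with a warning.
    """
    genes = pd.Index(genes) if genes is not None else m.genes
    if len(genes) < 2 or m.shape[1] < 3:
        raise ValueError("need >= 2 genes and >= 3 cells")
    vals = m.values.loc[genes].values
    constant = vals.std(axis=1) == 0
    ranks = pd.DataFrame(vals.T).rank().values  # cells x genes, average ranks
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    if constant.any():
        warnings.warn(f"{constant.sum()} constant gene(s): correlation set to 0",
                      stacklevel=2)
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


def _ward_linkage_from_corr(corr: np.ndarray) -> np.ndarray:
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    return sch.linkage(ssd.squareform(dist, checks=False), method="ward")


def cluster_gene_modules(corr: pd.DataFrame, mode: str = "in_vivo",
                         n_modules: int = 5, n_initial: int = 300,
                         min_size: int = 4) -> GeneModuleSet:
    """Cut the gene dendrogram into modules.

    ``in_vivo`` mode cuts to exactly ``n_modules`` clusters; ``in_vitro``
    mode cuts to ``n_initial`` fine-grained clusters and retains those with
    at least ``min_size`` genes.
    """
    genes = corr.index
    if mode not in ("in_vivo", "in_vitro"):
        raise ConfigurationError("mode must be in_vivo or in_vitro")
    target = n_modules if mode == "in_vivo" else n_initial
    if target > len(genes):
        raise ConfigurationError(f"requested {target} modules from "
                                 f"{len(genes)} genes")
    link = _ward_linkage_from_corr(corr.values.astype(float))
    labels = sch.fcluster(link, t=target, criterion="maxclust")
    modules: dict[str, list[str]] = {}
    for lab in sorted(set(labels)):
        members = list(genes[labels == lab])
        if mode == "in_vitro" and len(members) < min_size:
            continue
        modules[f"module_{len(modules) + 1}"] = members
    if mode == "in_vitro" and not modules:
        warnings.warn("no module reached min_size; empty module set",
                      stacklevel=2)
    params = {"mode": mode, "n_modules": n_modules, "n_initial": n_initial,
              "min_size": min_size}
    return GeneModuleSet(modules=modules, mode=mode, params=params)


def cluster_cells(m: ExpressionMatrix, genes, n_clusters: int) -> pd.Series:
    """Ward clustering of cells on 1 - Spearman rho of z-scored gene levels."""
    genes = pd.Index(genes)
    if n_clusters > m.shape[1]:
        raise ConfigurationError("more clusters than cells")
    vals = m.values.loc[genes].values.astype(float)
    sd = vals.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    ranks = pd.DataFrame(z).rank().values  # rank each gene... cells are columns
    corr = np.corrcoef(ranks, rowvar=False)  # cell x cell over genes
    link = _ward_linkage_from_corr(corr)
    labels = sch.fcluster(link, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=m.cells, name="cluster")


def module_activity_scores(m: ExpressionMatrix, modules: GeneModuleSet
                           ) -> pd.DataFrame:
    """Cells x modules activity: per-cell module mean, z by module, z by cell."""
    if len(modules) == 0:
        raise ValueError("empty module set")
    cols = {}
    for name, genes in modules.modules.items():
        present = [g for g in genes if g in m.genes]
        if not present:
            raise ValueError(f"module {name!r} has no measured genes")
        cols[name] = m.values.loc[present].mean(axis=0)
    scores = pd.DataFrame(cols)  # cells x modules
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=0).replace(0, 1)
    row_sd = scores.std(axis=1, ddof=0)
    centered = scores.sub(scores.mean(axis=1), axis=0)
    if len(modules) == 1:
        return centered * 0.0  # z of a single value is defined as 0
    return centered.div(row_sd.replace(0, 1), axis=0)


# ---------------------------------------------------------------------------
# Tobit likelihood-ratio differential expression
# ---------------------------------------------------------------------------

def _tobit_negll_grad(mu: np.ndarray, log_sigma: float, y: np.ndarray,
                      censored: np.ndarray, limit: float
                      ) -> tuple[float, np.ndarray, float]:
    """Negative log-likelihood and its gradient wrt (per-obs mu, log sigma).

    Returns (negll, dnegll/dmu per observation, dnegll/dlog_sigma).
    """
    sigma = np.exp(log_sigma)
    ll = 0.0
    dmu = np.zeros_like(y)
    dls = 0.0
    unc = ~censored
    if unc.any():
        z = (y[unc] - mu[unc]) / sigma
        ll += np.sum(-0.5 * np.log(2 * np.pi) - log_sigma - 0.5 * z ** 2)
        dmu[unc] = z / sigma
        dls += np.sum(z ** 2 - 1.0)
    if censored.any():
        a = (limit - mu[censored]) / sigma
        ll += np.sum(stats.norm.logcdf(a))
        ratio = np.exp(stats.norm.logpdf(a) - stats.norm.logcdf(a))
        dmu[censored] = -ratio / sigma
        dls += np.sum(-ratio * a)
    return -ll, -dmu, -dls


def _fit_tobit(y: np.ndarray, groups: np.ndarray | None, limit: float
               ) -> tuple[float, bool]:
    """Maximum log-likelihood of the Tobit model; groups=None -> common mean."""
    censored = y <= limit
    if censored.all():
        # degenerate: all values at the limit; likelihood is flat in mu << limit
        return 0.0, False
    obs = y[~censored]
    mu0 = float(obs.mean())
    sd0 = float(max(obs.std(ddof=0), 1e-3))

    if groups is None:
        def negll(theta):
            f, dmu, dls = _tobit_negll_grad(np.full_like(y, theta[0]),
                                            theta[1], y, censored, limit)
            return f, np.array([dmu.sum(), dls])
        x0 = np.array([mu0, np.log(sd0)])
    else:
        def negll(theta):
            mu = np.where(groups, theta[1], theta[0])
            f, dmu, dls = _tobit_negll_grad(mu, theta[2], y, censored, limit)
            return f, np.array([dmu[~groups].sum(), dmu[groups].sum(), dls])
        x0 = np.array([mu0, mu0, np.log(sd0)])
    res = scipy.optimize.minimize(negll, x0, jac=True, method="L-BFGS-B",
                                  options={"maxiter": 500, "ftol": 1e-12})
    if not res.success:  # rare; retry with a derivative-free pass
        res2 = scipy.optimize.minimize(lambda th: negll(th)[0], x0,
                                       method="Nelder-Mead",
                                       options={"xatol": 1e-6, "fatol": 1e-9,
                                                "maxiter": 2000})
        return -float(res2.fun), bool(res2.success)
    return -float(res.fun), True


def tobit_lrt_de(m: ExpressionMatrix, labels, detection_limit: float = 0.0
                 ) -> DEResult:
    """Per-gene LRT between group-specific-mean and common-mean Tobit fits.

    ``labels`` is a two-group partition over the cells (any two distinct
    values).  Values at or below ``detection_limit`` are treated as
    left-censored.  The statistic 2(l_alt - l_null) is referred to
    chi-square with df = 1; non-convergent fits are flagged and given
    p = 1 (conservative).
    """
    labels = pd.Series(labels, index=m.cells) if not isinstance(labels, pd.Series) else labels
    uniq = labels.unique()
    if len(uniq) != 2:
        raise ConfigurationError("labels must define exactly two groups")
    grp = (labels == uniq[1]).values
    if grp.sum() < 3 or (~grp).sum() < 3:
        raise ConfigurationError("both groups need >= 3 cells")
    rows = []
    for g in m.genes:
        y = m.values.loc[g].values.astype(float)
        ll_null, ok0 = _fit_tobit(y, None, detection_limit)
        ll_alt, ok1 = _fit_tobit(y, grp, detection_limit)
        converged = ok0 and ok1
        lrt = max(2.0 * (ll_alt - ll_null), 0.0)
        p = float(stats.chi2.sf(lrt, df=1)) if converged else 1.0
        rows.append((lrt if converged else 0.0, 1, p, converged))
    table = pd.DataFrame(rows, index=m.genes,
                         columns=["lrt", "df", "p", "converged"])
    return DEResult(table=table, detection_limit=detection_limit)
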