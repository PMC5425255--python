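"""Exhaustive signed-topology search for the three-factor circuit.

All 2^6 = 64 sign assignments of the TF->TF edges are fitted to a
six-experiment objective (three wild-type signalling conditions, one Bra
mutant, two Msgn1/Tbx6 mutants) by restarted differential evolution over
the six binding affinities, searched in log10 space within [0.01, 1000].
Restart-best solutions are clustered with Gaussian mixtures (BIC-selected
component count); a topology's score is the mean score of its best cluster
with at least four members.

The target time-point table is a package convention encoding the
qualitative endpoint behaviour of each experiment (targets live on the
per-gene max-scaled [0, 1] axis used by the distance function).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import differential_evolution
from sklearn.mixture import GaussianMixture

from . import grn_model
from .errors import ConfigurationError
from .grn_model import (SPECIES, RegulatoryTopology, _alpha_vector,
                        _integrate_rk4, get_schedule)

LOG10_BOUNDS = (-2.0, 3.0)


@dataclasses.dataclass
class Experiment:
    name: str
    condition: str
    mutant: str
    targets: list[tuple[float, str, float]]  # (time, gene, level in [0,1])

    def __post_init__(self):
        for t, gene, level in self.targets:
            if gene not in SPECIES:
                raise ConfigurationError(f"unknown gene {gene!r}")
            if not 0.0 <= level <= 1.0:
                raise ConfigurationError("target levels must lie in [0,1]")
            if not 0.0 <= t <= grn_model.T_END:
                raise ConfigurationError("target times must lie in the window")


@dataclasses.dataclass
class ObjectiveSet:
    experiments: list[Experiment]

    def __post_init__(self):
        if len(self.experiments) == 0:
            raise ConfigurationError("need at least one experiment")


def default_objectives() -> ObjectiveSet:
    """Six-experiment target table (D3 = t 1, D4 = t 2, D5 = t 3).

    Encodes: a transient NMP-like Bra/Sox2 co-expression state at D3 that
    resolves to mesoderm under sustained Wnt, to neural under RA, stays
    anterior-neural under basal signals; no mesoderm without Bra; persistent
    NMP state without Msgn1/Tbx6 under Wnt and delayed Bra decay without it
    after Wnt withdrawal.
    """
    d3_nmp = [(1.0, "Bra", 0.8), (1.0, "Sox2", 0.4), (1.0, "MsgnTbx6", 0.1)]
    return ObjectiveSet([
        Experiment("wt_mesodermal", "mesodermal", "none",
                   d3_nmp + [(3.0, "Bra", 0.1), (3.0, "Sox2", 0.1),
                             (3.0, "MsgnTbx6", 0.8)]),
        Experiment("wt_neural1", "neural1", "none",
                   d3_nmp + [(3.0, "Sox2", 0.8), (3.0, "Bra", 0.05),
                             (3.0, "MsgnTbx6", 0.05)]),
        Experiment("wt_anterior", "anterior", "none",
                   [(1.0, "Sox2", 0.8), (1.0, "Bra", 0.05),
                    (1.0, "MsgnTbx6", 0.05),
                    (3.0, "Sox2", 0.8), (3.0, "Bra", 0.05),
                    (3.0, "MsgnTbx6", 0.05)]),
        Experiment("bra_mut_mesodermal", "mesodermal", "bra",
                   [(3.0, "MsgnTbx6", 0.05), (3.0, "Sox2", 0.8)]),
        Experiment("msgn_mut_mesodermal", "mesodermal", "msgntbx6",
                   [(3.0, "Bra", 0.8), (3.0, "Sox2", 0.4)]),
        Experiment("msgn_mut_neural2", "neural2", "msgntbx6",
                   [(2.0, "Bra", 0.5), (3.0, "Bra", 0.2), (3.0, "Sox2", 0.7)]),
    ])


# ---------------------------------------------------------------------------
# Packed fast objective
# ---------------------------------------------------------------------------

@njit(cache=False, fastmath=True)
def _objective_core(kvec, act, alphas, ra_steps, wnt_steps, dt,
                    tgt_exp, tgt_step, tgt_gene, tgt_level, n_exp):
    kmat = np.zeros((3, 3))
    reg = np.array([2, 0, 1, 2, 1, 0])
    tgt = np.array([1, 1, 0, 0, 2, 2])
    for e in range(6):
        kmat[reg[e], tgt[e]] = kvec[e]
    n_steps = ra_steps.shape[1]
    x0 = np.array([0.8, 0.001, 0.001])
    trajs = np.empty((n_exp, n_steps + 1, 3))
    for e in range(n_exp):
        trajs[e] = _integrate_rk4(x0, kmat, act, alphas[e], ra_steps[e],
                                  wnt_steps[e], dt)
    gene_max = np.full(3, 1e-9)
    for e in range(n_exp):
        for s in range(n_steps + 1):
            for j in range(3):
                if trajs[e, s, j] > gene_max[j]:
                    gene_max[j] = trajs[e, s, j]
    sums = np.zeros(n_exp)
    counts = np.zeros(n_exp)
    for i in range(tgt_exp.size):
        e = tgt_exp[i]
        sim = trajs[e, tgt_step[i], tgt_gene[i]] / gene_max[tgt_gene[i]]
        sums[e] += abs(sim - tgt_level[i])
        counts[e] += 1.0
    total = 0.0
    for e in range(n_exp):
        if counts[e] > 0:
            total += sums[e] / counts[e]
    return total


class _PackedObjective:
    """Experiment schedules, mutants and targets packed for the jitted core."""

    def __init__(self, objectives: ObjectiveSet, dt: float = 0.005):
        self.dt = dt
        n_exp = len(objectives.experiments)
        n_steps = int(round(grn_model.T_END / dt))
        self.alphas = np.empty((n_exp, 3))
        self.ra = np.empty((n_exp, n_steps))
        self.wnt = np.empty((n_exp, n_steps))
        t_e, t_s, t_g, t_l = [], [], [], []
        for e, exp in enumerate(objectives.experiments):
            self.alphas[e] = _alpha_vector(exp.mutant)
            sched = get_schedule(exp.condition)
            self.ra[e], self.wnt[e] = sched.per_step(dt)
            for (t, gene, level) in exp.targets:
                t_e.append(e)
                t_s.append(int(round(t / dt)))
                t_g.append(SPECIES.index(gene))
                t_l.append(level)
        self.tgt_exp = np.array(t_e, dtype=np.int64)
        self.tgt_step = np.array(t_s, dtype=np.int64)
        self.tgt_gene = np.array(t_g, dtype=np.int64)
        self.tgt_level = np.array(t_l, dtype=np.float64)
        self.n_exp = n_exp

    def __call__(self, kvec: np.ndarray, act: np.ndarray) -> float:
        return float(_objective_core(
            np.asarray(kvec, dtype=float), act, self.alphas, self.ra,
            self.wnt, self.dt, self.tgt_exp, self.tgt_step, self.tgt_gene,
            self.tgt_level, self.n_exp))


def objective_distance(topology: RegulatoryTopology, params,
                       objectives: ObjectiveSet, dt: float = 0.005) -> float:
    """Six-experiment distance: per-gene max-scaled mean absolute target error.

    Trajectories of each gene are divided by that gene's maximum over all
    experiments before comparison; per-experiment scores (mean absolute
    difference at the target points) are summed.
    """
    packed = _PackedObjective(objectives, dt)
    k = np.asarray(params.k if hasattr(params, "k") else params, dtype=float)
    try:
        return packed(k, topology.activator_matrix())
    except Exception:
        return float("inf")


def enumerate_topologies() -> list[RegulatoryTopology]:
    """All 64 sign assignments of the six TF->TF edges, in id order."""
    return [RegulatoryTopology.from_id(i) for i in range(64)]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FitResult:
    topology: RegulatoryTopology
    restarts: pd.DataFrame          # columns: score, k1..k6 (linear scale)
    clusters: list[dict] | None = None
    score: float | None = None      # mean score of the best retained cluster
    resolved: bool | None = None

    @property
    def best_score(self) -> float:
        return float(self.restarts["score"].min())


def _restart_rng(seed: int, topology_id: int, restart: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, topology_id, restart]))


def fit_topology(topology: RegulatoryTopology, objectives: ObjectiveSet,
                 n_restarts: int = 30, seed: int = 0, maxiter: int = 300,
                 popsize: int = 15, tol: float = 1e-8,
                 dt: float = 0.005, polish: bool = True) -> FitResult:
    """Restarted differential evolution over log10 affinities in [-2, 3].

    Restart RNG streams derive from (seed, topology id, restart index), so
    results are independent of execution order and parallel scheduling.
    """
    packed = _PackedObjective(objectives, dt)
    act = topology.activator_matrix()

    def func(logk):
        return packed(10.0 ** np.asarray(logk), act)

    rows = []
    for r in range(n_restarts):
        rng = _restart_rng(seed, topology.id, r)
        res = differential_evolution(
            func, bounds=[LOG10_BOUNDS] * 6, strategy="best1bin",
            maxiter=maxiter, popsize=popsize, tol=tol, seed=rng,
            polish=polish, init="latinhypercube")
        rows.append([float(res.fun)] + list(10.0 ** res.x))
    restarts = pd.DataFrame(rows, columns=["score"] + [f"k{i+1}" for i in range(6)])
    return FitResult(topology=topology, restarts=restarts)


def cluster_solutions(result: FitResult, max_components: int = 5,
                      min_cluster_size: int = 4, seed: int = 0) -> FitResult:
    """Cluster restart-best parameter vectors with a BIC-selected GMM.

    Clustering runs on log10 parameters; clusters with at least
    ``min_cluster_size`` members are retained and the topology score is the
    mean score of the retained cluster with the lowest mean score.  Without
    any retained cluster the topology is flagged unresolved and scored by
    the mean over all restarts.
    """
    if len(result.restarts) < 2:
        raise ConfigurationError("need at least 2 restarts to cluster")
    logk = np.log10(result.restarts[[f"k{i+1}" for i in range(6)]].values)
    scores = result.restarts["score"].values
    n = logk.shape[0]
    best_bic, best_labels, best_k = np.inf, np.zeros(n, dtype=int), 1
    for k in range(1, min(max_components, n) + 1):
        # diagonal covariance: with ~30 restarts in 6-D a full covariance
        # (27 params/component) overfits and BIC degenerates to max components
        gmm = GaussianMixture(n_components=k, covariance_type="diag",
                              random_state=seed, n_init=3, reg_covar=1e-6)
        labels = gmm.fit_predict(logk)
        bic = gmm.bic(logk)
        if bic < best_bic:
            best_bic, best_labels, best_k = bic, labels, k
    clusters = []
    for c in range(best_k):
        members = np.flatnonzero(best_labels == c)
        clusters.append({
            "members": members,
            "size": int(members.size),
            "mean_score": float(scores[members].mean()),
            "mean_log10_k": logk[members].mean(axis=0),
            "retained": bool(members.size >= min_cluster_size),
        })
    retained = [c for c in clusters if c["retained"]]
    if retained:
        best = min(retained, key=lambda c: c["mean_score"])
        score, resolved = best["mean_score"], True
    else:
        score, resolved = float(scores.mean()), False
    return dataclasses.replace(result, clusters=clusters, score=score,
                               resolved=resolved)


def rank_topologies(objectives: ObjectiveSet | None = None,
                    n_restarts: int = 30, seed: int = 0, maxiter: int = 300,
                    popsize: int = 15, dt: float = 0.005,
                    min_cluster_size: int | str = "auto",
                    topology_ids=None) -> pd.DataFrame:
    """Fit every topology and return the scoreboard, sorted ascending.

    Results depend only on (seed, topology id, restart index), never on
    execution order.  ``min_cluster_size="auto"`` scales the 4-of-30
    cluster-retention rule proportionally with the restart budget, so that
    scaled-down rankings score each topology by its best coherent solution
    group instead of a mean polluted by local-optimum captures.
    """
    objectives = objectives or default_objectives()
    if min_cluster_size == "auto":
        min_cluster_size = max(1, round(4 * n_restarts / 30))
    ids = list(topology_ids) if topology_ids is not None else list(range(64))
    rows = []
    for tid in ids:
        topo = RegulatoryTopology.from_id(tid)
        fit = fit_topology(topo, objectives, n_restarts=n_restarts, seed=seed,
                           maxiter=maxiter, popsize=popsize, dt=dt)
        fit = cluster_solutions(fit, min_cluster_size=min_cluster_size,
                                seed=seed)
        best_cluster = min((c for c in fit.clusters if c["retained"]),
                           key=lambda c: c["mean_score"], default=None)
        mean_k = (10.0 ** best_cluster["mean_log10_k"]
                  if best_cluster is not None else
                  fit.restarts[[f"k{i+1}" for i in range(6)]].mean().values)
        sign_vec = "".join("A" if a else "R" for a in topo.activator)
        rows.append([tid, sign_vec, fit.score, fit.resolved,
                     sum(c["retained"] for c in fit.clusters),
                     fit.best_score] + list(mean_k))
    board = pd.DataFrame(rows, columns=(
        ["topology_id", "sign_vector", "score", "resolved", "n_retained",
         "best_restart_score"] + [f"k{i+1}" for i in range(6)]))
    return board.sort_values("score").reset_index(drop=True)


def count_top_separated(scores, max_top: int = 8, gap_factor: float = 3.0) -> int:
    """Size of the clearly separated top-scoring group.

    Scans the sorted scores from the best downwards and ends the leading
    group at the first consecutive gap exceeding ``gap_factor`` times the
    median adjacent gap among the ``max_top`` best (falling back to the
    largest gap when no gap is that pronounced).
    """
    s = np.sort(np.asarray(scores, dtype=float))
    if s.size < 2:
        return s.size
    gaps = np.diff(s[:max_top])
    cut = gap_factor * float(np.median(gaps))
    for i, gapx in enumerate(gaps):
        if gapx > cut:
            return i + 1
    return int(np.argmax(gaps)) + 1
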