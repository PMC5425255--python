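"""Synthetic inputs for every pipeline stage.

Three generators:

* a bifurcating single-cell count matrix (NMP trunk splitting into a
  mesodermal and a neural branch) with negative-binomial noise, per-cell
  library-size variation and dropout;
* three-colour cytometry event tables drawn from four log-normal
  populations plus configurable debris and doublet contamination;
* trajectory ensembles produced by the circuit model itself, for
  topology- and fate-recovery tests.

Ground truth (branch labels, latent pseudotime, gene programs, population
labels) is returned in sidecar tables, never embedded in the data, so that
pipeline tests cannot leak it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import grn_model
from .containers import ExpressionMatrix
from .errors import ConfigurationError

PROGRAMS = ("nmp", "mesoderm", "neural", "housekeeping")
BRANCHES = ("nmp", "meso_branch", "neural_branch")


@dataclasses.dataclass
class BranchingSpec:
    """Configuration of the bifurcating count-matrix generator.

    Program mean curves along latent pseudotime are logistic ramps
    (midpoint 0.5, steepness ``ramp_steepness``): the NMP program decays
    along both branches, the mesodermal / neural programs rise only on
    their own branch, housekeeping genes stay flat.
    """

    n_cells_per_branch: int = 200
    n_genes: int = 200
    program_sizes: dict = dataclasses.field(
        default_factory=lambda: {"nmp": 50, "mesoderm": 50, "neural": 50,
                                 "housekeeping": 50})
    nb_dispersion: float = 0.1
    dropout_rate: float = 0.2
    library_size_mean: float = 1e6
    library_size_cv: float = 0.1
    ramp_steepness: float = 10.0
    baseline_fraction: float = 0.02  # off-state mean relative to the gene max
    seed: int = 0

    def __post_init__(self):
        # coerce YAML/JSON-borne scalars (e.g. "2.0e4") to numbers
        self.n_cells_per_branch = int(self.n_cells_per_branch)
        self.n_genes = int(self.n_genes)
        self.nb_dispersion = float(self.nb_dispersion)
        self.dropout_rate = float(self.dropout_rate)
        self.library_size_mean = float(self.library_size_mean)
        self.library_size_cv = float(self.library_size_cv)
        self.ramp_steepness = float(self.ramp_steepness)
        self.program_sizes = {k: int(v) for k, v in self.program_sizes.items()}
        if self.n_cells_per_branch <= 0 or self.n_genes <= 0:
            raise ConfigurationError("cell and gene counts must be positive")
        unknown = set(self.program_sizes) - set(PROGRAMS)
        if unknown:
            raise ConfigurationError(f"unknown programs: {sorted(unknown)}")
        if any(v < 0 for v in self.program_sizes.values()):
            raise ConfigurationError("program sizes must be >= 0")
        if sum(self.program_sizes.values()) > self.n_genes:
            raise ConfigurationError("program sizes exceed n_genes")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.library_size_mean <= 0:
            raise ConfigurationError("library_size_mean must be > 0")


@dataclasses.dataclass
class SyntheticTruth:
    """Sidecar ground truth for a generated branching matrix."""

    cells: pd.DataFrame    # columns: branch, pseudotime
    genes: pd.DataFrame    # columns: program, max_mean
    expected_counts: pd.DataFrame  # genes x cells expected count (pre-dropout)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "truth_cells.tsv", sep="\t")
        self.genes.to_csv(out / "truth_genes.tsv", sep="\t")


def _logistic(t: np.ndarray, steepness: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-steepness * (t - 0.5)))


def simulate_branching_counts(spec: BranchingSpec
                              ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a genes x cells count matrix with a known bifurcation.

    Cells carry one of three labels: ``nmp`` (trunk, latent pseudotime in
    [0, 0.5)) or ``meso_branch`` / ``neural_branch`` (pseudotime in
    [0.5, 1]).  Counts are negative-binomial around library-scaled program
    means and then thinned by independent Bernoulli dropout.  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_b = spec.n_cells_per_branch

    branches = np.repeat(BRANCHES, n_b)
    t = np.empty(branches.size)
    t[branches == "nmp"] = rng.uniform(0.0, 0.5, n_b)
    t[branches == "meso_branch"] = rng.uniform(0.5, 1.0, n_b)
    t[branches == "neural_branch"] = rng.uniform(0.5, 1.0, n_b)
    cell_ids = [f"cell_{i:04d}" for i in range(branches.size)]

    programs = []
    for prog in PROGRAMS:
        programs += [prog] * spec.program_sizes.get(prog, 0)
    programs += ["housekeeping"] * (spec.n_genes - len(programs))
    programs = np.array(programs)
    gene_ids = [f"g_{p}_{i:04d}" for i, p in enumerate(programs)]

    # per-gene maximal mean (relative units), log-uniform across a decade
    max_mean = 10 ** rng.uniform(1.5, 2.5, spec.n_genes)

    ramp_up = _logistic(t, spec.ramp_steepness)            # 0 -> 1
    base = spec.baseline_fraction
    rel = np.empty((spec.n_genes, branches.size))
    on_meso = (branches != "neural_branch").astype(float)
    on_neural = (branches != "meso_branch").astype(float)
    for g in range(spec.n_genes):
        p = programs[g]
        if p == "nmp":
            profile = (1.0 - ramp_up) * (1.0 - base) + base
        elif p == "mesoderm":
            profile = on_meso * ramp_up * (1.0 - base) + base
        elif p == "neural":
            profile = on_neural * ramp_up * (1.0 - base) + base
        else:
            profile = np.full_like(t, 0.5)
        rel[g] = max_mean[g] * profile

    # library sizes concentrate around library_size_mean (gamma, cv ~ 10%)
    cv = max(spec.library_size_cv, 1e-9)
    shape = 1.0 / cv ** 2
    lib = rng.gamma(shape, spec.library_size_mean / shape, branches.size)
    lam = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]

    if spec.nb_dispersion <= 1e-12:
        counts = rng.poisson(lam)
    else:
        nb_shape = 1.0 / spec.nb_dispersion
        counts = rng.poisson(rng.gamma(nb_shape, lam * spec.nb_dispersion))
    if spec.dropout_rate > 0:
        keep = rng.random(counts.shape) >= spec.dropout_rate
        counts = counts * keep

    values = pd.DataFrame(counts.astype(np.int64), index=gene_ids,
                          columns=cell_ids)
    matrix = ExpressionMatrix(values, layer="counts")
    truth = SyntheticTruth(
        cells=pd.DataFrame({"branch": branches, "pseudotime": t},
                           index=cell_ids),
        genes=pd.DataFrame({"program": programs, "max_mean": max_mean},
                           index=gene_ids),
        expected_counts=pd.DataFrame(lam, index=gene_ids, columns=cell_ids),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Cytometry events
# ---------------------------------------------------------------------------

FACS_CHANNELS = ("FSC-A", "FSC-H", "SSC-A", "Bra", "Sox2", "Tbx6")
FACS_POPULATIONS = ("nmp", "mesoderm", "neural", "unassigned")

# log10 location per (population, marker); scale in decades.
DEFAULT_CHANNEL_PARAMS = {
    "nmp": {"Bra": 3.8, "Sox2": 2.4, "Tbx6": 2.1},
    "mesoderm": {"Bra": 2.1, "Sox2": 2.1, "Tbx6": 3.8},
    "neural": {"Bra": 2.1, "Sox2": 3.8, "Tbx6": 2.1},
    "unassigned": {"Bra": 2.1, "Sox2": 2.1, "Tbx6": 2.1},
}
DEFAULT_CHANNEL_SIGMA = 0.12  # decades

_SCATTER = {
    "FSC-A": (4.7, 0.08),
    "SSC-A": (4.5, 0.12),
}
_DEBRIS_SCATTER = {
    "FSC-A": (3.6, 0.15),
    "SSC-A": (3.2, 0.2),
}
FSC_H_RATIO = 1.5  # singlet FSC-A / FSC-H trend


def simulate_facs_events(proportions, n_events: int,
                         channel_params: dict | None = None,
                         sigma: float = DEFAULT_CHANNEL_SIGMA,
                         debris_rate: float = 0.05,
                         doublet_rate: float = 0.05,
                         seed: int = 0) -> pd.DataFrame:
    """Cytometry event table from four log-normal populations.

    ``proportions`` orders populations as ``FACS_POPULATIONS``.  Debris
    events sit low in FSC-A/SSC-A; doublets follow an FSC-A ~ 2 x FSC-H
    trend.  Truth columns (``population``, ``is_debris``, ``is_doublet``)
    ride along for recovery tests.
    """
    proportions = np.asarray(proportions, dtype=float)
    if proportions.size != 4 or (proportions < 0).any():
        raise ConfigurationError("need 4 non-negative population proportions")
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ConfigurationError("proportions must sum to 1")
    if n_events <= 0:
        raise ConfigurationError("n_events must be positive")
    params = channel_params or DEFAULT_CHANNEL_PARAMS
    rng = np.random.default_rng(seed)

    pop = rng.choice(len(FACS_POPULATIONS), size=n_events, p=proportions)
    is_debris = rng.random(n_events) < debris_rate
    is_doublet = (~is_debris) & (rng.random(n_events) < doublet_rate /
                                 max(1.0 - debris_rate, 1e-12))

    cols = {}
    for ch, (loc, sc) in _SCATTER.items():
        cols[ch] = 10 ** rng.normal(loc, sc, n_events)
    for ch, (loc, sc) in _DEBRIS_SCATTER.items():
        cols[ch] = np.where(is_debris, 10 ** rng.normal(loc, sc, n_events),
                            cols[ch])
    ratio_noise = 10 ** rng.normal(0.0, 0.01, n_events)
    cols["FSC-H"] = cols["FSC-A"] / FSC_H_RATIO * ratio_noise
    # a doublet carries roughly twice the area at singlet-like height
    cols["FSC-A"] = np.where(is_doublet, cols["FSC-A"] * 2.0, cols["FSC-A"])

    for marker in ("Bra", "Sox2", "Tbx6"):
        loc = np.array([params[p][marker] for p in FACS_POPULATIONS])[pop]
        cols[marker] = 10 ** rng.normal(loc, sigma)
    events = pd.DataFrame(cols, columns=list(FACS_CHANNELS))
    events["population"] = np.array(FACS_POPULATIONS)[pop]
    events["is_debris"] = is_debris
    events["is_doublet"] = is_doublet
    return events


# ---------------------------------------------------------------------------
# Model-generated trajectories
# ---------------------------------------------------------------------------

def simulate_from_circuit(model: grn_model.CircuitModel, condition_name: str,
                          n_cells: int = 100, omega: float = 100.0,
                          seed: int = 0, dt: float = 1e-3
                          ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Ensemble of CLE trajectories under a named signalling condition.

    Returns ``(trajectories, endpoint_labels, t)`` where ``trajectories``
    has shape (n_cells, n_times, 3) in SPECIES order.
    """
    schedule = grn_model.get_schedule(condition_name)  # raises on bad name
    rng = np.random.default_rng(seed)
    trajs = []
    labels = []
    t = None
    for _ in range(n_cells):
        df = grn_model.simulate_cle(model.topology, model.params, schedule,
                                    omega=omega, dt=dt, seed=rng)
        trajs.append(df.values)
        labels.append(grn_model.classify_endpoint(df.iloc[-1].values))
        t = df.index.values
    return np.stack(trajs), labels, t
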