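"""Thermodynamic occupancy model of the Sox2 / Bra / Msgn1-Tbx6 circuit.

Transcription of each factor is proportional to the equilibrium probability
that RNA polymerase occupies its promoter.  Every combination of bound
regulators contributes a statistical weight; activators (cooperativity c > 1)
stabilise the polymerase-bound states, repressors (c = 0) only populate the
unbound ones.  With maximal production rate alpha and linear degradation
delta the concentration of each factor obeys

    dx/dt = alpha * p_bound(x) - delta * x

With alpha = delta = 2 the dynamics are confined to [0, 1] per species.
Two fixed signalling inputs drive the circuit: Wnt activates Bra and
retinoic acid (RA) activates Sox2.  Days D2..D5 of the differentiation
protocol map to t in [0, 3] (one time unit per day).

A numba-compiled fixed-step RK4 / Euler-Maruyama core backs the deterministic
and Chemical-Langevin simulators so that the topology search can afford tens
of thousands of simulations.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp

from .errors import ConfigurationError

SPECIES = ("Sox2", "Bra", "MsgnTbx6")

# Ordered TF->TF edges, following the order in which the binding affinities
# are optimised: (regulator, target).
EDGES = (
    ("MsgnTbx6", "Bra"),   # K_MB
    ("Sox2", "Bra"),       # K_SB
    ("Bra", "Sox2"),       # K_BS
    ("MsgnTbx6", "Sox2"),  # K_MS
    ("Bra", "MsgnTbx6"),   # K_BM
    ("Sox2", "MsgnTbx6"),  # K_SM
)

K_SIGNAL = 10.0     # Wnt->Bra and RA->Sox2 binding affinity (fixed)
C_ACTIVATOR = 10.0  # cooperativity of activators
C_REPRESSOR = 0.0   # repressors exclude polymerase entirely
K_POL = 1.0         # polymerase binding affinity (fixed)
X_POL = 1.0         # polymerase concentration; only the product K_POL*X_POL matters
ALPHA = 2.0         # maximal production rate
DELTA = 2.0         # degradation rate
X0_BASAL = 0.001    # initial level of Bra, MsgnTbx6 and both signals at D2
X0_SOX2 = 0.8       # epiblast state: Sox2 starts high
T_END = 3.0         # D2..D5 in days

K_BOUNDS = (0.01, 1000.0)


@dataclasses.dataclass(frozen=True)
class RegulatoryTopology:
    """Sign assignment (activator=True) for the six TF->TF interactions.

    Encoded as a 6-bit integer: bit i corresponds to ``EDGES[i]``; id 0 is
    all-repressive, id 63 all-activating.
    """

    activator: tuple[bool, bool, bool, bool, bool, bool]

    def __post_init__(self):
        if len(self.activator) != 6:
            raise ConfigurationError("a topology needs exactly 6 signed edges")

    @classmethod
    def from_id(cls, code: int) -> "RegulatoryTopology":
        if not 0 <= code < 64:
            raise ConfigurationError("topology id must be in [0, 63]")
        return cls(tuple(bool((code >> i) & 1) for i in range(6)))

    @property
    def id(self) -> int:
        return sum(int(a) << i for i, a in enumerate(self.activator))

    def sign(self, regulator: str, target: str) -> str:
        i = EDGES.index((regulator, target))
        return "activator" if self.activator[i] else "repressor"

    def activator_matrix(self) -> np.ndarray:
        """3x3 boolean (regulator, target) matrix in SPECIES order."""
        act = np.zeros((3, 3), dtype=np.bool_)
        for flag, (reg, tgt) in zip(self.activator, EDGES):
            act[SPECIES.index(reg), SPECIES.index(tgt)] = flag
        return act


@dataclasses.dataclass
class ModelParameters:
    """Kinetic parameters; only the six TF->TF affinities are free."""

    k: tuple[float, ...] = (1.0,) * 6  # aligned with EDGES
    n_sites: int = 2

    def __post_init__(self):
        if len(self.k) != 6:
            raise ConfigurationError("expected 6 binding affinities")
        if any(v < 0 for v in self.k):
            raise ConfigurationError("binding affinities must be >= 0")

    def validate_bounds(self) -> None:
        lo, hi = K_BOUNDS
        if any(not lo <= v <= hi for v in self.k):
            raise ConfigurationError(f"optimised affinities must lie in [{lo}, {hi}]")

    def k_matrix(self) -> np.ndarray:
        mat = np.zeros((3, 3))
        for val, (reg, tgt) in zip(self.k, EDGES):
            mat[SPECIES.index(reg), SPECIES.index(tgt)] = val
        return mat


@dataclasses.dataclass
class SignalingSchedule:
    """Piecewise-constant external RA / Wnt concentrations over [0, T_END].

    ``breaks`` has one more element than the level vectors; segment ``i``
    spans ``[breaks[i], breaks[i+1])``.
    """

    breaks: tuple[float, ...]
    ra: tuple[float, ...]
    wnt: tuple[float, ...]
    name: str = "custom"

    def __post_init__(self):
        if len(self.breaks) != len(self.ra) + 1 or len(self.ra) != len(self.wnt):
            raise ConfigurationError("inconsistent schedule segment counts")
        if any(v < 0 for v in self.ra + self.wnt):
            raise ConfigurationError("external concentrations must be >= 0")
        if self.breaks[0] != 0.0 or self.breaks[-1] != T_END:
            raise ConfigurationError(f"schedule must span [0, {T_END}]")
        if list(self.breaks) != sorted(self.breaks):
            raise ConfigurationError("schedule breakpoints must increase")

    def levels_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.breaks, t, side="right") - 1
        idx = min(max(idx, 0), len(self.ra) - 1)
        return self.ra[idx], self.wnt[idx]

    def per_step(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Effective (basal + external) signal levels sampled every dt."""
        n = int(round(T_END / dt))
        t = (np.arange(n) + 0.5) * dt
        idx = np.clip(np.searchsorted(self.breaks, t, side="right") - 1, 0,
                      len(self.ra) - 1)
        ra = X0_BASAL + np.asarray(self.ra, dtype=float)[idx]
        wnt = X0_BASAL + np.asarray(self.wnt, dtype=float)[idx]
        return ra, wnt


_PRESETS = {
    # Wnt high + basal RA for the whole differentiation window.
    "mesodermal": SignalingSchedule((0.0, T_END), (0.1,), (1.0,), "mesodermal"),
    # Switch to high RA / no Wnt at D3.
    "neural1": SignalingSchedule((0.0, 1.0, T_END), (0.1, 1.0), (1.0, 0.0), "neural1"),
    # Withdraw Wnt at D3, keep RA basal ("NB" medium).
    "neural2": SignalingSchedule((0.0, 1.0, T_END), (0.1, 0.1), (1.0, 0.0), "neural2"),
    # Basal Wnt and RA throughout.
    "anterior": SignalingSchedule((0.0, T_END), (0.1,), (0.1,), "anterior"),
}
_PRESETS["raplus"] = _PRESETS["neural1"]
_PRESETS["nb"] = _PRESETS["neural2"]

MUTANTS = ("none", "bra", "msgntbx6")


def get_schedule(name: str) -> SignalingSchedule:
    try:
        return _PRESETS[name.lower()]
    except KeyError:
        raise ConfigurationError(
            f"unknown signalling condition {name!r}; known: {sorted(_PRESETS)}"
        ) from None


def _alpha_vector(mutant: str) -> np.ndarray:
    mutant = mutant.lower()
    if mutant not in MUTANTS:
        raise ConfigurationError(f"unknown mutant {mutant!r}; known: {MUTANTS}")
    alpha = np.full(3, ALPHA)
    if mutant == "bra":
        alpha[SPECIES.index("Bra")] = 0.0
    elif mutant == "msgntbx6":
        alpha[SPECIES.index("MsgnTbx6")] = 0.0
    return alpha


@dataclasses.dataclass
class CircuitModel:
    """Topology + kinetic parameters + signalling schedule bundle."""

    topology: RegulatoryTopology
    params: ModelParameters
    schedule: SignalingSchedule | str = "mesodermal"

    def resolved_schedule(self) -> SignalingSchedule:
        if isinstance(self.schedule, str):
            return get_schedule(self.schedule)
        return self.schedule

    def to_dict(self) -> dict:
        sched = self.schedule if isinstance(self.schedule, str) else {
            "breaks": list(self.schedule.breaks),
            "ra": list(self.schedule.ra),
            "wnt": list(self.schedule.wnt),
            "name": self.schedule.name,
        }
        return {
            "signs": {f"{reg}->{tgt}": ("activator" if a else "repressor")
                      for a, (reg, tgt) in zip(self.topology.activator, EDGES)},
            "k": {f"{reg}->{tgt}": float(v)
                  for v, (reg, tgt) in zip(self.params.k, EDGES)},
            "n_sites": self.params.n_sites,
            "schedule": sched,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CircuitModel":
        signs = data["signs"]
        kvals = data["k"]
        activator = []
        k = []
        for reg, tgt in EDGES:
            key = f"{reg}->{tgt}"
            activator.append(signs[key] == "activator")
            k.append(float(kvals[key]))
        sched = data.get("schedule", "mesodermal")
        if isinstance(sched, dict):
            sched = SignalingSchedule(tuple(sched["breaks"]),
                                      tuple(sched["ra"]), tuple(sched["wnt"]),
                                      sched.get("name", "custom"))
        return cls(RegulatoryTopology(tuple(activator)),
                   ModelParameters(tuple(k), n_sites=data.get("n_sites", 2)),
                   sched)


# ---------------------------------------------------------------------------
# Occupancy algebra
# ---------------------------------------------------------------------------

def statistical_weights(target: str, topology: RegulatoryTopology,
                        params: ModelParameters, state: dict[str, float]
                        ) -> tuple[float, float]:
    """Summed statistical weights of polymerase-bound and unbound states.

    ``state`` maps species names to concentrations and may carry the
    effective signal levels under keys ``RA`` and ``Wnt`` (default 0).
    Activators enter the bound sum with cooperativity c = 10; repressors
    (c = 0) contribute only to the unbound sum.  Each regulator binds
    ``params.n_sites`` sites independently, hence the power.
    """
    if target not in SPECIES:
        raise ConfigurationError(f"unknown target {target!r}")
    for name in SPECIES:
        if state.get(name, 0.0) < 0:
            raise ValueError(f"negative concentration for {name}")
    n = params.n_sites
    z_bound = K_POL * X_POL
    z_unbound = 1.0
    for val, (reg, tgt) in zip(params.k, EDGES):
        if tgt != target:
            continue
        x = state.get(reg, 0.0)
        z_unbound *= (1.0 + val * x) ** n
        if topology.sign(reg, tgt) == "activator":
            z_bound *= (1.0 + val * C_ACTIVATOR * x) ** n
    # Fixed signal inputs: RA activates Sox2, Wnt activates Bra.
    signal = {"Sox2": state.get("RA", 0.0), "Bra": state.get("Wnt", 0.0)}.get(target)
    if signal is not None and signal > 0:
        z_unbound *= (1.0 + K_SIGNAL * signal) ** n
        z_bound *= (1.0 + K_SIGNAL * C_ACTIVATOR * signal) ** n
    return z_bound, z_unbound


def p_bound(target: str, topology: RegulatoryTopology, params: ModelParameters,
            state: dict[str, float]) -> float:
    zb, zu = statistical_weights(target, topology, params, state)
    return zb / (zu + zb)


# ---------------------------------------------------------------------------
# Numba core (fixed n_sites = 2, the model default)
# ---------------------------------------------------------------------------

@njit(cache=False, fastmath=True)
def _rhs_core(x, ra, wnt, kmat, act, alpha):
    dx = np.empty(3)
    for j in range(3):
        zb = 1.0  # K_POL * X_POL
        zu = 1.0
        for i in range(3):
            if i == j:
                continue
            t = kmat[i, j] * x[i]
            zu *= (1.0 + t) * (1.0 + t)
            if act[i, j]:
                u = 10.0 * t
                zb *= (1.0 + u) * (1.0 + u)
        if j == 0:  # RA -> Sox2
            s = 10.0 * ra
            zu *= (1.0 + s) * (1.0 + s)
            u = 10.0 * s
            zb *= (1.0 + u) * (1.0 + u)
        elif j == 1:  # Wnt -> Bra
            s = 10.0 * wnt
            zu *= (1.0 + s) * (1.0 + s)
            u = 10.0 * s
            zb *= (1.0 + u) * (1.0 + u)
        p = zb / (zu + zb)
        dx[j] = alpha[j] * p - 2.0 * x[j]
    return dx


@njit(cache=False, fastmath=True)
def _integrate_rk4(x0, kmat, act, alpha, ra_steps, wnt_steps, dt):
    n = ra_steps.shape[0]
    out = np.empty((n + 1, 3))
    x = x0.copy()
    out[0] = x
    for s in range(n):
        ra = ra_steps[s]
        wnt = wnt_steps[s]
        k1 = _rhs_core(x, ra, wnt, kmat, act, alpha)
        k2 = _rhs_core(x + 0.5 * dt * k1, ra, wnt, kmat, act, alpha)
        k3 = _rhs_core(x + 0.5 * dt * k2, ra, wnt, kmat, act, alpha)
        k4 = _rhs_core(x + dt * k3, ra, wnt, kmat, act, alpha)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[s + 1] = x
    return out


@njit(cache=False, fastmath=True)
def _integrate_cle(x0, kmat, act, alpha, ra_steps, wnt_steps, dt, omega, noise):
    n = ra_steps.shape[0]
    out = np.empty((n + 1, 3))
    x = x0.copy()
    out[0] = x
    sqdt = math.sqrt(dt)
    for s in range(n):
        ra = ra_steps[s]
        wnt = wnt_steps[s]
        for j in range(3):
            zb = 1.0
            zu = 1.0
            for i in range(3):
                if i == j:
                    continue
                t = kmat[i, j] * x[i]
                zu *= (1.0 + t) * (1.0 + t)
                if act[i, j]:
                    u = 10.0 * t
                    zb *= (1.0 + u) * (1.0 + u)
            if j == 0:
                sig = 10.0 * ra
            elif j == 1:
                sig = 10.0 * wnt
            else:
                sig = 0.0
            if sig > 0.0:
                zu *= (1.0 + sig) * (1.0 + sig)
                u = 10.0 * sig
                zb *= (1.0 + u) * (1.0 + u)
            p = zb / (zu + zb)
            a = alpha[j] * p
            d = 2.0 * x[j]
            amp = math.sqrt(max(a + d, 0.0) / omega)
            x[j] = x[j] + (a - d) * dt + amp * sqdt * noise[s, j]
            if x[j] < 0.0:  # CLE guard: reflect to the admissible domain
                x[j] = 0.0
            if abs(x[j]) > 10.0:
                out[0, 0] = np.nan  # instability sentinel
                return out
        out[s + 1] = x
    return out


def _initial_state() -> np.ndarray:
    x0 = np.array([X0_SOX2, X0_BASAL, X0_BASAL])
    return x0


# ---------------------------------------------------------------------------
# Public simulators
# ---------------------------------------------------------------------------

def simulate_ode(topology: RegulatoryTopology, params: ModelParameters,
                 schedule: SignalingSchedule | str, mutant: str = "none",
                 t_grid: np.ndarray | None = None, rtol: float = 1e-8,
                 ra_feedback: tuple[float, float] | None = None
                 ) -> pd.DataFrame:
    """Deterministic trajectory on ``t_grid`` (default 301 points over D2..D5).

    Integrates each constant-signal segment separately with an adaptive
    solver so that schedule discontinuities never straddle a step.

    ``ra_feedback=(alpha_R, delta_R)`` switches on the optional
    mesoderm-driven RA production term dx_R/dt = alpha_R x_M - delta_R x_R
    (off by default): the dynamic RA level then adds to the scheduled one.
    """
    if isinstance(schedule, str):
        schedule = get_schedule(schedule)
    if t_grid is None:
        t_grid = np.linspace(0.0, T_END, 301)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] < 0 or t_grid[-1] > T_END:
        raise ConfigurationError(f"t_grid must lie within [0, {T_END}]")
    alpha = _alpha_vector(mutant)
    kmat = params.k_matrix()
    act = topology.activator_matrix()

    if ra_feedback is None:
        def rhs(t, x, ra_eff, wnt_eff):
            return _rhs_core(np.maximum(x, 0.0), ra_eff, wnt_eff, kmat, act,
                             alpha)
    else:
        a_r, d_r = ra_feedback

        def rhs(t, x, ra_eff, wnt_eff):
            xc = np.maximum(x, 0.0)
            core = _rhs_core(xc[:3], ra_eff + xc[3], wnt_eff, kmat, act, alpha)
            return np.concatenate([core,
                                   [a_r * xc[SPECIES.index("MsgnTbx6")]
                                    - d_r * xc[3]]])

    x = _initial_state()
    if ra_feedback is not None:
        x = np.concatenate([x, [0.0]])
    rows = np.empty((t_grid.size, x.size))
    filled = 0
    if t_grid[0] == 0.0:
        rows[0] = x
        filled = 1
    edges = list(schedule.breaks)
    for i in range(len(edges) - 1):
        t0, t1 = edges[i], edges[i + 1]
        ra_eff = X0_BASAL + schedule.ra[i]
        wnt_eff = X0_BASAL + schedule.wnt[i]
        inside = t_grid[(t_grid > t0) & (t_grid <= t1)]
        t_eval = np.union1d(inside, [t1])
        sol = solve_ivp(rhs, (t0, t1), x, t_eval=t_eval, args=(ra_eff, wnt_eff),
                        rtol=rtol, atol=1e-10, method="LSODA")
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on segment [{t0}, {t1}]: "
                               f"{sol.message}")
        if inside.size:
            keep = np.isin(sol.t, inside)
            rows[filled:filled + inside.size] = sol.y.T[keep]
            filled += inside.size
        x = sol.y[:, -1]
    columns = list(SPECIES) + (["RA_dyn"] if ra_feedback is not None else [])
    return pd.DataFrame(rows, index=pd.Index(t_grid, name="t"), columns=columns)


def simulate_ode_fast(topology: RegulatoryTopology, params: ModelParameters,
                      schedule: SignalingSchedule | str, mutant: str = "none",
                      dt: float = 0.005) -> pd.DataFrame:
    """Fixed-step RK4 deterministic trajectory (numba core, fast path)."""
    if isinstance(schedule, str):
        schedule = get_schedule(schedule)
    ra, wnt = schedule.per_step(dt)
    out = _integrate_rk4(_initial_state(), params.k_matrix(),
                         topology.activator_matrix(), _alpha_vector(mutant),
                         ra, wnt, dt)
    t = np.arange(out.shape[0]) * dt
    return pd.DataFrame(out, index=pd.Index(t, name="t"), columns=SPECIES)


def simulate_cle(topology: RegulatoryTopology, params: ModelParameters,
                 schedule: SignalingSchedule | str, mutant: str = "none",
                 omega: float = 100.0, dt: float = 1e-3,
                 seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Chemical-Langevin trajectory by Euler-Maruyama.

    Noise amplitude per species is sqrt((production + degradation)/omega);
    states are clipped at zero after each step.  A blow-up beyond |x| > 10
    signals an unstable step size and raises.
    """
    if omega <= 0:
        raise ConfigurationError("omega must be > 0")
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    if isinstance(schedule, str):
        schedule = get_schedule(schedule)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ra, wnt = schedule.per_step(dt)
    noise = rng.standard_normal((ra.size, 3))
    out = _integrate_cle(_initial_state(), params.k_matrix(),
                         topology.activator_matrix(), _alpha_vector(mutant),
                         ra, wnt, dt, float(omega), noise)
    if np.isnan(out[0, 0]):
        raise RuntimeError("CLE integration unstable (|x| > 10); reduce dt")
    t = np.arange(out.shape[0]) * dt
    return pd.DataFrame(out, index=pd.Index(t, name="t"), columns=SPECIES)


ENDPOINT_CLASSES = ("neural", "mesoderm", "NMP", "unassigned")
ENDPOINT_THRESHOLD = 0.5


def classify_endpoint(state) -> str:
    """Label a D5 state by 0.5 thresholds on clipped concentrations."""
    x = np.clip(np.asarray(state, dtype=float), 0.0, 1.0)
    x_s, x_b, x_m = x
    if x_s >= ENDPOINT_THRESHOLD and x_m < ENDPOINT_THRESHOLD:
        return "neural"
    if x_m >= ENDPOINT_THRESHOLD and x_s < ENDPOINT_THRESHOLD:
        return "mesoderm"
    if x_b >= ENDPOINT_THRESHOLD:
        return "NMP"
    return "unassigned"


def io_map(topology: RegulatoryTopology, params: ModelParameters,
           ra_levels, wnt_levels, n_reps: int = 100, omega: float = 100.0,
           seed: int = 0, dt: float = 1e-3) -> pd.DataFrame:
    """Endpoint-class proportions over an (RA, Wnt) signal grid.

    Every trajectory shares a D2-D3 RA-low / Wnt-high phase; the grid levels
    apply from D3 to D5.  Rows are (ra, wnt) pairs, columns the four endpoint
    classes; each row sums to 1.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    ra_levels = np.asarray(ra_levels, dtype=float)
    wnt_levels = np.asarray(wnt_levels, dtype=float)
    if (ra_levels < 0).any() or (wnt_levels < 0).any():
        raise ConfigurationError("signal levels must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    index = []
    for ra in ra_levels:
        for wnt in wnt_levels:
            sched = SignalingSchedule((0.0, 1.0, T_END), (0.1, float(ra)),
                                      (1.0, float(wnt)), name=f"io_{ra}_{wnt}")
            counts = dict.fromkeys(ENDPOINT_CLASSES, 0)
            for _ in range(n_reps):
                traj = simulate_cle(topology, params, sched, omega=omega,
                                    dt=dt, seed=rng)
                counts[classify_endpoint(traj.iloc[-1].values)] += 1
            rows.append([counts[c] / n_reps for c in ENDPOINT_CLASSES])
            index.append((float(ra), float(wnt)))
    idx = pd.MultiIndex.from_tuples(index, names=["ra", "wnt"])
    return pd.DataFrame(rows, index=idx, columns=ENDPOINT_CLASSES)


def find_fixed_points(topology: RegulatoryTopology, params: ModelParameters,
                      ra: float = 0.1, wnt: float = 0.1, n_starts: int = 100,
                      seed: int = 0, t_relax: float = 200.0,
                      tol: float = 1e-6) -> list[dict]:
    """Stable fixed points under sustained signals, by forward relaxation.

    Integrates from random initial states in [0,1]^3, deduplicates the
    endpoints and checks local stability via finite-difference Jacobian
    eigenvalues.  Returns a list of {"x": state, "stable": bool} records.
    """
    rng = np.random.default_rng(seed)
    kmat = params.k_matrix()
    act = topology.activator_matrix()
    alpha = np.full(3, ALPHA)
    ra_eff = X0_BASAL + ra
    wnt_eff = X0_BASAL + wnt

    def rhs(x):
        return _rhs_core(np.maximum(x, 0.0), ra_eff, wnt_eff, kmat, act, alpha)

    found: list[dict] = []
    for _ in range(n_starts):
        x = rng.uniform(0, 1, 3)
        sol = solve_ivp(lambda t, y: rhs(y), (0, t_relax), x, rtol=1e-10,
                        atol=1e-12, method="LSODA")
        xf = sol.y[:, -1]
        if np.linalg.norm(rhs(xf)) > 1e-6:
            continue
        if any(np.allclose(xf, f["x"], atol=1e-4) for f in found):
            continue
        eps = 1e-6
        jac = np.empty((3, 3))
        for j in range(3):
            dx = np.zeros(3)
            dx[j] = eps
            jac[:, j] = (rhs(xf + dx) - rhs(xf - dx)) / (2 * eps)
        stable = bool(np.all(np.linalg.eigvals(jac).real < 0))
        found.append({"x": xf, "stable": stable})
    return found


# Reference circuit: the hallmark cross-repressive wiring (all TF->TF edges
# repressive except Bra activating Msgn1/Tbx6) with affinities from this
# package's own differential-evolution fit of the default objectives
# (see topology_search; frozen here so downstream analyses have a concrete
# default model).
BEST_TOPOLOGY = RegulatoryTopology.from_id(16)  # bit 4 = Bra->MsgnTbx6 activator
REFERENCE_K = (392.0, 0.425, 6.17, 59.3, 998.5, 106.8)


def reference_model(schedule: str = "mesodermal") -> CircuitModel:
    return CircuitModel(BEST_TOPOLOGY, ModelParameters(REFERENCE_K), schedule)
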