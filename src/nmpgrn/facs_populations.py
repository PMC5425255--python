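"""Cytometry quantification: gating, logicle transform, k-means populations.

Debris is removed by minimum FSC-A / SSC-A thresholds and doublets by
their deviation from the singlet FSC-A ~ FSC-H trend.  Marker channels
(Bra, Sox2, Tbx6) are mapped through the biexponential logicle transform
(logarithmic at high signal, linear through zero) whose width parameter is
trained per channel.  Populations are found by k-means (k = 4) on the
pooled, size-matched transformed intensities of two samples and named by
their marker signature; every event of each full sample is then assigned
to its nearest centre.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.cluster import KMeans

from .errors import ConfigurationError, EmptyResultError

MARKER_CHANNELS = ("Bra", "Sox2", "Tbx6")
POPULATION_NAMES = ("nmp", "mesoderm", "neural", "unassigned")


def read_events_csv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = [c for c in ("FSC-A", "FSC-H", "SSC-A") + MARKER_CHANNELS
               if c not in events.columns]
    if missing:
        raise ConfigurationError(f"event table lacks channels: {missing}")
    if events[list(MARKER_CHANNELS)].isna().any().any():
        raise ValueError("missing channel values in event table")
    return events


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GateParams:
    """Defaults are tuned to the synthetic event generator's populations."""

    min_fsc_a: float = 2e4
    min_ssc_a: float = 5e3
    doublet_band: float = 0.35  # relative deviation from the median A/H ratio


def gate_events(events: pd.DataFrame, params: GateParams | None = None
                ) -> pd.DataFrame:
    """Remove debris (low scatter) then doublets (off the A ~ H trend)."""
    if len(events) == 0:
        raise EmptyResultError("empty event table")
    params = params or GateParams()
    keep = ((events["FSC-A"] >= params.min_fsc_a)
            & (events["SSC-A"] >= params.min_ssc_a))
    singletish = events[keep]
    if len(singletish) == 0:
        raise EmptyResultError("all events fell below the scatter gate")
    ratio = singletish["FSC-A"] / singletish["FSC-H"]
    centre = float(np.median(ratio))
    if np.isinf(params.doublet_band):
        return singletish.copy()
    in_band = (ratio >= centre * (1 - params.doublet_band)) & \
              (ratio <= centre * (1 + params.doublet_band))
    gated = singletish[in_band]
    if len(gated) == 0:
        raise EmptyResultError("all events gated out")
    return gated.copy()


# ---------------------------------------------------------------------------
# Logicle transform
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LogicleParams:
    """T: top of scale; M: decades; W: linearisation width (decades);
    A: additional negative decades (0 here)."""

    T: float
    W: float
    M: float = 4.5
    A: float = 0.0

    def __post_init__(self):
        if self.T <= 0:
            raise ConfigurationError("T must be > 0")
        if not 0 <= self.W <= self.M / 2:
            raise ConfigurationError("need 0 <= W <= M/2")


def _logicle_p(w_natural: float) -> float:
    """Solve w = 2 p ln(p) / (p + 1) for the biexponential shape p >= 1."""
    if w_natural <= 0:
        return 1.0
    return brentq(lambda p: 2 * p * np.log(p) / (p + 1) - w_natural,
                  1.0 + 1e-12, 1e6)


def logicle_inverse(u, params: LogicleParams):
    """Biexponential: map scale position u in [0, 1] back to intensity."""
    m = (params.M + params.A) * np.log(10)
    w = params.W * np.log(10)
    p = _logicle_p(w)
    y = np.asarray(u, dtype=float) * m

    def biexp_upper(yv):
        e = yv - w
        return (params.T * np.exp(-(m - w))
                * (np.exp(e) - p ** 2 * np.exp(-e / p) + p ** 2 - 1))

    upper = y >= w
    out = np.where(upper, biexp_upper(np.where(upper, y, w)),
                   -biexp_upper(np.where(upper, w, 2 * w - y)))
    return out if out.shape else float(out)


def logicle_transform(values, params: LogicleParams):
    """Map intensities to logicle scale positions in [0, 1] (vectorised
    bisection of the strictly monotone biexponential)."""
    x = np.atleast_1d(np.asarray(values, dtype=float))
    lo = np.full(x.shape, -1.0)
    hi = np.full(x.shape, 2.0)
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        too_low = logicle_inverse(mid, params) < x
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    out = 0.5 * (lo + hi)
    return out if np.ndim(values) else float(out[0])


def estimate_logicle(values, M: float = 4.5, A: float = 0.0,
                     default_w: float = 0.5) -> LogicleParams:
    """Per-channel parameter training.

    T is the channel maximum; W derives from the 5th percentile r of the
    negative events as (M - log10(T/|r|)) / 2, the usual auto-estimation
    convention; with no negative events W falls back to ``default_w``.
    """
    values = np.asarray(values, dtype=float)
    t = float(values.max())
    neg = values[values < 0]
    if neg.size:
        r = float(np.percentile(neg, 5))
        w = max((M - np.log10(t / abs(r))) / 2, 0.0)
    else:
        w = default_w
    return LogicleParams(T=t, W=min(w, M / 2), M=M, A=A)


def transform_markers(events: pd.DataFrame,
                      params: dict[str, LogicleParams] | None = None
                      ) -> tuple[pd.DataFrame, dict[str, LogicleParams]]:
    """Logicle-transform the marker channels (training params if absent)."""
    params = params or {ch: estimate_logicle(events[ch].values)
                        for ch in MARKER_CHANNELS}
    out = events.copy()
    for ch in MARKER_CHANNELS:
        out[ch] = logicle_transform(events[ch].values, params[ch])
    return out, params


# ---------------------------------------------------------------------------
# Population identification
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PopulationModel:
    centers: pd.DataFrame            # index: population name; columns markers
    labels: dict[str, pd.Series]     # per-sample per-event population name


def _name_centers(centers: np.ndarray) -> list[str]:
    """Signature naming: highest Tbx6 -> mesoderm, then highest Sox2 ->
    neural, then highest Bra -> NMP, remainder unassigned (Bra breaks ties
    implicitly through argmax order)."""
    names = [None] * centers.shape[0]
    free = set(range(centers.shape[0]))
    for channel, name in ((2, "mesoderm"), (1, "neural"), (0, "nmp")):
        pick = max(free, key=lambda i: centers[i, channel])
        names[pick] = name
        free.discard(pick)
    for i in sorted(free):
        names[i] = "unassigned" if len(free) == 1 else f"unassigned_{i}"
    return names


def kmeans_populations(sample_a: pd.DataFrame, sample_b: pd.DataFrame,
                       k: int = 4, seed: int = 0) -> PopulationModel:
    """k-means over pooled size-matched samples, nearest-centre assignment.

    Both inputs must already be gated and logicle-transformed.  The larger
    sample is randomly downsampled (seeded) to the smaller's size before
    clustering; all events of both full samples are then assigned to their
    nearest centre.
    """
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise EmptyResultError("empty sample")
    rng = np.random.default_rng(seed)
    xa = sample_a[list(MARKER_CHANNELS)].values
    xb = sample_b[list(MARKER_CHANNELS)].values
    n = min(len(xa), len(xb))
    pool = np.vstack([
        xa[rng.choice(len(xa), n, replace=False)] if len(xa) > n else xa,
        xb[rng.choice(len(xb), n, replace=False)] if len(xb) > n else xb,
    ])
    if np.unique(pool, axis=0).shape[0] < k:
        raise ConfigurationError("fewer distinct events than clusters")
    km = KMeans(n_clusters=k, random_state=int(rng.integers(2 ** 31)),
                n_init=10).fit(pool)
    names = _name_centers(km.cluster_centers_)
    centers = pd.DataFrame(km.cluster_centers_, index=names,
                           columns=MARKER_CHANNELS)
    labels = {}
    for tag, x, sample in (("a", xa, sample_a), ("b", xb, sample_b)):
        d = ((x[:, None, :] - km.cluster_centers_[None, :, :]) ** 2).sum(-1)
        labels[tag] = pd.Series(np.array(names)[d.argmin(1)],
                                index=sample.index, name="population")
    return PopulationModel(centers=centers, labels=labels)


def population_ratios(labels: dict[str, pd.Series]) -> pd.DataFrame:
    """Per-sample fraction of events in each named population (rows sum to 1)."""
    pops = sorted({p for s in labels.values() for p in s.unique()}
                  | set(POPULATION_NAMES))
    rows = {}
    for sample, s in labels.items():
        frac = s.value_counts(normalize=True)
        rows[sample] = [float(frac.get(p, 0.0)) for p in pops]
    return pd.DataFrame.from_dict(rows, orient="index", columns=pops)
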