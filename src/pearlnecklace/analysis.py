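"""Pearl/string decomposition of chain conformations and asymmetry statistics.

A pearl is a dense cluster of monomers: a monomer is *dense* when it has at
least ``n_dense`` non-bonded neighbors (chain distance >= 2) within ``r_c``;
pearls are the connected components of the dense monomers under the
within-``r_c`` contact graph, kept when they hold at least ``min_size``
monomers.  Remaining monomers within ``r_c`` of exactly one pearl are
re-attached to it; everything else is string/tail.  Defaults r_c = 1.5 sigma,
n_dense = 3, min_size = 4 separate taut strings (which have no non-bonded
contacts at all) from collapsed droplets.

From a decomposition follow the necklace observables: the pearl asymmetry
parameters x_i = m_i/Mp - 1/n and y_i = q_i/Qp - 1/n (mass-sorted,
sum-zero by construction), the string allocation ms = Ns/N and qs = Qs/Q,
densities of visited states, the pearl-number time series n(t), dwell times
and switching events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .landscape import SimplexPoint, vertex
from .simulator import Conformation, Trajectory

__all__ = [
    "PearlDecomposition",
    "StateSeries",
    "SwitchEvent",
    "DwellTimes",
    "identify_pearls",
    "asymmetry",
    "density_of_states",
    "count_timeseries",
    "dwell_times",
    "switching_path",
]

STRING_LABEL = 0


@dataclass(frozen=True)
class PearlDecomposition:
    """Per-monomer pearl/string labels and the derived necklace bookkeeping.

    ``labels[i]`` is the pearl id (1..n, mass-sorted descending) or 0 for
    string/tail monomers.  ``q`` holds per-pearl net charges projected onto
    the chain's majority sign, so Qp + Qs = Q holds for both PE and PA.
    """

    labels: np.ndarray
    m: np.ndarray            # per-pearl monomer counts, descending
    q: np.ndarray            # per-pearl charges (majority-sign projected)
    N: int
    Q: int                   # chain net charge (PE: #charges; PA: |majority-minority|)

    @property
    def n(self) -> int:
        return self.m.size

    @property
    def Mp(self) -> int:
        return int(self.m.sum())

    @property
    def Qp(self) -> int:
        return int(self.q.sum())

    @property
    def Ns(self) -> int:
        return self.N - self.Mp

    @property
    def Qs(self) -> int:
        return self.Q - self.Qp

    @property
    def ms(self) -> float:
        return self.Ns / self.N

    @property
    def qs(self) -> float:
        """Charge fraction on strings; NaN for a neutral chain."""
        return self.Qs / self.Q if self.Q != 0 else math.nan


def identify_pearls(
    conf: Conformation,
    r_c: float = 1.5,
    n_dense: int = 3,
    min_size: int = 4,
) -> PearlDecomposition:
    """Decompose a conformation into pearls and strings (deterministic)."""
    pos = conf.positions
    N = pos.shape[0]
    dist = squareform(pdist(pos))
    contact = dist < r_c
    np.fill_diagonal(contact, False)
    # bonded neighbors (chain distance <= 1) never count
    idx = np.arange(N)
    nonbonded = np.abs(idx[:, None] - idx[None, :]) >= 2
    contact &= nonbonded

    dense = contact.sum(axis=1) >= n_dense
    labels = np.zeros(N, dtype=np.int64)
    pearls: list[np.ndarray] = []
    if dense.any():
        sub = contact[np.ix_(dense, dense)]
        n_comp, comp = connected_components(csr_matrix(sub), directed=False)
        dense_idx = np.flatnonzero(dense)
        for c in range(n_comp):
            members = dense_idx[comp == c]
            if members.size >= min_size:
                pearls.append(members)

    if pearls:
        tentative = np.zeros(N, dtype=np.int64)
        for pid, members in enumerate(pearls, start=1):
            tentative[members] = pid
        # re-attach unassigned monomers in contact with exactly one pearl
        unassigned = np.flatnonzero(tentative == 0)
        for i in unassigned:
            touched = np.unique(tentative[contact[i]])
            touched = touched[touched > 0]
            if touched.size == 1:
                tentative[i] = touched[0]
        # relabel mass-sorted descending (stable: ties keep chain order)
        sizes = np.array([(tentative == pid).sum() for pid in range(1, len(pearls) + 1)])
        order = np.argsort(-sizes, kind="stable")
        for rank, pid in enumerate(order, start=1):
            labels[tentative == pid + 1] = rank

    z = conf.charges
    total = int(z.sum())
    if total > 0:
        majority = 1
    elif total < 0:
        majority = -1
    else:
        majority = 1
    n_pearls = int(labels.max())
    m = np.array([(labels == pid).sum() for pid in range(1, n_pearls + 1)], dtype=np.int64)
    q = np.array(
        [majority * int(z[labels == pid].sum()) for pid in range(1, n_pearls + 1)],
        dtype=np.int64,
    )
    Q = abs(total)
    return PearlDecomposition(labels=labels, m=m, q=q, N=N, Q=Q)


def asymmetry(decomp: PearlDecomposition):
    """Mass-sorted excess masses/charges (x_i, y_i) and the simplex point.

    x_i = m_i/Mp - 1/n and y_i = q_i/Qp - 1/n; both sum to zero by
    construction.  When the pearls carry no net charge (Qp = 0) the y_i are
    undefined and returned as NaN.
    """
    if decomp.n < 1 or decomp.Mp == 0:
        raise ValueError("decomposition has no pearls")
    n = decomp.n
    x = decomp.m / decomp.Mp - 1.0 / n
    if decomp.Qp != 0:
        y = decomp.q / decomp.Qp - 1.0 / n
    else:
        y = np.full(n, np.nan)
    point = SimplexPoint(n=n, coords=tuple(x[:-1]))
    return x, y, point


@dataclass(frozen=True)
class _FrameState:
    time: float
    n: int
    x: np.ndarray | None
    y: np.ndarray | None
    ms: float
    qs: float

    @property
    def simplex_point(self) -> SimplexPoint | None:
        if self.n < 1 or self.x is None:
            return None
        return SimplexPoint(n=self.n, coords=tuple(self.x[:-1]))


@dataclass
class StateSeries:
    """Per-frame pearl states of a trajectory at fixed sampling interval."""

    times: np.ndarray
    n: np.ndarray
    frames: list = field(default_factory=list)   # list[_FrameState]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.times.size != self.n.size:
            raise ValueError("times and n must be aligned")

    def __len__(self) -> int:
        return self.times.size

    @property
    def interval(self) -> float:
        if len(self) < 2:
            raise ValueError("need at least two samples to define an interval")
        dts = np.diff(self.times)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("series is not uniformly sampled")
        return float(dts[0])


def count_timeseries(
    traj: Trajectory,
    r_c: float = 1.5,
    n_dense: int = 3,
    min_size: int = 4,
) -> StateSeries:
    """Decompose every frame; frames with no detected pearl yield n = 0."""
    states = []
    for conf in traj:
        d = identify_pearls(conf, r_c=r_c, n_dense=n_dense, min_size=min_size)
        if d.n >= 1:
            x, y, _ = asymmetry(d)
            states.append(_FrameState(conf.time, d.n, x, y, d.ms, d.qs))
        else:
            states.append(_FrameState(conf.time, 0, None, None, 1.0,
                                      d.qs if d.Q else math.nan))
    return StateSeries(
        times=np.array([s.time for s in states]),
        n=np.array([s.n for s in states]),
        frames=states,
    )


@dataclass(frozen=True)
class DwellTimes:
    """Dwell durations of a given n-state; censored runs touch the series ends."""

    durations: tuple          # interior (complete) dwell durations, tau
    censored: tuple           # durations of runs touching either boundary
    n_state: int

    @property
    def mean(self) -> float:
        """Mean over complete dwells; NaN if the state was only seen censored."""
        return float(np.mean(self.durations)) if self.durations else math.nan


def dwell_times(series: StateSeries, n_state: int) -> DwellTimes:
    """Durations of maximal runs of n(t) == n_state (run length x interval).

    Runs touching the first or last sample are censored — their true length
    is unknown — and are excluded from the mean by default.
    """
    interval = series.interval
    n = series.n
    durations = []
    censored = []
    i = 0
    while i < n.size:
        if n[i] == n_state:
            j = i
            while j + 1 < n.size and n[j + 1] == n_state:
                j += 1
            length = (j - i + 1) * interval
            if i == 0 or j == n.size - 1:
                censored.append(length)
            else:
                durations.append(length)
            i = j + 1
        else:
            i += 1
    return DwellTimes(durations=tuple(durations), censored=tuple(censored),
                      n_state=n_state)


@dataclass(frozen=True)
class SwitchEvent:
    time: float
    n_before: int
    n_after: int
    point: SimplexPoint | None       # simplex location just after the switch
    nearest_vertex: int | None       # nl of the nearest V(nl, n-nl), or None


def switching_path(series: StateSeries) -> list:
    """One event per change of n(t), annotated with the post-change simplex
    location and its nearest vertex V(nl, n-nl) (Euclidean distance in the
    state's own simplex coordinates)."""
    if len(series) < 2:
        raise ValueError("series must have at least two samples")
    events = []
    for i in range(1, len(series)):
        if series.n[i] == series.n[i - 1]:
            continue
        st = series.frames[i] if series.frames else None
        point = st.simplex_point if st is not None else None
        nearest = None
        if point is not None and point.n >= 1:
            dists = [
                (np.linalg.norm(point.x_full - vertex(point.n, nl).x_full), nl)
                for nl in range(1, point.n + 1)
            ]
            nearest = min(dists)[1]
        events.append(SwitchEvent(
            time=float(series.times[i]), n_before=int(series.n[i - 1]),
            n_after=int(series.n[i]), point=point, nearest_vertex=nearest,
        ))
    return events


def density_of_states(
    states: Sequence,
    kind: str = "xy",
    n: int | None = 2,
    bins: int = 50,
    ranges=None,
):
    """2D histogram of visited states, normalized so the peak bin equals 1.

    ``kind="xy"``: each n-pearl state with the requested pearl count
    contributes one (x_i, y_i) point per pearl; states with Qp = 0 (undefined
    y) are skipped.  For n = 2 the histogram is made exactly point-symmetric
    about the origin by also binning the mirrored points (-x, -y) — the
    symmetry the sum-zero constraints impose.

    ``kind="msqs"``: one (ms, qs) point per state with the requested n (any n
    if ``n`` is None).

    ``states`` may be a StateSeries or an iterable of frame states.
    Returns (hist, x_edges, y_edges).
    """
    frames = states.frames if isinstance(states, StateSeries) else list(states)
    pts = []
    if kind == "xy":
        for st in frames:
            if st.n < 1 or (n is not None and st.n != n):
                continue
            if st.y is None or np.any(np.isnan(st.y)):
                continue
            for xi, yi in zip(st.x, st.y):
                pts.append((xi, yi))
    elif kind == "msqs":
        for st in frames:
            if st.n < 1 or (n is not None and st.n != n):
                continue
            if math.isnan(st.qs):
                continue
            pts.append((st.ms, st.qs))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if not pts:
        raise ValueError("no states selected for the histogram")
    pts = np.asarray(pts, dtype=float)

    symmetrize = kind == "xy" and n == 2
    if ranges is None:
        if symmetrize:
            lim_x = float(np.abs(pts[:, 0]).max()) or 1e-6
            lim_y = float(np.abs(pts[:, 1]).max()) or 1e-6
            ranges = [[-1.0001 * lim_x, 1.0001 * lim_x],
                      [-1.0001 * lim_y, 1.0001 * lim_y]]
        else:
            pad = 1e-9
            ranges = [[pts[:, 0].min() - pad, pts[:, 0].max() + pad],
                      [pts[:, 1].min() - pad, pts[:, 1].max() + pad]]
    hist, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins, range=ranges)
    if symmetrize:
        # bin the mirrored point set with the mirrored binning rule: exact
        hist = hist + hist[::-1, ::-1]
    peak = hist.max()
    if peak > 0:
        hist = hist / peak
    return hist, xe, ye
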