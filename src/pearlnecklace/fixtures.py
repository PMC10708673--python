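"""Synthetic necklace conformations and n(t) series with planted ground truth.

``make_necklace`` builds a pearl-necklace conformation from an explicit plan
(pearl sizes/charges, string lengths) so that every analysis operation can be
tested without running dynamics: pearls are compact balls of melt-like
density threaded by a single continuous chain path (concentric spherical
shell spirals plus a radial exit), strings are taut segments along the
necklace axis, and the junctions keep string monomers outside the detection
radius of the pearls, so the planted decomposition is recovered exactly by
``identify_pearls`` at (and around) its default parameters.

``make_switching_series`` plants an n(t) pattern with known dwell times and
simplex locations for the time-series operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .analysis import PearlDecomposition, StateSeries, _FrameState
from .landscape import vertex
from .simulator import Conformation

__all__ = ["NecklacePlan", "make_necklace", "make_switching_series"]


@dataclass(frozen=True)
class NecklacePlan:
    """Blueprint of a planted necklace.

    ``pearls`` is a sequence of (monomer_count, charge_count) pairs;
    ``strings`` the monomer counts of the connecting/terminal segments, one
    more entry than pearls (first and last are the tails and may be zero,
    interior strings must be positive to keep pearls separated).
    """

    pearls: tuple
    strings: tuple
    density: float = 0.8          # monomers / sigma^3 inside pearls
    string_spacing: float = 1.0   # sigma
    junction_gap: float = 1.4     # pearl pole cap to first string monomer, sigma
    string_charges: tuple | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        pearls = tuple((int(m), int(q)) for m, q in self.pearls)
        strings = tuple(int(s) for s in self.strings)
        object.__setattr__(self, "pearls", pearls)
        object.__setattr__(self, "strings", strings)
        if len(strings) != len(pearls) + 1:
            raise ValueError("need len(strings) == len(pearls) + 1 (tails included)")
        if self.density < 0.5:
            raise ValueError("pearl density must be >= 0.5 / sigma^3 (compact)")
        if not (0.9 <= self.string_spacing <= 1.1):
            raise ValueError("string spacing must lie in [0.9, 1.1] sigma")
        for m, q in pearls:
            if m < 12:
                raise ValueError(f"pearl of {m} monomers is below the buildable minimum (12)")
            if q > m:
                raise ValueError("pearl charge count cannot exceed its monomer count")
        for s in strings[1:-1]:
            if s < 1:
                raise ValueError("interior strings must have at least one monomer")
        if any(s < 0 for s in strings):
            raise ValueError("string lengths must be non-negative")

    @property
    def N(self) -> int:
        return sum(m for m, _ in self.pearls) + sum(self.strings)


# ---------------------------------------------------------------------------
# geometry helpers

def _spiral(r: float, n_pts: int, spacing_target: float) -> np.ndarray:
    """Pole-to-pole spiral on a sphere of radius r (polar axis = x) with
    ``n_pts`` points at equal arc spacing; starts at the -x pole, ends at +x.

    The number of turns is chosen so the arc spacing is as close as possible
    to ``spacing_target``.
    """
    if n_pts == 1:
        return np.array([[r, 0.0, 0.0]])
    theta_grid = np.linspace(0.0, math.pi, 2000)
    best = None
    t_max = max(2, int(math.ceil(math.pi * r / spacing_target)) + 2)
    for turns in range(1, t_max + 1):
        dl = r * np.sqrt(1.0 + (2.0 * turns) ** 2 * np.sin(theta_grid) ** 2)
        arc = np.trapezoid(dl, theta_grid)
        s = arc / (n_pts - 1)
        # feasible bond spacings first, then closeness to the target
        key = (s > 1.4, abs(s - spacing_target))
        if best is None or key < best[0]:
            best = (key, s, turns)
    _, spacing, turns = best
    if spacing > 1.4:
        raise ValueError(
            f"infeasible shell: {n_pts} points on radius {r:.2f} would need "
            f"bond spacing {spacing:.2f} sigma"
        )
    dl = r * np.sqrt(1.0 + (2.0 * turns) ** 2 * np.sin(theta_grid) ** 2)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (dl[1:] + dl[:-1]) * np.diff(theta_grid))])
    targets = np.linspace(0.0, cum[-1], n_pts)
    thetas = np.interp(targets, cum, theta_grid)
    phis = 2.0 * turns * thetas
    # theta measured from the -x pole
    x = -r * np.cos(thetas)
    yz_r = r * np.sin(thetas)
    return np.column_stack([x, yz_r * np.cos(phis), yz_r * np.sin(phis)])


_MAX_SPACING = 1.05  # sigma; keeps pearls internally connected down to r_c = 1.3
_CAP_OFFSET = 0.4   # sigma; pole caps push the string junction clear of the shell


def _ball_path(m: int, density: float) -> tuple:
    """Continuous chain path of ``m`` beads filling a ball (center at origin).

    Layout: an entry pole cap protruding ``_CAP_OFFSET`` beyond the -x pole,
    a center bead and K concentric shells at radii k*dR carrying bead counts
    proportional to their area, traversed as pole-to-pole spirals — outer
    shell first (trimmed short of the +x pole), inner shells alternating —
    then a radial exit along +x and an exit pole cap beyond the +x pole.
    The caps guarantee that the nearest *non-bonded* pearl bead seen from an
    adjacent string monomer is farther than any sensible detection radius,
    so planted decompositions are recovered exactly.  The shell spacing dR
    and the in-shell spacing are both capped at ``_MAX_SPACING`` so the ball
    never falls below the target density and stays connected at detection
    radii down to 1.3 sigma.  Returns (positions, half_length) with
    half_length the distance from the center to either cap.
    """
    a = density ** (-1.0 / 3.0)        # nominal spacing at the target density
    r_nom = (3.0 * m / (4.0 * math.pi * density)) ** (1.0 / 3.0)
    best = None
    for K in range(1, 9):
        n_tot = m - 3 - K              # beads on shells (center, drill, 2 caps removed)
        if n_tot < 3 * K:
            continue
        sum_k2 = K * (K + 1) * (2 * K + 1) // 6
        c = math.sqrt(4.0 * math.pi * sum_k2 / n_tot)   # s = c * dR
        dR = min(r_nom / K, _MAX_SPACING / c, _MAX_SPACING)
        if dR < 0.5:
            continue
        s = c * dR
        score = abs(dR - a) + abs(s - a)
        if best is None or score < best[0]:
            best = (score, K, dR, s)
    if best is None:
        raise ValueError(f"pearl of {m} monomers too small for shell construction")
    _, K, dR, s = best
    # area-proportional shell counts summing exactly to n_tot
    n_tot = m - 3 - K
    weights = np.arange(1, K + 1) ** 2
    counts = np.floor(n_tot * weights / weights.sum()).astype(int)
    counts = np.maximum(counts, 1)
    rema = n_tot - counts.sum()
    order_by_rem = np.argsort(-(n_tot * weights / weights.sum() - counts))
    for idx in order_by_rem[:abs(rema)]:
        counts[idx] += int(np.sign(rema))

    parts = []
    r_out = K * dR
    half = r_out + _CAP_OFFSET
    parts.append(np.array([[-half, 0.0, 0.0]]))          # entry pole cap
    # trim the outer spiral short of the +x pole: the radial exit ends there,
    # and a duplicated pole bead would pull the first string monomer within
    # the detection radius of a non-bonded pearl bead
    outer = _spiral(r_out, counts[K - 1] + 1, s)[:-1]    # -x pole -> near +x pole
    parts.append(outer)
    flip = True                                          # next shell starts at +x pole
    for k in range(K - 1, 0, -1):
        sh = _spiral(k * dR, counts[k - 1], s)
        if flip:
            sh = sh[::-1]
        parts.append(sh)
        flip = not flip
    parts.append(np.zeros((1, 3)))                       # center
    drill = np.zeros((K, 3))
    drill[:, 0] = dR * np.arange(1, K + 1)               # exit along +x to the +x pole
    parts.append(drill)
    parts.append(np.array([[half, 0.0, 0.0]]))           # exit pole cap
    pos = np.concatenate(parts)
    assert pos.shape[0] == m, (pos.shape[0], m)
    return pos, half


def _spread_indices(count: int, among: int) -> np.ndarray:
    """``count`` indices spread evenly over range(among)."""
    if count == 0:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.linspace(0, among - 1, count).round().astype(np.int64))


# ---------------------------------------------------------------------------
# operations

def make_necklace(plan: NecklacePlan, jitter: float = 0.0):
    """Build the planted conformation and its ground-truth decomposition.

    ``jitter`` adds Gaussian thermal noise of the given amplitude (sigma
    units, at most 0.1) to every coordinate; planted recovery is exact at
    jitter = 0 and robust to small jitter.

    Returns ``(Conformation, PearlDecomposition)``; pearls in the truth are
    mass-sorted descending, matching :func:`pearlnecklace.analysis.identify_pearls`.
    """
    if jitter < 0 or jitter > 0.1:
        raise ValueError("jitter amplitude must lie in [0, 0.1] sigma")
    sp = plan.string_spacing
    gap = plan.junction_gap
    positions = []
    chain_labels = []                 # pearl id in chain order, 0 for string
    cursor = 0.0                      # x of the last placed bead
    started = False

    def _place_string(count: int) -> None:
        nonlocal cursor, started
        for _ in range(count):
            x = cursor + (sp if started else 0.0)
            positions.append([x, 0.0, 0.0])
            chain_labels.append(0)
            cursor = x
            started = True

    n_pearls = len(plan.pearls)
    for i in range(n_pearls + 1):
        # string segment i, with the wider junction gap next to pearls
        count = plan.strings[i]
        for k in range(count):
            if not started:
                x = 0.0
            elif k == 0 and i > 0:
                x = cursor + gap      # leaving a pearl
            else:
                x = cursor + sp
            positions.append([x, 0.0, 0.0])
            chain_labels.append(0)
            cursor = x
            started = True
        if i == n_pearls:
            break
        m, _q = plan.pearls[i]
        ball, r = _ball_path(m, plan.density)
        entry = (cursor + (gap if started else 0.0)) + r   # ball center x
        ball = ball + np.array([entry, 0.0, 0.0])
        positions.extend(ball.tolist())
        chain_labels.extend([i + 1] * m)
        cursor = entry + r            # exit pole
        started = True

    pos = np.asarray(positions)
    chain_labels = np.asarray(chain_labels, dtype=np.int64)
    assert pos.shape[0] == plan.N

    # charges: spread each pearl's charge count evenly over its beads
    charges = np.zeros(plan.N, dtype=np.int64)
    for pid, (m, q) in enumerate(plan.pearls, start=1):
        members = np.flatnonzero(chain_labels == pid)
        charges[members[_spread_indices(q, m)]] = 1
    if plan.string_charges is not None:
        string_idx = np.flatnonzero(chain_labels == 0)
        if len(plan.string_charges) != 1 and len(plan.string_charges) != len(plan.strings):
            raise ValueError("string_charges must match the number of string segments")
        qs_total = sum(plan.string_charges)
        charges[string_idx[_spread_indices(qs_total, string_idx.size)]] = 1

    if jitter > 0:
        rng = np.random.default_rng(plan.seed)
        pos = pos + rng.normal(scale=jitter, size=pos.shape)

    conf = Conformation(pos, charges, 0.0)

    # ground truth, relabeled mass-sorted descending (stable on ties)
    sizes = np.array([(chain_labels == pid).sum() for pid in range(1, n_pearls + 1)])
    order = np.argsort(-sizes, kind="stable")
    labels = np.zeros(plan.N, dtype=np.int64)
    for rank, pidx in enumerate(order, start=1):
        labels[chain_labels == pidx + 1] = rank
    m_sorted = sizes[order]
    q_sorted = np.array(
        [int(charges[chain_labels == pidx + 1].sum()) for pidx in order], dtype=np.int64
    )
    truth = PearlDecomposition(
        labels=labels, m=m_sorted, q=q_sorted, N=plan.N, Q=int(abs(charges.sum())),
    )
    return conf, truth


def make_switching_series(
    pattern: Sequence, sampling: float, ms: float = 0.2, qs: float = 0.25
) -> StateSeries:
    """Planted n(t) series from segments of (n_state, duration[, coords]).

    Durations must be positive multiples of the sampling interval; each
    segment contributes duration/sampling samples.  ``coords`` (optional)
    places the segment at an explicit simplex location; by default segments
    sit at the one-large-pearl vertex V(1, n-1) of their own simplex.
    """
    if sampling <= 0:
        raise ValueError("sampling interval must be positive")
    times = []
    ns = []
    frames = []
    t = 0.0
    for seg in pattern:
        if len(seg) == 2:
            n_state, duration = seg
            coords = None
        else:
            n_state, duration, coords = seg
        k = duration / sampling
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise ValueError(
                f"duration {duration} is not a positive multiple of sampling={sampling}"
            )
        if n_state >= 1:
            if coords is None:
                x_full = vertex(n_state, 1).x_full if n_state > 1 else np.zeros(1)
            else:
                c = np.asarray(coords, dtype=float)
                x_full = np.concatenate([c, [-c.sum()]])
            y_full = x_full.copy()
        else:
            x_full = y_full = None
        for _ in range(int(round(k))):
            times.append(t)
            ns.append(int(n_state))
            frames.append(_FrameState(
                time=t, n=int(n_state), x=x_full, y=y_full,
                ms=(1.0 if n_state == 0 else ms), qs=qs,
            ))
            t += sampling
    return StateSeries(times=np.array(times), n=np.array(ns), frames=frames)
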