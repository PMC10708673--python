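"""Energy landscape of n-pearl states of a charged globule in poor solvent.

A necklace of ``n`` pearls is described by the relative excess masses
``x_i`` and excess charges ``y_i`` of its pearls, defined through

    m_i / Mp = 1/n + x_i,        q_i / Qp = 1/n + y_i,

so the even split is the zero vector.  Keeping only the pearl surface energy
and the electrostatic self-energy of each pearl (string energies and
pearl–pearl interactions are neglected), the energy in units of the surface
energy of the single-globule reference state is

    E = sum_i (1/n + x_i)^(2/3)
        + chi * sum_i (1/n + y_i)^2 / (1/n + x_i)^(1/3)
        - 1 - chi,

with chi the ratio of electrostatic to surface energy of the reference
globule.  Mass and charge conservation impose sum x_i = sum y_i = 0, so the
state space is 2(n-1)-dimensional; projecting onto the mass coordinates and
sorting them descending yields the (n-1)-simplex whose vertices V(nl, ns)
are states of nl equal large pearls and ns = n - nl vanishing pearls.

Because the energy is quadratic in the charges, every stationary point has
the charges "equilibrated": q_i* proportional to m_i^(1/3).  Eliminating the
charges exactly gives the reduced landscape

    E_eq(m) = sum_i m_i^(2/3) + chi / sum_i m_i^(1/3) - 1 - chi,

on which all extrema are located.  Stationary points come in two-group
families (nl large pearls of equal mass, ns small pearls of equal mass); the
symmetric state x = y = 0 turns from the highest-energy saddle into the
minimum at chi = n, and the asymmetric branches disappear at a critical
chi_c (equal to n for n = 2, strictly larger for the one-large-pearl branch
with n >= 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "AsymmetryState",
    "ExtremumRecord",
    "SimplexPoint",
    "energy",
    "symmetric_energy",
    "equilibrated_energy",
    "find_extremum",
    "chi_critical",
    "stability_transition",
    "vertex",
    "in_simplex",
    "classify_stability",
]

CONSTRAINT_TOL = 1e-12
_EIG_TOL = 1e-9


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class AsymmetryState:
    """An n-pearl state: control parameter chi and excess masses/charges."""

    n: int
    chi: float
    x: tuple
    y: tuple

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.x) != self.n or len(self.y) != self.n:
            raise ValueError("x and y must each have length n")
        if abs(sum(self.x)) > 1e-9 or abs(sum(self.y)) > 1e-9:
            raise ValueError("sum of x and of y must vanish (mass/charge conservation)")

    @property
    def masses(self) -> np.ndarray:
        return 1.0 / self.n + np.asarray(self.x, dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return 1.0 / self.n + np.asarray(self.y, dtype=float)


@dataclass(frozen=True)
class SimplexPoint:
    """Mass-sorted excess masses of an n-pearl state, smallest pearl excluded.

    ``coords`` holds x_1 >= ... >= x_{n-1}; the last excess mass is fixed by
    conservation, x_n = -sum(coords), and must keep 1/n + x_n >= 0.
    """

    n: int
    coords: tuple

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.coords) != self.n - 1:
            raise ValueError(f"coords must have length n-1={self.n - 1}")

    @property
    def x_full(self) -> np.ndarray:
        """All n excess masses, including the implied smallest one."""
        c = np.asarray(self.coords, dtype=float)
        return np.concatenate([c, [-c.sum()]])

    @classmethod
    def from_masses(cls, masses: Sequence[float]) -> "SimplexPoint":
        m = np.sort(np.asarray(masses, dtype=float))[::-1]
        total = m.sum()
        if total <= 0:
            raise ValueError("total mass must be positive")
        n = m.size
        x = m / total - 1.0 / n
        return cls(n=n, coords=tuple(x[:-1]))


@dataclass(frozen=True)
class ExtremumRecord:
    """A stationary point E(nl, ns) of the charge-equilibrated landscape."""

    n: int
    nl: int
    ns: int
    chi: float
    mass_large: float
    mass_small: float
    x_large: float
    x_small: float
    y_large: float
    y_small: float
    energy: float
    stability: str          # "minimum", "saddle", "maximum", or "degenerate"
    n_negative: int         # negative eigenvalues of the projected Hessian
    chi_c: float | None     # critical chi of this branch (None for nl = n)

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.mass_large] * self.nl + [self.mass_small] * self.ns)

    @property
    def simplex_point(self) -> SimplexPoint:
        return SimplexPoint.from_masses(self.masses)


# ---------------------------------------------------------------------------
# energies

def energy(state: AsymmetryState) -> float:
    """Energy of an n-pearl state, in units of the reference surface energy.

    A pearl of zero mass and zero charge contributes nothing; zero mass with
    nonzero charge is a domain error (infinite self-energy of a point charge).
    The single-globule reference (n=1, x=y=0) maps to exactly 0.
    """
    m = state.masses
    q = state.charges
    if abs(m.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("constraint violation: masses/charges must each sum to 1")
    if np.any(m < -CONSTRAINT_TOL):
        raise ValueError("negative pearl mass")
    m = np.clip(m, 0.0, None)
    zero_mass = m == 0.0
    if np.any(zero_mass & (np.abs(q) > CONSTRAINT_TOL)):
        raise ValueError("zero-mass pearl with nonzero charge has infinite self-energy")
    surf = np.sum(m ** (2.0 / 3.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        elec_terms = np.where(zero_mass, 0.0, q ** 2 / np.where(zero_mass, 1.0, m) ** (1.0 / 3.0))
    return float(surf + state.chi * elec_terms.sum() - 1.0 - state.chi)


def symmetric_energy(n: int, chi: float) -> float:
    """Energy of the evenly split n-pearl state: n^(1/3) + chi*n^(-2/3) - 1 - chi."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(n ** (1.0 / 3.0) + chi * n ** (-2.0 / 3.0) - 1.0 - chi)


def equilibrated_energy(masses: Sequence[float], chi: float) -> tuple:
    """Energy minimized over the charge split at fixed pearl masses.

    The electrostatic term is quadratic in the charges, so the constrained
    minimizer is q_i* = m_i^(1/3) / sum_j m_j^(1/3) (zero-mass pearls carry no
    charge) and the reduced energy is

        E_eq = sum m_i^(2/3) + chi / sum m_i^(1/3) - 1 - chi.

    Returns ``(energy, y_star)`` with y_i* = q_i* - 1/n.
    """
    m = np.asarray(masses, dtype=float)
    if np.any(m < -CONSTRAINT_TOL):
        raise ValueError("negative pearl mass")
    m = np.clip(m, 0.0, None)
    if abs(m.sum() - 1.0) > 1e-9:
        raise ValueError(f"masses must sum to 1, got {m.sum()}")
    if np.all(m == 0.0):
        raise ValueError("all masses zero")
    n = m.size
    s = np.sum(m ** (1.0 / 3.0))
    q_star = m ** (1.0 / 3.0) / s
    e = float(np.sum(m ** (2.0 / 3.0)) + chi / s - 1.0 - chi)
    return e, q_star - 1.0 / n


# ---------------------------------------------------------------------------
# simplex geometry

def vertex(n: int, nl: int) -> SimplexPoint:
    """Vertex V(nl, ns): nl pearls of mass 1/nl, n-nl pearls of mass 0."""
    if not (1 <= nl <= n):
        raise ValueError(f"nl must lie in [1, n], got nl={nl}, n={n}")
    x = [1.0 / nl - 1.0 / n] * nl + [-1.0 / n] * (n - nl)
    return SimplexPoint(n=n, coords=tuple(x[: n - 1]))


def in_simplex(point: SimplexPoint) -> tuple:
    """Whether the point lies in the closed (n-1)-simplex, plus any violations.

    The n linear inequalities are the n-1 ranking conditions
    x_1 >= x_2 >= ... >= x_n (with x_n implied by conservation) and the
    positivity of the smallest pearl, 1/n + x_n >= 0.
    """
    x = point.x_full
    n = point.n
    tol = 1e-12
    violations = []
    for i in range(n - 1):
        if x[i] < x[i + 1] - tol:
            violations.append(f"ranking violated: x_{i + 1}={x[i]:.6g} < x_{i + 2}={x[i + 1]:.6g}")
    if 1.0 / n + x[-1] < -tol:
        violations.append(f"smallest pearl mass negative: 1/n + x_n = {1.0 / n + x[-1]:.6g}")
    return (not violations), violations


# ---------------------------------------------------------------------------
# stationary points of the two-group ansatz

def _branch_chi(n: int, nl: int, u: float) -> float:
    """chi at which the (nl, ns) stationary branch sits at small-pearl mass u^3.

    Pairwise stationarity of E_eq between the large group (mass a) and the
    small group (mass b = u^3, nl*a + ns*b = 1) requires

        chi = 2 S^2 / (a^(-1/3) + b^(-1/3)),   S = nl a^(1/3) + ns b^(1/3),

    written here in the variable u = b^(1/3), which is regular at both the
    vertex (u = 0, chi = 0) and the symmetric point (u = (1/n)^(1/3),
    chi = n).
    """
    ns = n - nl
    b = u ** 3
    a = (1.0 - ns * b) / nl
    if a <= 0:
        raise ValueError("large-pearl mass must be positive")
    s = nl * a ** (1.0 / 3.0) + ns * u
    return 2.0 * s * s * u / (1.0 + u * a ** (-1.0 / 3.0))


def chi_critical(n: int, nl: int) -> float:
    """Critical chi beyond which the asymmetric (nl, ns) branch ceases to exist.

    Computed as the maximum of the branch condition chi(u) over the admissible
    small-pearl masses.  For the one-large-pearl branch with n >= 3 the
    maximum is an interior fold and chi_c > n; for n = 2 (and generally when
    the maximum sits at the symmetric point) chi_c = n and the branch simply
    merges with the symmetric state.
    """
    if not (1 <= nl < n):
        raise ValueError(f"require 1 <= nl < n, got nl={nl}, n={n}")
    u_sym = (1.0 / n) ** (1.0 / 3.0)
    res = minimize_scalar(
        lambda u: -_branch_chi(n, nl, u), bounds=(0.0, u_sym), method="bounded",
        options={"xatol": 1e-13},
    )
    if not res.success:
        raise RuntimeError(
            f"chi_c search failed for (n={n}, nl={nl}) on u in [0, {u_sym}]: {res.message}"
        )
    # the boundary u = u_sym (symmetric point) has chi = n exactly
    return max(float(-res.fun), float(n))


def find_extremum(n: int, nl: int, chi: float, branch: str = "primary"):
    """Locate the stationary point E(nl, ns) of the equilibrated landscape.

    For ``nl = n`` this is the symmetric state.  For ``nl < n`` the two-group
    ansatz (nl pearls of mass a, ns pearls of mass b) is solved for the
    stationary small-pearl mass.  ``branch="primary"`` follows the branch
    continuously connected to the vertex V(nl, ns) at chi -> 0 (the more
    asymmetric solution); ``branch="upper"`` returns, where it exists
    (n < chi < chi_c), the second, weakly asymmetric solution created at the
    chi = n bifurcation.  Returns ``None`` when the requested branch does not
    exist at this chi (e.g. chi > chi_c).
    """
    if not (1 <= nl <= n):
        raise ValueError(f"nl must lie in [1, n], got nl={nl}, n={n}")
    if chi < 0:
        raise ValueError("chi must be >= 0")
    ns = n - nl
    if n == 1:
        return ExtremumRecord(
            n=1, nl=1, ns=0, chi=chi, mass_large=1.0, mass_small=0.0,
            x_large=0.0, x_small=0.0, y_large=0.0, y_small=0.0,
            energy=0.0, stability="minimum", n_negative=0, chi_c=None,
        )
    if nl == n:
        masses = np.full(n, 1.0 / n)
        e = symmetric_energy(n, chi)
        stability, n_neg = classify_stability(masses, chi)
        return ExtremumRecord(
            n=n, nl=n, ns=0, chi=chi, mass_large=1.0 / n, mass_small=1.0 / n,
            x_large=0.0, x_small=0.0, y_large=0.0, y_small=0.0,
            energy=e, stability=stability, n_negative=n_neg, chi_c=None,
        )

    u_sym = (1.0 / n) ** (1.0 / 3.0)
    res = minimize_scalar(
        lambda u: -_branch_chi(n, nl, u), bounds=(0.0, u_sym), method="bounded",
        options={"xatol": 1e-13},
    )
    u_star = float(res.x)
    chi_c = max(float(-res.fun), float(n))

    if chi == 0.0:
        u_root = 0.0  # degenerate vertex solution
    elif branch == "primary":
        if chi > chi_c:
            return None
        f = lambda u: _branch_chi(n, nl, u) - chi
        if f(u_star) < 0:  # chi numerically above the fold
            return None
        u_root = brentq(f, 0.0, u_star, xtol=1e-15, rtol=8.9e-16)
    elif branch == "upper":
        if not (n < chi <= chi_c):
            return None
        f = lambda u: _branch_chi(n, nl, u) - chi
        if f(u_star) < 0:
            return None
        u_root = brentq(f, u_star, u_sym, xtol=1e-15, rtol=8.9e-16)
    else:
        raise ValueError(f"unknown branch {branch!r}")

    b = u_root ** 3
    a = (1.0 - ns * b) / nl
    masses = np.array([a] * nl + [b] * ns)
    e, y_star = equilibrated_energy(masses, chi)
    stability, n_neg = classify_stability(masses, chi)
    return ExtremumRecord(
        n=n, nl=nl, ns=ns, chi=chi, mass_large=a, mass_small=b,
        x_large=a - 1.0 / n, x_small=b - 1.0 / n,
        y_large=float(y_star[0]), y_small=float(y_star[-1]),
        energy=e, stability=stability, n_negative=n_neg, chi_c=chi_c,
    )


# ---------------------------------------------------------------------------
# stability

def _reduced_energy_fn(n: int, chi: float):
    """Full (x, y) energy as a function of orthonormal coordinates on the
    2(n-1)-dimensional constraint subspace sum x = sum y = 0."""
    basis = null_space(np.ones((1, n)))  # n x (n-1), orthonormal

    def f(z: np.ndarray, m0: np.ndarray, q0: np.ndarray) -> float:
        zx, zy = z[: n - 1], z[n - 1:]
        m = m0 + basis @ zx
        q = q0 + basis @ zy
        if np.any(m <= 0.0):
            return np.inf
        return float(np.sum(m ** (2.0 / 3.0)) + chi * np.sum(q ** 2 / m ** (1.0 / 3.0))
                     - 1.0 - chi)

    return f, basis


def projected_hessian(masses: Sequence[float], chi: float, h: float | None = None) -> np.ndarray:
    """Numerical Hessian of the full (x, y) energy at the charge-equilibrated
    state with the given masses, projected onto the constraint subspace."""
    m0 = np.asarray(masses, dtype=float)
    n = m0.size
    _, y_star = equilibrated_energy(m0, chi)
    q0 = 1.0 / n + y_star
    f, _ = _reduced_energy_fn(n, chi)
    dim = 2 * (n - 1)
    if h is None:
        h = min(1e-5, 0.05 * float(m0.min())) if m0.min() > 0 else 1e-5
    H = np.empty((dim, dim))
    z0 = np.zeros(dim)
    f0 = f(z0, m0, q0)
    for i in range(dim):
        for j in range(i, dim):
            zi = np.zeros(dim); zi[i] = h
            zj = np.zeros(dim); zj[j] = h
            if i == j:
                val = (f(z0 + 2 * zi, m0, q0) - 2 * f0 + f(z0 - 2 * zi, m0, q0)) / (4 * h * h)
            else:
                val = (f(z0 + zi + zj, m0, q0) - f(z0 + zi - zj, m0, q0)
                       - f(z0 - zi + zj, m0, q0) + f(z0 - zi - zj, m0, q0)) / (4 * h * h)
            H[i, j] = H[j, i] = val
    return H


def classify_stability(masses: Sequence[float], chi: float) -> tuple:
    """Classify a stationary point from its projected-Hessian eigenvalues.

    Returns ``(label, n_negative)`` with label "minimum", "maximum",
    "saddle", or "degenerate".  Eigenvalues below -1e-9 count negative,
    above +1e-9 positive.  States with a vanishing pearl mass cannot be
    classified by finite differences and are reported "degenerate".
    """
    m = np.asarray(masses, dtype=float)
    if m.min() < 1e-8:
        return "degenerate", 0
    H = projected_hessian(m, chi)
    # scale-aware degeneracy threshold
    scale = max(1.0, float(np.abs(H).max()))
    eig = np.linalg.eigvalsh(H)
    n_neg = int(np.sum(eig < -_EIG_TOL * scale))
    n_pos = int(np.sum(eig > _EIG_TOL * scale))
    dim = eig.size
    if n_neg + n_pos < dim:
        return "degenerate", n_neg
    if n_neg == 0:
        return "minimum", 0
    if n_pos == 0:
        return "maximum", n_neg
    return "saddle", n_neg


def stability_transition(n: int, bracket: tuple | None = None, tol: float = 1e-8) -> float:
    """chi at which the symmetric state's smallest projected-Hessian eigenvalue
    changes sign (saddle -> minimum).  Analytically this happens at chi = n;
    the value is found here by bisection on the numerically computed
    eigenvalue."""
    if n < 2:
        raise ValueError("n must be >= 2")
    masses = np.full(n, 1.0 / n)

    def smallest_eig(chi: float) -> float:
        return float(np.linalg.eigvalsh(projected_hessian(masses, chi)).min())

    lo, hi = bracket if bracket is not None else (0.25 * n, 2.0 * n)
    if smallest_eig(lo) >= 0 or smallest_eig(hi) <= 0:
        raise RuntimeError(f"bisection bracket ({lo}, {hi}) does not straddle the transition")
    return float(brentq(smallest_eig, lo, hi, xtol=tol))
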