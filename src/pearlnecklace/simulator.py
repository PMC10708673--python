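"""Langevin dynamics of a single coarse-grained bead-spring PE/PA chain.

The chain is the standard bead-spring model in implicit poor solvent at
infinite dilution: FENE bonds between consecutive beads, full (attractive,
unshifted) Lennard-Jones between all pairs with cutoff ``r_cut``, and bare
unscreened Coulomb ``lB z_i z_j / r`` among the charged beads; no explicit
counterions or salt.  Reduced units throughout: sigma = kT = m = 1, so the
time unit is tau = sigma*sqrt(m/kT) = 1.

Integration is BAOAB Langevin splitting: two half kicks and half drifts
around an exact Ornstein-Uhlenbeck velocity update.  With gamma = 0 the O
step is the identity and the scheme reduces to velocity Verlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._kernels import forces_and_energies
from .sequences import ChargeSequence

__all__ = [
    "ForceField",
    "Conformation",
    "Trajectory",
    "SimulationError",
    "build_initial_conformation",
    "potential_energy",
    "step_langevin",
    "run_protocol",
    "LangevinIntegrator",
    "radius_of_gyration",
]


class SimulationError(RuntimeError):
    """Raised on numerical divergence; carries the step index and, for
    protocol runs, the partial trajectory collected so far."""

    def __init__(self, message: str, step: int | None = None, partial=None):
        super().__init__(message)
        self.step = step
        self.partial = partial


@dataclass(frozen=True)
class ForceField:
    """Force-field constants in reduced units (sigma = kT = m = 1).

    Defaults follow the community-standard bead-spring parametrization:
    FENE k = 30 kT/sigma^2, R0 = 1.5 sigma; LJ cutoff 2.5 sigma with
    eps_LJ = 1.5 kT (a rather poor solvent, the PE default — use 1.0 for the
    marginally poor PA case); Bjerrum length 3 sigma; friction 1/tau.
    """

    fene_k: float = 30.0
    fene_r0: float = 1.5
    lj_eps: float = 1.5
    lj_sigma: float = 1.0
    lj_cutoff: float = 2.5
    bjerrum: float = 3.0
    gamma: float = 1.0
    kT: float = 1.0

    def __post_init__(self) -> None:
        for name in ("fene_k", "fene_r0", "lj_eps", "lj_sigma", "lj_cutoff", "kT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.lj_cutoff < 2 ** (1 / 6) * self.lj_sigma:
            raise ValueError("lj_cutoff must be at least 2^(1/6) sigma")

    @classmethod
    def pe_default(cls) -> "ForceField":
        return cls(lj_eps=1.5)

    @classmethod
    def pa_default(cls) -> "ForceField":
        return cls(lj_eps=1.0)

    def to_dict(self) -> dict:
        return {
            "fene_k": self.fene_k, "fene_r0": self.fene_r0, "lj_eps": self.lj_eps,
            "lj_sigma": self.lj_sigma, "lj_cutoff": self.lj_cutoff,
            "bjerrum": self.bjerrum, "gamma": self.gamma, "kT": self.kT,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForceField":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class Conformation:
    """Bead coordinates (sigma units), per-bead integer charges, and time (tau)."""

    positions: np.ndarray
    charges: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        z = np.asarray(self.charges, dtype=np.int64)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if z.shape != (pos.shape[0],):
            raise ValueError("charges must have shape (N,)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", z)

    @property
    def N(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Time-ordered conformations at a fixed sampling interval."""

    positions: np.ndarray          # (frames, N, 3)
    times: np.ndarray              # (frames,)
    charges: np.ndarray            # (N,)
    metadata: dict = field(default_factory=dict)
    diagnostics: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.charges = np.asarray(self.charges, dtype=np.int64)
        if self.positions.ndim != 3 or self.positions.shape[0] != self.times.size:
            raise ValueError("positions must be (frames, N, 3) aligned with times")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def __getitem__(self, i: int) -> Conformation:
        return Conformation(self.positions[i], self.charges, float(self.times[i]))

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @classmethod
    def from_frames(cls, frames: Sequence[Conformation], metadata=None, diagnostics=None):
        if not frames:
            raise ValueError("need at least one frame")
        return cls(
            positions=np.stack([f.positions for f in frames]),
            times=np.array([f.time for f in frames]),
            charges=frames[0].charges,
            metadata=metadata or {},
            diagnostics=diagnostics or [],
        )


def radius_of_gyration(positions: np.ndarray) -> float:
    pos = np.asarray(positions, dtype=float)
    return float(np.sqrt(((pos - pos.mean(axis=0)) ** 2).sum(axis=1).mean()))


def build_initial_conformation(
    seq: ChargeSequence, mode: str = "random-walk", seed: int | None = None,
    bond_length: float = 1.0,
) -> Conformation:
    """Initial chain configuration with charges placed on the charge sites.

    ``extended``: straight line along x with the given bond length.
    ``random-walk``: freely jointed unit steps, rejecting beads that come
    within 0.8 sigma of any earlier bead (with backtracking), so the start
    configuration has no hard overlaps.
    """
    z = seq.per_monomer_charges()
    N = seq.N
    if mode == "extended":
        pos = np.zeros((N, 3))
        pos[:, 0] = np.arange(N) * bond_length
        return Conformation(pos, z, 0.0)
    if mode != "random-walk":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    pos = np.zeros((N, 3))
    i = 1
    stuck = 0
    while i < N:
        v = rng.normal(size=3)
        v *= bond_length / np.linalg.norm(v)
        cand = pos[i - 1] + v
        d2 = ((pos[: max(i - 1, 0)] - cand) ** 2).sum(axis=1)
        if d2.size == 0 or d2.min() >= 0.8 ** 2:
            pos[i] = cand
            i += 1
            stuck = 0
        else:
            stuck += 1
            if stuck > 200:  # back off one bead and retry
                i = max(1, i - 1)
                stuck = 0
    return Conformation(pos, z, 0.0)


def potential_energy(conf: Conformation, ff: ForceField) -> dict:
    """Potential-energy components in kT: bond, lj, coulomb, total."""
    _, e_bond, e_lj, e_coul, diverged = forces_and_energies(
        conf.positions, conf.charges.astype(np.float64),
        ff.lj_eps, ff.lj_sigma, ff.lj_cutoff, ff.bjerrum, ff.fene_k, ff.fene_r0,
    )
    if diverged:
        raise SimulationError("bond length beyond FENE divergence length r0")
    return {"bond": e_bond, "lj": e_lj, "coulomb": e_coul,
            "total": e_bond + e_lj + e_coul}


class LangevinIntegrator:
    """BAOAB Langevin integrator holding positions, velocities and RNG state."""

    def __init__(
        self,
        conf: Conformation,
        ff: ForceField,
        dt: float = 0.005,
        seed: int | np.random.Generator | None = None,
        velocities: np.ndarray | str | None = "maxwell",
    ):
        if dt > 0.01:
            raise ValueError("dt must not exceed 0.01 tau")
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.ff = ff
        self.dt = float(dt)
        self.rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.positions = conf.positions.copy()
        self.charges = conf.charges.copy()
        self._zf = self.charges.astype(np.float64)
        self.time = float(conf.time)
        self.step_count = 0
        N = conf.N
        if isinstance(velocities, str) and velocities == "maxwell":
            self.velocities = self.rng.normal(scale=math.sqrt(ff.kT), size=(N, 3))
        elif velocities is None:
            self.velocities = np.zeros((N, 3))
        else:
            self.velocities = np.asarray(velocities, dtype=float).copy()
        # OU coefficients for the exact velocity update
        c1 = math.exp(-ff.gamma * self.dt)
        self._c1 = c1
        self._c2 = math.sqrt((1.0 - c1 * c1) * ff.kT)
        self.forces = self._compute_forces()

    def _compute_forces(self) -> np.ndarray:
        f, e_bond, e_lj, e_coul, diverged = forces_and_energies(
            self.positions, self._zf,
            self.ff.lj_eps, self.ff.lj_sigma, self.ff.lj_cutoff,
            self.ff.bjerrum, self.ff.fene_k, self.ff.fene_r0,
        )
        if diverged or not np.all(np.isfinite(f)):
            raise SimulationError(
                f"diverged at step {self.step_count} (t={self.time:.3f} tau)",
                step=self.step_count,
            )
        self._energies = (e_bond, e_lj, e_coul)
        return f

    def step(self, n_steps: int = 1) -> None:
        dt = self.dt
        half = 0.5 * dt
        for _ in range(n_steps):
            self.velocities += half * self.forces
            self.positions += half * self.velocities
            if self.ff.gamma > 0:
                noise = self.rng.normal(size=self.positions.shape)
                self.velocities = self._c1 * self.velocities + self._c2 * noise
            self.positions += half * self.velocities
            self.forces = self._compute_forces()
            self.velocities += half * self.forces
            self.step_count += 1
            self.time += dt

    @property
    def conformation(self) -> Conformation:
        return Conformation(self.positions.copy(), self.charges.copy(), self.time)

    def kinetic_energy(self) -> float:
        return float(0.5 * (self.velocities ** 2).sum())

    def energies(self) -> dict:
        e_bond, e_lj, e_coul = self._energies
        return {"bond": e_bond, "lj": e_lj, "coulomb": e_coul,
                "kinetic": self.kinetic_energy(),
                "total": e_bond + e_lj + e_coul + self.kinetic_energy()}


def step_langevin(
    conf: Conformation,
    ff: ForceField,
    dt: float,
    seed: int | np.random.Generator | None = None,
    velocities: np.ndarray | None = None,
    n_steps: int = 1,
) -> Conformation:
    """Advance a conformation by ``n_steps`` BAOAB updates (stateless wrapper)."""
    integ = LangevinIntegrator(conf, ff, dt=dt, seed=seed,
                               velocities=velocities if velocities is not None else None)
    integ.step(n_steps)
    return integ.conformation


def run_protocol(
    seq: ChargeSequence,
    ff: ForceField,
    t_equil: float,
    t_prod: float,
    sample_every: float,
    dt: float = 0.005,
    seed: int | None = None,
    initial: str = "random-walk",
) -> Trajectory:
    """Equilibrate, then sample the production run at a fixed interval.

    Returns ``floor(t_prod / sample_every)`` frames taken at the end of each
    sampling interval, with per-sample diagnostics (energy components,
    kinetic energy, radius of gyration).  On divergence a
    :class:`SimulationError` carrying the partial trajectory is raised.
    """
    if t_equil <= 0 or t_prod <= 0:
        raise ValueError("t_equil and t_prod must be positive")
    rng = np.random.default_rng(seed)
    conf0 = build_initial_conformation(seq, mode=initial, seed=rng.integers(2 ** 31))
    integ = LangevinIntegrator(conf0, ff, dt=dt, seed=rng)
    n_equil = int(round(t_equil / dt))
    n_per_sample = int(round(sample_every / dt))
    n_samples = int(math.floor(t_prod / sample_every))
    frames: list = []
    diagnostics: list = []
    metadata = {
        "force_field": ff.to_dict(), "seed": seed, "dt": dt,
        "t_equil": t_equil, "t_prod": t_prod, "sample_every": sample_every,
        "model": seq.model, "N": seq.N, "p": seq.p, "Q": seq.Q,
        "sequence_seed": seq.seed, "initial": initial,
    }
    try:
        integ.step(n_equil)
        for _ in range(n_samples):
            integ.step(n_per_sample)
            frames.append(integ.conformation)
            diag = integ.energies()
            diag["time"] = integ.time
            diag["rg"] = radius_of_gyration(integ.positions)
            diagnostics.append(diag)
    except SimulationError as err:
        partial = Trajectory.from_frames(frames, metadata, diagnostics) if frames else None
        raise SimulationError(str(err), step=err.step, partial=partial) from err
    return Trajectory.from_frames(frames, metadata, diagnostics)
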