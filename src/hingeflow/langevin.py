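"""Langevin dynamics on a constrained double-well potential.

The hinge transport of water between Layer-1 and Layer-2 is reduced to a
single particle of water mass diffusing on a 1D double well along z.  The
well minima sit at the mean octanol molecular lengths of the two layers
(-0.868 nm and +0.854 nm), the barrier at z = 0, and the two barrier
heights are the forward/reverse Arrhenius activation energies.  The
potential is a piecewise quartic: on each side of the barrier

    U(z) = -E_a + E_a (2 s^2 - s^4),   s = (z - z_min) / |z_min| ,

which has U' = 0 at the minimum and the barrier, U(0) = 0 and well depth
E_a exactly, with harmonic continuations beyond the minima matching the
local curvature.  Dynamics follow the underdamped Langevin equation
M z̈ = -U'(z) - γ M ż + √(2 M γ k_B T) R(t), discretised with BAOAB.

Internal units: Å, ps, amu, kcal/mol (1 kcal/mol = 418.4 amu Å²/ps²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

R_KCAL = 1.98720425864083e-3  # kcal mol^-1 K^-1
KCAL_TO_AKMA = 418.4  # kcal/mol → amu Å^2 ps^-2
WATER_MASS = 18.015  # amu


@dataclass
class DoubleWellSpec:
    """Well positions in nm (field convention), barrier heights in kcal/mol."""

    z_left: float = -0.868  # nm
    z_right: float = 0.854  # nm
    barrier_z: float = 0.0
    Ea_fwd: float = 6.00  # kcal/mol, left→right barrier
    Ea_rev: float = 5.60  # kcal/mol, right→left barrier

    def __post_init__(self) -> None:
        if not (self.z_left < 0.0 < self.z_right):
            raise ValueError("wells must straddle the barrier: z_left < 0 < z_right")
        if self.barrier_z != 0.0:
            raise ValueError("the barrier is fixed at z = 0")
        if self.Ea_fwd <= 0 or self.Ea_rev <= 0:
            raise ValueError("barrier heights must be positive")


@dataclass
class LdConfig:
    T: float = 300.0  # K
    mass: float = WATER_MASS  # amu
    friction: float = 0.5  # ps^-1
    dt: float = 0.02  # ps, inner integration step
    sample_interval: float = 1.0  # ps
    n_samples: int = 100_000
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.T, self.mass, self.friction, self.dt, self.sample_interval) <= 0:
            raise ValueError("T, mass, friction, dt, sample_interval must be positive")
        if self.dt > self.sample_interval:
            raise ValueError("dt must not exceed sample_interval")


def build_double_well(spec: DoubleWellSpec):
    """Return vectorised (U, force) callables, z in nm, U in kcal/mol.

    The built potential satisfies U(0)-U(z_left) = Ea_fwd and
    U(0)-U(z_right) = Ea_rev to better than 1e-9, with U' = 0 at both
    minima and the barrier.
    """
    zl, zr = spec.z_left, spec.z_right
    ef, er = spec.Ea_fwd, spec.Ea_rev
    kl = 4.0 * ef / zl**2
    kr = 4.0 * er / zr**2

    def U(z):
        z = np.asarray(z, dtype=float)
        out = np.empty_like(z)
        left_h = z < zl
        left = (z >= zl) & (z <= 0)
        right = (z > 0) & (z <= zr)
        right_h = z > zr
        out[left_h] = -ef + 0.5 * kl * (z[left_h] - zl) ** 2
        s = (z[left] - zl) / (-zl)
        out[left] = -ef + ef * (2 * s**2 - s**4)
        s = (zr - z[right]) / zr
        out[right] = -er + er * (2 * s**2 - s**4)
        out[right_h] = -er + 0.5 * kr * (z[right_h] - zr) ** 2
        return out

    def force(z):
        z = np.asarray(z, dtype=float)
        out = np.empty_like(z)
        left_h = z < zl
        left = (z >= zl) & (z <= 0)
        right = (z > 0) & (z <= zr)
        right_h = z > zr
        out[left_h] = -kl * (z[left_h] - zl)
        s = (z[left] - zl) / (-zl)
        out[left] = ef * (4 * s - 4 * s**3) / zl  # zl < 0: restoring
        s = (zr - z[right]) / zr
        out[right] = er * (4 * s - 4 * s**3) / zr
        out[right_h] = -kr * (z[right_h] - zr)
        return out

    # sanity: the stated constraints hold exactly (up to float rounding)
    for z0, target in ((zl, -ef), (zr, -er), (0.0, 0.0)):
        if abs(float(U(np.array([z0]))[0]) - target) > 1e-9:
            raise AssertionError("double-well constraint violated")
    return U, force


@njit(cache=True, inline="always", fastmath=True)
def _force_akma(z, zl, zr, ef, er, kl, kr):
    """-dU/dz in amu Å ps^-2; z and well positions in Å, Ea pre-scaled."""
    if z < zl:
        return -kl * (z - zl)
    if z <= 0.0:
        s = (z - zl) / (-zl)
        return ef * (4.0 * s - 4.0 * s * s * s) / zl
    if z <= zr:
        s = (zr - z) / zr
        return er * (4.0 * s - 4.0 * s * s * s) / zr
    return -kr * (z - zr)


@njit(cache=True, fastmath=True)
def _run_replicate(
    seed,
    z0,
    mass,
    kT,
    friction,
    dt,
    n_inner,
    n_samples,
    zl,
    zr,
    ef,
    er,
    kl,
    kr,
    store,
):
    np.random.seed(seed)
    z = z0
    v = math.sqrt(kT / mass) * np.random.normal()
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(kT / mass * (1.0 - c1 * c1))
    fwd = 0
    bwd = 0
    well = 0  # 0 = left, 1 = right
    n_store = n_samples if store else 0
    pos = np.empty(n_store)
    vel = np.empty(n_store)
    diverged = False
    half = 0.5 * dt
    f = _force_akma(z, zl, zr, ef, er, kl, kr)
    for s_idx in range(n_samples):
        for _ in range(n_inner):
            v += half * f / mass
            z += half * v
            v = c1 * v + c2 * np.random.normal()
            z += half * v
            f = _force_akma(z, zl, zr, ef, er, kl, kr)
            v += half * f / mass
        if store:
            pos[s_idx] = z
            vel[s_idx] = v
        if well == 0 and z >= zr:
            fwd += 1
            well = 1
        elif well == 1 and z <= zl:
            bwd += 1
            well = 0
        if abs(z) > 10.0 * abs(zr) or abs(z) > 10.0 * abs(zl):
            diverged = True
            break
    return fwd, bwd, pos, vel, diverged


@dataclass
class LDTrajectory:
    times: np.ndarray  # ps
    positions: np.ndarray  # (n_stored, n_samples), nm
    velocities: np.ndarray  # (n_stored, n_samples), nm/ps


@dataclass
class CrossingRecord:
    forward: np.ndarray  # per-replicate counts
    backward: np.ndarray
    ratio: float
    sem: float
    friction: float
    seed: int

    @property
    def total_forward(self) -> int:
        return int(self.forward.sum())

    @property
    def total_backward(self) -> int:
        return int(self.backward.sum())


def simulate(
    spec: DoubleWellSpec,
    config: LdConfig,
    store_replicates: int = 0,
) -> tuple[LDTrajectory, CrossingRecord]:
    """Run ``n_replicates`` independent Langevin trajectories on the well.

    Every replicate starts at the left minimum with a Maxwell-Boltzmann
    velocity.  A well-to-well transition is counted when the particle,
    last assigned to one minimum, reaches the other minimum's z position
    (hysteresis at the minima, evaluated at the 1 ps sample points), so
    per-replicate forward and backward counts differ by at most one.  The
    crossing ratio is Σ forward / Σ backward over all replicates with a
    3-block SEM over replicate blocks.
    """
    n_inner = int(round(config.sample_interval / config.dt))
    zl = spec.z_left * 10.0  # nm → Å
    zr = spec.z_right * 10.0
    ef = spec.Ea_fwd * KCAL_TO_AKMA
    er = spec.Ea_rev * KCAL_TO_AKMA
    kl = 4.0 * ef / zl**2
    kr = 4.0 * er / zr**2
    kT = R_KCAL * config.T * KCAL_TO_AKMA

    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_replicates)
    fwd = np.zeros(config.n_replicates, dtype=int)
    bwd = np.zeros(config.n_replicates, dtype=int)
    pos_list, vel_list = [], []
    for r in range(config.n_replicates):
        store = r < store_replicates
        f, b, pos, vel, diverged = _run_replicate(
            seeds[r],
            zl,
            config.mass,
            kT,
            config.friction,
            config.dt,
            n_inner,
            config.n_samples,
            zl,
            zr,
            ef,
            er,
            kl,
            kr,
            store,
        )
        if diverged:
            raise RuntimeError(
                f"replicate {r} diverged (|z| > 10 |z_min|); try a smaller dt"
            )
        fwd[r], bwd[r] = f, b
        if store:
            pos_list.append(pos * 0.1)  # Å → nm
            vel_list.append(vel * 0.1)

    total_b = bwd.sum()
    ratio = fwd.sum() / total_b if total_b > 0 else float("inf")
    blocks = np.array_split(np.arange(config.n_replicates), 3)
    block_ratios = []
    for blk in blocks:
        b = bwd[blk].sum()
        if b > 0:
            block_ratios.append(fwd[blk].sum() / b)
    sem = (
        float(np.std(block_ratios, ddof=1) / math.sqrt(len(block_ratios)))
        if len(block_ratios) > 1
        else float("nan")
    )
    times = np.arange(config.n_samples) * config.sample_interval
    traj = LDTrajectory(
        times=times,
        positions=np.array(pos_list) if pos_list else np.empty((0, 0)),
        velocities=np.array(vel_list) if vel_list else np.empty((0, 0)),
    )
    record = CrossingRecord(
        forward=fwd,
        backward=bwd,
        ratio=float(ratio),
        sem=sem,
        friction=config.friction,
        seed=config.seed,
    )
    return traj, record


@dataclass
class OccupancyReport:
    observed_left: float
    observed_right: float
    boltzmann_left: float
    boltzmann_right: float
    sem: float
    flagged: bool  # a well was never visited


def occupancy_check(
    traj: LDTrajectory, spec: DoubleWellSpec, config: LdConfig
) -> OccupancyReport:
    """Compare basin occupancies against basin-integrated Boltzmann weights.

    Basins are split at the barrier (z = 0); the reference weights are
    ∫ exp(-U/kT) dz over each basin (quadrature out to 4 harmonic widths
    past the minima).  The SEM is a 3-block average over stored replicates.
    """
    if traj.positions.size == 0:
        raise ValueError("trajectory holds no stored positions")
    z = traj.positions
    visited_left = bool((z < 0).any())
    visited_right = bool((z > 0).any())
    flagged = not (visited_left and visited_right)

    obs_left = float((z < 0).mean())
    per_rep = (z < 0).mean(axis=1)
    if len(per_rep) >= 3:
        bm = np.array([b.mean() for b in np.array_split(per_rep, 3)])
        sem = float(bm.std(ddof=1) / math.sqrt(3))
    else:
        n = z.shape[1]
        bm = np.array([b.mean() for b in np.array_split((z < 0).ravel(), 3)])
        sem = float(bm.std(ddof=1) / math.sqrt(3))

    U, _ = build_double_well(spec)
    kT = R_KCAL * config.T
    pad_l = 4.0 * math.sqrt(kT / (4 * spec.Ea_fwd / spec.z_left**2))
    pad_r = 4.0 * math.sqrt(kT / (4 * spec.Ea_rev / spec.z_right**2))
    zg_l = np.linspace(spec.z_left - pad_l, 0.0, 4001)
    zg_r = np.linspace(0.0, spec.z_right + pad_r, 4001)
    u0 = min(-spec.Ea_fwd, -spec.Ea_rev)  # shift to avoid overflow
    w_l = np.trapezoid(np.exp(-(U(zg_l) - u0) / kT), zg_l)
    w_r = np.trapezoid(np.exp(-(U(zg_r) - u0) / kT), zg_r)
    boltz_left = float(w_l / (w_l + w_r))
    return OccupancyReport(
        observed_left=obs_left,
        observed_right=1.0 - obs_left,
        boltzmann_left=boltz_left,
        boltzmann_right=1.0 - boltz_left,
        sem=sem,
        flagged=flagged,
    )
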