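"""Dynamic model: a coarse-grained helix-favoring polymer under annealing.

The polymer is a string of unit-mass particles joined by rigid bonds (SHAKE
constraints).  Three interactions act on it, all in reduced units with the
Boltzmann constant equal to 1:

* a purely repulsive truncated-shifted Lennard-Jones (WCA) pair potential,
  ``V(r) = 4[(1/r)^12 - (1/r)^6] + 1`` for ``r < r_cut = 2^(1/6)``, between
  all particle pairs except directly bonded neighbors, with the minimum-image
  convention in a cubic periodic box;
* a stiff harmonic bend restraint ``V = bend_k * (phi - phi_eq)^2`` holding
  the deflection angle between consecutive bonds at ``phi_eq = 2*pi/hp``
  (``hp`` links per helix turn);
* a torsion potential ``V = torsion_k * (1 - cos(tau - theta0))`` on every
  dihedral of four consecutive particles, with equilibrium
  ``theta0 = arcsin(1.1 * r_cut / (hp * l))`` chosen so that successive helix
  turns clear each other by slightly more than the pair cutoff.

With ten links and ``hp = 5`` the ground state is a two-turn helix.  Newton's
equations are integrated by the leap-frog scheme; a velocity-scaling bath
pins the instantaneous kinetic temperature to a target that is annealed
geometrically (``T <- gamma * T`` every ``anneal_period`` steps after an
initial burn-in).  Cooling from a random coil folds the chain ("freezing");
reversing the schedule unfolds it ("melting"); concatenating the two gives a
single fold/unfold trajectory with the folded state at its midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from ._geometry import chain_from_internal
from .containers import (InvalidInputError, InvalidParameterError,
                         StructureEnsemble, concatenate_ensembles)

__all__ = [
    "DynamicsConfig",
    "freezing_config",
    "melting_config",
    "annealing_temperature",
    "init_random_coil",
    "init_ideal_helix",
    "simulate_anneal",
    "concatenate_fold_unfold",
    "potential_energy",
    "IntegrationError",
]

DEFAULT_R_CUT = 2.0 ** (1.0 / 6.0)


class IntegrationError(RuntimeError):
    """SHAKE failed to converge during integration."""


@dataclass(frozen=True)
class DynamicsConfig:
    """Parameters of the dynamic model, in reduced units (k_B = 1).

    ``T0`` is the initial bath temperature and ``gamma`` the geometric
    annealing factor; ``gamma < 1`` cools (folds), ``gamma > 1`` heats
    (unfolds).
    """

    T0: float
    gamma: float
    n_links: int = 10
    link_length: float = 1.3
    helix_period: int = 5
    r_cut: float = DEFAULT_R_CUT
    timestep: float = 0.004
    box_side: float = 12.0
    torsion_k: float = 5.0
    bend_k: float = 100.0
    total_steps: int = 210_000
    anneal_period: int = 4_000
    burn_in: int = 10_000
    save_period: int = 400

    def __post_init__(self) -> None:
        if self.n_links < 3:
            raise InvalidParameterError("n_links must be >= 3 (need a dihedral)")
        s = 1.1 * self.r_cut / (self.helix_period * self.link_length)
        if not 0.0 < s <= 1.0:
            raise InvalidParameterError(
                f"1.1*r_cut/(hp*l) = {s:.4f} outside (0, 1]; theta0 undefined"
            )
        if self.total_steps < self.burn_in:
            raise InvalidParameterError("total_steps must be >= burn_in")
        prod = self.total_steps - self.burn_in
        if prod % self.anneal_period or prod % self.save_period:
            raise InvalidParameterError(
                "anneal_period and save_period must divide total_steps - burn_in"
            )

    @property
    def n_particles(self) -> int:
        return self.n_links + 1

    @property
    def phi_eq(self) -> float:
        """Fixed deflection angle between consecutive bonds, 2*pi/hp."""
        return 2.0 * math.pi / self.helix_period

    @property
    def theta_eq(self) -> float:
        """Equilibrium torsion angle theta0 = arcsin(1.1*r_cut/(hp*l))."""
        return math.asin(1.1 * self.r_cut / (self.helix_period * self.link_length))

    @property
    def n_saved_frames(self) -> int:
        return (self.total_steps - self.burn_in) // self.save_period

    @property
    def dof(self) -> int:
        """Kinetic degrees of freedom: 3N minus the rigid-bond constraints."""
        return 3 * self.n_particles - self.n_links


def freezing_config(**overrides) -> DynamicsConfig:
    """Folding run: start hot (T0 = 6) and cool by gamma = 0.925."""
    return replace(DynamicsConfig(T0=6.0, gamma=0.925), **overrides)


def melting_config(**overrides) -> DynamicsConfig:
    """Unfolding run: start cold (T0 = 0.1217) and heat by gamma = 1.0811."""
    return replace(DynamicsConfig(T0=0.1217, gamma=1.0811), **overrides)


def annealing_temperature(config: DynamicsConfig, step: int) -> float:
    """Bath target temperature at an integration step.

    The temperature is ``T0`` through the burn-in, then multiplied by
    ``gamma`` at every annealing event (steps ``burn_in + anneal_period*i``,
    the final step included).
    """
    if not 0 <= step <= config.total_steps:
        raise InvalidParameterError(
            f"step {step} outside [0, {config.total_steps}]"
        )
    if step <= config.burn_in:
        return config.T0
    events = (step - config.burn_in) // config.anneal_period
    return config.T0 * config.gamma ** events


def init_random_coil(config: DynamicsConfig, seed: int,
                     min_separation: float = 0.8) -> np.ndarray:
    """Random coil: equilibrium bends, torsions i.i.d. uniform on [0, 2*pi).

    Torsion sets placing any non-bonded pair closer than ``min_separation``
    (deep inside the repulsive core, where the resulting force would exceed
    the integrator's stable range) are rejected and redrawn; such overlaps
    carry enormous potential energy and are not representative coil states.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    n_bonds = config.n_links
    deflections = np.full(n_bonds - 1, config.phi_eq)
    for _ in range(1000):
        torsions = rng.uniform(0.0, 2.0 * np.pi, n_bonds - 2)
        pos = chain_from_internal(config.link_length, deflections, torsions)
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff * diff).sum(axis=2))
        iu = np.triu_indices(config.n_particles, 2)  # non-bonded pairs only
        if dist[iu].min() >= min_separation:
            return pos
    raise InvalidParameterError(
        "could not draw an overlap-free random coil; min_separation too large"
    )


def init_ideal_helix(config: DynamicsConfig) -> np.ndarray:
    """Ideal helix: equilibrium bends and all torsions at theta0."""
    n_bonds = config.n_links
    deflections = np.full(n_bonds - 1, config.phi_eq)
    torsions = np.full(n_bonds - 2, config.theta_eq)
    return chain_from_internal(config.link_length, deflections, torsions)


# --------------------------------------------------------------------------
# numba kernels


@njit(cache=False)
def _forces(pos, box, rcut2, kbend, phi_eq, ktor, theta0, F):
    n = pos.shape[0]
    F[:, :] = 0.0
    energy = 0.0
    # WCA repulsion between non-bonded pairs, minimum image
    for i in range(n - 2):
        for j in range(i + 2, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rcut2:
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                inv12 = inv6 * inv6
                energy += 4.0 * (inv12 - inv6) + 1.0
                coef = (48.0 * inv12 - 24.0 * inv6) * inv2
                F[i, 0] += coef * dx
                F[i, 1] += coef * dy
                F[i, 2] += coef * dz
                F[j, 0] -= coef * dx
                F[j, 1] -= coef * dy
                F[j, 2] -= coef * dz
    # harmonic restraint on the deflection angle at each internal joint
    for i in range(1, n - 1):
        ux = pos[i, 0] - pos[i - 1, 0]
        uy = pos[i, 1] - pos[i - 1, 1]
        uz = pos[i, 2] - pos[i - 1, 2]
        vx = pos[i + 1, 0] - pos[i, 0]
        vy = pos[i + 1, 1] - pos[i, 1]
        vz = pos[i + 1, 2] - pos[i, 2]
        lu = math.sqrt(ux * ux + uy * uy + uz * uz)
        lv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (lu * lv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        alpha = math.acos(c)
        energy += kbend * (alpha - phi_eq) ** 2
        s2 = 1.0 - c * c
        if s2 < 1e-16:
            continue  # angle gradient singular exactly at 0 or pi
        dVda = 2.0 * kbend * (alpha - phi_eq)
        dadc = -1.0 / math.sqrt(s2)
        pref = dVda * dadc
        # dc/du and dc/dv
        dcux = vx / (lu * lv) - c * ux / (lu * lu)
        dcuy = vy / (lu * lv) - c * uy / (lu * lu)
        dcuz = vz / (lu * lv) - c * uz / (lu * lu)
        dcvx = ux / (lu * lv) - c * vx / (lv * lv)
        dcvy = uy / (lu * lv) - c * vy / (lv * lv)
        dcvz = uz / (lu * lv) - c * vz / (lv * lv)
        F[i - 1, 0] += pref * dcux
        F[i - 1, 1] += pref * dcuy
        F[i - 1, 2] += pref * dcuz
        F[i, 0] -= pref * (dcux - dcvx)
        F[i, 1] -= pref * (dcuy - dcvy)
        F[i, 2] -= pref * (dcuz - dcvz)
        F[i + 1, 0] -= pref * dcvx
        F[i + 1, 1] -= pref * dcvy
        F[i + 1, 2] -= pref * dcvz
    # torsion potential on each dihedral
    for i in range(n - 3):
        b1x = pos[i + 1, 0] - pos[i, 0]
        b1y = pos[i + 1, 1] - pos[i, 1]
        b1z = pos[i + 1, 2] - pos[i, 2]
        b2x = pos[i + 2, 0] - pos[i + 1, 0]
        b2y = pos[i + 2, 1] - pos[i + 1, 1]
        b2z = pos[i + 2, 2] - pos[i + 1, 2]
        b3x = pos[i + 3, 0] - pos[i + 2, 0]
        b3y = pos[i + 3, 1] - pos[i + 2, 1]
        b3z = pos[i + 3, 2] - pos[i + 2, 2]
        mx = b1y * b2z - b1z * b2y
        my = b1z * b2x - b1x * b2z
        mz = b1x * b2y - b1y * b2x
        nx = b2y * b3z - b2z * b3y
        ny = b2z * b3x - b2x * b3z
        nz = b2x * b3y - b2y * b3x
        m2 = mx * mx + my * my + mz * mz
        n2 = nx * nx + ny * ny + nz * nz
        lb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if m2 < 1e-16 or n2 < 1e-16:
            continue
        # tau = atan2((m x n) . b2hat, m . n)
        cxx = my * nz - mz * ny
        cxy = mz * nx - mx * nz
        cxz = mx * ny - my * nx
        y = (cxx * b2x + cxy * b2y + cxz * b2z) / lb2
        x = mx * nx + my * ny + mz * nz
        tau = math.atan2(y, x)
        energy += ktor * (1.0 - math.cos(tau - theta0))
        dVdt = ktor * math.sin(tau - theta0)
        # dtau/dr for the outer atoms
        g0 = -lb2 / m2
        g3 = lb2 / n2
        d0x = g0 * mx
        d0y = g0 * my
        d0z = g0 * mz
        d3x = g3 * nx
        d3y = g3 * ny
        d3z = g3 * nz
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (lb2 * lb2)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (lb2 * lb2)
        d1x = -(1.0 + s12) * d0x + s32 * d3x
        d1y = -(1.0 + s12) * d0y + s32 * d3y
        d1z = -(1.0 + s12) * d0z + s32 * d3z
        d2x = s12 * d0x - (1.0 + s32) * d3x
        d2y = s12 * d0y - (1.0 + s32) * d3y
        d2z = s12 * d0z - (1.0 + s32) * d3z
        F[i, 0] -= dVdt * d0x
        F[i, 1] -= dVdt * d0y
        F[i, 2] -= dVdt * d0z
        F[i + 1, 0] -= dVdt * d1x
        F[i + 1, 1] -= dVdt * d1y
        F[i + 1, 2] -= dVdt * d1z
        F[i + 2, 0] -= dVdt * d2x
        F[i + 2, 1] -= dVdt * d2y
        F[i + 2, 2] -= dVdt * d2z
        F[i + 3, 0] -= dVdt * d3x
        F[i + 3, 1] -= dVdt * d3y
        F[i + 3, 2] -= dVdt * d3z
    return energy


@njit(cache=False)
def _shake(ref, pos, bond_l, tol, maxiter):
    """Iteratively restore rigid bond lengths; returns True on convergence."""
    n = pos.shape[0]
    l2 = bond_l * bond_l
    for _ in range(maxiter):
        worst = 0.0
        for i in range(n - 1):
            dx = pos[i + 1, 0] - pos[i, 0]
            dy = pos[i + 1, 1] - pos[i, 1]
            dz = pos[i + 1, 2] - pos[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            diff = d2 - l2
            rel = abs(diff) / l2
            if rel > worst:
                worst = rel
            if rel > tol:
                rx = ref[i + 1, 0] - ref[i, 0]
                ry = ref[i + 1, 1] - ref[i, 1]
                rz = ref[i + 1, 2] - ref[i, 2]
                dot = dx * rx + dy * ry + dz * rz
                if abs(dot) < 1e-12:
                    continue
                g = diff / (4.0 * dot)
                pos[i + 1, 0] -= g * rx
                pos[i + 1, 1] -= g * ry
                pos[i + 1, 2] -= g * rz
                pos[i, 0] += g * rx
                pos[i, 1] += g * ry
                pos[i, 2] += g * rz
        if worst <= tol:
            return True
    return False


@njit(cache=False)
def _integrate(pos, vel, bath, dt, box, rcut2, bond_l, kbend, phi_eq, ktor,
               theta0, dof, tol, maxiter, save_steps, frames, temps):
    n = pos.shape[0]
    F = np.zeros((n, 3))
    old = np.zeros((n, 3))
    nsave = 0
    nsteps = bath.shape[0]
    for step in range(1, nsteps + 1):
        _forces(pos, box, rcut2, kbend, phi_eq, ktor, theta0, F)
        for i in range(n):
            vel[i, 0] += dt * F[i, 0]
            vel[i, 1] += dt * F[i, 1]
            vel[i, 2] += dt * F[i, 2]
            old[i, 0] = pos[i, 0]
            old[i, 1] = pos[i, 1]
            old[i, 2] = pos[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        if not _shake(old, pos, bond_l, tol, maxiter):
            return step
        ke = 0.0
        for i in range(n):
            vel[i, 0] = (pos[i, 0] - old[i, 0]) / dt
            vel[i, 1] = (pos[i, 1] - old[i, 1]) / dt
            vel[i, 2] = (pos[i, 2] - old[i, 2]) / dt
            ke += (vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1]
                   + vel[i, 2] * vel[i, 2])
        t_inst = ke / dof
        t_target = bath[step - 1]
        if t_inst > 0.0:
            scale = math.sqrt(t_target / t_inst)
            for i in range(n):
                vel[i, 0] *= scale
                vel[i, 1] *= scale
                vel[i, 2] *= scale
        if nsave < save_steps.shape[0] and step == save_steps[nsave]:
            ke2 = 0.0
            for i in range(n):
                frames[nsave, i, 0] = pos[i, 0]
                frames[nsave, i, 1] = pos[i, 1]
                frames[nsave, i, 2] = pos[i, 2]
                ke2 += (vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1]
                        + vel[i, 2] * vel[i, 2])
            temps[nsave] = ke2 / dof
            nsave += 1
    return 0


# --------------------------------------------------------------------------
# public driver


def potential_energy(config: DynamicsConfig, pos: np.ndarray) -> float:
    """Total potential energy (WCA + bend restraint + torsion) of a state."""
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    F = np.zeros_like(pos)
    return float(_forces(pos, config.box_side, config.r_cut ** 2,
                         config.bend_k, config.phi_eq, config.torsion_k,
                         config.theta_eq, F))


def forces(config: DynamicsConfig, pos: np.ndarray) -> np.ndarray:
    """Analytic forces on every particle for a given configuration."""
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    F = np.zeros_like(pos)
    _forces(pos, config.box_side, config.r_cut ** 2, config.bend_k,
            config.phi_eq, config.torsion_k, config.theta_eq, F)
    return F


def maxwell_velocities(config: DynamicsConfig, seed: int) -> np.ndarray:
    """Maxwell-distributed initial velocities at T0, COM motion removed.

    After removing the net linear momentum the velocities are rescaled so the
    kinetic temperature (with constrained degrees of freedom removed) is
    exactly ``T0``.
    """
    rng = np.random.default_rng(seed)
    n = config.n_particles
    if config.T0 <= 0.0:
        return np.zeros((n, 3))
    vel = rng.normal(0.0, math.sqrt(config.T0), size=(n, 3))
    vel -= vel.mean(axis=0)
    t_inst = (vel * vel).sum() / config.dof
    if t_inst > 0.0:
        vel *= math.sqrt(config.T0 / t_inst)
    return vel


def simulate_anneal(config: DynamicsConfig, initial: np.ndarray,
                    seed: int, return_temperatures: bool = False):
    """Integrate the annealed dynamics and return the saved trajectory.

    Runs ``total_steps`` of leap-frog integration with SHAKE bond constraints
    and per-step velocity scaling to the annealed bath target.  Frames are
    saved every ``save_period`` steps after the burn-in, yielding
    ``(total_steps - burn_in) / save_period`` frames.  Fully reproducible:
    the same seed gives a bitwise-identical trajectory.  With
    ``return_temperatures`` the measured kinetic temperature at each saved
    step is returned alongside the ensemble.

    Raises
    ------
    IntegrationError
        If SHAKE fails to converge, reporting the offending step.
    InvalidInputError
        If ``initial`` violates the bond constraints.
    """
    pos = np.ascontiguousarray(initial, dtype=np.float64).copy()
    if pos.shape != (config.n_particles, 3):
        raise InvalidInputError(
            f"initial structure must have shape ({config.n_particles}, 3)"
        )
    bonds = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    if np.any(np.abs(bonds - config.link_length) > 1e-6 * config.link_length):
        raise InvalidInputError("initial structure violates bond constraints")
    vel = maxwell_velocities(config, seed)
    bath = np.array([annealing_temperature(config, s)
                     for s in range(1, config.total_steps + 1)])
    save_steps = np.arange(config.burn_in + config.save_period,
                           config.total_steps + 1, config.save_period,
                           dtype=np.int64)
    frames = np.empty((save_steps.size, config.n_particles, 3))
    temps = np.empty(save_steps.size)
    fail = _integrate(pos, vel, bath, config.timestep, config.box_side,
                      config.r_cut ** 2, config.link_length, config.bend_k,
                      config.phi_eq, config.torsion_k, config.theta_eq,
                      config.dof, 1e-8, 500, save_steps, frames, temps)
    if fail:
        raise IntegrationError(f"SHAKE failed to converge at step {fail}")
    ensemble = StructureEnsemble(frames)
    if return_temperatures:
        return ensemble, temps
    return ensemble


def saved_frame_temperatures(config: DynamicsConfig) -> np.ndarray:
    """Bath target temperature at each saved frame."""
    steps = np.arange(config.burn_in + config.save_period,
                      config.total_steps + 1, config.save_period)
    return np.array([annealing_temperature(config, int(s)) for s in steps])


def concatenate_fold_unfold(freeze: StructureEnsemble,
                            melt: StructureEnsemble) -> StructureEnsemble:
    """Concatenate the freezing and melting runs, renumbering times 1..n1+n2."""
    return concatenate_ensembles(freeze, melt)


def run_fold_unfold(seed: int, freeze_cfg: DynamicsConfig | None = None,
                    melt_cfg: DynamicsConfig | None = None
                    ) -> tuple[StructureEnsemble, StructureEnsemble, StructureEnsemble]:
    """Run the full freezing-then-melting protocol.

    The freezing run starts from a random coil; the melting run starts from
    the ideal helix.  Independent seeds for the two phases are derived from
    ``seed`` by seed-sequence spawning.  Returns
    ``(freeze, melt, concatenated)``.
    """
    freeze_cfg = freeze_cfg or freezing_config()
    melt_cfg = melt_cfg or melting_config()
    child = np.random.SeedSequence(seed).spawn(3)
    coil_seed, f_seed, m_seed = (int(c.generate_state(1)[0] % (2 ** 31))
                                 for c in child)
    coil = init_random_coil(freeze_cfg, coil_seed)
    freeze = simulate_anneal(freeze_cfg, coil, f_seed)
    helix = init_ideal_helix(melt_cfg)
    melt = simulate_anneal(melt_cfg, helix, m_seed)
    return freeze, melt, concatenate_fold_unfold(freeze, melt)
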