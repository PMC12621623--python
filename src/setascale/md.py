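"""Velocity-Verlet NVT dynamics of spatula beads.

Interactions: anisotropic harmonic bonds within the spatula, a truncated and
energy-shifted 12-6 Lennard-Jones potential between spatula beads and the
frozen substrate, and harmonic anchor-point (AP) springs tethering selected
beads to fixed virtual particles in the bridging domain.

Thermostats act on two groups: a canonical-sampling stochastic velocity
rescaling thermostat (coupling time 2 ps) outside the bridging domain and a
weak Berendsen thermostat (10 ps) inside it, which dissipates the kinetic
energy injected by load steps.  The simulated system is a vacuum over an
immobile slab: no pairwise friction terms, no periodic boundaries.

Units: nm, Da, kJ/mol, ps (the derived molecular time unit equals 1 ps);
forces kJ/mol/nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .units import BOLTZMANN_KJ_MOL_K
from .spatula import SpatulaModel, Substrate

KB = BOLTZMANN_KJ_MOL_K


@dataclass(frozen=True)
class MDParams:
    """Molecular-dynamics iteration parameters."""

    dt_fs: float = 20.0
    temperature_K: float = 300.0
    lj_eps: float = 290.0  # kJ/mol
    lj_sigma: float = 4.0  # nm
    r_cutoff: float = 12.0  # nm
    tau_outside_ps: float = 2.0  # velocity-rescaling coupling time
    tau_inside_ps: float = 10.0  # Berendsen coupling time
    n_md: int = 7000  # steps per FEM-MD iteration
    window_fraction: float = 0.5  # force-averaging window (final portion)
    skin: float = 2.0  # Verlet skin, nm

    def __post_init__(self) -> None:
        if not (0 < self.window_fraction <= 1):
            raise ValueError("window fraction must lie in (0, 1]")
        if self.r_cutoff <= 0 or self.lj_sigma <= 0:
            raise ValueError("LJ parameters must be positive")

    @property
    def dt_ps(self) -> float:
        return self.dt_fs * 1e-3


@dataclass
class MDSystem:
    """One spatula + substrate + anchor points, laid out for the kernels."""

    model: SpatulaModel
    substrate: Substrate
    params: MDParams
    ap_pos: np.ndarray  # (Na, 3) fixed during one MD phase
    ap_bead: np.ndarray  # (Na,) bead index per AP
    ap_b0: np.ndarray  # (Na,) spring equilibrium lengths
    ap_k: float  # kJ/mol/nm^2
    inside_bd: np.ndarray = field(default=None)  # bool per bead
    group: np.ndarray = field(default=None)  # int64 bead group (spatula id)

    def __post_init__(self) -> None:
        if self.inside_bd is None:
            m = np.zeros(self.model.n_beads, dtype=np.bool_)
            m[self.ap_bead] = True
            self.inside_bd = m
        if self.group is None:
            self.group = np.zeros(self.model.n_beads, dtype=np.int64)
        self.group = np.asarray(self.group, dtype=np.int64)
        self._sub_tree = cKDTree(self.substrate.coords)

    @property
    def n_groups(self) -> int:
        return int(self.group.max()) + 1 if len(self.group) else 1

    def lj_pairs(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(bead, substrate-bead) pairs within cutoff + skin."""
        r = self.params.r_cutoff + self.params.skin
        neigh = self._sub_tree.query_ball_point(pos, r)
        pi, pj = [], []
        for i, lst in enumerate(neigh):
            pi.extend([i] * len(lst))
            pj.extend(lst)
        return (np.asarray(pi, dtype=np.int64),
                np.asarray(pj, dtype=np.int64))


def maxwell_boltzmann_velocities(
    n: int, mass: float, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    if temperature <= 0:
        return np.zeros((n, 3))
    s = np.sqrt(KB * temperature / mass)
    return rng.normal(0.0, s, (n, 3))


@njit(cache=True)
def _forces(pos, bi, bj, b0, Kb, sub, pi, pj, eps, sig, rcut,
            ap_bead, ap_pos, ap_b0, ap_k, ext, group, f, ap_f, sub_f):
    """Fill f (per bead), ap_f (force exerted on each AP) and sub_f (substrate
    force on each bead group, e.g. per spatula); return (potential energy,
    status)."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    for g in range(sub_f.shape[0]):
        sub_f[g, 0] = 0.0
        sub_f[g, 1] = 0.0
        sub_f[g, 2] = 0.0
    pe = 0.0
    # bonds
    for b in range(bi.shape[0]):
        i, j = bi[b], bj[b]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-6:
            return pe, 1
        dr = r - b0[b]
        pe += 0.5 * Kb[b] * dr * dr
        c = Kb[b] * dr / r
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i, 2] += c * dz
        f[j, 0] -= c * dx
        f[j, 1] -= c * dy
        f[j, 2] -= c * dz
    # LJ with frozen substrate, energy-shifted so V(rcut) = 0 exactly
    rc2 = rcut * rcut
    sc2 = sig * sig / rc2
    sc6 = sc2 * sc2 * sc2
    vshift = 4.0 * eps * (sc6 * sc6 - sc6)
    for p in range(pi.shape[0]):
        i, j = pi[p], pj[p]
        dx = pos[i, 0] - sub[j, 0]
        dy = pos[i, 1] - sub[j, 1]
        dz = pos[i, 2] - sub[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        if r2 < 1e-12:
            return pe, 1
        s2 = sig * sig / r2
        s6 = s2 * s2 * s2
        s12 = s6 * s6
        pe += 4.0 * eps * (s12 - s6) - vshift
        c = 24.0 * eps * (2.0 * s12 - s6) / r2
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i, 2] += c * dz
        g = group[i]
        sub_f[g, 0] += c * dx
        sub_f[g, 1] += c * dy
        sub_f[g, 2] += c * dz
    # anchor-point springs
    for a in range(ap_bead.shape[0]):
        i = ap_bead[a]
        dx = pos[i, 0] - ap_pos[a, 0]
        dy = pos[i, 1] - ap_pos[a, 1]
        dz = pos[i, 2] - ap_pos[a, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - ap_b0[a]
        pe += 0.5 * ap_k * dr * dr
        if r > 1e-12:
            c = ap_k * dr / r
            # force on the bead (towards the AP when stretched)
            f[i, 0] -= c * dx
            f[i, 1] -= c * dy
            f[i, 2] -= c * dz
            # force exerted on the AP by the MD system
            ap_f[a, 0] = c * dx
            ap_f[a, 1] = c * dy
            ap_f[a, 2] = c * dz
        else:
            ap_f[a, 0] = 0.0
            ap_f[a, 1] = 0.0
            ap_f[a, 2] = 0.0
    # constant external per-bead forces (e.g. a hung test weight)
    for i in range(n):
        f[i, 0] += ext[i, 0]
        f[i, 1] += ext[i, 1]
        f[i, 2] += ext[i, 2]
        pe -= ext[i, 0] * pos[i, 0] + ext[i, 1] * pos[i, 1] + ext[i, 2] * pos[i, 2]
    return pe, 0


@njit(cache=True)
def _group_kinetic(vel, mask, mass):
    k = 0.0
    n = 0
    for i in range(vel.shape[0]):
        if mask[i]:
            k += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            n += 1
    return 0.5 * mass * k, n


@njit(cache=True)
def _scale_group(vel, mask, factor):
    for i in range(vel.shape[0]):
        if mask[i]:
            vel[i, 0] *= factor
            vel[i, 1] *= factor
            vel[i, 2] *= factor


@njit(cache=True)
def _run_chunk(
    pos, vel, mass, dt, step0, max_steps,
    bi, bj, b0, Kb,
    sub, pi, pj, eps, sig, rcut,
    ap_bead, ap_pos, ap_b0, ap_k, ext, group,
    inside_bd, outside_bd,
    thermostat_on, T_target, tau_out, tau_in,
    csvr_r1, csvr_sum,
    win_start, ap_acc, sub_acc, acc_count,
    ref_pos, half_skin,
    temp_trace, energy_trace,
    f, ap_f, sub_f,
):
    """Integrate until max_steps done or a neighbour rebuild is needed.

    Returns (steps_done, status): status 0 ok, 1 unphysical overlap,
    2 non-finite coordinate, 3 rebuild requested.
    """
    n = pos.shape[0]
    c_out = np.exp(-dt / tau_out)
    kT = KB * T_target
    steps = 0
    for local in range(max_steps):
        step = step0 + local
        # velocity Verlet
        for i in range(n):
            inv = 0.5 * dt / mass
            vel[i, 0] += f[i, 0] * inv
            vel[i, 1] += f[i, 1] * inv
            vel[i, 2] += f[i, 2] * inv
            pos[i, 0] += vel[i, 0] * dt
            pos[i, 1] += vel[i, 1] * dt
            pos[i, 2] += vel[i, 2] * dt
        pe, status = _forces(
            pos, bi, bj, b0, Kb, sub, pi, pj, eps, sig, rcut,
            ap_bead, ap_pos, ap_b0, ap_k, ext, group, f, ap_f, sub_f,
        )
        if status != 0:
            return steps, status
        for i in range(n):
            inv = 0.5 * dt / mass
            vel[i, 0] += f[i, 0] * inv
            vel[i, 1] += f[i, 1] * inv
            vel[i, 2] += f[i, 2] * inv

        ke_total = 0.0
        if thermostat_on:
            # canonical-sampling velocity rescaling outside the BD
            ke_out, n_out = _group_kinetic(vel, outside_bd, mass)
            if n_out > 0 and ke_out > 1e-12:
                ndf = 3.0 * n_out
                kbar = 0.5 * ndf * kT
                r1 = csvr_r1[step]
                ssum = csvr_sum[step]  # sum of (ndf-1) squared normals
                fac = kbar * (1.0 - c_out) / (ndf * ke_out)
                a2 = (
                    c_out
                    + fac * (r1 * r1 + ssum)
                    + 2.0 * r1 * np.sqrt(c_out * fac)
                )
                if a2 < 0.0:
                    a2 = 0.0
                _scale_group(vel, outside_bd, np.sqrt(a2))
            # Berendsen inside the BD
            ke_in, n_in = _group_kinetic(vel, inside_bd, mass)
            if n_in > 0 and ke_in > 1e-12:
                T_in = 2.0 * ke_in / (3.0 * n_in * KB)
                lam2 = 1.0 + (dt / tau_in) * (T_target / T_in - 1.0)
                if lam2 < 0.0:
                    lam2 = 0.0
                _scale_group(vel, inside_bd, np.sqrt(lam2))

        for i in range(n):
            ke_total += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
        ke_total *= 0.5 * mass
        temp_trace[step] = 2.0 * ke_total / (3.0 * n * KB)
        energy_trace[step] = pe + ke_total

        if step >= win_start:
            for a in range(ap_f.shape[0]):
                ap_acc[a, 0] += ap_f[a, 0]
                ap_acc[a, 1] += ap_f[a, 1]
                ap_acc[a, 2] += ap_f[a, 2]
            for g in range(sub_f.shape[0]):
                sub_acc[g, 0] += sub_f[g, 0]
                sub_acc[g, 1] += sub_f[g, 1]
                sub_acc[g, 2] += sub_f[g, 2]
            acc_count[0] += 1

        steps += 1
        if (local + 1) % 10 == 0 or steps == max_steps:
            maxd2 = 0.0
            for i in range(n):
                d2 = (
                    (pos[i, 0] - ref_pos[i, 0]) ** 2
                    + (pos[i, 1] - ref_pos[i, 1]) ** 2
                    + (pos[i, 2] - ref_pos[i, 2]) ** 2
                )
                if d2 > maxd2:
                    maxd2 = d2
            if not np.isfinite(maxd2):
                return steps, 2
            if maxd2 > half_skin * half_skin and steps < max_steps:
                return steps, 3
    return steps, 0


@dataclass
class PhaseResult:
    """Output of one MD phase."""

    f_ap_mean: np.ndarray  # (Na, 3) time-averaged force on each AP, kJ/mol/nm
    substrate_force_by_group: np.ndarray  # (ng, 3) per bead group (spatula)
    temperature_trace: np.ndarray
    energy_trace: np.ndarray
    potential_energy: float

    @property
    def substrate_force_mean(self) -> np.ndarray:
        """(3,) total time-averaged substrate force on the beads."""
        return self.substrate_force_by_group.sum(axis=0)


def forces_and_energy(
    system: MDSystem, pos: np.ndarray, ext_force: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Analytic forces, per-AP forces and potential energy at a configuration."""
    pi, pj = system.lj_pairs(pos)
    f = np.zeros_like(pos)
    ap_f = np.zeros_like(system.ap_pos)
    m = system.model
    p = system.params
    ext = np.zeros_like(pos) if ext_force is None else np.asarray(ext_force, float)
    sub_f = np.zeros((system.n_groups, 3))
    pe, status = _forces(
        pos, m.bonds[:, 0].astype(np.int64), m.bonds[:, 1].astype(np.int64),
        m.b0, m.K, system.substrate.coords, pi, pj,
        p.lj_eps, p.lj_sigma, p.r_cutoff,
        system.ap_bead.astype(np.int64), system.ap_pos, system.ap_b0,
        system.ap_k, ext, system.group, f, ap_f, sub_f,
    )
    if status != 0:
        raise ValueError("unphysical state: overlapping beads")
    return f, ap_f, pe


def run_md_phase(
    system: MDSystem,
    pos: np.ndarray,
    vel: np.ndarray,
    n_steps: int | None = None,
    rng: np.random.Generator | int | None = None,
    thermostat: bool = True,
    temperature: float | None = None,
    ext_force: np.ndarray | None = None,
) -> PhaseResult:
    """Advance one MD phase in place and average AP/substrate forces over the
    final window of the trajectory."""
    p = system.params
    m = system.model
    n_steps = p.n_md if n_steps is None else n_steps
    T = p.temperature_K if temperature is None else temperature
    rng = np.random.default_rng(rng)
    dt = p.dt_ps

    n_out = int(np.sum(~system.inside_bd))
    if thermostat and T > 0:
        csvr_r1 = rng.standard_normal(n_steps)
        csvr_sum = rng.chisquare(max(3 * n_out - 1, 1), n_steps)
    else:
        csvr_r1 = np.zeros(n_steps)
        csvr_sum = np.zeros(n_steps)

    win_start = int(np.floor(n_steps * (1.0 - p.window_fraction)))
    ap_acc = np.zeros_like(system.ap_pos)
    sub_acc = np.zeros((system.n_groups, 3))
    acc_count = np.zeros(1, dtype=np.int64)
    temp_trace = np.zeros(n_steps)
    energy_trace = np.zeros(n_steps)
    f = np.zeros_like(pos)
    ap_f = np.zeros_like(system.ap_pos)
    sub_f = np.zeros((system.n_groups, 3))

    bi = m.bonds[:, 0].astype(np.int64)
    bj = m.bonds[:, 1].astype(np.int64)
    ap_bead = system.ap_bead.astype(np.int64)
    outside = ~system.inside_bd
    ext = np.zeros_like(pos) if ext_force is None else np.asarray(ext_force, float)

    done = 0
    while done < n_steps:
        pi, pj = system.lj_pairs(pos)
        ref = pos.copy()
        # forces must be current before the first half-kick
        _, status = _forces(
            pos, bi, bj, m.b0, m.K, system.substrate.coords, pi, pj,
            p.lj_eps, p.lj_sigma, p.r_cutoff,
            ap_bead, system.ap_pos, system.ap_b0, system.ap_k, ext,
            system.group, f, ap_f, sub_f,
        )
        if status != 0:
            raise ValueError("unphysical state: overlapping beads")
        steps, status = _run_chunk(
            pos, vel, m.mass, dt, done, n_steps - done,
            bi, bj, m.b0, m.K,
            system.substrate.coords, pi, pj, p.lj_eps, p.lj_sigma, p.r_cutoff,
            ap_bead, system.ap_pos, system.ap_b0, system.ap_k, ext,
            system.group, system.inside_bd, outside,
            thermostat, T, p.tau_outside_ps, p.tau_inside_ps,
            csvr_r1, csvr_sum,
            win_start, ap_acc, sub_acc, acc_count,
            ref, p.skin / 2.0,
            temp_trace, energy_trace,
            f, ap_f, sub_f,
        )
        done += steps
        if status == 1:
            raise ValueError("unphysical state: overlapping beads")
        if status == 2 or not np.all(np.isfinite(pos)):
            raise FloatingPointError(
                f"non-finite coordinates after {done} steps"
            )

    cnt = max(int(acc_count[0]), 1)
    pe_final = float(energy_trace[-1] - _kinetic(vel, m.mass)) if n_steps else 0.0
    return PhaseResult(
        f_ap_mean=ap_acc / cnt,
        substrate_force_by_group=sub_acc / cnt,
        temperature_trace=temp_trace,
        energy_trace=energy_trace,
        potential_energy=pe_final,
    )


def _kinetic(vel: np.ndarray, mass: float) -> float:
    return float(0.5 * mass * np.sum(vel**2))
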