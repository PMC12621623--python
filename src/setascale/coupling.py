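"""Concurrent MD-FEM coupling: bridging domains, anchor-point pairing, the
alternating FEM-MD iteration loop, and the preload - relax - pull-off
protocol.

One FEM-MD iteration is: (a) an MD phase with the anchor points (APs) held
fixed, producing window-averaged AP forces; (b) a static FEM solve with the
beads frozen, the driver nodes displaced (first iteration of a load step)
or fully fixed (subsequent iterations), and the averaged AP forces applied
as nodal loads on the bridging-domain (BD) nodes; (c) the displaced BD node
positions become the AP positions for the next MD phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import count_contacts
from .fem import FEMSystem, driver_force_reported
from .geometry import SetaMesh
from .material import ElasticParams
from .md import MDSystem, MDParams, run_md_phase, maxwell_boltzmann_velocities
from .spatula import (
    SpatulaModel,
    Substrate,
    REGION_PAD,
    REGION_TIP,
)
from .units import KJ_MOL_NM_TO_NN, NN_PER_NM_TO_KJ_MOL_NM2


@dataclass(frozen=True)
class LoadProtocol:
    """Load-step schedule for the preload - relax - pull-off protocol."""

    eps_ls_nm: float = 1.0  # driver displacement per load step
    n_iter: int = 10  # FEM-MD iterations per load step
    n_md: int = 7000  # MD steps per iteration
    dt_md_fs: float = 20.0
    preload_target_nN: float = 320.0  # summed spatula-substrate force
    preload_steps: int | None = None  # fixed-length preload overrides target
    relax_steps: int = 1
    clearance_nm: float = 13.0  # initial lowest-bead height above substrate
    max_load_steps: int = 1000
    detach_confirm: int = 3  # consecutive zero-contact steps ending pull-off

    def __post_init__(self) -> None:
        if min(self.eps_ls_nm, self.n_iter, self.n_md, self.dt_md_fs) <= 0:
            raise ValueError("protocol fields must be positive")

    @property
    def dt_ls_ns(self) -> float:
        return self.n_iter * self.n_md * self.dt_md_fs * 1e-6

    @property
    def pull_velocity_m_s(self) -> float:
        # 1 nm/ns = 1 m/s
        return self.eps_ls_nm / self.dt_ls_ns


def load_step_time(protocol: LoadProtocol) -> tuple[float, float]:
    """(load-step duration in ns, pull velocity in m/s)."""
    return protocol.dt_ls_ns, protocol.pull_velocity_m_s


@dataclass(frozen=True)
class BridgingDomain:
    """AP <-> bead pairing for one spatula.

    Every AP coincides with one BD FE node of the spatula's terminal branch;
    each is tethered to a distinct nearby bead (injective pairing) by a
    harmonic spring whose equilibrium length is the pairing-time distance.
    """

    spatula_id: int
    fe_nodes: np.ndarray  # global FE node indices, ascending
    ap_coords: np.ndarray  # (Na, 3) = mesh node positions at pairing time
    bead_indices: np.ndarray  # (Na,) spatula-local bead indices
    b0: np.ndarray  # (Na,) pairing-time AP-bead distances
    k_MD_nN_per_nm: float = 0.28
    k_FE_nN_per_nm: float = 0.08

    def __post_init__(self) -> None:
        if len(np.unique(self.bead_indices)) != len(self.bead_indices):
            raise ValueError("AP-bead pairing must be injective")
        if not (len(self.fe_nodes) == len(self.bead_indices) == len(self.b0)):
            raise ValueError("inconsistent bridging-domain arrays")


def build_bridging_domain(
    mesh: SetaMesh,
    spatula: SpatulaModel,
    spatula_id: int,
    distance_cap: float | None = None,
    k_MD_nN_per_nm: float = 0.28,
    k_FE_nN_per_nm: float = 0.08,
) -> BridgingDomain:
    """Pair every BD node of the spatula's terminal branch with a distinct
    nearby bead.

    Greedy rule: visit FE nodes in ascending global index; each takes its
    nearest not-yet-paired bead (ties broken by bead index).  Beads farther
    than the distance cap (default 2x the spatula's mean bond length) are
    not eligible; if any AP finds no eligible bead the pairing is rejected.
    """
    nodes = np.sort(np.asarray(mesh.bd_nodes[spatula_id], dtype=np.int64))
    ap_xyz = mesh.nodes[nodes]
    beads = spatula.coords
    cap = 2.0 * float(spatula.b0.mean()) if distance_cap is None else distance_cap
    if len(beads) < len(nodes):
        raise ValueError(
            f"spatula {spatula_id}: {len(beads)} beads < {len(nodes)} APs"
        )
    d = np.linalg.norm(ap_xyz[:, None, :] - beads[None, :, :], axis=2)
    paired = np.full(len(nodes), -1, dtype=np.int64)
    taken = np.zeros(len(beads), dtype=bool)
    for a in range(len(nodes)):
        cand = np.nonzero(~taken & (d[a] <= cap))[0]
        if len(cand) == 0:
            raise ValueError(
                f"spatula {spatula_id}: AP at node {nodes[a]} has no unpaired "
                f"bead within cap {cap:.2f} nm "
                f"({len(nodes)} APs, {int((~taken).sum())} beads left)"
            )
        # nearest; np.argmin returns the first (lowest bead index) on ties
        paired[a] = cand[np.argmin(d[a, cand])]
        taken[paired[a]] = True
    b0 = d[np.arange(len(nodes)), paired]
    return BridgingDomain(
        spatula_id=spatula_id,
        fe_nodes=nodes,
        ap_coords=ap_xyz.copy(),
        bead_indices=paired,
        b0=b0,
        k_MD_nN_per_nm=k_MD_nN_per_nm,
        k_FE_nN_per_nm=k_FE_nN_per_nm,
    )


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix mapping unit-normalised a onto b."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite vectors: rotate pi about any perpendicular axis
        p = np.eye(3)[np.argmin(np.abs(a))]
        v = np.cross(a, p)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def place_spatula(
    model: SpatulaModel,
    frame: tuple[np.ndarray, np.ndarray, np.ndarray],
    overlap_fraction: float = 0.9,
) -> SpatulaModel:
    """Rigidly move a spatula so its shaft continues its terminal FE branch.

    ``frame`` is (branch top, branch cut end, unit axis pointing tipward).
    The shaft axis is aligned with the branch axis and the shaft top is
    placed ``overlap_fraction x shaft length`` above the cut end, so the
    shaft overlaps the branch's bridging-domain band.
    """
    top, cut, axis = frame
    up = -np.asarray(axis, float)  # from pad towards seta base
    R = rotation_between(model.shaft_axis, up)
    # shaft length is not stored on the model; use the axial extent of the
    # shaft-region beads
    shaft_beads = model.coords[model.regions == 2]
    ax_extent = float(np.ptp(shaft_beads @ model.shaft_axis)) if len(shaft_beads) else 0.0
    target_top = np.asarray(cut, float) + overlap_fraction * ax_extent * up
    t = target_top - R @ model.shaft_top
    return model.transformed(R, t)


def merge_spatulae(models: list[SpatulaModel]) -> tuple[SpatulaModel, np.ndarray, np.ndarray]:
    """Concatenate placed spatulae into one bead system.

    Returns (merged model, bead offsets per spatula, bead->spatula map).
    Per-spatula frame fields (fibril, shaft axis) of the merged model are
    taken from the first spatula and must not be used; the per-spatula
    models remain the authority.
    """
    offsets = np.cumsum([0] + [m.n_beads for m in models])[:-1]
    coords = np.vstack([m.coords for m in models])
    regions = np.concatenate([m.regions for m in models])
    bonds = np.vstack([m.bonds + off for m, off in zip(models, offsets)])
    b0 = np.concatenate([m.b0 for m in models])
    K = np.concatenate([m.K for m in models])
    group = np.concatenate(
        [np.full(m.n_beads, i, dtype=np.int64) for i, m in enumerate(models)]
    )
    merged = replace(models[0], coords=coords, regions=regions, bonds=bonds,
                     b0=b0, K=K)
    return merged, offsets, group


@dataclass
class CoupledSystem:
    """Assembled seta FE mesh + placed spatulae + substrate + BDs."""

    mesh: SetaMesh
    fem: FEMSystem
    material: ElasticParams
    spatulae: list[SpatulaModel]
    substrate: Substrate
    bds: list[BridgingDomain]
    md: MDSystem
    md_params: MDParams
    protocol: LoadProtocol
    bead_offsets: np.ndarray
    ap_nodes: np.ndarray  # (Na,) global FE node indices, all BDs concatenated
    ap_ref: np.ndarray  # (Na, 3) BD node positions at assembly time
    tip_masks: list[np.ndarray] = field(default_factory=list)
    pad_masks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tip_masks:
            g = self.md.group
            reg = self.md.model.regions
            for i in range(len(self.spatulae)):
                self.tip_masks.append((g == i) & (reg == REGION_TIP))
                self.pad_masks.append((g == i) & (reg == REGION_PAD))

    @property
    def n_spatulae(self) -> int:
        return len(self.spatulae)


def assemble(
    mesh: SetaMesh,
    material: ElasticParams,
    spatulae: list[SpatulaModel],
    substrate: Substrate,
    md_params: MDParams,
    protocol: LoadProtocol,
    k_MD_nN_per_nm: float = 0.28,
    k_FE_nN_per_nm: float = 0.08,
) -> CoupledSystem:
    """Place spatulae on the terminal branches, shift the whole assembly to
    the initial clearance, pair anchor points, and build the FE operator."""
    if len(spatulae) != len(mesh.bd_nodes):
        raise ValueError(
            f"{len(spatulae)} spatulae for {len(mesh.bd_nodes)} terminal branches"
        )
    placed = [place_spatula(m, f) for m, f in zip(spatulae, mesh.branch_frames)]
    # global vertical shift: lowest bead ends clearance_nm above the substrate
    low = min(m.coords[:, 1].min() for m in placed)
    shift = np.array([0.0, protocol.clearance_nm - low, 0.0])
    placed = [m.transformed(np.eye(3), shift) for m in placed]
    mesh = replace(mesh, nodes=mesh.nodes + shift)

    bds = [
        build_bridging_domain(mesh, m, i, k_MD_nN_per_nm=k_MD_nN_per_nm,
                              k_FE_nN_per_nm=k_FE_nN_per_nm)
        for i, m in enumerate(placed)
    ]
    merged, offsets, group = merge_spatulae(placed)

    ap_nodes = np.concatenate([bd.fe_nodes for bd in bds])
    ap_ref = np.concatenate([bd.ap_coords for bd in bds])
    ap_bead = np.concatenate(
        [bd.bead_indices + off for bd, off in zip(bds, offsets)]
    )
    ap_b0 = np.concatenate([bd.b0 for bd in bds])

    # beads inside the bridging domain (weak Berendsen group) = tethered beads
    inside = np.zeros(merged.n_beads, dtype=np.bool_)
    inside[ap_bead] = True

    md = MDSystem(
        model=merged,
        substrate=substrate,
        params=md_params,
        ap_pos=ap_ref.copy(),
        ap_bead=ap_bead,
        ap_b0=ap_b0,
        ap_k=k_MD_nN_per_nm * NN_PER_NM_TO_KJ_MOL_NM2,
        inside_bd=inside,
        group=group,
    )
    fem = FEMSystem.build(mesh, material, k_FE=k_FE_nN_per_nm)
    return CoupledSystem(
        mesh=mesh, fem=fem, material=material, spatulae=placed,
        substrate=substrate, bds=bds, md=md, md_params=md_params,
        protocol=protocol, bead_offsets=offsets, ap_nodes=ap_nodes,
        ap_ref=ap_ref,
    )


@dataclass
class RunState:
    """Mutable protocol state: bead phase space, FE displacement, driver."""

    pos: np.ndarray
    vel: np.ndarray
    U: np.ndarray  # (n_nodes, 3) FE displacement
    driver_u_nm: float = 0.0
    load_step: int = 0
    records: list = field(default_factory=list)


def init_state(cs: CoupledSystem, rng: np.random.Generator,
               temperature: float | None = None) -> RunState:
    T = cs.md_params.temperature_K if temperature is None else temperature
    pos = cs.md.model.coords.copy()
    vel = maxwell_boltzmann_velocities(len(pos), cs.md.model.mass, T, rng)
    U = np.zeros((cs.mesh.n_nodes, 3))
    cs.md.ap_pos[:] = cs.ap_ref
    return RunState(pos=pos, vel=vel, U=U)


def run_iteration(
    cs: CoupledSystem,
    state: RunState,
    first: bool,
    dy_nm: float,
    rng: np.random.Generator,
    temperature: float | None = None,
    ext_force: np.ndarray | None = None,
):
    """One FEM-MD iteration; returns (MD phase result, driver reactions)."""
    res = run_md_phase(cs.md, state.pos, state.vel, rng=rng,
                       temperature=temperature, ext_force=ext_force)
    loads = np.zeros((cs.mesh.n_nodes, 3))
    loads[cs.ap_nodes] = res.f_ap_mean * KJ_MOL_NM_TO_NN
    if first:
        state.driver_u_nm += dy_nm
    U, reactions = cs.fem.solve_static(
        np.array([0.0, state.driver_u_nm, 0.0]), U_prev=state.U, loads=loads
    )
    new_ap = cs.ap_ref + U[cs.ap_nodes]
    jump = np.linalg.norm(new_ap - cs.md.ap_pos, axis=1).max()
    if jump > 10.0 * cs.protocol.eps_ls_nm:
        raise RuntimeError(
            f"coupling divergence: AP moved {jump:.2f} nm in one iteration "
            f"(load step {state.load_step}, driver {state.driver_u_nm:.1f} nm)"
        )
    cs.md.ap_pos[:] = new_ap
    state.U = U
    return res, reactions


def run_load_step(
    cs: CoupledSystem,
    state: RunState,
    dy_nm: float,
    phase: str,
    rng: np.random.Generator,
    temperature: float | None = None,
) -> dict:
    """One load step (n_iter FEM-MD iterations) plus its measurement record."""
    p = cs.protocol
    for it in range(p.n_iter):
        res, reactions = run_iteration(cs, state, it == 0, dy_nm, rng,
                                       temperature=temperature)
    state.load_step += 1
    f_sub = res.substrate_force_by_group * KJ_MOL_NM_TO_NN
    f_ap = res.f_ap_mean.sum(axis=0) * KJ_MOL_NM_TO_NN
    rec = {
        "load_step": state.load_step,
        "time_ns": state.load_step * p.dt_ls_ns,
        "phase": phase,
        "driver_u_nm": state.driver_u_nm,
        "f_sub_x_nN": float(f_sub[:, 0].sum()),
        "f_sub_y_nN": float(f_sub[:, 1].sum()),
        "f_sub_z_nN": float(f_sub[:, 2].sum()),
        "f_ap_x_nN": float(f_ap[0]),
        "f_ap_y_nN": float(f_ap[1]),
        "f_ap_z_nN": float(f_ap[2]),
        "f_driver_nN": driver_force_reported(reactions),
    }
    total_contacts = 0
    cutoff = cs.md_params.r_cutoff
    for i in range(cs.n_spatulae):
        beads = state.pos[cs.md.group == i]
        c = count_contacts(beads, cs.substrate.coords, cutoff=cutoff)
        total_contacts += c
        rec[f"contacts_s{i}"] = c
        rec[f"f_sub_y_s{i}_nN"] = float(f_sub[i, 1])
        tip = state.pos[cs.tip_masks[i]].mean(axis=0)
        pad = state.pos[cs.pad_masks[i]].mean(axis=0)
        rec[f"tip_x_s{i}_nm"] = float(tip[0])
        rec[f"tip_y_s{i}_nm"] = float(tip[1])
        rec[f"pad_x_s{i}_nm"] = float(pad[0])
        rec[f"pad_y_s{i}_nm"] = float(pad[1])
    rec["contacts"] = total_contacts
    state.records.append(rec)
    return rec


@dataclass
class RunResult:
    """Protocol outcome: the per-load-step table plus run metadata."""

    records: list
    protocol: LoadProtocol
    n_spatulae: int
    orientations: tuple[str, ...]
    seed: int
    completed: bool
    phase_bounds: dict

    def series(self):
        from .analysis import ProfileSeries

        return ProfileSeries.from_records(
            self.records, self.n_spatulae, self.protocol.dt_ls_ns,
            self.orientations,
        )


def run_protocol(cs: CoupledSystem, seed: int,
                 temperature: float | None = None) -> RunResult:
    """Preload (driver -Y until the summed spatula-substrate force reaches
    the target while in contact), relax (no displacement), pull off (+Y until
    every spatula has lost contact for the confirmation horizon)."""
    p = cs.protocol
    ss = np.random.SeedSequence(seed)
    rng_vel, rng_md = [np.random.default_rng(s) for s in ss.spawn(2)]
    state = init_state(cs, rng_vel, temperature=temperature)
    phase_bounds = {}

    # --- preload ---
    n_pre = 0
    while True:
        rec = run_load_step(cs, state, -p.eps_ls_nm, "preload", rng_md,
                            temperature=temperature)
        n_pre += 1
        if p.preload_steps is not None:
            if n_pre >= p.preload_steps:
                break
        elif rec["contacts"] > 0 and rec["f_sub_y_nN"] >= p.preload_target_nN:
            break
        if state.load_step >= p.max_load_steps:
            raise RuntimeError(
                "preload target not reached within max load steps; "
                f"last substrate force {rec['f_sub_y_nN']:.3f} nN, "
                f"records={len(state.records)}"
            )
    phase_bounds["preload_end"] = state.load_step

    # --- relax ---
    for _ in range(p.relax_steps):
        run_load_step(cs, state, 0.0, "relax", rng_md, temperature=temperature)
    phase_bounds["relax_end"] = state.load_step

    # --- pull-off ---
    zero_streak = 0
    completed = False
    while state.load_step < p.max_load_steps:
        rec = run_load_step(cs, state, +p.eps_ls_nm, "pulloff", rng_md,
                            temperature=temperature)
        zero_streak = zero_streak + 1 if rec["contacts"] == 0 else 0
        if zero_streak >= p.detach_confirm:
            completed = True
            break
    phase_bounds["pulloff_end"] = state.load_step

    orientations = tuple(m.orientation for m in cs.spatulae)
    return RunResult(
        records=state.records,
        protocol=p,
        n_spatulae=cs.n_spatulae,
        orientations=orientations,
        seed=seed,
        completed=completed,
        phase_bounds=phase_bounds,
    )


def run_shear(
    md: MDSystem,
    speed_m_s: float,
    seed: int,
    preload_target_nN: float = 2.0,
    approach_step_nm: float = 0.5,
    slide_distance_nm: float = 8.0,
    hold_phases: int = 2,
    max_phases: int = 400,
    discard_fraction: float = 0.25,
) -> dict:
    """Pure-MD shear run for the friction-versus-speed trend.

    The anchor points are first lowered until the windowed normal substrate
    force is compressive at the target, held, then displaced along +X at the
    requested speed while Y and Z stay fixed.  Returns the apparent friction
    coefficient mu = mean|F_x| / mean|F_y| over the steady part of sliding.
    """
    from .analysis import friction_coefficient

    ss = np.random.SeedSequence(seed)
    rng_vel, rng_md = [np.random.default_rng(s) for s in ss.spawn(2)]
    pos = md.model.coords.copy()
    vel = maxwell_boltzmann_velocities(len(pos), md.model.mass,
                                       md.params.temperature_K, rng_vel)
    phase_ns = md.params.n_md * md.params.dt_fs * 1e-6
    # approach
    n = 0
    while True:
        md.ap_pos[:, 1] -= approach_step_nm
        res = run_md_phase(md, pos, vel, rng=rng_md)
        fy = res.substrate_force_mean[1] * KJ_MOL_NM_TO_NN
        n += 1
        if fy >= preload_target_nN:
            break
        if n >= max_phases:
            raise RuntimeError(
                f"shear preload target {preload_target_nN} nN not reached; "
                f"last normal force {fy:.3f} nN"
            )
    for _ in range(hold_phases):
        res = run_md_phase(md, pos, vel, rng=rng_md)
    # slide
    dx = speed_m_s * phase_ns  # nm per phase (1 m/s = 1 nm/ns)
    n_slide = max(int(np.ceil(slide_distance_nm / dx)), 4)
    fx, fy = [], []
    for _ in range(n_slide):
        md.ap_pos[:, 0] += dx
        res = run_md_phase(md, pos, vel, rng=rng_md)
        f = res.substrate_force_mean * KJ_MOL_NM_TO_NN
        fx.append(f[0])
        fy.append(f[1])
    start = int(len(fx) * discard_fraction)
    mu = friction_coefficient(np.array(fx[start:]), np.array(fy[start:]))
    return {
        "mu": mu,
        "speed_m_s": speed_m_s,
        "f_lateral_nN": np.array(fx),
        "f_normal_nN": np.array(fy),
        "n_approach_phases": n,
        "n_slide_phases": n_slide,
    }
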