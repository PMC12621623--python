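"""Deterministic miniature systems: a desk-scale seta with four spatulae
that exercises every module and the full protocol in minutes.

The mini preset is a reduced stand-in for the 16-spatula system: a two-level
seta whose terminal fibrils are thinned to match the miniature spatula
shaft, four spatulae in alternating orientations (tip-first / pad-parallel
by parity), and a shortened load-step schedule.  Everything is generated
from a single master seed; rebuilding with the same seed is bitwise
identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .coupling import CoupledSystem, LoadProtocol, assemble
from .geometry import GeometryParams, build_skeleton, generate_mesh, mini_params
from .material import ElasticParams, sample_material
from .md import MDParams, MDSystem
from .spatula import build_spatula, build_substrate
from .units import NN_PER_NM_TO_KJ_MOL_NM2

#: nominal bead count of a full-scale spatula (full preset, jitter-free
#: lattice fill); used only to scale the preload target
FULL_SPATULA_BEADS_NOMINAL = 15260

#: the full-scale system's per-spatula preload share, nN
PRELOAD_PER_SPATULA_NN = 20.0


@dataclass(frozen=True)
class MiniPreset:
    """Parameters of the miniature system."""

    n_levels: int = 2
    n_spatulae: int = 4
    n_iter: int = 6
    n_md: int = 2000
    eps_ls_nm: float = 1.0
    relax_steps: int = 1
    clearance_nm: float = 13.0
    max_load_steps: int = 250
    mesh_order: int = 1
    substrate_margin_nm: float = 300.0


@dataclass
class MiniSystem:
    """Everything needed to run and analyse a mini protocol."""

    cs: CoupledSystem
    geometry: GeometryParams
    material: ElasticParams
    preset: MiniPreset
    seed: int


def scaled_preload_target(n_spatulae: int, beads_per_spatula: int) -> float:
    """Preload target mirroring the full-scale per-spatula share, scaled by
    spatula count and the bead-count ratio of the mini spatula."""
    ratio = beads_per_spatula / FULL_SPATULA_BEADS_NOMINAL
    return PRELOAD_PER_SPATULA_NN * n_spatulae * ratio


def make_mini_system(seed: int, preset: MiniPreset | None = None,
                     **protocol_overrides) -> MiniSystem:
    """Build the deterministic miniature seta-spatula system."""
    preset = preset or MiniPreset()
    ss = np.random.SeedSequence(seed)
    keys = ss.spawn(2 + preset.n_spatulae)
    rng_mat, rng_sub = np.random.default_rng(keys[0]), np.random.default_rng(keys[1])

    geom = mini_params(n_levels=preset.n_levels)
    skeleton = build_skeleton(geom)
    mesh = generate_mesh(skeleton, mesh_density=geom.mesh_density,
                         order=preset.mesh_order)
    if len(mesh.bd_nodes) != preset.n_spatulae:
        raise ValueError(
            f"mini mesh has {len(mesh.bd_nodes)} terminal branches, "
            f"preset expects {preset.n_spatulae}"
        )
    material = sample_material(rng=rng_mat)

    spatulae = [
        build_spatula(
            preset="mini",
            orientation="tip-first" if i % 2 == 0 else "pad-parallel",
            rng=np.random.default_rng(keys[2 + i]),
        )
        for i in range(preset.n_spatulae)
    ]

    xs = [frame[1][0] for frame in mesh.branch_frames]
    m = preset.substrate_margin_nm
    substrate = build_substrate(
        extent=(min(xs) - m, max(xs) + m, -m, m), rng=rng_sub
    )

    beads_per_spatula = int(np.mean([s.n_beads for s in spatulae]))
    protocol_kwargs = dict(
        eps_ls_nm=preset.eps_ls_nm,
        n_iter=preset.n_iter,
        n_md=preset.n_md,
        preload_target_nN=scaled_preload_target(preset.n_spatulae,
                                                beads_per_spatula),
        relax_steps=preset.relax_steps,
        clearance_nm=preset.clearance_nm,
        max_load_steps=preset.max_load_steps,
    )
    protocol_kwargs.update(protocol_overrides)
    protocol = LoadProtocol(**protocol_kwargs)
    md_params = MDParams(n_md=preset.n_md)

    cs = assemble(mesh, material, spatulae, substrate, md_params, protocol)

    # At mini scale the scaled force target is reached while the higher-
    # hanging pad-parallel spatulae are still out of interaction range, so
    # the preset fixes the preload depth geometrically: descend until the
    # highest spatula's lowest bead is pressed to ~1 LJ diameter above the
    # substrate.  The scaled force target remains recorded in the protocol.
    if "preload_steps" not in protocol_overrides:
        highest = max(m.coords[:, 1].min() for m in cs.spatulae)
        depth = highest - md_params.lj_sigma
        steps = int(np.ceil(depth / preset.eps_ls_nm))
        cs.protocol = replace(cs.protocol, preload_steps=steps)
    return MiniSystem(cs=cs, geometry=geom, material=material, preset=preset,
                      seed=seed)


def make_mini_shear_system(
    seed: int,
    n_md: int = 1500,
    clearance_nm: float = 8.0,
    n_anchors: int = 20,
) -> MDSystem:
    """Single pad-parallel mini spatula over a substrate, anchored at its
    uppermost shaft beads, for pure-MD shear runs."""
    ss = np.random.SeedSequence(seed)
    k_spat, k_sub = ss.spawn(2)
    model = build_spatula(preset="mini", orientation="pad-parallel",
                          rng=np.random.default_rng(k_spat))
    low = model.coords[:, 1].min()
    model = model.transformed(np.eye(3),
                              np.array([0.0, clearance_nm - low, 0.0]))
    span = 200.0
    substrate = build_substrate(extent=(-span, span, -span, span),
                                rng=np.random.default_rng(k_sub))
    # anchor the uppermost shaft beads at their own positions (b0 = 0)
    shaft = np.nonzero(model.regions == 2)[0]
    order = shaft[np.argsort(model.coords[shaft, 1])[::-1][:n_anchors]]
    ap_bead = np.sort(order)
    return MDSystem(
        model=model,
        substrate=substrate,
        params=MDParams(n_md=n_md),
        ap_pos=model.coords[ap_bead].copy(),
        ap_bead=ap_bead,
        ap_b0=np.zeros(len(ap_bead)),
        ap_k=0.28 * NN_PER_NM_TO_KJ_MOL_NM2,
    )
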