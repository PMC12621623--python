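import numpy as np
import pytest

from setascale.md import (
    MDParams,
    MDSystem,
    forces_and_energy,
    maxwell_boltzmann_velocities,
    run_md_phase,
)
from setascale.spatula import Substrate, SpatulaModel, build_substrate
from setascale.units import BOLTZMANN_KJ_MOL_K, NN_PER_NM_TO_KJ_MOL_NM2

MASS = 65228.0
K_BOND = 0.28 * NN_PER_NM_TO_KJ_MOL_NM2


def toy_model(coords, bonds=None, b0=None, K=None):
    coords = np.asarray(coords, float)
    bonds = (np.zeros((0, 2), dtype=np.int64) if bonds is None
             else np.asarray(bonds, dtype=np.int64))
    b0 = np.zeros(len(bonds)) if b0 is None else np.asarray(b0, float)
    K = np.full(len(bonds), K_BOND) if K is None else np.asarray(K, float)
    return SpatulaModel(
        coords=coords, regions=np.zeros(len(coords), dtype=int), mass=MASS,
        bonds=bonds, b0=b0, K=K, fibril=np.array([0.0, 1.0, 0.0]),
        shaft_axis=np.array([0.0, 1.0, 0.0]), shaft_top=np.zeros(3),
    )


def toy_system(model, substrate=None, ap_bead=(), ap_pos=None, ap_b0=None,
               group=None, **params):
    if substrate is None:
        substrate = Substrate(coords=np.array([[0.0, -1e6, 0.0]]),
                              spacing=2.0, has_bulk=False)
    ap_bead = np.asarray(ap_bead, dtype=np.int64)
    if ap_pos is None:
        ap_pos = model.coords[ap_bead].copy() if len(ap_bead) else np.zeros((0, 3))
    if ap_b0 is None:
        ap_b0 = np.zeros(len(ap_bead))
    return MDSystem(
        model=model, substrate=substrate, params=MDParams(**params),
        ap_pos=np.asarray(ap_pos, float), ap_bead=ap_bead,
        ap_b0=np.asarray(ap_b0, float), ap_k=K_BOND, group=group,
    )


# ----------------------------------------------------------------- forces

def test_forces_match_finite_differences():
    rng = np.random.default_rng(0)
    coords = rng.uniform(-10, 10, (12, 3)) + [0, 15, 0]
    bonds = np.array([[i, (i + 1) % 12] for i in range(12)])
    b0 = np.linalg.norm(coords[bonds[:, 1]] - coords[bonds[:, 0]], axis=1) * 0.97
    model = toy_model(coords, bonds, b0)
    sub = build_substrate(extent=(-15, 15, -15, 15), rng=rng)
    ext = rng.normal(0, 0.5, coords.shape)
    sys = toy_system(model, substrate=sub, ap_bead=[0, 5],
                     ap_pos=coords[[0, 5]] + 0.5, ap_b0=[0.3, 0.1])
    pos = coords.copy()
    f, _, _ = forces_and_energy(sys, pos, ext_force=ext)
    h = 1e-5
    for i, d in [(0, 0), (3, 1), (5, 2), (7, 1), (11, 0)]:
        pp = pos.copy(); pp[i, d] += h
        pm = pos.copy(); pm[i, d] -= h
        _, _, ep = forces_and_energy(sys, pp, ext_force=ext)
        _, _, em = forces_and_energy(sys, pm, ext_force=ext)
        fd = -(ep - em) / (2 * h)
        assert fd == pytest.approx(f[i, d], rel=1e-6, abs=1e-8)


def test_lj_pair_potential_energy_shifted():
    eps, sig, rcut = 290.0, 4.0, 12.0
    sub = Substrate(coords=np.array([[0.0, 0.0, 0.0]]), spacing=2.0,
                    has_bulk=False)

    def pe_at(r):
        sys = toy_system(toy_model([[0.0, r, 0.0]]), substrate=sub)
        _, _, pe = forces_and_energy(sys, np.array([[0.0, r, 0.0]]))
        return pe

    def lj(r):
        s6 = (sig / r) ** 6
        return 4 * eps * (s6 * s6 - s6)

    # energy-shifted: V(rcut) = 0, zero beyond the cutoff, continuous across
    assert pe_at(13.0) == 0.0
    assert pe_at(11.999) == pytest.approx(0.0, abs=2e-3)
    for r in (4.2, 4.6, 6.0, 10.0):
        assert pe_at(r) == pytest.approx(lj(r) - lj(rcut), rel=1e-12)
    # minimum at 2^(1/6) sigma is the full well depth minus the shift
    rmin = 2 ** (1 / 6) * sig
    assert pe_at(rmin) == pytest.approx(-eps - lj(rcut), rel=1e-9)


def test_lj_force_matches_derivative():
    sub = Substrate(coords=np.array([[0.0, 0.0, 0.0]]), spacing=2.0,
                    has_bulk=False)
    sys = toy_system(toy_model([[0.0, 6.0, 0.0]]), substrate=sub)
    eps, sig = 290.0, 4.0
    r = 6.0
    f, _, _ = forces_and_energy(sys, np.array([[0.0, r, 0.0]]))
    s6 = (sig / r) ** 6
    dV = 24 * eps / r * (s6 - 2 * s6 * s6)  # dV/dr
    assert f[0, 1] == pytest.approx(-dV, rel=1e-12)
    assert f[0, 0] == 0.0 and f[0, 2] == 0.0


def test_overlap_raises():
    sub = Substrate(coords=np.array([[0.0, 0.0, 0.0]]), spacing=2.0,
                    has_bulk=False)
    sys = toy_system(toy_model([[0.0, 0.0, 0.0]]), substrate=sub)
    with pytest.raises(ValueError, match="overlap"):
        forces_and_energy(sys, np.array([[0.0, 0.0, 0.0]]))


# -------------------------------------------------------------- integrator

def test_harmonic_dimer_oscillation_frequency():
    # two bonded beads stretched 1 nm: kinetic energy oscillates at twice
    # the angular frequency omega = sqrt(2 K / m) of the relative coordinate
    b0 = 8.0
    model = toy_model([[0.0, 20.0, 0.0], [0.0, 20.0 + b0 + 1.0, 0.0]],
                      bonds=[[0, 1]], b0=[b0])
    sys = toy_system(model, dt_fs=20.0, n_md=65536)
    pos = model.coords.copy()
    vel = np.zeros_like(pos)
    res = run_md_phase(sys, pos, vel, thermostat=False,
                       rng=np.random.default_rng(0))
    ke = res.temperature_trace  # proportional to kinetic energy
    spec = np.abs(np.fft.rfft(ke - ke.mean()))
    freq = np.fft.rfftfreq(len(ke), d=sys.params.dt_ps)
    f_peak = freq[np.argmax(spec)]
    omega = np.sqrt(2 * K_BOND / MASS)
    assert f_peak == pytest.approx(2 * omega / (2 * np.pi), rel=0.05)
    # the motion stays on the bond axis
    assert np.abs(pos[:, [0, 2]]).max() < 1e-9


def test_nve_energy_conservation_short(mini_spatula):
    model = mini_spatula
    low = model.coords[:, 1].min()
    model = model.transformed(np.eye(3), np.array([0.0, 8.0 - low, 0.0]))
    sub = build_substrate(extent=(-150, 150, -150, 150),
                          rng=np.random.default_rng(2))
    sys = toy_system(model, substrate=sub, n_md=2000)
    pos = model.coords.copy()
    vel = maxwell_boltzmann_velocities(len(pos), MASS, 300.0,
                                       np.random.default_rng(3))
    res = run_md_phase(sys, pos, vel, thermostat=False,
                       rng=np.random.default_rng(4))
    e = res.energy_trace
    assert np.abs(e - e[0]).max() / abs(e[0]) < 1e-3


def test_thermostat_holds_target_temperature(mini_spatula):
    # isolated network far from the substrate: canonical sampling at 300 K
    sys = toy_system(mini_spatula, n_md=4000)
    pos = mini_spatula.coords.copy()
    vel = maxwell_boltzmann_velocities(len(pos), MASS, 300.0,
                                       np.random.default_rng(5))
    res = run_md_phase(sys, pos, vel, rng=np.random.default_rng(6))
    mean_T = res.temperature_trace[2000:].mean()
    assert mean_T == pytest.approx(300.0, abs=10.0)


def test_zero_temperature_thermostat_damps(mini_spatula):
    sys = toy_system(mini_spatula, n_md=2000)
    pos = mini_spatula.coords.copy()
    vel = maxwell_boltzmann_velocities(len(pos), MASS, 300.0,
                                       np.random.default_rng(7))
    res = run_md_phase(sys, pos, vel, temperature=0.0,
                       rng=np.random.default_rng(8))
    assert res.temperature_trace[-1] < 1.0  # K


def test_md_phase_deterministic(mini_spatula):
    def one(seed):
        sys = toy_system(mini_spatula, n_md=500)
        pos = mini_spatula.coords.copy()
        vel = maxwell_boltzmann_velocities(len(pos), MASS, 300.0,
                                           np.random.default_rng(9))
        run_md_phase(sys, pos, vel, rng=np.random.default_rng(seed))
        return pos, vel

    p1, v1 = one(10)
    p2, v2 = one(10)
    p3, _ = one(11)
    assert np.array_equal(p1, p2) and np.array_equal(v1, v2)
    assert not np.array_equal(p1, p3)


def test_ap_springs_pull_beads():
    # a single bead tethered to a displaced AP relaxes towards it at T = 0
    model = toy_model([[0.0, 50.0, 0.0]])
    target = np.array([[5.0, 55.0, 0.0]])
    # tau ~ 5 ps is near critical damping for this spring and mass
    sys = toy_system(model, ap_bead=[0], ap_pos=target, ap_b0=[0.0],
                     n_md=10000, tau_inside_ps=5.0)
    pos = model.coords.copy()
    vel = np.zeros_like(pos)
    run_md_phase(sys, pos, vel, temperature=0.0, rng=np.random.default_rng(0))
    assert pos[0] == pytest.approx(target[0], abs=0.05)
    # force on the AP is equal and opposite to the spring force on the bead:
    # once settled on the target it vanishes
    res = run_md_phase(sys, pos, vel, n_steps=2000, temperature=0.0,
                      rng=np.random.default_rng(1))
    assert np.abs(res.f_ap_mean).max() < 0.5


def test_substrate_force_by_group():
    # two beads in different groups: only the near one feels the substrate
    sub = build_substrate(extent=(-20, 20, -20, 20),
                          rng=np.random.default_rng(1))
    model = toy_model([[0.0, 5.0, 0.0], [0.0, 40.0, 0.0]])
    sys = toy_system(model, substrate=sub, group=np.array([0, 1]), n_md=50)
    pos = model.coords.copy()
    vel = np.zeros_like(pos)
    res = run_md_phase(sys, pos, vel, thermostat=False,
                       rng=np.random.default_rng(2))
    assert res.substrate_force_by_group.shape == (2, 3)
    assert np.abs(res.substrate_force_by_group[1]).max() < 1e-12
    assert res.substrate_force_mean == pytest.approx(
        res.substrate_force_by_group.sum(axis=0))


def test_maxwell_boltzmann_statistics():
    rng = np.random.default_rng(12)
    v = maxwell_boltzmann_velocities(20000, MASS, 300.0, rng)
    expected_var = BOLTZMANN_KJ_MOL_K * 300.0 / MASS
    assert v.var() == pytest.approx(expected_var, rel=0.03)
    assert np.abs(v.mean()) < 3 * np.sqrt(expected_var / v.size)
    assert np.all(maxwell_boltzmann_velocities(5, MASS, 0.0, rng) == 0.0)


def test_params_validation():
    with pytest.raises(ValueError):
        MDParams(window_fraction=0.0)
    with pytest.raises(ValueError):
        MDParams(lj_sigma=-1.0)
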