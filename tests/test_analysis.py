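import numpy as np
import pandas as pd
import pytest

from setascale.analysis import (
    ProfileSeries,
    contact_plateau_levels,
    count_contacts,
    detect_detachment,
    friction_coefficient,
    per_spatula_minima,
    run_report,
    sliding_velocity,
)


def make_series(contacts_per_spatula, f_sub_y=None, per_spatula_f=None,
                phases=None, dt_ls_ns=1.4, orientations=("tip-first", "pad-parallel")):
    """Small synthetic run table with the columns the analysis consumes."""
    n_sp = len(contacts_per_spatula)
    n = len(contacts_per_spatula[0])
    steps = np.arange(1, n + 1)
    rec = {
        "load_step": steps,
        "time_ns": steps * dt_ls_ns,
        "phase": phases if phases is not None else ["pulloff"] * n,
        "driver_u_nm": np.zeros(n),
        "f_sub_y_nN": f_sub_y if f_sub_y is not None else np.zeros(n),
        "contacts": np.sum(contacts_per_spatula, axis=0),
    }
    for i, c in enumerate(contacts_per_spatula):
        rec[f"contacts_s{i}"] = c
        rec[f"f_sub_y_s{i}_nN"] = (per_spatula_f[i] if per_spatula_f is not None
                                   else np.zeros(n))
    return ProfileSeries(pd.DataFrame(rec), n_sp, dt_ls_ns,
                         tuple(orientations[:n_sp]))


# ----------------------------------------------------------------- contacts

def test_count_contacts_tree_equals_brute():
    rng = np.random.default_rng(0)
    a = rng.uniform(-20, 20, (120, 3))
    b = rng.uniform(-20, 20, (200, 3))
    assert count_contacts(a, b, cutoff=6.0) == count_contacts(
        a, b, cutoff=6.0, brute=True)


def test_count_contacts_strict_inequality():
    a = np.array([[0.0, 5.0, 0.0]])
    b = np.array([[0.0, 0.0, 0.0]])
    assert count_contacts(a, b, cutoff=5.0) == 0  # boundary pair excluded
    assert count_contacts(a, b, cutoff=5.0 + 1e-9) == 1
    assert count_contacts(np.zeros((0, 3)), b) == 0
    with pytest.raises(ValueError):
        count_contacts(a, b, cutoff=0.0)


def test_profile_series_rejects_bad_contacts():
    with pytest.raises(ValueError, match="non-negative integers"):
        make_series([[-1, 0, 0], [0, 0, 0]])


# --------------------------------------------------------------- detachment

def test_detachment_stays_zero_rule():
    # transient contact loss (step 3) must not register; the final zero run
    # starts at step 5
    s = make_series([[3, 1, 0, 1, 0, 0, 0], [2, 2, 2, 2, 2, 2, 2]],
                    per_spatula_f=[[0, -1, 0, -2, 0, 0, 0]] * 2)
    events = detect_detachment(s, confirm=3)
    assert len(events) == 1
    e = events[0]
    assert e.spatula_id == 0
    assert e.load_step == 5
    assert e.time_ns == pytest.approx(5 * 1.4)
    assert e.peak_force_nN == 2.0
    assert e.contact_mode == "tip-dominant"


def test_detachment_requires_confirmation():
    # the trailing zero run is shorter than the confirmation horizon
    s = make_series([[3, 2, 1, 0, 0], [1, 1, 1, 1, 1]])
    assert detect_detachment(s, confirm=3) == []
    assert len(detect_detachment(s, confirm=2)) == 1


def test_detachment_never_attached_excluded():
    s = make_series([[0, 0, 0, 0, 0], [2, 1, 0, 0, 0]])
    events = detect_detachment(s, confirm=3)
    assert [e.spatula_id for e in events] == [1]
    assert events[0].contact_mode == "pad-dominant"


def test_detachment_events_ordered_by_time():
    s = make_series([[1, 1, 0, 0, 0, 0], [2, 2, 2, 0, 0, 0]])
    events = detect_detachment(s, confirm=3)
    assert [e.spatula_id for e in events] == [0, 1]
    assert events[0].load_step < events[1].load_step


# ------------------------------------------------------------------- minima

def test_per_spatula_minima_conventions():
    f0 = [0, -8.0, -2.0, 0, 0]
    f1 = [0, -1.0, -6.0, 0, 0]
    total = (np.array(f0) + np.array(f1)).tolist()
    s = make_series([[1, 1, 1, 0, 0], [1, 1, 1, 1, 0]],
                    f_sub_y=total, per_spatula_f=[f0, f1])
    out = per_spatula_minima(s)
    assert out["seta_min_nN"] == -9.0
    assert out["per_spatula_Fmin_nN"] == {0: 8.0, 1: 6.0}
    assert out["naive_average_nN"] == pytest.approx(4.5)
    assert out["per_spatula_average_nN"] == pytest.approx(7.0)
    # asynchronous minima: per-spatula averaging exceeds the naive split
    assert out["per_spatula_average_nN"] >= out["naive_average_nN"]
    assert out["excluded_spatulae"] == []


def test_per_spatula_minima_excludes_never_contacting():
    s = make_series([[1, 1, 0], [0, 0, 0]],
                    f_sub_y=[0, -3.0, 0], per_spatula_f=[[0, -3.0, 0], [0, 0, 0]])
    out = per_spatula_minima(s)
    assert out["excluded_spatulae"] == [1]
    assert 1 not in out["per_spatula_Fmin_nN"]


def test_per_spatula_minima_requires_pulloff():
    s = make_series([[1, 1], [1, 1]], phases=["preload", "preload"])
    with pytest.raises(ValueError, match="pull-off"):
        per_spatula_minima(s)


# ----------------------------------------------------------------- plateaus

def test_contact_plateau_levels_two_stage():
    c = [0, 0, 6800, 6810, 6805, 6795, 6802, 5000, 3900, 3910, 3895, 3905,
         3890, 2000, 600, 0, 0]
    levels = contact_plateau_levels(np.array(c, float))
    assert len(levels) >= 2
    assert levels[0] == pytest.approx(6802, rel=0.02)
    assert any(abs(lv - 3900) / 3900 < 0.02 for lv in levels[1:])


def test_contact_plateau_levels_monotone_decay_single():
    c = np.linspace(5000, 0, 40)
    # a steady ramp has no sustained level below the 10% spread rule except
    # possibly near its start; it must not report two
    levels = contact_plateau_levels(c, window=5)
    assert len(levels) <= 1


def test_contact_plateau_levels_flat_series():
    c = np.full(30, 4000.0)
    assert len(contact_plateau_levels(c)) == 1
    assert contact_plateau_levels(np.zeros(30)) == []


# ------------------------------------------------------------------ sliding

def test_sliding_velocity_exact_ramp():
    # 1 nm per 1.4 ns load step = 0.714 m/s
    t = np.arange(30) * 1.4
    x = 100.0 + np.arange(30) * 1.0
    assert sliding_velocity(t, x) == pytest.approx(1.0 / 1.4, rel=1e-12)


def test_sliding_velocity_noisy_ols():
    rng = np.random.default_rng(4)
    t = np.arange(200) * 1.4
    x = 0.5 * t + rng.normal(0, 0.3, 200)
    v = sliding_velocity(t, x)
    # OLS slope standard error
    se = 0.3 / np.sqrt(np.sum((t - t.mean()) ** 2))
    assert abs(v - 0.5) < 3 * se
    with pytest.raises(ValueError, match="3 samples"):
        sliding_velocity(t[:2], x[:2])


def test_sliding_velocity_window():
    t = np.arange(20) * 1.0
    x = np.where(t < 10, 0.0, (t - 10) * 2.0)
    assert sliding_velocity(t, x, window=slice(10, None)) == pytest.approx(2.0)


# ----------------------------------------------------------------- friction

def test_friction_coefficient_examples():
    fl = np.array([1.0, -1.0, 1.0, -1.0])
    fn = np.array([2.0, 2.0, 2.0, 2.0])
    assert friction_coefficient(fl, fn) == pytest.approx(0.5)
    # adhesion-dominated sliding: negative normal force, same magnitude rule
    assert friction_coefficient(fl, -fn) == pytest.approx(0.5)


def test_friction_coefficient_rejects_sign_change():
    with pytest.raises(ValueError, match="sign-ambiguous"):
        friction_coefficient(np.ones(4), np.array([1.0, -1.0, 1.0, 1.0]))
    with pytest.raises(ValueError, match="nonzero"):
        friction_coefficient(np.ones(3), np.zeros(3))


# ------------------------------------------------------------------- report

def test_run_report_smoke():
    f0 = [2.0, -8.0, -2.0, 0, 0]
    f1 = [1.0, -1.0, -6.0, 0, 0]
    total = (np.array(f0) + np.array(f1)).tolist()
    s = make_series([[5, 3, 1, 0, 0], [6, 6, 2, 0, 0]],
                    f_sub_y=total, per_spatula_f=[f0, f1],
                    phases=["preload"] + ["pulloff"] * 4)
    rep = run_report(s, confirm=2)
    assert rep["adhesion_minimum_nN"] == -9.0
    assert rep["detachment_order"] == [0, 1]
    assert rep["preload_max_nN"] == 3.0
    assert rep["n_load_steps"] == 5
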