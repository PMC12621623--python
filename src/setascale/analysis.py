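"""Observables computed from protocol run records.

Signed force profiles (compression positive, adhesion negative), contact
counts, per-spatula adhesion minima under the naive and per-spatula averaging
conventions, detachment events under the stays-zero rule, sliding velocity,
and the apparent friction coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


def count_contacts(
    spatula_beads: np.ndarray,
    substrate_beads: np.ndarray,
    cutoff: float = 12.0,
    brute: bool = False,
) -> int:
    """Number of spatula-substrate bead pairs with distance strictly below
    the cutoff.  The tree-based count and the O(N^2) brute-force count are
    exact and must agree."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = np.atleast_2d(np.asarray(spatula_beads, float))
    b = np.atleast_2d(np.asarray(substrate_beads, float))
    if len(a) == 0 or len(b) == 0:
        return 0
    if brute:
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        return int((d2 < cutoff * cutoff).sum())
    tree = cKDTree(b)
    # query_ball_point includes boundary points; enforce the strict inequality
    neigh = tree.query_ball_point(a, cutoff)
    total = 0
    for i, lst in enumerate(neigh):
        if not lst:
            continue
        d2 = ((b[lst] - a[i]) ** 2).sum(axis=1)
        total += int((d2 < cutoff * cutoff).sum())
    return total


@dataclass
class ProfileSeries:
    """Per-load-step measurement table for one protocol run.

    Columns: time_ns, load_step, phase, driver_u_nm, f_sub_{x,y,z}_nN,
    f_ap_{x,y,z}_nN, f_driver_nN, contacts, and per spatula i:
    f_sub_y_s{i}_nN, contacts_s{i}, tip_x_s{i}_nm, tip_y_s{i}_nm,
    pad_x_s{i}_nm, pad_y_s{i}_nm.
    """

    frame: pd.DataFrame
    n_spatulae: int
    dt_ls_ns: float
    orientations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        f = self.frame
        cols = [f"contacts_s{i}" for i in range(self.n_spatulae)] + ["contacts"]
        for c in cols:
            v = f[c].to_numpy()
            if np.any(v < 0) or not np.all(v == v.astype(int)):
                raise ValueError(f"contact counts must be non-negative integers ({c})")

    @classmethod
    def from_records(
        cls,
        records: list[dict],
        n_spatulae: int,
        dt_ls_ns: float,
        orientations: tuple[str, ...] = (),
    ) -> "ProfileSeries":
        return cls(pd.DataFrame.from_records(records), n_spatulae, dt_ls_ns,
                   tuple(orientations))

    def phase_mask(self, phase: str) -> np.ndarray:
        return (self.frame["phase"] == phase).to_numpy()


def per_spatula_minima(series: ProfileSeries) -> dict:
    """Per-spatula adhesion minima over the pull-off phase, plus the naive
    and per-spatula averaging conventions.

    naive average    = |most negative seta-level force| / n_spatulae
    per-spatula avg  = mean over spatulae of each one's own |F_min|

    Spatulae that never contact the substrate are excluded and flagged.
    """
    f = series.frame
    pull = series.phase_mask("pulloff")
    if not pull.any():
        raise ValueError("series does not cover a pull-off phase")
    sub = f.loc[pull]
    total = sub["f_sub_y_nN"].to_numpy()
    i_min = int(np.argmin(total))
    seta_min = float(total[i_min])

    minima, times, excluded = {}, {}, []
    for i in range(series.n_spatulae):
        contacts_any = (f[f"contacts_s{i}"].to_numpy() > 0).any()
        if not contacts_any:
            excluded.append(i)
            continue
        fi = sub[f"f_sub_y_s{i}_nN"].to_numpy()
        k = int(np.argmin(fi))
        minima[i] = abs(float(fi[k]))
        times[i] = float(sub["time_ns"].to_numpy()[k])

    naive = abs(seta_min) / series.n_spatulae
    per_spat = float(np.mean(list(minima.values()))) if minima else float("nan")
    return {
        "seta_min_nN": seta_min,
        "seta_min_time_ns": float(sub["time_ns"].to_numpy()[i_min]),
        "per_spatula_Fmin_nN": minima,
        "per_spatula_Fmin_time_ns": times,
        "naive_average_nN": naive,
        "per_spatula_average_nN": per_spat,
        "excluded_spatulae": excluded,
    }


@dataclass(frozen=True)
class DetachmentEvent:
    """One spatula's detachment under the stays-zero rule."""

    spatula_id: int
    load_step: int
    time_ns: float
    peak_force_nN: float  # |F_min| of this spatula before detachment
    peak_time_ns: float
    contact_mode: str  # "tip-dominant" | "pad-dominant"

    def __post_init__(self) -> None:
        if self.peak_time_ns > self.time_ns + 1e-12:
            raise ValueError("peak time must not exceed detachment time")


def detect_detachment(series: ProfileSeries, confirm: int = 3) -> list[DetachmentEvent]:
    """Detachment events, ordered by time.

    A spatula detaches at the first load step of the final run of zero
    contacts, provided that run persists for at least ``confirm`` load steps
    (transient contact loss during tip slip must not register).
    """
    f = series.frame
    steps = f["load_step"].to_numpy()
    events = []
    for i in range(series.n_spatulae):
        c = f[f"contacts_s{i}"].to_numpy()
        if (c == 0).all() or c[-1] != 0:
            continue  # never attached, or still attached at the end
        last_nonzero = int(np.max(np.nonzero(c)[0]))
        start = last_nonzero + 1
        if len(c) - start < confirm:
            continue  # not yet confirmed
        step = int(steps[start])
        fi = f[f"f_sub_y_s{i}_nN"].to_numpy()[: start + 1]
        k = int(np.argmin(fi))
        mode = "pad-dominant"
        if series.orientations and series.orientations[i] == "tip-first":
            mode = "tip-dominant"
        events.append(
            DetachmentEvent(
                spatula_id=i,
                load_step=step,
                time_ns=step * series.dt_ls_ns,
                peak_force_nN=abs(float(fi[k])),
                peak_time_ns=float(f["time_ns"].to_numpy()[k]),
                contact_mode=mode,
            )
        )
    events.sort(key=lambda e: (e.time_ns, e.spatula_id))
    return events


def contact_plateau_levels(
    contacts: np.ndarray,
    window: int = 5,
    rel_spread: float = 0.10,
    level_ratio: float = 1.4,
    min_fraction: float = 0.05,
) -> list[float]:
    """Distinct sustained contact-count levels in a contact series.

    A plateau is a run of ``window`` consecutive steps whose spread
    (max - min) stays below ``rel_spread`` of the window mean and whose mean
    exceeds ``min_fraction`` of the series maximum.  Window means are merged
    greedily: a new level is opened only when it differs from every accepted
    level by more than ``level_ratio`` (as a ratio).  Returns the accepted
    levels in descending order; a peeling spatula that pauses at a partial
    contact patch yields two or more levels.
    """
    c = np.asarray(contacts, float)
    cmax = c.max() if len(c) else 0.0
    if cmax <= 0 or len(c) < window:
        return []
    levels: list[float] = []
    for i in range(len(c) - window + 1):
        w = c[i : i + window]
        m = w.mean()
        if m < min_fraction * cmax or (w.max() - w.min()) > rel_spread * m:
            continue
        if all(max(m, lv) / min(m, lv) > level_ratio for lv in levels):
            levels.append(m)
    return sorted(levels, reverse=True)


def sliding_velocity(time_ns: np.ndarray, x_nm: np.ndarray,
                     window: slice | None = None) -> float:
    """Least-squares slope of a pad X-position series, in m/s
    (1 nm/ns = 1 m/s)."""
    t = np.asarray(time_ns, float)
    x = np.asarray(x_nm, float)
    if window is not None:
        t, x = t[window], x[window]
    if len(t) < 3:
        raise ValueError("window must contain at least 3 samples")
    slope = np.polyfit(t, x, 1)[0]  # nm/ns
    return float(slope)


def friction_coefficient(f_lateral_nN: np.ndarray, f_normal_nN: np.ndarray,
                         window: slice | None = None) -> float:
    """Apparent friction coefficient mu = mean|F_lat| / mean|F_norm| over the
    window.  Windows in which the normal force changes sign are rejected."""
    fl = np.asarray(f_lateral_nN, float)
    fn = np.asarray(f_normal_nN, float)
    if window is not None:
        fl, fn = fl[window], fn[window]
    if len(fn) == 0 or np.all(fn == 0):
        raise ValueError("normal force must be nonzero over the window")
    if fn.min() < 0 < fn.max():
        raise ValueError("sign-ambiguous normal force: window rejected")
    return float(np.mean(np.abs(fl)) / np.mean(np.abs(fn)))


def run_report(series: ProfileSeries, confirm: int = 3) -> dict:
    """Summary report: averaging conventions, detachment order, per-phase
    extremes."""
    minima = per_spatula_minima(series)
    events = detect_detachment(series, confirm=confirm)
    f = series.frame
    report = {
        "n_load_steps": int(len(f)),
        "preload_max_nN": float(f.loc[series.phase_mask("preload"), "f_sub_y_nN"].max())
        if series.phase_mask("preload").any() else None,
        "adhesion_minimum_nN": minima["seta_min_nN"],
        "naive_average_nN": minima["naive_average_nN"],
        "per_spatula_average_nN": minima["per_spatula_average_nN"],
        "excluded_spatulae": minima["excluded_spatulae"],
        "detachment_order": [e.spatula_id for e in events],
        "detachment_load_steps": [e.load_step for e in events],
        "detachment_times_ns": [e.time_ns for e in events],
    }
    return report
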