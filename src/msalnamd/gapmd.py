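"""Gap-driven dynamics: accelerated sampling of small-gap regions.

Where the gap between a chosen adjacent pair of adiabatic states exceeds a
threshold (default 0.03 Hartree, the range where surface hops typically
happen), the trajectory is propagated along the negative interstate-gap
gradient, F_gap = F_upper - F_lower, which by construction drives it toward
near-degeneracy.  Below the threshold it propagates on one adiabatic
surface (the configured branch).  Because switching between the two force
fields does not conserve energy, any excess energy accumulated relative to
the initial total is removed by scaling the velocities along the momenta,

    v' = sqrt(1 - E_excess / E_k) v ;

if the excess exceeds the kinetic energy the step falls back to surface
propagation regardless of the gap.  gapMD is a sampler: its geometries feed
active learning, not observables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .initial_conditions import InitialCondition
from .surface_hopping import Trajectory, _Recorder, TrajectoryState
from .units import masses_au

__all__ = ["GapMDConfig", "gap_force", "scale_excess", "propagate_gapmd"]


@dataclass
class GapMDConfig:
    threshold: float = 0.03          # Hartree
    pair: Tuple[int, int] = (0, 1)   # (lower, upper), adjacent
    branch: str = "lower"            # surface followed when gap < threshold
    dt: float = 4.134                # a.u. time (~0.1 fs)
    max_time: float = 4134.0
    seed: int = 0

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("gap threshold must be positive")
        lo, up = self.pair
        if up != lo + 1:
            raise ValueError("pair must be adjacent (upper = lower + 1)")
        if self.branch not in ("upper", "lower"):
            raise ValueError("branch must be 'upper' or 'lower'")


def gap_force(f_upper: np.ndarray, f_lower: np.ndarray) -> np.ndarray:
    """F_gap = F_upper - F_lower  (the negative interstate-gap gradient)."""
    f_upper = np.asarray(f_upper, dtype=float)
    f_lower = np.asarray(f_lower, dtype=float)
    if f_upper.shape != f_lower.shape:
        raise ValueError(
            f"force shapes differ: {f_upper.shape} vs {f_lower.shape}"
        )
    return f_upper - f_lower


def scale_excess(velocities: np.ndarray, e_excess: float, e_k: float):
    """Velocity scaling that removes ``e_excess`` of kinetic energy.

    Returns the scaled velocities, or None (the switch-to-surface signal)
    when the excess exceeds the available kinetic energy.  Non-positive
    excess leaves the velocities unchanged.
    """
    if e_k < 0:
        raise ValueError("kinetic energy must be non-negative")
    if e_excess <= 0:
        return velocities
    if e_excess > e_k:
        return None
    return np.sqrt(1.0 - e_excess / e_k) * velocities


def propagate_gapmd(
    initial: InitialCondition,
    potential,
    config: GapMDConfig,
    al_monitor=None,
) -> Trajectory:
    """Propagate one gap-driven trajectory.

    Each step re-evaluates the switching condition (no hysteresis).  The
    excess energy is measured against the step-zero total energy, with the
    potential-energy bookkeeping of the current mode: kinetic + branch
    surface in surface mode, kinetic + lower surface while following the
    gap gradient.  With an ``al_monitor`` the same per-step checks as in
    surface hopping apply (negative gap first, then surface uncertainties).
    """
    lo, up = config.pair
    if up >= potential.n_states:
        raise ValueError("pair exceeds potential state count")
    masses = np.asarray(masses_au(potential.elements))[:, None]
    dt = config.dt
    n_steps = int(round(config.max_time / dt))
    branch_state = up if config.branch == "upper" else lo

    rec = _Recorder(monitored=al_monitor is not None)
    modes = []

    x = initial.coords.copy()
    v = initial.velocities.copy()
    res = potential.evaluate(x)

    def kinetic(vel):
        return 0.5 * float((masses * vel * vel).sum())

    def gap_of(r):
        return float(r.energies[up] - r.energies[lo])

    def mode_of(r, vel):
        return "gap" if gap_of(r) >= config.threshold else "surface"

    mode = mode_of(res, v)
    e_pot0 = float(res.energies[lo if mode == "gap" else branch_state])
    total0 = kinetic(v) + e_pot0

    verdict = "completed"
    ok = True
    state = _gap_snapshot(0.0, x, v, lo if mode == "gap" else branch_state,
                          res, masses)
    ok, verdict = _check_and_record(rec, state, al_monitor)
    modes.append(mode)

    step = 0
    while ok and step < n_steps:
        step += 1
        gap_now = gap_of(res)
        use_gap = gap_now >= config.threshold
        if use_gap:
            f = gap_force(-res.gradients[up], -res.gradients[lo])
        else:
            f = -res.gradients[branch_state]
        a = f / masses
        x_new = x + v * dt + 0.5 * a * dt**2
        try:
            res_new = potential.evaluate(x_new)
        except ValueError:
            verdict, ok = "unphysical", False
            rec.message = f"evaluation failed at step {step}"
            break
        if not (np.all(np.isfinite(res_new.energies))
                and np.all(np.isfinite(res_new.gradients))):
            verdict, ok = "unphysical", False
            rec.message = f"non-finite energies/forces at step {step}"
            break
        if use_gap:
            f_new = gap_force(-res_new.gradients[up], -res_new.gradients[lo])
        else:
            f_new = -res_new.gradients[branch_state]
        v_new = v + 0.5 * (a + f_new / masses) * dt

        this_mode = "gap" if use_gap else "surface"
        if use_gap:
            e_k = kinetic(v_new)
            e_excess = e_k + float(res_new.energies[lo]) - total0
            scaled = scale_excess(v_new, e_excess, e_k)
            if scaled is None:
                # not enough kinetic energy: redo this step on the surface
                this_mode = "surface"
                a_s = -res.gradients[branch_state] / masses
                x_new = x + v * dt + 0.5 * a_s * dt**2
                res_new = potential.evaluate(x_new)
                a_s_new = -res_new.gradients[branch_state] / masses
                v_new = v + 0.5 * (a_s + a_s_new) * dt
            else:
                v_new = scaled

        x, v, res = x_new, v_new, res_new
        active = lo if this_mode == "gap" else branch_state
        state = _gap_snapshot(step * dt, x, v, active, res, masses)
        ok, verdict = _check_and_record(rec, state, al_monitor)
        modes.append(this_mode)

    traj = rec.build(verdict)
    traj.mode = np.array(modes)
    return traj


def _gap_snapshot(t, x, v, active, res, masses) -> TrajectoryState:
    kin = 0.5 * float((masses * v * v).sum())
    return TrajectoryState(
        time=t, coords=x.copy(), velocities=v.copy(), active_state=active,
        energies=res.energies.copy(), forces=-res.gradients.copy(),
        kinetic=kin,
    )


def _check_and_record(rec, state, al_monitor):
    if al_monitor is None:
        rec.add(state)
        return True, "completed"
    e_aux = al_monitor.aux_energies(state.coords)
    verdict = al_monitor.check(state.energies, e_aux, state.active_state)
    rec.add(state, e_aux)
    if verdict != "ok":
        rec.stop_step = len(rec.times) - 1
        return False, verdict
    return True, "completed"
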