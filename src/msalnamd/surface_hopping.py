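"""Landau-Zener-Belyaev-Lebedev (LZBL) trajectory surface hopping.

Nuclei follow velocity-Verlet dynamics on the active adiabatic surface.
At every strict local minimum (in time) of the gap Z to an adjacent state,
the hop probability

    P = exp( -(pi / 2 hbar) * sqrt( Z^3 / Zdd ) )

is evaluated from the gap and its second time derivative Zdd (three-point
finite difference), and a seeded uniform draw decides the hop.  Hops are
applied at the gap-minimum step, which requires one step of lookahead: the
provisionally propagated step is discarded, velocities are rescaled along
the momentum direction to conserve total energy, and propagation resumes on
the new surface.  Upward hops without sufficient kinetic energy are
frustrated (logged, no state change).  No nonadiabatic coupling vectors are
needed anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .initial_conditions import InitialCondition
from .units import masses_au

__all__ = [
    "TrajectoryState",
    "HopEvent",
    "Trajectory",
    "lz_probability",
    "detect_gap_minimum",
    "rescale_after_hop",
    "propagate_tsh",
]

HBAR = 1.0  # atomic units throughout


@dataclass
class TrajectoryState:
    """Snapshot of one propagation step."""

    time: float
    coords: np.ndarray
    velocities: np.ndarray
    active_state: int
    energies: np.ndarray           # per-state potential energies
    forces: np.ndarray             # per-state forces (n_states, n_atoms, 3)
    kinetic: float

    @property
    def total_energy(self) -> float:
        return self.kinetic + float(self.energies[self.active_state])


@dataclass
class HopEvent:
    time: float
    from_state: int
    to_state: int
    gap: float
    zdd: float
    probability: float
    draw: float
    accepted: bool
    frustrated: bool


@dataclass
class Trajectory:
    """Time series of a single (gap)MD / TSH run."""

    times: np.ndarray
    coords: np.ndarray             # (T, n_atoms, 3)
    velocities: np.ndarray
    active_state: np.ndarray       # (T,)
    energies: np.ndarray           # (T, n_states) main-potential energies
    kinetic: np.ndarray            # (T,)
    hops: List[HopEvent] = field(default_factory=list)
    verdict: str = "completed"
    stop_step: Optional[int] = None
    aux_energies: Optional[np.ndarray] = None   # (T, n_states) when monitored
    uq: Optional[np.ndarray] = None             # (T, n_states) |aux - main|
    mode: Optional[np.ndarray] = None           # gapMD: per-step mode flag
    message: str = ""

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def total_energy(self) -> np.ndarray:
        idx = np.arange(len(self.times))
        return self.kinetic + self.energies[idx, self.active_state]

    def state_at_times(self, grid: np.ndarray) -> np.ndarray:
        """Active state at each grid time (last recorded step <= t)."""
        pos = np.searchsorted(self.times, np.asarray(grid) + 1e-12, side="right") - 1
        pos = np.clip(pos, 0, len(self.times) - 1)
        return self.active_state[pos]

    def export_xyz(self, path, elements, comment: str = "") -> None:
        from .io_cli import write_xyz

        write_xyz(path, [(list(elements), c) for c in self.coords], comment)

    def to_frame(self):
        import pandas as pd

        n_states = self.energies.shape[1]
        data = {"time": self.times, "active_state": self.active_state,
                "kinetic": self.kinetic}
        for s in range(n_states):
            data[f"energy_{s}"] = self.energies[:, s]
        return pd.DataFrame(data)

    def save(self, path) -> None:
        import json

        extras = {}
        for name in ("aux_energies", "uq", "mode"):
            arr = getattr(self, name)
            if arr is not None:
                extras[name] = arr
        hops = json.dumps([vars(h) for h in self.hops])
        np.savez(
            path,
            times=self.times, coords=self.coords, velocities=self.velocities,
            active_state=self.active_state, energies=self.energies,
            kinetic=self.kinetic,
            meta=np.frombuffer(json.dumps(
                {"verdict": self.verdict, "stop_step": self.stop_step,
                 "message": self.message}).encode(), dtype=np.uint8),
            hops=np.frombuffer(hops.encode(), dtype=np.uint8),
            **extras,
        )

    @classmethod
    def load(cls, path) -> "Trajectory":
        import json

        with np.load(path) as d:
            meta = json.loads(bytes(d["meta"]).decode())
            hops = [HopEvent(**h) for h in json.loads(bytes(d["hops"]).decode())]
            return cls(
                times=d["times"], coords=d["coords"],
                velocities=d["velocities"], active_state=d["active_state"],
                energies=d["energies"], kinetic=d["kinetic"], hops=hops,
                verdict=meta["verdict"], stop_step=meta["stop_step"],
                aux_energies=d["aux_energies"] if "aux_energies" in d else None,
                uq=d["uq"] if "uq" in d else None,
                mode=d["mode"] if "mode" in d else None,
                message=meta["message"],
            )


def lz_probability(z: float, zdd: float) -> float:
    """LZBL hopping probability at a gap minimum.

    ``z`` is the gap (Hartree, >= 0) and ``zdd`` its second time derivative
    (Hartree per squared atomic time unit).  ``zdd <= 0`` means the
    three-point minimum test failed numerically; the no-hop sentinel 0.0 is
    returned rather than raising.
    """
    if z < 0:
        raise ValueError("gap must be non-negative at a gap minimum")
    if zdd <= 0:
        return 0.0
    return math.exp(-(math.pi / (2.0 * HBAR)) * math.sqrt(z**3 / zdd))


def detect_gap_minimum(z_prev: float, z_curr: float, z_next: float,
                       dt: float) -> Tuple[bool, float]:
    """Three-point strict-minimum test with the finite-difference Zdd."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    zdd = (z_prev - 2.0 * z_curr + z_next) / dt**2
    return (z_prev > z_curr and z_next > z_curr), zdd


def rescale_after_hop(state: TrajectoryState, delta_e: float,
                      reservoir: str = "total", masses=None):
    """Velocities after a hop with potential-energy change ``delta_e``.

    The whole velocity vector is scaled by s = sqrt(1 - delta_e / E_k) so
    kinetic energy changes by exactly -delta_e (total energy conserved).
    ``reservoir`` selects the kinetic energy treated as available:
    ``total`` (default) or ``com_removed`` (kinetic energy in the
    center-of-mass frame).  Returns the new velocities, or None if the hop
    is frustrated (delta_e exceeds the reservoir).
    """
    e_k = state.kinetic
    if reservoir == "total":
        e_res = e_k
    elif reservoir == "com_removed":
        # kinetic energy in the center-of-mass frame; COM translation cannot
        # be converted into potential energy by an interatomic process
        if masses is None:
            raise ValueError("com_removed reservoir requires masses")
        m = np.asarray(masses, dtype=float)[:, None]
        v = state.velocities
        v_com = (m * v).sum(axis=0) / m.sum()
        e_res = e_k - 0.5 * float(m.sum() * (v_com**2).sum())
    else:
        raise ValueError(f"unknown reservoir {reservoir!r}")
    if delta_e > e_res or e_k <= 0.0 and delta_e > 0:
        return None
    s2 = 1.0 - delta_e / e_k if e_k > 0 else 1.0
    if s2 < 0:
        return None
    return math.sqrt(s2) * state.velocities


def propagate_tsh(
    initial: InitialCondition,
    potential,
    dt: float,
    max_time: float,
    seed: int,
    al_monitor=None,
    hopping: bool = True,
    reservoir: str = "total",
) -> Trajectory:
    """Propagate one LZBL-TSH trajectory.

    ``potential`` provides ``evaluate(coords) -> result`` with per-state
    ``energies`` and ``gradients``, plus ``elements`` and ``n_states``
    (either the analytic oracle or an ML potential adapter).  When
    ``al_monitor`` is given, each step is screened in order: negative gap,
    current-surface uncertainty, adjacent-surface uncertainty; the first
    failure stops the trajectory with that verdict and flags the geometry.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_states = potential.n_states
    if not 0 <= initial.state < n_states:
        raise ValueError(f"initial state {initial.state} out of range")
    masses = np.asarray(masses_au(potential.elements))[:, None]
    rng = np.random.default_rng(seed)
    n_steps = int(round(max_time / dt))

    rec = _Recorder(monitored=al_monitor is not None)

    x = initial.coords.copy()
    v = initial.velocities.copy()
    j = int(initial.state)

    res = potential.evaluate(x)
    verdict, stop = "completed", None
    state = _snapshot(0.0, x, v, j, res, masses)
    ok, verdict = _record_checked(rec, state, al_monitor)
    gap_hist: List[np.ndarray] = [res.energies.copy()]
    step = 0
    while ok and step < n_steps:
        step += 1
        a = -res.gradients[j] / masses
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
        a_new = -res_new.gradients[j] / masses
        v_new = v + 0.5 * (a + a_new) * dt

        gap_hist.append(res_new.energies.copy())
        hop_done = False
        if hopping and len(gap_hist) >= 3:
            hop_done, res, x, v = _attempt_hops(
                rec, gap_hist, j, dt, rng, potential, masses, x, v,
                reservoir, step,
            )
            if hop_done:
                j = rec.hops[-1].to_state
                gap_hist = [res.energies.copy()]
                step -= 1  # the provisional step was discarded; redo its time
                continue  # re-propagate from the hop step on the new surface

        x, v, res = x_new, v_new, res_new
        state = _snapshot(step * dt, x, v, j, res, masses)
        ok, verdict = _record_checked(rec, state, al_monitor)
        if len(gap_hist) > 3:
            gap_hist.pop(0)

    return rec.build(verdict)


# -- internals -------------------------------------------------------------


def _snapshot(t, x, v, j, res, masses) -> TrajectoryState:
    kin = 0.5 * float((masses * v * v).sum())
    return TrajectoryState(
        time=t, coords=x.copy(), velocities=v.copy(), active_state=j,
        energies=res.energies.copy(), forces=-res.gradients.copy(),
        kinetic=kin,
    )


def _record_checked(rec, state, al_monitor):
    """Record a step; run the AL step checks (negative gap, then current-
    surface, then adjacent-surface uncertainty) if monitored."""
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


def _attempt_hops(rec, gap_hist, j, dt, rng, potential, masses, x_prev,
                  v_prev, reservoir, step):
    """Check all adjacent pairs for a gap minimum at the previous step.

    ``gap_hist`` holds energies at steps (n-1, n, n+1); the candidate hop
    applies at step n, whose phase-space point is (x_prev, v_prev) — the
    provisional step n+1 has not yet been committed.
    """
    e_prev2, e_prev, e_curr = gap_hist[-3], gap_hist[-2], gap_hist[-1]
    candidates = []
    for k in (j - 1, j + 1):
        if not 0 <= k < len(e_prev):
            continue
        z3 = (abs(e_prev2[k] - e_prev2[j]), abs(e_prev[k] - e_prev[j]),
              abs(e_curr[k] - e_curr[j]))
        is_min, zdd = detect_gap_minimum(z3[0], z3[1], z3[2], dt)
        if is_min:
            p = lz_probability(z3[1], zdd)
            candidates.append((p, -k, k, z3[1], zdd))
    # larger probability attempted first; tie broken toward the lower state
    candidates.sort(reverse=True)
    for p, _, k, z, zdd in candidates:
        draw = float(rng.random())
        if draw >= p:
            rec.hops.append(HopEvent((step - 1) * dt, j, k, z, zdd, p, draw,
                                     accepted=False, frustrated=False))
            continue
        kin = 0.5 * float((masses * v_prev * v_prev).sum())
        state_prev = TrajectoryState(
            time=(step - 1) * dt, coords=x_prev, velocities=v_prev,
            active_state=j, energies=e_prev, forces=None, kinetic=kin,
        )
        delta_e = float(e_prev[k] - e_prev[j])
        v_new = rescale_after_hop(state_prev, delta_e, reservoir,
                                  masses=masses[:, 0])
        if v_new is None:
            rec.hops.append(HopEvent((step - 1) * dt, j, k, z, zdd, p, draw,
                                     accepted=True, frustrated=True))
            continue
        rec.hops.append(HopEvent((step - 1) * dt, j, k, z, zdd, p, draw,
                                 accepted=True, frustrated=False))
        # revert the provisional step: overwrite the recorded step n with the
        # post-hop state and resume from there
        res = potential.evaluate(x_prev)
        rec.replace_last_velocity(v_new, k, masses)
        return True, res, x_prev.copy(), v_new
    return False, None, None, None


class _Recorder:
    def __init__(self, monitored: bool):
        self.times, self.coords, self.velocities = [], [], []
        self.active, self.energies, self.kinetic = [], [], []
        self.aux = [] if monitored else None
        self.hops: List[HopEvent] = []
        self.stop_step = None
        self.message = ""

    def add(self, state: TrajectoryState, e_aux=None):
        self.times.append(state.time)
        self.coords.append(state.coords)
        self.velocities.append(state.velocities)
        self.active.append(state.active_state)
        self.energies.append(state.energies)
        self.kinetic.append(state.kinetic)
        if self.aux is not None:
            self.aux.append(np.asarray(e_aux))

    def replace_last_velocity(self, v_new, new_state, masses):
        self.velocities[-1] = v_new.copy()
        self.active[-1] = new_state
        self.kinetic[-1] = 0.5 * float((masses * v_new * v_new).sum())

    def build(self, verdict: str) -> Trajectory:
        energies = np.array(self.energies)
        aux = np.array(self.aux) if self.aux is not None else None
        return Trajectory(
            times=np.array(self.times),
            coords=np.array(self.coords),
            velocities=np.array(self.velocities),
            active_state=np.array(self.active, dtype=int),
            energies=energies,
            kinetic=np.array(self.kinetic),
            hops=self.hops,
            verdict=verdict,
            stop_step=self.stop_step,
            aux_energies=aux,
            uq=np.abs(aux - energies) if aux is not None else None,
            message=self.message,
        )
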