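"""Observables from trajectory-swarm ensembles.

Populations are trajectory counts per state with 95% normal-approximation
binomial bands; ground-state rises are fit with P(t) = A (1 - exp(-t/tau));
quantum yields are reactive-trajectory fractions with the binomial
normal-approximation interval; geometry classifiers cover the methylene
dihedral scheme for fulvene-like hops and the C-N-N-C dihedral bins used
for azobenzene-like photoisomerization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PopulationCurve",
    "DecayFit",
    "YieldEstimate",
    "populations",
    "fit_decay",
    "quantum_yield",
    "mean_methylene_dihedral",
    "classify_fulvene_hop",
    "classify_azobenzene",
    "dihedral_angle",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class PopulationCurve:
    times: np.ndarray            # (T,)
    fractions: np.ndarray        # (T, n_states), rows sum to 1
    half_width: np.ndarray       # (T, n_states) 95% binomial half-widths
    n_traj: int

    def state(self, s: int) -> np.ndarray:
        return self.fractions[:, s]


@dataclass
class DecayFit:
    amplitude: float             # A, infinite-time population limit
    tau: float                   # timescale, units of the input time grid
    amplitude_stderr: float
    tau_stderr: float
    residual_norm: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("fitted tau must be positive")


@dataclass
class YieldEstimate:
    phi: float
    n_reactive: int
    n_traj: int
    half_width: float

    @property
    def rounded(self) -> str:
        return f"{self.phi:.2f} +- {self.half_width:.2f}"


def populations(trajectories: Sequence, time_grid: np.ndarray) -> PopulationCurve:
    """Per-state occupation fractions over an ensemble.

    All trajectories must share the time step; the state at each grid time
    is the last recorded step at or before it (no interpolation).
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("empty trajectory ensemble")
    dts = {round(t.dt, 12) for t in trajectories}
    if len(dts) > 1:
        raise ValueError(f"trajectories have differing time steps: {dts}")
    grid = np.asarray(time_grid, dtype=float)
    n_states = max(t.energies.shape[1] for t in trajectories)
    n = len(trajectories)
    counts = np.zeros((len(grid), n_states))
    for t in trajectories:
        states = t.state_at_times(grid)
        counts[np.arange(len(grid)), states] += 1
    frac = counts / n
    half = Z95 * np.sqrt(frac * (1.0 - frac) / n)
    return PopulationCurve(times=grid, fractions=frac, half_width=half, n_traj=n)


def fit_decay(times: np.ndarray, occupation: np.ndarray,
              a0: Optional[float] = None, tau0: Optional[float] = None) -> DecayFit:
    """Fit P(t) = A (1 - exp(-t / tau)) to a ground-state population rise.

    Starting values default to A0 = final occupation, tau0 = time at which
    the curve first reaches A0/2.  Standard errors come from the fit
    covariance.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(occupation, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    if a0 is None:
        a0 = max(float(p[-1]), 1e-6)
    if tau0 is None:
        above = np.nonzero(p >= 0.5 * a0)[0]
        tau0 = float(t[above[0]]) if len(above) and t[above[0]] > 0 else \
            float(t[-1]) / 3.0

    def model(tt, a, tau):
        return a * (1.0 - np.exp(-tt / tau))

    try:
        popt, pcov = curve_fit(
            model, t, p, p0=(a0, tau0),
            bounds=((0.0, 1e-12), (1.5, np.inf)), maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"decay fit failed to converge (A0={a0:.3g}, tau0={tau0:.3g}): {exc}"
        ) from exc
    perr = np.sqrt(np.diag(pcov))
    resid = p - model(t, *popt)
    return DecayFit(
        amplitude=float(popt[0]), tau=float(popt[1]),
        amplitude_stderr=float(perr[0]), tau_stderr=float(perr[1]),
        residual_norm=float(np.linalg.norm(resid)),
    )


def quantum_yield(reactive_flags: Sequence[bool]) -> YieldEstimate:
    """Phi = N_reactive / N_traj with the 95% normal-approximation interval."""
    flags = np.asarray(reactive_flags, dtype=bool)
    n = len(flags)
    if n < 1:
        raise ValueError("need at least one trajectory")
    n_reactive = int(flags.sum())
    phi = n_reactive / n
    half = Z95 * np.sqrt(phi * (1.0 - phi) / n)
    return YieldEstimate(phi=phi, n_reactive=n_reactive, n_traj=n,
                         half_width=float(half))


def mean_methylene_dihedral(dihedrals_deg: Sequence[float]) -> float:
    """Mean absolute methylene dihedral: quarter-sum of |cis1|, |cis2|,
    |trans1|, |trans2| (degrees)."""
    d = np.asarray(dihedrals_deg, dtype=float)
    if d.shape != (4,):
        raise ValueError("expected exactly four signed dihedrals")
    return float(np.abs(d).mean())


def classify_fulvene_hop(phi_deg: float, bond_angstrom: float) -> str:
    """Hop-geometry class from the mean methylene dihedral and the C=CH2
    bond length: ``planar`` (phi < 30 deg), else ``twisted-stretched``
    (bond > 1.55 A) or ``twisted-shrunk``.  Boundary values go to the
    lower-named class (planar / twisted-shrunk)."""
    if not (np.isfinite(phi_deg) and np.isfinite(bond_angstrom)):
        raise ValueError("inputs must be finite")
    if phi_deg <= 30.0:
        return "planar"
    if bond_angstrom > 1.55:
        return "twisted-stretched"
    return "twisted-shrunk"


def classify_azobenzene(dihedral_deg: float, scheme: str = "yield") -> str:
    """Isomer label from the absolute C-N-N-C dihedral (degrees, 0..180).

    ``yield`` scheme: cis below 60 deg, trans otherwise.  ``three-bin``
    scheme: cis below 40, intermediate 40-140, trans above 140.  Boundary
    values go to the lower-named bin (cis / intermediate).
    """
    d = abs(float(dihedral_deg))
    if not 0.0 <= d <= 180.0:
        raise ValueError("absolute dihedral must lie in [0, 180] degrees")
    if scheme == "yield":
        return "cis" if d <= 60.0 else "trans"
    if scheme == "three-bin":
        if d <= 40.0:
            return "cis"
        if d <= 140.0:
            return "intermediate"
        return "trans"
    raise ValueError(f"unknown scheme {scheme!r}")


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang != -180.0 else 180.0)
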