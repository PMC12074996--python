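"""Harmonic-oscillator Wigner sampling of initial conditions.

Positions and momenta are drawn from the ground-vibrational-state (T = 0)
Wigner distribution of each normal mode: in mass-weighted atomic units,
Q ~ N(0, hbar/(2 omega)) and P ~ N(0, hbar omega / 2), independently per
mode.  Frequencies below a floor (default 100 cm^-1) are raised to the
floor so that soft modes do not produce unphysically distorted samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .units import HARTREE_IN_EV, INVCM_TO_AU

__all__ = [
    "NormalModeData",
    "InitialCondition",
    "wigner_sample",
    "filter_excitation_window",
]


@dataclass
class NormalModeData:
    """Equilibrium geometry, masses and mass-weighted normal modes."""

    coords_ref: np.ndarray       # (n_atoms, 3) Bohr
    masses: np.ndarray           # (n_atoms,) electron-mass units
    freqs_cm1: np.ndarray        # (n_modes,) cm^-1, real
    modes: np.ndarray            # (3*n_atoms, n_modes) mass-weighted, orthonormal
    elements: Optional[list] = None

    def __post_init__(self):
        self.coords_ref = np.asarray(self.coords_ref, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.freqs_cm1 = np.asarray(self.freqs_cm1, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        gram = self.modes.T @ self.modes
        if not np.allclose(gram, np.eye(self.modes.shape[1]), atol=1e-8):
            raise ValueError("mode vectors are not orthonormal to 1e-8")
        if np.any(self.freqs_cm1 < 0) or np.iscomplexobj(self.freqs_cm1):
            raise ValueError("imaginary/negative frequencies must be handled upstream")

    @property
    def n_atoms(self) -> int:
        return self.coords_ref.shape[0]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def save(self, path) -> None:
        np.savez(
            path,
            coords_ref=self.coords_ref,
            masses=self.masses,
            freqs_cm1=self.freqs_cm1,
            modes=self.modes,
            elements=np.asarray(self.elements or [], dtype="U4"),
        )

    @classmethod
    def load(cls, path) -> "NormalModeData":
        with np.load(path) as d:
            elements = [str(e) for e in d["elements"]] or None
            return cls(d["coords_ref"], d["masses"], d["freqs_cm1"],
                       d["modes"], elements)


@dataclass
class InitialCondition:
    coords: np.ndarray       # (n_atoms, 3) Bohr
    velocities: np.ndarray   # (n_atoms, 3) Bohr / a.t.u.
    state: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.coords.shape != self.velocities.shape:
            raise ValueError("coords / velocities shape mismatch")
        if not (np.all(np.isfinite(self.coords))
                and np.all(np.isfinite(self.velocities))):
            raise ValueError("non-finite initial condition")


def wigner_sample(
    modes: NormalModeData,
    n: int,
    seed: int,
    frequency_floor: float = 100.0,
    remove_com_motion: bool = False,
) -> List[InitialCondition]:
    """Draw ``n`` ground-state Wigner samples (positions and velocities).

    ``frequency_floor`` is in cm^-1; all mode frequencies below it are set
    to the floor before sampling.  With ``remove_com_motion`` the total
    linear momentum of each sample is projected out.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if frequency_floor <= 0:
        raise ValueError("frequency_floor must be positive")

    rng = np.random.default_rng(seed)
    omega = np.maximum(modes.freqs_cm1, frequency_floor) * INVCM_TO_AU
    sqrt_m = np.sqrt(np.repeat(modes.masses, 3))

    sigma_q = np.sqrt(0.5 / omega)
    sigma_p = np.sqrt(0.5 * omega)
    out = []
    for _ in range(n):
        q = sigma_q * rng.standard_normal(modes.n_modes)
        p = sigma_p * rng.standard_normal(modes.n_modes)
        dx = (modes.modes @ q) / sqrt_m
        v = (modes.modes @ p) / sqrt_m
        coords = modes.coords_ref + dx.reshape(-1, 3)
        vel = v.reshape(-1, 3)
        if remove_com_motion:
            mom = modes.masses[:, None] * vel
            vel = vel - mom.sum(axis=0) / modes.masses.sum()
        out.append(InitialCondition(coords=coords, velocities=vel, state=0))
    return out


def filter_excitation_window(
    conditions: Sequence[InitialCondition],
    reference,
    from_state: int,
    to_state: int,
    center: float,
    half_width: float,
) -> List[InitialCondition]:
    """Keep conditions whose vertical ``from_state -> to_state`` gap (eV)
    lies within ``center +- half_width``; kept conditions start on
    ``to_state``.

    ``reference`` is anything with an ``evaluate(coords)`` returning
    per-state energies (oracle or ML potential), or a callable returning an
    energy array directly.
    """
    if center <= 0 or half_width <= 0:
        raise ValueError("center and half_width must be positive")
    kept = []
    for i, cond in enumerate(conditions):
        try:
            if hasattr(reference, "evaluate"):
                energies = reference.evaluate(cond.coords).energies
            else:
                energies = np.asarray(reference(cond.coords))
        except Exception as exc:
            raise RuntimeError(f"evaluator failed for condition {i}: {exc}") from exc
        gap_ev = (energies[to_state] - energies[from_state]) * HARTREE_IN_EV
        if center - half_width <= gap_ev <= center + half_width:
            kept.append(
                InitialCondition(
                    coords=cond.coords.copy(),
                    velocities=cond.velocities.copy(),
                    state=to_state,
                )
            )
    return kept
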