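"""Analytic multi-state diabatic model Hamiltonians.

These linear-vibronic-coupling (LVC) style models play the role of the
"reference electronic-structure method": they provide exact multi-state
energies and analytic energy gradients at any geometry, cheaply enough to
label thousands of points, and their avoided crossings / conical
intersections give surface-hopping dynamics something to hop through.

The diabatic matrix, in terms of the displacement Dx = x - x_ref (Bohr), is

    H_kk(Dx) = E0_k + g_k . Dx + 1/2 Dx^T K_k Dx
    H_kl(Dx) = c_kl + lam_kl . Dx          (k != l)

with symmetric positive semi-definite force-constant matrices K_k and a
symmetric coupling block.  Adiabatic states are the ascending eigenvalues of
H; gradients follow from the Hellmann-Feynman (eigenvector sandwich) rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .training_data import TrainingRecord, TrainingSet
from .units import masses_au

logger = logging.getLogger(__name__)

__all__ = [
    "DiabaticModel",
    "AdiabaticResult",
    "make_lvc_model",
    "eval_adiabatic",
    "generate_labeled_set",
    "normal_mode_data",
]

#: eigenvalues closer than this (Hartree) are treated as degenerate when
#: assembling gradients
DEGENERACY_TOL = 1e-12


@dataclass
class AdiabaticResult:
    """Per-geometry adiabatic energies, gradients and adjacent-state gaps.

    ``energies``   (n_states,)            total state energies, Hartree
    ``gradients``  (n_states, n_atoms, 3) dE/dx, Hartree/Bohr
    ``gaps``       (n_states - 1,)        energies[k+1] - energies[k]
    """

    energies: np.ndarray
    gradients: np.ndarray
    gaps: np.ndarray

    @property
    def forces(self) -> np.ndarray:
        return -self.gradients


@dataclass
class DiabaticModel:
    """LVC-style diabatic model Hamiltonian for ``n_atoms`` atoms and
    ``n_states`` electronic states."""

    ref_coords: np.ndarray          # (n_atoms, 3) Bohr
    elements: list
    e0: np.ndarray                  # (S,) vertical offsets, strictly increasing
    g: np.ndarray                   # (S, 3N) linear shifts
    k: np.ndarray                   # (S, 3N, 3N) force constants, sym. PSD
    c: np.ndarray                   # (S, S) constant couplings, symmetric
    lam: np.ndarray                 # (S, S, 3N) linear couplings, symmetric
    seed: int = 0
    remove_translation: bool = False
    _proj: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return self.ref_coords.shape[0]

    @property
    def n_states(self) -> int:
        return self.e0.shape[0]

    def __post_init__(self):
        self.ref_coords = np.asarray(self.ref_coords, dtype=float)
        if self.remove_translation and self._proj is None:
            n3 = 3 * self.n_atoms
            # projector onto the complement of the three uniform translations
            t = np.zeros((n3, 3))
            for a in range(3):
                t[a::3, a] = 1.0
            t /= np.sqrt(self.n_atoms)
            self._proj = np.eye(n3) - t @ t.T

    # -- evaluation -------------------------------------------------------

    def displacement(self, coords: np.ndarray) -> np.ndarray:
        dx = (np.asarray(coords, dtype=float) - self.ref_coords).ravel()
        if self.remove_translation:
            dx = self._proj @ dx
        return dx

    def hamiltonian(self, coords: np.ndarray) -> np.ndarray:
        """Diabatic matrix at ``coords`` (n_atoms, 3)."""
        dx = self.displacement(coords)
        h = self.c + self.lam @ dx
        diag = self.e0 + self.g @ dx + 0.5 * np.einsum("i,sij,j->s", dx, self.k, dx)
        h[np.diag_indices_from(h)] = diag
        return h

    def evaluate(self, coords: np.ndarray) -> AdiabaticResult:
        return eval_adiabatic(self, coords)

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Write the model to a single ``.npz`` container."""
        np.savez(
            path,
            ref_coords=self.ref_coords,
            elements=np.asarray(self.elements, dtype="U4"),
            e0=self.e0,
            g=self.g,
            k=self.k,
            c=self.c,
            lam=self.lam,
            meta=np.frombuffer(
                json.dumps(
                    {"seed": int(self.seed),
                     "remove_translation": bool(self.remove_translation)}
                ).encode(),
                dtype=np.uint8,
            ),
        )

    @classmethod
    def load(cls, path) -> "DiabaticModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            return cls(
                ref_coords=data["ref_coords"],
                elements=[str(e) for e in data["elements"]],
                e0=data["e0"],
                g=data["g"],
                k=data["k"],
                c=data["c"],
                lam=data["lam"],
                seed=meta["seed"],
                remove_translation=meta["remove_translation"],
            )


def make_lvc_model(
    n_atoms: int,
    n_states: int,
    seed: int,
    *,
    coupling_scale: float = 0.01,
    linear_coupling_scale: float = 0.005,
    gap_scale: float = 0.08,
    stiffness_scale: float = 1.0,
    shift_scale: float = 0.01,
    crossing_range: float = 1.5,
    ensure_crossing: bool = True,
    remove_translation: bool = False,
) -> DiabaticModel:
    """Build a reproducible random LVC model.

    The first two diabats are constructed to cross along the softest normal
    coordinate of the ground-state diabat within ``+-crossing_range`` Bohr of
    the reference geometry, so every model has at least one reachable avoided
    crossing (a conical-intersection seam once couplings are switched on).

    ``coupling_scale`` (Hartree) and ``linear_coupling_scale`` (Hartree/Bohr)
    control the off-diagonal block; ``gap_scale`` sets the typical vertical
    spacing between states; ``stiffness_scale`` multiplies all force
    constants.
    """
    if n_atoms < 1:
        raise ValueError(f"n_atoms must be >= 1, got {n_atoms}")
    if n_states < 2:
        raise ValueError(f"n_states must be >= 2, got {n_states}")

    rng = np.random.default_rng(seed)
    n3 = 3 * n_atoms

    # reference geometry: loose chain along z with some jitter
    ref = np.zeros((n_atoms, 3))
    ref[:, 2] = 2.2 * np.arange(n_atoms)
    ref += 0.15 * rng.standard_normal((n_atoms, 3))
    element_cycle = ["C", "H", "O", "N"]
    elements = [element_cycle[i % len(element_cycle)] for i in range(n_atoms)]
    masses = np.repeat(masses_au(elements), 3)

    # force constants: shared mass-weighted eigenvectors with per-state
    # frequency spectra (PSD by construction); K = M^1/2 Q w^2 Q^T M^1/2 so
    # the mass-weighted Hessian has exactly the drawn frequencies
    # (~200-900 cm^-1)
    q, _ = np.linalg.qr(rng.standard_normal((n3, n3)))
    sqrt_m = np.sqrt(masses)
    k = np.empty((n_states, n3, n3))
    omega0 = None
    for s in range(n_states):
        freqs = rng.uniform(1.0e-3, 4.0e-3, size=n3)  # a.u. angular frequency
        kmw = (q * (stiffness_scale * freqs**2)) @ q.T
        k[s] = sqrt_m[:, None] * kmw * sqrt_m[None, :]
        k[s] = 0.5 * (k[s] + k[s].T)
        if s == 0:
            omega0 = freqs

    # vertical offsets: strictly increasing with jittered spacing gap_scale
    spacings = gap_scale * rng.uniform(0.7, 1.3, size=n_states - 1)
    e0 = np.concatenate([[0.0], np.cumsum(spacings)])

    # linear shifts via displaced minima: g_s = -K_s dx*_s keeps every
    # diabat's minimum within ~shift_scale-size excursions of the reference
    min_disp = 20.0 * shift_scale * rng.standard_normal((n_states, n3)) / np.sqrt(n3)
    min_disp[0] *= 0.3  # reference geometry sits near the ground-diabat minimum
    g = -np.einsum("sij,sj->si", k, min_disp)

    if ensure_crossing:
        # Engineer a diabat-0/1 crossing along one normal-mode direction u,
        # at t* Bohr from the reference, low enough on diabat 0 to be
        # reachable after vertical excitation to state 1.  The direction is
        # the mode whose Cartesian stiffness is closest to a moderate target
        # so neither the crossing energy nor the upper-diabat tilt explodes.
        u_all = q / sqrt_m[:, None]
        u_all /= np.linalg.norm(u_all, axis=0)
        k_u = np.einsum("ij,jk,ki->i", u_all.T, k[0], u_all)
        target = 0.05 * stiffness_scale
        j_dir = int(np.argmin(np.abs(k_u - target)))
        u = u_all[:, j_dir]
        t_star = 0.7 * crossing_range
        d_k = float(u @ (k[1] - k[0]) @ u)
        # d1(t)-d0(t) = (e0_1-e0_0) + t dg + t^2/2 d_k  ==  0 at t = t_star
        dg = -((e0[1] - e0[0]) + 0.5 * t_star**2 * d_k) / t_star
        g[1] = g[1] - (g[1] @ u) * u + ((g[0] @ u) + dg) * u
        # verification scan: the two diabats must cross within the range
        t = np.linspace(-crossing_range, crossing_range, 201)
        diff = (
            (e0[0] + t * (g[0] @ u) + 0.5 * t**2 * (u @ k[0] @ u))
            - (e0[1] + t * (g[1] @ u) + 0.5 * t**2 * (u @ k[1] @ u))
        )
        if not np.any(np.sign(diff[:-1]) != np.sign(diff[1:])):  # pragma: no cover
            raise RuntimeError("failed to construct a diabat crossing")

    # couplings: symmetric, zero diagonal
    c = coupling_scale * rng.standard_normal((n_states, n_states))
    c = 0.5 * (c + c.T)
    np.fill_diagonal(c, 0.0)
    lam = linear_coupling_scale * rng.standard_normal((n_states, n_states, n3))
    lam = 0.5 * (lam + lam.transpose(1, 0, 2))
    for s in range(n_states):
        lam[s, s] = 0.0

    return DiabaticModel(
        ref_coords=ref,
        elements=elements,
        e0=e0,
        g=g,
        k=k,
        c=c,
        lam=lam,
        seed=seed,
        remove_translation=remove_translation,
    )


def eval_adiabatic(model: DiabaticModel, coords: np.ndarray) -> AdiabaticResult:
    """Adiabatic energies, analytic gradients and adjacent gaps at ``coords``.

    Energies are the ascending eigenvalues of the diabatic matrix; gradients
    use the Hellmann-Feynman rule dE_s/dx = v_s^T (dH/dx) v_s.  Within a
    degenerate block the gradients are replaced by the symmetrized subspace
    average (and a warning is logged); trajectories never evaluate exactly at
    a degeneracy in practice.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != model.ref_coords.shape:
        raise ValueError(
            f"coords shape {coords.shape} does not match model "
            f"{model.ref_coords.shape}"
        )
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords contain non-finite values")

    h = model.hamiltonian(coords)
    energies, vecs = np.linalg.eigh(h)  # ascending, stable for symmetric input

    dx = model.displacement(coords)
    s_n = model.n_states
    n3 = dx.shape[0]
    # dH/dx_i as (S, S, 3N): diagonal from g_k + K_k dx, off-diagonal lam
    dh = model.lam.copy()
    diag = model.g + np.einsum("sij,j->si", model.k, dx)
    dh[np.arange(s_n), np.arange(s_n), :] = diag
    if model.remove_translation:
        dh = dh @ model._proj

    # sandwich rule, vectorized: grad[s, i] = sum_ab V[a,s] V[b,s] dh[a,b,i]
    grads = np.einsum("as,bs,abi->si", vecs, vecs, dh)

    # degenerate blocks: average the diagonal sandwich over the block
    start = 0
    for end in range(1, s_n + 1):
        if end == s_n or energies[end] - energies[end - 1] > DEGENERACY_TOL:
            if end - start > 1:
                logger.warning(
                    "degenerate eigenvalues (states %d..%d); using subspace-"
                    "averaged gradients", start, end - 1,
                )
                grads[start:end] = grads[start:end].mean(axis=0)
            start = end

    grads = grads.reshape(s_n, model.n_atoms, 3)
    return AdiabaticResult(
        energies=energies, gradients=grads, gaps=np.diff(energies)
    )


def generate_labeled_set(model: DiabaticModel, geometries) -> TrainingSet:
    """Label a list of geometries with the model's energies and forces."""
    geometries = list(geometries)
    if not geometries:
        raise ValueError("geometries list is empty")
    records = []
    for i, coords in enumerate(geometries):
        try:
            res = eval_adiabatic(model, coords)
        except ValueError as exc:
            raise ValueError(f"labeling failed for geometry {i}: {exc}") from exc
        records.append(
            TrainingRecord(
                coords=np.asarray(coords, dtype=float),
                elements=list(model.elements),
                energies=res.energies.copy(),
                forces=res.forces.copy(),
            )
        )
    return TrainingSet(records)


def normal_mode_data(model: DiabaticModel, state: int = 0):
    """Harmonic normal modes of one diabatic surface at the reference geometry.

    Returns an ``initial_conditions.NormalModeData`` built from the
    mass-weighted force-constant matrix of diabat ``state``.  Frequencies are
    returned for every mode with a positive eigenvalue; non-positive
    eigenvalues (possible only with translation-projected models) are dropped.
    """
    from .initial_conditions import NormalModeData
    from .units import HARTREE_IN_INVCM

    masses = np.repeat(masses_au(model.elements), 3)
    mw = model.k[state] / np.sqrt(np.outer(masses, masses))
    w2, modes = np.linalg.eigh(mw)
    keep = w2 > 1e-12
    freqs_cm1 = np.sqrt(w2[keep]) * HARTREE_IN_INVCM
    return NormalModeData(
        coords_ref=model.ref_coords.copy(),
        masses=np.asarray(masses_au(model.elements)),
        freqs_cm1=freqs_cm1,
        modes=modes[:, keep],
        elements=list(model.elements),
    )
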