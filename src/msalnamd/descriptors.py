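"""Atom-centered descriptors and their coordinate Jacobians.

Two backends sit behind the same interface:

* :class:`DescriptorConfig` — ANI-type symmetry functions (radial Gaussian
  shells per neighbor element, angular shells per element pair), invariant
  to global rotation/translation and to permutation of same-element atoms.
* :class:`DisplacementConfig` — the flattened displacement from a reference
  geometry, exposed as one "SYS" site for the whole system.  Analytic model
  Hamiltonians are defined in a laboratory frame, which no invariant
  descriptor can resolve, so lab-frame potentials are learned with this
  backend.

Both produce per-site descriptor vectors plus (optionally) the Jacobian
d(descriptor)/d(Cartesian coordinate in Bohr) needed for force predictions.
Distances entering the symmetry functions are measured in Angstrom, matching
the conventional parameterization; coordinates everywhere else are Bohr.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .units import BOHR_IN_ANGSTROM

__all__ = ["DescriptorConfig", "DisplacementConfig", "featurize"]


def _cutoff(r: float, rc: float) -> float:
    return 0.5 * np.cos(np.pi * r / rc) + 0.5 if r < rc else 0.0


def _cutoff_d(r: float, rc: float) -> float:
    return -0.5 * np.pi / rc * np.sin(np.pi * r / rc) if r < rc else 0.0


@dataclass
class DescriptorConfig:
    """ANI-type symmetry-function parameters (lengths in Angstrom)."""

    elements: Tuple[str, ...] = ("H", "C", "N", "O")
    radial_cutoff: float = 5.2
    angular_cutoff: float = 3.5
    radial_centers: Tuple[float, ...] = (0.9, 1.44, 1.98, 2.52, 3.06, 3.6, 4.14, 4.68)
    radial_eta: float = 4.0
    angular_centers: Tuple[float, ...] = (0.9, 2.2)
    angular_eta: float = 4.0
    theta_centers: Tuple[float, ...] = (0.3927, 1.1781, 1.9635, 2.7489)
    zeta: float = 8.0

    def __post_init__(self):
        if self.radial_cutoff <= 0 or self.angular_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.angular_cutoff > self.radial_cutoff:
            raise ValueError("angular cutoff must not exceed radial cutoff")
        if max(self.radial_centers) >= self.radial_cutoff:
            raise ValueError("radial shell centers must lie within the cutoff")
        if max(self.angular_centers) >= self.angular_cutoff:
            raise ValueError("angular shell centers must lie within the cutoff")

    @property
    def element_pairs(self) -> List[Tuple[str, str]]:
        e = self.elements
        return [(e[i], e[j]) for i in range(len(e)) for j in range(i, len(e))]

    @property
    def dim(self) -> int:
        n_e = len(self.elements)
        n_rad = n_e * len(self.radial_centers)
        n_ang = len(self.element_pairs) * len(self.theta_centers) * len(
            self.angular_centers
        )
        return n_rad + n_ang

    def site_elements(self, elements: Sequence[str]) -> List[str]:
        for e in elements:
            if e not in self.elements:
                raise ValueError(f"element {e!r} not in supported set {self.elements}")
        return list(elements)

    # -- evaluation -------------------------------------------------------

    def featurize(self, coords_bohr: np.ndarray, elements: Sequence[str]):
        return self._eval(coords_bohr, elements, jacobian=False)[0]

    def featurize_with_jacobian(self, coords_bohr, elements):
        return self._eval(coords_bohr, elements, jacobian=True)

    def _eval(self, coords_bohr, elements, jacobian: bool):
        self.site_elements(elements)
        coords = np.asarray(coords_bohr, dtype=float) * BOHR_IN_ANGSTROM
        n = coords.shape[0]
        dim = self.dim
        desc = np.zeros((n, dim))
        jac = np.zeros((n, dim, n, 3)) if jacobian else None
        # chain factor Angstrom/Bohr for Jacobians w.r.t. Bohr coordinates
        chain = BOHR_IN_ANGSTROM

        e_index = {e: k for k, e in enumerate(self.elements)}
        n_rs = len(self.radial_centers)
        pair_index = {}
        for p, (a, b) in enumerate(self.element_pairs):
            pair_index[(a, b)] = p
            pair_index[(b, a)] = p
        ang_base = len(self.elements) * n_rs
        n_ts, n_as = len(self.theta_centers), len(self.angular_centers)

        # radial part
        for i in range(n):
            for j in range(n):
                if j == i:
                    continue
                rij_vec = coords[j] - coords[i]
                r = float(np.linalg.norm(rij_vec))
                if r >= self.radial_cutoff:
                    continue
                fc = _cutoff(r, self.radial_cutoff)
                base = e_index[elements[j]] * n_rs
                for s, rs in enumerate(self.radial_centers):
                    g = np.exp(-self.radial_eta * (r - rs) ** 2)
                    desc[i, base + s] += g * fc
                    if jacobian:
                        dgdr = (
                            -2.0 * self.radial_eta * (r - rs) * g * fc
                            + g * _cutoff_d(r, self.radial_cutoff)
                        )
                        drdxj = rij_vec / r
                        jac[i, base + s, j] += dgdr * drdxj * chain
                        jac[i, base + s, i] -= dgdr * drdxj * chain

        # angular part
        two_pref = 2.0 ** (1.0 - self.zeta)
        for i in range(n):
            for j in range(n):
                if j == i:
                    continue
                u = coords[j] - coords[i]
                rij = float(np.linalg.norm(u))
                if rij >= self.angular_cutoff:
                    continue
                for k in range(j + 1, n):
                    if k == i:
                        continue
                    v = coords[k] - coords[i]
                    rik = float(np.linalg.norm(v))
                    if rik >= self.angular_cutoff:
                        continue
                    fcj = _cutoff(rij, self.angular_cutoff)
                    fck = _cutoff(rik, self.angular_cutoff)
                    cos_t = float(u @ v) / (rij * rik)
                    # 0.95 factor removes the arccos singularity at +-1
                    ct = 0.95 * cos_t
                    theta = np.arccos(ct)
                    ravg = 0.5 * (rij + rik)
                    p = pair_index[(elements[j], elements[k])]
                    for ts, t0 in enumerate(self.theta_centers):
                        afac = (1.0 + np.cos(theta - t0)) ** self.zeta
                        dafac_dtheta = (
                            -self.zeta
                            * (1.0 + np.cos(theta - t0)) ** (self.zeta - 1.0)
                            * np.sin(theta - t0)
                        )
                        for rs, r0 in enumerate(self.angular_centers):
                            gfac = np.exp(-self.angular_eta * (ravg - r0) ** 2)
                            idx = ang_base + (p * n_ts + ts) * n_as + rs
                            val = two_pref * afac * gfac * fcj * fck
                            desc[i, idx] += val
                            if not jacobian:
                                continue
                            # d/d r_ij and d/d r_ik (through gfac and cutoffs)
                            dgdravg = -2.0 * self.angular_eta * (ravg - r0) * gfac
                            d_rij = two_pref * afac * (
                                0.5 * dgdravg * fcj * fck
                                + gfac * _cutoff_d(rij, self.angular_cutoff) * fck
                            )
                            d_rik = two_pref * afac * (
                                0.5 * dgdravg * fcj * fck
                                + gfac * fcj * _cutoff_d(rik, self.angular_cutoff)
                            )
                            # d/d cos_t through theta = arccos(0.95 cos_t)
                            dtheta_dcos = -0.95 / np.sqrt(1.0 - ct * ct)
                            d_cos = (
                                two_pref
                                * dafac_dtheta
                                * dtheta_dcos
                                * gfac
                                * fcj
                                * fck
                            )
                            # geometry chain rules
                            drij_du = u / rij
                            drik_dv = v / rik
                            dcos_du = v / (rij * rik) - cos_t * u / rij**2
                            dcos_dv = u / (rij * rik) - cos_t * v / rik**2
                            gj = d_rij * drij_du + d_cos * dcos_du
                            gk = d_rik * drik_dv + d_cos * dcos_dv
                            jac[i, idx, j] += gj * chain
                            jac[i, idx, k] += gk * chain
                            jac[i, idx, i] -= (gj + gk) * chain
        return desc, jac


@dataclass
class DisplacementConfig:
    """Flattened displacement from a reference geometry as one system site.

    ``scale`` (Bohr) normalizes the feature magnitude.  The Jacobian is a
    constant: identity / scale.
    """

    ref_coords: np.ndarray
    scale: float = 1.0
    elements: Tuple[str, ...] = ("SYS",)

    def __post_init__(self):
        self.ref_coords = np.asarray(self.ref_coords, dtype=float)
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def dim(self) -> int:
        return self.ref_coords.size

    def site_elements(self, elements: Sequence[str]) -> List[str]:
        return ["SYS"]

    def featurize(self, coords_bohr, elements):
        coords = np.asarray(coords_bohr, dtype=float)
        if coords.shape != self.ref_coords.shape:
            raise ValueError(
                f"coords shape {coords.shape} does not match reference "
                f"{self.ref_coords.shape}"
            )
        return ((coords - self.ref_coords).ravel() / self.scale)[None, :]

    def featurize_with_jacobian(self, coords_bohr, elements):
        desc = self.featurize(coords_bohr, elements)
        n = self.ref_coords.shape[0]
        jac = (np.eye(3 * n) / self.scale).reshape(1, 3 * n, n, 3)
        return desc, jac


def featurize(coords, elements, config) -> np.ndarray:
    """Per-site descriptor vectors for a geometry (Bohr)."""
    return config.featurize(coords, elements)
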