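"""Unit conversions.

Everything inside the package works in Hartree atomic units (Hartree, Bohr,
electron mass, atomic time unit, hbar = 1).  Angstrom, eV, fs, cm^-1 and amu
appear only at I/O boundaries.
"""

from __future__ import annotations

# CODATA-2018 values
BOHR_IN_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_IN_ANGSTROM
HARTREE_IN_EV = 27.211386245988
EV_TO_HARTREE = 1.0 / HARTREE_IN_EV
AU_TIME_IN_FS = 0.02418884326509  # one atomic time unit in femtoseconds
FS_TO_AU_TIME = 1.0 / AU_TIME_IN_FS
HARTREE_IN_INVCM = 219474.6313632  # Hartree expressed in cm^-1
INVCM_TO_AU = 1.0 / HARTREE_IN_INVCM  # cm^-1 -> angular frequency in a.u.
AMU_TO_AU_MASS = 1822.888486209

#: Standard atomic weights (amu) for the elements the toy models use.
ATOMIC_MASS_AMU = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "S": 32.06,
    # "X" labels a virtual / model site (unit amu mass)
    "X": 1.0,
    # "SYS" labels the single whole-system site of the displacement descriptor
    "SYS": 1.0,
}


def masses_au(elements) -> "list[float]":
    """Atomic masses in electron-mass units for a list of element symbols."""
    try:
        return [ATOMIC_MASS_AMU[e] * AMU_TO_AU_MASS for e in elements]
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"no mass tabulated for element {exc.args[0]!r}") from None
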