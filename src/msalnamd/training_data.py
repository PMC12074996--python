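"""Labeled multi-state training data.

A :class:`TrainingSet` is an ordered collection of records, each carrying a
geometry (Bohr), element labels, per-state energies (Hartree, ascending for
reference labels) and optionally per-state forces (Hartree/Bohr).  Records
may carry different numbers of states, which is what lets one model train on
mixed 2-state / 4-state data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, List, Optional

import numpy as np

__all__ = ["TrainingRecord", "TrainingSet"]


@dataclass
class TrainingRecord:
    coords: np.ndarray                 # (n_atoms, 3) Bohr
    elements: list
    energies: np.ndarray               # (n_states,) Hartree
    forces: Optional[np.ndarray] = None  # (n_states, n_atoms, 3) Hartree/Bohr
    tag: Optional[str] = None          # sampling-criterion provenance

    @property
    def n_states(self) -> int:
        return len(self.energies)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            expect = (self.n_states,) + self.coords.shape
            if self.forces.shape != expect:
                raise ValueError(
                    f"forces shape {self.forces.shape}, expected {expect}"
                )


@dataclass
class TrainingSet:
    records: List[TrainingRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return TrainingSet(self.records[i])
        return self.records[i]

    def __iter__(self):
        return iter(self.records)

    def append(self, record: TrainingRecord) -> None:
        self.records.append(record)

    def extend(self, records: Iterable[TrainingRecord]) -> None:
        self.records.extend(records)

    @property
    def max_states(self) -> int:
        return max(r.n_states for r in self.records)

    def subset(self, indices) -> "TrainingSet":
        return TrainingSet([self.records[i] for i in indices])

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Single structured ``.npz`` container (documented schema).

        Ragged per-record shapes are stored flat with offsets: ``coords``
        concatenated over records, ``energies`` likewise, ``n_atoms`` /
        ``n_states`` per record, forces flat with a per-record presence flag.
        """
        coords = np.concatenate([r.coords.ravel() for r in self.records])
        energies = np.concatenate([r.energies for r in self.records])
        n_atoms = np.array([r.coords.shape[0] for r in self.records])
        n_states = np.array([r.n_states for r in self.records])
        has_forces = np.array([r.forces is not None for r in self.records])
        forces = (
            np.concatenate(
                [r.forces.ravel() for r in self.records if r.forces is not None]
            )
            if has_forces.any()
            else np.zeros(0)
        )
        elements = json.dumps([list(r.elements) for r in self.records])
        tags = json.dumps([r.tag for r in self.records])
        np.savez(
            path,
            coords=coords,
            energies=energies,
            forces=forces,
            n_atoms=n_atoms,
            n_states=n_states,
            has_forces=has_forces,
            elements=np.frombuffer(elements.encode(), dtype=np.uint8),
            tags=np.frombuffer(tags.encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "TrainingSet":
        with np.load(path) as d:
            elements = json.loads(bytes(d["elements"]).decode())
            tags = json.loads(bytes(d["tags"]).decode())
            records = []
            c_off = e_off = f_off = 0
            for i in range(len(d["n_atoms"])):
                na, ns = int(d["n_atoms"][i]), int(d["n_states"][i])
                coords = d["coords"][c_off : c_off + 3 * na].reshape(na, 3)
                c_off += 3 * na
                energies = d["energies"][e_off : e_off + ns]
                e_off += ns
                forces = None
                if d["has_forces"][i]:
                    forces = d["forces"][f_off : f_off + ns * 3 * na].reshape(
                        ns, na, 3
                    )
                    f_off += ns * 3 * na
                records.append(
                    TrainingRecord(coords, elements[i], energies, forces, tags[i])
                )
        return cls(records)
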