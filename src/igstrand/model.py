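"""Internal atomic model: atoms, residues, chains, structures.

Coordinates are Cartesian, in Angstrom, throughout the package. Residues are
identified by the author key ``(chain_id, seq_num, icode)``; residue order
within a chain follows file order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: One-letter codes accepted for ``Residue.aa`` (X marks nonstandard residues).
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_HYDROGEN = {"H", "D"}

ResidueKey = tuple[str, int, str]


@dataclass
class AtomRecord:
    """A single atom: label, element and position (Angstrom)."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be 3 finite components")
        self.element = self.element.strip().upper()

    @property
    def is_heavy(self) -> bool:
        return self.element not in _HYDROGEN


@dataclass
class Residue:
    """An amino-acid residue with its atoms.

    ``aa`` is the one-letter code; nonstandard residues that still carry a CA
    atom are kept as ``X`` so structural numbering can pass through them.
    """

    chain_id: str
    seq_num: int
    icode: str
    aa: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.aa not in STANDARD_AA and self.aa != "X":
            raise ValueError(f"residue aa must be a standard letter or X, got {self.aa!r}")

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def ca_trace(self) -> np.ndarray:
        """Cα coordinates of residues that have a CA atom, in chain order."""
        return np.array([r.ca.coord for r in self.residues if r.ca is not None])

    def ca_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.ca is not None]


@dataclass
class StructureModel:
    """A parsed structure: ordered chains of ordered residues."""

    id: str
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for chain in self.chains:
            for res in chain:
                if res.key in seen:
                    raise ValueError(f"duplicate residue key {res.key} in model {self.id!r}")
                seen.add(res.key)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in model {self.id!r}")

    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c

    def residue(self, key: ResidueKey) -> Residue:
        for c in self.chains:
            if c.chain_id != key[0]:
                continue
            for r in c:
                if r.key == key:
                    return r
        raise KeyError(f"no residue {key} in model {self.id!r}")
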