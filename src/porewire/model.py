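"""Core domain model: atoms, topologies and trajectory frames.

The package keeps a deliberately small in-memory model. A :class:`Topology`
is an immutable, ordered list of :class:`AtomRecord` plus the hydrogen →
parent connectivity needed for geometric hydrogen-bond detection; a
:class:`Frame` is one time-stamped coordinate set. Residue numbering is kept
1-based exactly as in the source PDB so that published residue numbers
(e.g. Glu908, Ser915 of the SERCA C-terminal pore) can be used verbatim in
configuration; all internal atom indices ("ordinals") are 0-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Role",
    "AtomRecord",
    "Topology",
    "Frame",
    "WATER_RESIDUE_NAMES",
    "FormatError",
    "SelectionError",
    "TopologyError",
    "TrajectoryError",
    "ConfigError",
    "GeometryError",
    "ScenarioError",
]

#: Residue-name dialects all normalised to one internal water flag.
WATER_RESIDUE_NAMES = frozenset({"HOH", "TIP3", "SOL", "WAT", "TIP3P", "SPC"})


class FormatError(ValueError):
    """A structure/trajectory file could not be parsed."""


class SelectionError(KeyError):
    """An atom/residue selection resolved to nothing (or ambiguously)."""


class TopologyError(ValueError):
    """Frame/topology mismatch (e.g. atom-count disagreement)."""


class TrajectoryError(ValueError):
    """Trajectory-level problem (e.g. zero frames)."""


class ConfigError(ValueError):
    """Invalid run configuration."""


class GeometryError(ValueError):
    """Degenerate geometric input (too few / collinear points)."""


class ScenarioError(ValueError):
    """Infeasible synthetic-scenario script."""


class Role(enum.Enum):
    """Hydrogen-bonding role of an atom, derived from a role table.

    Water oxygens can both donate and accept, hence ``donor_acceptor``.
    """

    donor = "donor"
    acceptor = "acceptor"
    donor_acceptor = "donor_acceptor"
    hydrogen = "hydrogen"
    other = "other"

    @property
    def can_donate(self) -> bool:
        return self in (Role.donor, Role.donor_acceptor)

    @property
    def can_accept(self) -> bool:
        return self in (Role.acceptor, Role.donor_acceptor)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership and H-bonding role."""

    ordinal: int
    name: str
    resname: str
    resid: int
    chain: str
    element: str
    role: Role


class Topology:
    """Ordered atom list plus hydrogen→parent connectivity.

    Parameters
    ----------
    atoms:
        Atom records; ``atoms[i].ordinal`` must equal ``i``.
    h_parent:
        Mapping hydrogen ordinal → bonded heavy-atom ordinal. Every atom
        whose role is :attr:`Role.hydrogen` must appear exactly once.
    """

    def __init__(self, atoms: Sequence[AtomRecord], h_parent: dict[int, int] | None = None):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        for i, a in enumerate(self.atoms):
            if a.ordinal != i:
                raise TopologyError(f"atom ordinal {a.ordinal} at position {i}")
        self.h_parent: dict[int, int] = dict(h_parent or {})
        for h in self._hydrogens():
            if h not in self.h_parent:
                raise TopologyError(f"hydrogen ordinal {h} has no recorded parent")
        # children: heavy ordinal -> tuple of attached hydrogen ordinals
        children: dict[int, list[int]] = {}
        for h, p in self.h_parent.items():
            children.setdefault(p, []).append(h)
        self.h_children: dict[int, tuple[int, ...]] = {
            p: tuple(sorted(hs)) for p, hs in children.items()
        }
        self._index: dict[tuple[str, int, str], int] = {}
        for a in self.atoms:
            key = (a.chain, a.resid, a.name)
            if key in self._index:
                raise TopologyError(
                    f"duplicate atom (chain={a.chain!r}, resid={a.resid}, name={a.name!r})"
                )
            self._index[key] = a.ordinal

    def _hydrogens(self) -> list[int]:
        return [a.ordinal for a in self.atoms if a.role is Role.hydrogen]

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def is_water(self, ordinal: int) -> bool:
        return self.atoms[ordinal].resname in WATER_RESIDUE_NAMES

    def water_oxygens(self) -> np.ndarray:
        """Ordinals of all water oxygen atoms, in atom order."""
        return np.array(
            [
                a.ordinal
                for a in self.atoms
                if a.resname in WATER_RESIDUE_NAMES and a.element == "O"
            ],
            dtype=int,
        )

    def atom(self, chain: str, resid: int, name: str) -> int:
        """Resolve one atom by (chain, resid, atom name) → ordinal."""
        try:
            return self._index[(chain, resid, name)]
        except KeyError:
            raise SelectionError(
                f"no atom (chain={chain!r}, resid={resid}, name={name!r})"
            ) from None

    def select(
        self,
        chain: str | None = None,
        resid: int | None = None,
        names: Iterable[str] | None = None,
        resname: str | None = None,
    ) -> np.ndarray:
        """Ordinals of all atoms matching every given criterion."""
        nameset = None if names is None else set(names)
        out = [
            a.ordinal
            for a in self.atoms
            if (chain is None or a.chain == chain)
            and (resid is None or a.resid == resid)
            and (nameset is None or a.name in nameset)
            and (resname is None or a.resname == resname)
        ]
        return np.array(out, dtype=int)

    def residue_atoms(self, resid: int, chain: str | None = None, heavy_only: bool = True) -> np.ndarray:
        out = [
            a.ordinal
            for a in self.atoms
            if a.resid == resid
            and (chain is None or a.chain == chain)
            and not (heavy_only and a.role is Role.hydrogen)
        ]
        if not out:
            raise SelectionError(f"no residue {resid}" + (f" in chain {chain}" if chain else ""))
        return np.array(out, dtype=int)

    def water_resid_of(self, ordinal: int) -> int:
        return self.atoms[ordinal].resid


@dataclass
class Frame:
    """One coordinate set (Å) at a time point (ps), optional orthorhombic box."""

    time: float
    coords: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TopologyError(f"coords must be (n, 3), got {self.coords.shape}")
        if self.time < 0:
            raise TrajectoryError(f"negative frame time {self.time}")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def check(self, topology: Topology) -> None:
        if self.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"frame has {self.n_atoms} atoms, topology has {topology.n_atoms}"
            )


def displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image displacement b − a (orthorhombic box, or none)."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box is not None:
        d = d - box * np.round(d / box)
    return d


def distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> float:
    return float(np.linalg.norm(displacement(a, b, box)))
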