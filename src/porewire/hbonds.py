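"""Geometric hydrogen-bond detection and per-frame H-bond graphs.

A hydrogen bond is accepted when the donor–acceptor heavy-atom distance is
within ``max_heavy_distance`` and (when hydrogens are present) the
donor–H···acceptor angle at the hydrogen is at least ``min_dha_angle``.
The defaults (3.5 Å, 150°) are the standard geometric criterion used in MD
trajectory analysis; both are configuration-exposed. In ``heavy_only`` mode
— needed for crystallographic waters, which carry no hydrogens — a bond is
accepted on the heavy-atom distance alone.

Candidate pairs come from a k-d tree (periodic when the frame has a box);
the result is required, and tested, to be identical to an all-pairs
brute-force evaluation of the same criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .model import Frame, Role, SelectionError, Topology, displacement

__all__ = ["HBondCriteria", "HBond", "detect_hbonds", "build_graph", "hbonds_to_table"]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance thresholds for hydrogen bonds."""

    max_heavy_distance: float = 3.5
    min_dha_angle: float = 150.0
    heavy_only: bool = False

    def __post_init__(self) -> None:
        if self.max_heavy_distance <= 0:
            raise ValueError("max_heavy_distance must be positive")
        if not 0.0 <= self.min_dha_angle <= 180.0:
            raise ValueError("min_dha_angle must be in [0, 180]")


@dataclass(frozen=True)
class HBond:
    """A donor–hydrogen–acceptor triple with its geometry.

    ``hydrogen`` and ``dha_angle`` are ``None`` in heavy-only mode.
    """

    donor: int
    hydrogen: int | None
    acceptor: int
    heavy_distance: float
    dha_angle: float | None

    @property
    def heavy_pair(self) -> tuple[int, int]:
        return (self.donor, self.acceptor) if self.donor < self.acceptor else (self.acceptor, self.donor)


def _candidate_pairs(coords: np.ndarray, cutoff: float, box: np.ndarray | None,
                     brute: bool) -> list[tuple[int, int]]:
    n = len(coords)
    if brute or n < 2:
        out = []
        for i in range(n):
            for j in range(i + 1, n):
                d = displacement(coords[i], coords[j], box)
                if float(np.linalg.norm(d)) <= cutoff:
                    out.append((i, j))
        return out
    if box is not None:
        wrapped = np.mod(coords, box)
        # guard against coordinates landing exactly on the upper box face
        wrapped = np.where(wrapped >= box, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box)
    else:
        tree = cKDTree(coords)
    return sorted((min(i, j), max(i, j)) for i, j in tree.query_pairs(cutoff, eps=0.0))


def _angle_at(h: np.ndarray, a: np.ndarray, b: np.ndarray, box) -> float:
    """Angle a–h–b in degrees (minimum image)."""
    v1 = displacement(h, a, box)
    v2 = displacement(h, b, box)
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    node_atoms: np.ndarray | list[int] | None = None,
    brute_force: bool = False,
) -> list[HBond]:
    """Find every hydrogen bond among ``node_atoms`` in one frame.

    ``node_atoms`` are heavy-atom ordinals (water oxygens plus designated
    side-chain heteroatoms); defaults to all water oxygens. The returned
    list is symmetric in the sense that the unordered heavy-pair set does
    not depend on atom enumeration order.
    """
    frame.check(topology)
    if node_atoms is None:
        node_atoms = topology.water_oxygens()
    nodes = np.asarray(node_atoms, dtype=int)
    if nodes.size == 0:
        raise SelectionError("node_atoms selection resolved to zero atoms")

    coords = frame.coords[nodes]
    pairs = _candidate_pairs(coords, criteria.max_heavy_distance, frame.box, brute_force)

    out: list[HBond] = []
    for li, lj in pairs:
        i, j = int(nodes[li]), int(nodes[lj])
        dist = float(np.linalg.norm(displacement(frame.coords[i], frame.coords[j], frame.box)))
        for donor, acceptor in ((i, j), (j, i)):
            r_d = topology.atoms[donor].role
            r_a = topology.atoms[acceptor].role
            if not (r_d.can_donate and r_a.can_accept):
                continue
            if criteria.heavy_only:
                out.append(HBond(donor, None, acceptor, dist, None))
                continue
            for h in topology.h_children.get(donor, ()):
                ang = _angle_at(frame.coords[h], frame.coords[donor],
                                frame.coords[acceptor], frame.box)
                if ang >= criteria.min_dha_angle:
                    out.append(HBond(donor, h, acceptor, dist, ang))
    return out


def build_graph(hbonds: list[HBond], node_atoms: np.ndarray | list[int]) -> nx.Graph:
    """Collapse H-bonds into a simple undirected graph on heavy atoms.

    Both donation directions of the same heavy pair become one edge; the
    edge keeps the heavy distance.
    """
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in np.asarray(node_atoms, dtype=int))
    for hb in hbonds:
        a, b = hb.heavy_pair
        if a == b:
            continue
        if not (g.has_node(a) and g.has_node(b)):
            raise ValueError(f"H-bond endpoint {a}-{b} outside the node set")
        g.add_edge(a, b, distance=hb.heavy_distance)
    return g


def hbonds_to_table(hbonds: list[HBond], time_ps: float) -> list[dict]:
    """Rows for TSV export (frame time, donor, acceptor, distance, angle)."""
    return [
        {
            "time_ps": time_ps,
            "donor": hb.donor,
            "hydrogen": -1 if hb.hydrogen is None else hb.hydrogen,
            "acceptor": hb.acceptor,
            "distance_A": round(hb.heavy_distance, 4),
            "dha_angle_deg": float("nan") if hb.dha_angle is None else round(hb.dha_angle, 2),
        }
        for hb in hbonds
    ]
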