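"""Pore hydration, crystallographic-water overlap and positional RMSD.

The C-terminal pore of the calcium pump has no published geometric
definition, only the identity of its lining residues; the envelope used
here is a capped cylinder spanning the two carboxylate carbons of the
endpoint glutamates (default radius 5 Å, padded 2 Å at both ends), with an
alternative lining-residue proximity mode (water oxygen within 4.5 Å of any
lining-residue polar atom). Both boundaries are closed (≤).

Crystal-water "overlap" reduces, per water, to a displacement bound after
rigid superposition: a simulation water matches a crystal water when it
lies within the cutoff (default 2 Å). Matching maximises the number of
matched pairs under the cutoff (maximum-cardinality bipartite matching,
Hopcroft–Karp); a purely greedy ascending-distance pairing is deterministic
but can drop a feasible match, so optimality is required and cross-checked
against an optimal-assignment oracle in the tests. Matches are reported in
ascending displacement order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    ConfigError,
    Frame,
    GeometryError,
    Role,
    SelectionError,
    Topology,
)

__all__ = [
    "AtomSelector",
    "PoreDefinition",
    "HydrationSeries",
    "OverlapResult",
    "waters_in_pore",
    "waters_near_lining",
    "hydration_timeseries",
    "match_crystal_waters",
    "superpose",
    "residue_rmsd_series",
]

#: Polar side-chain atom names per residue type, used by the lining mode.
_POLAR_SIDECHAIN = {
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}


@dataclass(frozen=True)
class AtomSelector:
    """(chain, resid, atom names) → one or more ordinals."""

    chain: str
    resid: int
    names: tuple[str, ...]

    def resolve(self, topology: Topology) -> np.ndarray:
        out = topology.select(chain=self.chain, resid=self.resid, names=self.names)
        if out.size == 0:
            raise SelectionError(
                f"selector chain={self.chain!r} resid={self.resid} names={self.names} "
                "resolved to zero atoms"
            )
        return out


def default_pore_lining() -> tuple[tuple[str, int], ...]:
    """The seven residues lining the C-terminal proton-release pore."""
    return (("A", 767), ("A", 836), ("A", 837), ("A", 908),
            ("A", 911), ("A", 914), ("A", 918))


@dataclass
class PoreDefinition:
    """Geometric envelope in which pore waters are counted."""

    lining_residues: tuple[tuple[str, int], ...] = field(default_factory=default_pore_lining)
    axis_start: AtomSelector = AtomSelector("A", 908, ("CD",))
    axis_end: AtomSelector = AtomSelector("A", 918, ("CD",))
    cylinder_radius: float = 5.0
    axis_padding: float = 2.0
    lining_cutoff: float = 4.5

    def __post_init__(self) -> None:
        if self.cylinder_radius <= 0:
            raise ConfigError("cylinder_radius must be positive")


def _axis_points(frame: Frame, topology: Topology, pore: PoreDefinition):
    p0 = frame.coords[pore.axis_start.resolve(topology)].mean(axis=0)
    p1 = frame.coords[pore.axis_end.resolve(topology)].mean(axis=0)
    return p0, p1


def waters_in_pore(frame: Frame, topology: Topology, pore: PoreDefinition) -> set[int]:
    """Water-oxygen ordinals inside the capped, padded cylinder (closed boundary)."""
    frame.check(topology)
    p0, p1 = _axis_points(frame, topology, pore)
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    if length == 0.0:
        raise GeometryError("pore axis endpoints coincide")
    u = axis / length
    ows = topology.water_oxygens()
    if ows.size == 0:
        return set()
    rel = frame.coords[ows] - p0
    t = rel @ u
    radial = np.linalg.norm(rel - np.outer(t, u), axis=1)
    inside = (
        (t >= -pore.axis_padding)
        & (t <= length + pore.axis_padding)
        & (radial <= pore.cylinder_radius)
    )
    return {int(i) for i in ows[inside]}


def waters_near_lining(frame: Frame, topology: Topology, pore: PoreDefinition) -> set[int]:
    """Alternative envelope: water O within ``lining_cutoff`` of any lining polar atom."""
    frame.check(topology)
    polar: list[int] = []
    for chain, resid in pore.lining_residues:
        members = topology.residue_atoms(resid, chain=chain)
        for i in members:
            a = topology.atoms[int(i)]
            if a.name in _POLAR_SIDECHAIN.get(a.resname, ()) or a.name == "O":
                polar.append(int(i))
    if not polar:
        raise SelectionError("no polar atoms found in lining residues")
    ows = topology.water_oxygens()
    if ows.size == 0:
        return set()
    d = np.linalg.norm(
        frame.coords[ows][:, None, :] - frame.coords[polar][None, :, :], axis=2
    )
    inside = (d <= pore.lining_cutoff).any(axis=1)
    return {int(i) for i in ows[inside]}


@dataclass
class HydrationSeries:
    """Per-frame pore water counts (times in ps)."""

    times: np.ndarray
    counts: np.ndarray
    interval: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.times.shape != self.counts.shape:
            raise ConfigError("times and counts must have equal length")
        if np.any(self.counts < 0):
            raise ConfigError("counts must be non-negative")

    def window_mean(self, t_start: float, t_end: float) -> float:
        mask = (self.times >= t_start) & (self.times <= t_end)
        if not mask.any():
            raise ConfigError(f"window [{t_start}, {t_end}] contains no samples")
        return float(self.counts[mask].mean())

    def window_means(self, windows: Sequence[tuple[float, float]]) -> list[float]:
        return [self.window_mean(a, b) for a, b in windows]


def hydration_timeseries(
    trajectory: Sequence[Frame],
    topology: Topology,
    pore: PoreDefinition,
    interval_ps: float | None = None,
    mode: str = "cylinder",
) -> HydrationSeries:
    """Count pore waters at a fixed reporting interval.

    ``interval_ps`` defaults to the frame spacing; a requested interval
    below the frame spacing is a configuration error.
    """
    if not trajectory:
        raise ConfigError("empty trajectory")
    times = np.array([f.time for f in trajectory])
    spacing = float(times[1] - times[0]) if len(times) > 1 else (interval_ps or 1.0)
    if interval_ps is None:
        interval_ps = spacing
    if interval_ps < spacing - 1e-9:
        raise ConfigError(
            f"interval {interval_ps} ps below frame spacing {spacing} ps"
        )
    step = max(1, int(round(interval_ps / spacing))) if spacing > 0 else 1
    counter = waters_in_pore if mode == "cylinder" else waters_near_lining
    sel = trajectory[::step]
    counts = [len(counter(f, topology, pore)) for f in sel]
    return HydrationSeries(
        times=np.array([f.time for f in sel]),
        counts=np.array(counts, dtype=int),
        interval=float(interval_ps),
    )


@dataclass
class OverlapResult:
    """Matching of simulation vs crystal waters under a displacement cutoff."""

    matches: list[tuple[int, int, float]]
    unmatched_crystal: list[int]
    cutoff: float

    @property
    def n_matched(self) -> int:
        return len(self.matches)


def match_crystal_waters(
    sim_frame: Frame,
    sim_waters: Sequence[int],
    crystal_frame: Frame,
    crystal_waters: Sequence[int],
    cutoff: float = 2.0,
) -> OverlapResult:
    """Match each crystal water to at most one simulation water.

    Both frames must already be superposed (see :func:`superpose`). The
    match count is the maximum achievable with every pair strictly within
    ``cutoff``; matches are listed in ascending displacement order.
    """
    import networkx as nx

    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    sim = list(map(int, sim_waters))
    cry = list(map(int, crystal_waters))
    if not sim or not cry:
        return OverlapResult([], cry, cutoff)
    d = np.linalg.norm(
        sim_frame.coords[sim][:, None, :] - crystal_frame.coords[cry][None, :, :],
        axis=2,
    )
    g = nx.Graph()
    top = [("s", i) for i in range(len(sim))]
    g.add_nodes_from(top, bipartite=0)
    g.add_nodes_from((("c", j) for j in range(len(cry))), bipartite=1)
    for i in range(len(sim)):
        for j in range(len(cry)):
            if d[i, j] < cutoff:
                g.add_edge(("s", i), ("c", j))
    pairing = nx.bipartite.maximum_matching(g, top_nodes=top)
    matches = sorted(
        (sim[i], cry[j[1]], float(d[i, j[1]]))
        for (kind, i), j in pairing.items()
        if kind == "s"
    )
    matches.sort(key=lambda m: (m[2], m[0]))
    matched_c = {c for _, c, _ in matches}
    unmatched = [c for c in cry if c not in matched_c]
    return OverlapResult(matches, unmatched, cutoff)


def superpose(
    mobile: Frame,
    reference: Frame,
    fit_atoms: Sequence[int],
) -> tuple[Frame, float]:
    """Least-squares rigid-body superposition (Kabsch) on ``fit_atoms``.

    Returns the transformed mobile frame (all atoms moved) and the RMSD of
    the fit atoms after superposition.
    """
    idx = np.asarray(fit_atoms, dtype=int)
    if idx.size < 3:
        raise GeometryError("superposition needs at least 3 fit atoms")
    x = mobile.coords[idx]
    y = reference.coords[idx]
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < 2:
        raise GeometryError("fit atoms are collinear")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, sign]) @ u.T
    moved = (mobile.coords - x.mean(axis=0)) @ rot.T + y.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((moved[idx] - y) ** 2, axis=1))))
    out = Frame(time=mobile.time, coords=moved, box=None)
    return out, rmsd


def residue_rmsd_series(
    trajectory: Sequence[Frame],
    topology: Topology,
    resid: int,
    reference: Frame,
    fit_atoms: Sequence[int],
    chain: str | None = None,
) -> tuple[float, float, np.ndarray]:
    """Per-frame heavy-atom RMSD of one residue after global superposition.

    Each frame is superposed onto the reference using ``fit_atoms`` (no
    per-residue refit); the residue RMSD is then computed over its heavy
    atoms. Returns (mean, standard deviation, per-frame values) in Å.
    """
    res = topology.residue_atoms(resid, chain=chain, heavy_only=True)
    vals = []
    for frame in trajectory:
        moved, _ = superpose(frame, reference, fit_atoms)
        diff = moved.coords[res] - reference.coords[res]
        vals.append(float(np.sqrt(np.mean(np.sum(diff**2, axis=1)))))
    arr = np.array(vals)
    return float(arr.mean()), float(arr.std()), arr
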