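"""Synthetic trajectories with planted ground truth.

The generator emits a ~200-atom stand-in scaffold — one 31-residue helix
(residues 748–778, hinge Ile761–Ile765, Arg762 guanidine group) flanking a
cylindrical pore bounded by the Glu908 and Glu918 carboxylates and lined by
Ser767, Arg836, Tyr837, Asn911, Asn914 and Ser915 — carrying the residue
names and numbers of the calcium pump's C-terminal proton-release pathway,
so that production configurations resolve verbatim. It is *not* a homology
model: the analyses under test depend only on naming, numbering and
geometry.

Three scenarios emulate the pump's three simulation regimes:

``hydration_onset``
    pore water occupancy steps 0 → 2 → 4 → 5 over the trajectory, ending
    with five pore waters, plus an optional crystal-style reference for
    overlap matching;
``wire_formation``
    a schedule of transient single-file water chains (lengths 6 and 7,
    O–O spacing 2.8 Å, hydrogens placed on-axis) bridging the two
    carboxylates, with lifetimes drawn uniformly from 150–250 ps;
``pore_closure``
    4–5 pore waters split between the two pore mouths with a > 5 Å dry gap
    (so no wire can form), a helix kink ramping to its final angle over the
    Ile761–Ile765 hinge, formation of the Arg762–Ser915 contact and
    breaking of the O(761)···N(765) backbone bond, all concomitant.

Every scenario is fully determined by its spec and seed; the pre-noise
coordinates realise the planted :class:`GroundTruth` exactly. Coordinate
noise (default sigma 0.05 Å) is i.i.d. per atom, except that an active
planted wire — whose H-bond geometry the script guarantees — is jittered
as a single rigid unit together with its anchoring carboxylate groups, so
planted events remain exactly recoverable at any noise level the generator
accepts while everything else fluctuates freely.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .model import (
    AtomRecord,
    Frame,
    Role,
    ScenarioError,
    Topology,
)
from . import io as pio

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "SyntheticTrajectory",
    "build_scaffold",
    "generate_trajectory",
    "make_crystal_reference",
]

# --------------------------------------------------------------------------
# scaffold geometry (all coordinates in Å; pore axis along z)

_PORE_SRC_OE1 = np.array([0.0, 0.0, 0.0])       # Glu908 OE1
_PORE_SNK_OE1 = np.array([0.0, 0.0, 19.6])      # Glu918 OE1; 7 x 2.8 Å spacing
_OO_SPACING = 2.8
_WATER_OH = 0.9572
# default second-hydrogen direction: 104.5 deg from the first (along +x)
_H2_DIR = np.array([np.cos(np.radians(104.5)), np.sin(np.radians(104.5)), 0.0])

_HELIX_X0, _HELIX_Y0 = 9.0, 0.0
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = np.radians(100.0)
_HELIX_FIRST, _HELIX_LAST = 748, 778
_CARBONYL_OFFSET = 1.72  # O/N axial offset giving O(i)..N(i+4) ~= 3.0 Å

_N_POOL = 14      # wire water pool
_N_SLOTS = 11     # pore occupancy slots

# occupancy slots: two clusters at the pore mouths, dry gap > 5.5 Å between
_SLOTS = np.array([
    [0.0, 0.0, 2.8],     # A1 (near Glu908)
    [0.0, 0.0, 16.8],    # B1 (near Glu918)
    [0.0, 0.0, 5.6],     # A2
    [0.0, 0.0, 14.0],    # B2
    [2.4, 1.5, 4.2],     # A3
    [2.4, 1.5, 15.4],    # B3
    [-1.8, -2.0, 3.5],   # A4
    [-1.8, -2.0, 15.9],  # B4
    [0.0, 2.8, 4.9],     # A5
    [0.0, 2.8, 13.3],    # B5
    [-2.6, 1.2, 17.5],   # B6
])

_HINGE_PIVOT_RESID = 763
_CONTACT_DIR = np.array([0.0, 1.0, 0.0])  # Ser915 O placed along +y off Arg762 NE
_OPEN_CONTACT_A = 8.0
_NATIVE_RESNAMES = {761: "ILE", 762: "ARG", 765: "ILE", 767: "SER"}


def _helix_ca(resid: int) -> np.ndarray:
    k = resid - _HELIX_FIRST
    phi = k * _HELIX_TWIST
    return np.array([
        _HELIX_X0 + _HELIX_RADIUS * np.cos(phi),
        _HELIX_Y0 + _HELIX_RADIUS * np.sin(phi),
        k * _HELIX_RISE - 6.0,
    ])


def wire_node_positions(length: int) -> np.ndarray:
    """Water-oxygen positions of a planted wire of ``length`` waters.

    Length 6 fits the endpoint separation exactly on-axis; length 7 uses a
    planar zigzag keeping every consecutive O–O distance at 2.8 Å. Other
    lengths cannot span the pore with physical spacing.
    """
    if length not in (6, 7):
        raise ScenarioError(
            f"a {length}-water wire cannot span the planted pore "
            "(supported lengths: 6 straight, 7 zigzag)"
        )
    n_links = length + 1
    span = _PORE_SNK_OE1[2] - _PORE_SRC_OE1[2]
    d_par = span / n_links
    lat = float(np.sqrt(max(_OO_SPACING**2 - d_par**2, 0.0)))
    out = []
    for k in range(1, length + 1):
        x = lat if (k % 2 == 1 and lat > 0) else 0.0
        out.append([x, 0.0, k * d_par])
    return np.array(out)


class Scaffold:
    """Topology + base coordinates + bookkeeping for the generator."""

    def __init__(self) -> None:
        atoms: list[AtomRecord] = []
        coords: list[np.ndarray] = []
        h_parent: dict[int, int] = {}
        self.designed_bonds: list[tuple[int, int]] = []

        def add(name, resname, resid, chain, element, role, pos):
            atoms.append(AtomRecord(len(atoms), name, resname, resid, chain, element, role))
            coords.append(np.asarray(pos, dtype=float))
            return len(atoms) - 1

        # helix backbone (N, CA, O per residue)
        for resid in range(_HELIX_FIRST, _HELIX_LAST + 1):
            resname = _NATIVE_RESNAMES.get(resid, "ALA")
            ca = _helix_ca(resid)
            add("N", resname, resid, "A", "N", Role.donor, ca + [0, 0, -_CARBONYL_OFFSET])
            add("CA", resname, resid, "A", "C", Role.other, ca)
            add("O", resname, resid, "A", "O", Role.acceptor, ca + [0, 0, _CARBONYL_OFFSET])

        # Arg762 guanidine group
        g0 = np.array([5.5, 0.0, 15.0])
        cz = add("CZ", "ARG", 762, "A", "C", Role.other, g0)
        ne = add("NE", "ARG", 762, "A", "N", Role.donor, g0 + [0.0, 1.33, 0.0])
        nh1 = add("NH1", "ARG", 762, "A", "N", Role.donor, g0 + [1.15, -0.66, 0.0])
        nh2 = add("NH2", "ARG", 762, "A", "N", Role.donor, g0 + [-1.15, -0.66, 0.0])
        self.designed_bonds += [(cz, ne), (cz, nh1), (cz, nh2)]
        self.arg762_ne = ne

        # Ser767 hydroxyl (side chain reaching the pore wall)
        add("OG", "SER", 767, "A", "O", Role.donor_acceptor, [3.5, 2.8, 9.5])

        # endpoint glutamates: CA, CD, OE1 (pore-facing), OE2
        self.endpoint_anchor: list[int] = []

        def glu(resid, zdir):
            base = _PORE_SRC_OE1 if resid == 908 else _PORE_SNK_OE1
            cd = base + [0.8, 0.0, -1.0 * zdir]
            add("CA", "GLU", resid, "A", "C", Role.other, base + [2.9, 0.0, -2.2 * zdir])
            icd = add("CD", "GLU", resid, "A", "C", Role.other, cd)
            ioe1 = add("OE1", "GLU", resid, "A", "O", Role.acceptor, base)
            ioe2 = add("OE2", "GLU", resid, "A", "O", Role.acceptor, base + [2.0, 0.0, -1.3 * zdir])
            self.designed_bonds += [(icd, ioe1), (icd, ioe2)]
            self.endpoint_anchor += [icd, ioe1, ioe2]

        glu(908, +1.0)
        glu(918, -1.0)

        # other lining residues (polar atoms kept > 3.5 Å from wire waters)
        add("CA", "ARG", 836, "A", "C", Role.other, [0.8, -7.0, 6.0])
        cz836 = add("CZ", "ARG", 836, "A", "C", Role.other, [0.8, -5.2, 6.0])
        for nm, off in (("NE", [0.0, 1.33, 0.0]), ("NH1", [1.15, -0.66, 0.0]),
                        ("NH2", [-1.15, -0.66, 0.0])):
            i = add(nm, "ARG", 836, "A", "N", Role.donor, np.array([0.8, -5.2, 6.0]) + off)
            self.designed_bonds.append((cz836, i))
        add("CA", "TYR", 837, "A", "C", Role.other, [-4.5, -4.5, 12.5])
        add("OH", "TYR", 837, "A", "O", Role.donor_acceptor, [-2.2, -2.8, 12.0])
        for resid, y in ((911, 4.8), (914, -4.8)):
            z = 14.0 if resid == 911 else 17.0
            add("CA", "ASN", resid, "A", "C", Role.other, [0.8, y * 1.5, z])
            cg = add("CG", "ASN", resid, "A", "C", Role.other, [0.8, y, z])
            od1 = add("OD1", "ASN", resid, "A", "O", Role.acceptor,
                      [0.8, y - np.sign(y) * 1.23, z])
            nd2 = add("ND2", "ASN", resid, "A", "N", Role.donor,
                      [0.8 + (1.1 if resid == 911 else -1.1), y + np.sign(y) * 0.6, z])
            self.designed_bonds += [(cg, od1), (cg, nd2)]

        # Ser915: backbone O is the gating-contact partner; default open (8 Å)
        o915_open = coords[self.arg762_ne] + _OPEN_CONTACT_A * _CONTACT_DIR
        add("N", "SER", 915, "A", "N", Role.donor, o915_open + [0.0, 1.4, 1.2])
        add("CA", "SER", 915, "A", "C", Role.other, o915_open + [0.0, 1.2, 2.6])
        self.ser915_o = add("O", "SER", 915, "A", "O", Role.acceptor, o915_open)
        add("OG", "SER", 915, "A", "O", Role.donor_acceptor, o915_open + [1.3, 2.0, 3.0])

        # waters: wire pool then occupancy slots; parked in a far reservoir
        self.pool_resids = list(range(2001, 2001 + _N_POOL))
        self.slot_resids = list(range(2101, 2101 + _N_SLOTS))
        self.water_o: dict[int, int] = {}
        self.water_h: dict[int, tuple[int, int]] = {}
        for j, resid in enumerate(self.pool_resids + self.slot_resids):
            pos = self._reservoir(j)
            o = add("OW", "HOH", resid, "W", "O", Role.donor_acceptor, pos)
            h1 = add("H1", "HOH", resid, "W", "H", Role.hydrogen,
                     pos + _WATER_OH * np.array([1.0, 0.0, 0.0]))
            h2 = add("H2", "HOH", resid, "W", "H", Role.hydrogen,
                     pos + _WATER_OH * _H2_DIR)
            h_parent[h1] = o
            h_parent[h2] = o
            self.water_o[resid] = o
            self.water_h[resid] = (h1, h2)
            self.designed_bonds += [(h1, o), (h2, o)]

        self.topology = Topology(atoms, h_parent)
        self.base = np.array(coords)
        self.helix_movable = self.topology.select(chain="A")
        self.helix_movable = np.array([
            i for i in self.helix_movable
            if self.topology.atoms[int(i)].resid >= _HINGE_PIVOT_RESID
            and _HELIX_FIRST <= self.topology.atoms[int(i)].resid <= _HELIX_LAST
        ])
        self.pivot = self.base[self.topology.atom("A", _HINGE_PIVOT_RESID, "CA")].copy()
        self.o761 = self.topology.atom("A", 761, "O")
        self.n765 = self.topology.atom("A", 765, "N")

    @staticmethod
    def _reservoir(j: int) -> np.ndarray:
        layer = 0.0 if j < _N_POOL else 22.0
        k = j if j < _N_POOL else j - _N_POOL
        return np.array([45.0 + 6.0 * (k % 5), 6.0 * (k // 5), 8.0 + layer])

    def place_water(self, coords: np.ndarray, resid: int, pos: np.ndarray,
                    h1_dir: np.ndarray | None = None, h2_dir: np.ndarray | None = None) -> None:
        o = self.water_o[resid]
        h1, h2 = self.water_h[resid]
        d1 = h1_dir if h1_dir is not None else np.array([1.0, 0.0, 0.0])
        d2 = h2_dir if h2_dir is not None else _H2_DIR
        coords[o] = pos
        coords[h1] = pos + _WATER_OH * d1 / np.linalg.norm(d1)
        coords[h2] = pos + _WATER_OH * d2 / np.linalg.norm(d2)


def build_scaffold(seed: int = 0) -> tuple[Topology, Frame]:
    """Deterministic stand-in topology + reference frame (same for any seed)."""
    sc = Scaffold()
    return sc.topology, Frame(time=0.0, coords=sc.base.copy())


# --------------------------------------------------------------------------
# scenario scripts


@dataclass
class ScenarioSpec:
    """Full script of one synthetic experiment; seed determines everything."""

    scenario: str
    n_frames: int
    frame_spacing_ps: float = 10.0
    seed: int = 0
    #: ((t_start_ps, t_end_ps), water count); t_start <= t < t_end
    occupancy_script: tuple[tuple[tuple[float, float], int], ...] = ()
    #: (start_frame, duration_frames, wire_length)
    wire_script: tuple[tuple[int, int, int], ...] = ()
    kink_script: tuple[int, float] | None = None        # (onset_frame, final_deg)
    contact_script: tuple[int, float, float] | None = None   # (onset, start_A, final_A)
    backbone_script: tuple[int, float, float] | None = None
    ramp_frames: int = 20
    noise_sigma_A: float = 0.05

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ScenarioError("n_frames must be >= 1")
        for (start, dur, length) in self.wire_script:
            if dur < 1 or start < 0 or start + dur > self.n_frames:
                raise ScenarioError(
                    f"wire event ({start}, {dur}) outside 0..{self.n_frames}"
                )
            wire_node_positions(length)  # validates feasibility
        for _, count in self.occupancy_script:
            if count > _N_SLOTS:
                raise ScenarioError(f"occupancy {count} exceeds the {_N_SLOTS} pore slots")

    # -- canonical study conditions -------------------------------------

    @classmethod
    def hydration_onset(cls, seed: int = 0, n_frames: int = 80,
                        frame_spacing_ps: float = 10.0) -> "ScenarioSpec":
        """Stepwise pore filling 0 → 2 → 4 → 5, ending with five pore waters."""
        total = n_frames * frame_spacing_ps
        script = (
            ((0.0, 0.20 * total), 0),
            ((0.20 * total, 0.35 * total), 2),
            ((0.35 * total, 0.45 * total), 4),
            ((0.45 * total, total + frame_spacing_ps), 5),
        )
        return cls("hydration_onset", n_frames, frame_spacing_ps, seed,
                   occupancy_script=script)

    @classmethod
    def two_phase_hydration(cls, seed: int = 0, n_frames: int = 60,
                            frame_spacing_ps: float = 10.0,
                            counts: tuple[int, int] = (4, 9)) -> "ScenarioSpec":
        """Two occupancy regimes (default 4 then 9 waters), half the frames each."""
        total = n_frames * frame_spacing_ps
        script = (
            ((0.0, total / 2), counts[0]),
            ((total / 2, total + frame_spacing_ps), counts[1]),
        )
        return cls("hydration_onset", n_frames, frame_spacing_ps, seed,
                   occupancy_script=script)

    @classmethod
    def wire_formation(cls, seed: int = 0, n_events: int = 130,
                       length_counts: dict[int, int] | None = None,
                       lifetime_frames: tuple[int, int] = (15, 25),
                       frame_spacing_ps: float = 10.0) -> "ScenarioSpec":
        """Back-to-back wire events; lifetimes uniform on 150–250 ps by default."""
        if length_counts is None:
            length_counts = {6: 100, 7: 30}
        if sum(length_counts.values()) != n_events:
            raise ScenarioError("length_counts must sum to n_events")
        rng = np.random.default_rng(seed)
        lengths = np.repeat(list(length_counts), list(length_counts.values()))
        rng.shuffle(lengths)
        durations = rng.integers(lifetime_frames[0], lifetime_frames[1] + 1, size=n_events)
        script = []
        frame = 2  # empty lead-in
        for length, dur in zip(lengths, durations):
            script.append((int(frame), int(dur), int(length)))
            frame += int(dur)
        return cls("wire_formation", frame + 2, frame_spacing_ps, seed,
                   wire_script=tuple(script))

    @classmethod
    def pore_closure(cls, seed: int = 0, n_frames: int = 100,
                     frame_spacing_ps: float = 10.0, final_angle: float = 20.0,
                     onset_frame: int = 10) -> "ScenarioSpec":
        """Split 4–5-water occupancy, no bridge, concomitant kink/contact/break."""
        total = n_frames * frame_spacing_ps
        blocks = []
        block = 10 * frame_spacing_ps
        t = 0.0
        k = 0
        while t < total:
            blocks.append(((t, min(t + block, total + frame_spacing_ps)), 4 + (k % 2)))
            t += block
            k += 1
        return cls("pore_closure", n_frames, frame_spacing_ps, seed,
                   occupancy_script=tuple(blocks),
                   kink_script=(onset_frame, final_angle),
                   contact_script=(onset_frame, _OPEN_CONTACT_A, 4.2),
                   backbone_script=(onset_frame, 3.0, 5.2))


@dataclass
class GroundTruth:
    """Exact description of the planted (pre-noise) features."""

    scenario: str
    seed: int
    frame_spacing_ps: float
    n_frames: int
    occupancy: list[int]
    pore_water_resids: list[list[int]]
    events: list[dict]
    bend_angle_deg: list[float]
    contact_distance_A: list[float]
    backbone_distance_A: list[float]

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticTrajectory:
    """Generated fixture: topology, frames and the planted truth."""

    spec: ScenarioSpec
    topology: Topology
    frames: list[Frame]
    ground_truth: GroundTruth
    scaffold: "Scaffold | None" = field(repr=False, default=None)

    def write(self, outdir: str | os.PathLike, trajectory_format: str = "dcd") -> dict[str, str]:
        """Write structure (PDB), trajectory (DCD or multi-MODEL PDB) and truth (JSON)."""
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "structure": os.path.join(outdir, "scaffold.pdb"),
            "trajectory": os.path.join(outdir, f"trajectory.{trajectory_format}"),
            "ground_truth": os.path.join(outdir, "ground_truth.json"),
        }
        pio.write_structure(self.topology, self.frames[0], paths["structure"])
        if trajectory_format == "dcd":
            pio.write_dcd(self.topology, self.frames, paths["trajectory"],
                          dt_ps=self.spec.frame_spacing_ps)
        elif trajectory_format == "pdb":
            pio.write_structure(self.topology, self.frames, paths["trajectory"])
        else:
            raise ScenarioError(f"unsupported trajectory format {trajectory_format!r}")
        self.ground_truth.to_json(paths["ground_truth"])
        return paths


def _occupancy_at(spec: ScenarioSpec, t: float) -> int:
    for (t0, t1), count in spec.occupancy_script:
        if t0 <= t < t1:
            return count
    return 0


def _ramp(frame: int, onset: int, ramp_frames: int, start: float, final: float) -> float:
    if frame < onset:
        return start
    if frame >= onset + ramp_frames:
        return final
    return start + (final - start) * (frame - onset) / ramp_frames


def generate_trajectory(spec: ScenarioSpec) -> SyntheticTrajectory:
    """Realise a scenario script as coordinates + exact ground truth."""
    sc = Scaffold()
    rng = np.random.default_rng(spec.seed)

    # assign pool waters to wire events by rotation, so that consecutive
    # events always carry different water sets (no accidental event merging)
    events = []
    rot = 0
    for (start, dur, length) in sorted(spec.wire_script):
        resids = [sc.pool_resids[(rot + j) % _N_POOL] for j in range(length)]
        rot = (rot + length) % _N_POOL
        events.append({
            "start_frame": start,
            "n_frames": dur,
            "length": length,
            "water_resids": resids,
        })
    for a in range(len(events)):
        for b in range(a + 1, len(events)):
            ea, eb = events[a], events[b]
            overlap = (ea["start_frame"] < eb["start_frame"] + eb["n_frames"]
                       and eb["start_frame"] < ea["start_frame"] + ea["n_frames"])
            if overlap and set(ea["water_resids"]) & set(eb["water_resids"]):
                raise ScenarioError(
                    "time-overlapping wire events share pool waters; reduce overlap"
                )

    frames: list[Frame] = []
    occupancy: list[int] = []
    pore_resids: list[list[int]] = []
    bend: list[float] = []
    contact: list[float] = []
    backbone: list[float] = []

    for f in range(spec.n_frames):
        t = f * spec.frame_spacing_ps
        coords = sc.base.copy()
        in_pore: list[int] = []

        # occupancy slots
        n_occ = _occupancy_at(spec, t)
        for j, resid in enumerate(sc.slot_resids):
            if j < n_occ:
                sc.place_water(coords, resid, _SLOTS[j])
                in_pore.append(resid)
        occupancy.append(n_occ)

        # active wires
        for ev in events:
            if not (ev["start_frame"] <= f < ev["start_frame"] + ev["n_frames"]):
                continue
            nodes = np.vstack([_PORE_SRC_OE1, wire_node_positions(ev["length"]), _PORE_SNK_OE1])
            for j, resid in enumerate(ev["water_resids"], start=1):
                # H1 donates back toward the source side, H2 toward the sink
                sc.place_water(coords, resid, nodes[j],
                               h1_dir=nodes[j - 1] - nodes[j],
                               h2_dir=nodes[j + 1] - nodes[j])
                in_pore.append(resid)
        pore_resids.append(sorted(in_pore))

        # helix kink: rigid rotation of residues >= pivot about the pivot CA
        angle = (_ramp(f, spec.kink_script[0], spec.ramp_frames, 0.0, spec.kink_script[1])
                 if spec.kink_script else 0.0)
        if angle:
            a = np.radians(angle)
            rot_m = np.array([[np.cos(a), 0.0, np.sin(a)],
                              [0.0, 1.0, 0.0],
                              [-np.sin(a), 0.0, np.cos(a)]])
            idx = sc.helix_movable
            coords[idx] = (coords[idx] - sc.pivot) @ rot_m.T + sc.pivot
        bend.append(angle)

        # planted backbone O(761)..N(765) separation
        if spec.backbone_script:
            onset, d0, d1 = spec.backbone_script
            d_bb = _ramp(f, onset, spec.ramp_frames, d0, d1)
            direction = coords[sc.n765] - coords[sc.o761]
            direction /= np.linalg.norm(direction)
            coords[sc.n765] = coords[sc.o761] + d_bb * direction
            backbone.append(d_bb)
        else:
            backbone.append(float(np.linalg.norm(coords[sc.n765] - coords[sc.o761])))

        # planted Arg762 guanidine .. Ser915 backbone-O distance
        if spec.contact_script:
            onset, d0, d1 = spec.contact_script
            d_c = _ramp(f, onset, spec.ramp_frames, d0, d1)
        else:
            d_c = _OPEN_CONTACT_A
        coords[sc.ser915_o] = coords[sc.arg762_ne] + d_c * _CONTACT_DIR
        contact.append(d_c)

        if spec.noise_sigma_A > 0:
            noise = rng.normal(0.0, spec.noise_sigma_A, coords.shape)
            # a planted wire is a scripted feature: it (and its anchoring
            # carboxylates) jitters as one rigid unit, modelling collective
            # motion, so the scripted H-bond geometry survives any noise level
            wire_atoms: list[int] = []
            for ev in events:
                if ev["start_frame"] <= f < ev["start_frame"] + ev["n_frames"]:
                    for resid in ev["water_resids"]:
                        wire_atoms.append(sc.water_o[resid])
                        wire_atoms.extend(sc.water_h[resid])
            if wire_atoms:
                shared = rng.normal(0.0, spec.noise_sigma_A, 3)
                noise[wire_atoms + sc.endpoint_anchor] = shared
            coords = coords + noise
        frames.append(Frame(time=t, coords=coords))

    gt = GroundTruth(
        scenario=spec.scenario,
        seed=spec.seed,
        frame_spacing_ps=spec.frame_spacing_ps,
        n_frames=spec.n_frames,
        occupancy=occupancy,
        pore_water_resids=pore_resids,
        events=events,
        bend_angle_deg=bend,
        contact_distance_A=contact,
        backbone_distance_A=backbone,
    )
    return SyntheticTrajectory(spec=spec, topology=sc.topology, frames=frames,
                               ground_truth=gt, scaffold=sc)


def make_crystal_reference(
    spec: ScenarioSpec,
    k_overlapping: int = 3,
    jitter_A: float = 0.5,
    path: str | os.PathLike | None = None,
) -> tuple[Topology, Frame]:
    """Crystal-style reference (no hydrogens) for overlap matching.

    Takes the final-frame planted pore waters of ``spec``, keeps
    ``k_overlapping`` of them displaced by exactly ``jitter_A`` in a random
    direction, and moves the remainder 3 Å away (well beyond the 2 Å
    overlap cutoff). The protein atoms are the scaffold's own, so the
    frames are already superposed.
    """
    traj = generate_trajectory(spec)
    sc = traj.scaffold
    final_resids = traj.ground_truth.pore_water_resids[-1]
    if k_overlapping > len(final_resids):
        raise ScenarioError(
            f"k_overlapping={k_overlapping} exceeds the {len(final_resids)} planted waters"
        )
    rng = np.random.default_rng(spec.seed + 1)
    planted = {r: _SLOTS[sc.slot_resids.index(r)] for r in final_resids
               if r in sc.slot_resids}
    if len(planted) != len(final_resids):
        raise ScenarioError("crystal reference requires a slot-water (wire-free) scenario")

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    for a in sc.topology.atoms:
        if a.chain != "A":
            continue
        atoms.append(AtomRecord(len(atoms), a.name, a.resname, a.resid, a.chain,
                                a.element, a.role))
        coords.append(sc.base[a.ordinal].copy())
    planted_arr = np.array([planted[r] for r in sorted(planted)])
    for j, resid in enumerate(sorted(planted)):
        pos = planted[resid].copy()
        if j < k_overlapping:
            if jitter_A > 0:
                # displace by exactly jitter_A, in a direction that does not
                # bring the water closer to any *other* planted position
                others = np.delete(planted_arr, j, axis=0)
                for _ in range(1000):
                    direction = rng.normal(size=3)
                    cand = pos + jitter_A * direction / np.linalg.norm(direction)
                    if len(others) == 0 or np.linalg.norm(others - cand, axis=1).min() > jitter_A:
                        pos = cand
                        break
                else:  # pragma: no cover - geometrically unreachable
                    raise ScenarioError("could not place jittered crystal water")
        else:
            pos = pos + np.array([0.0, -3.0, 0.0])
        atoms.append(AtomRecord(len(atoms), "OW", "HOH", 3000 + j, "W", "O",
                                Role.donor_acceptor))
        coords.append(pos)
    topo = Topology(atoms, {})
    frame = Frame(time=0.0, coords=np.array(coords))
    if path is not None:
        pio.write_structure(topo, frame, path)
    return topo, frame
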