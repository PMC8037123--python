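"""Helix hinge-bend angle and gating-contact geometry.

The M5 hinge bend is quantified as the angle between two principal axes
fitted by least squares through the Cα atoms of the helix segments
flanking the Ile761–Ile765 hinge (defaults: residues 748–760 and 766–778;
the flank definition, flank lengths and Cα-only fitting are configurable).
Axes are sign-oriented N→C along the chain so the angle is well defined in
[0°, 180°].

The module also tracks the canonical α-helical O(i)···N(i+4) backbone
hydrogen bond (Ile761→Ile765; flagged broken above 3.5 Å, consistent with
the H-bond default) and the Arg762 guanidine – Ser915 backbone-oxygen
gating contact (contact when the minimum distance is below 5 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import ConfigError, Frame, GeometryError, SelectionError, Topology
from .pore import AtomSelector

__all__ = [
    "HelixBendSpec",
    "GeometrySeries",
    "fit_helix_axis",
    "bend_angle",
    "backbone_hbond_distance",
    "contact_distance",
    "geometry_timeseries",
]

BACKBONE_HBOND_CUTOFF = 3.5  # Å; O(i)···N(i+4) flagged broken above this
CONTACT_CUTOFF = 5.0  # Å; residue-pair clustering criterion


@dataclass
class HelixBendSpec:
    """Residue ranges (inclusive) defining the hinge and its flanks."""

    chain: str = "A"
    pre_hinge: tuple[int, int] = (748, 760)
    post_hinge: tuple[int, int] = (766, 778)
    hinge: tuple[int, int] = (761, 765)
    axis_atom: str = "CA"
    contact_a: AtomSelector = field(default_factory=lambda: AtomSelector("A", 762, ("NE", "NH1", "NH2")))
    contact_b: AtomSelector = field(default_factory=lambda: AtomSelector("A", 915, ("O",)))
    backbone_donor_resid: int = 765  # provides N(i+4)
    backbone_acceptor_resid: int = 761  # provides O(i)

    def __post_init__(self) -> None:
        for lo, hi in (self.pre_hinge, self.post_hinge):
            if hi - lo + 1 < 6:
                raise ConfigError("flank ranges need >= 6 residues for stable axis fits")
        a, b, c = self.pre_hinge, self.hinge, self.post_hinge
        if not (a[1] < b[0] and b[1] < c[0]):
            raise ConfigError("pre-hinge, hinge and post-hinge ranges must be disjoint and ordered")

    def flank_atoms(self, topology: Topology, which: str) -> np.ndarray:
        lo, hi = self.pre_hinge if which == "pre" else self.post_hinge
        out = []
        for resid in range(lo, hi + 1):
            sel = topology.select(chain=self.chain, resid=resid, names=(self.axis_atom,))
            if sel.size != 1:
                raise SelectionError(
                    f"residue {resid} {self.axis_atom} missing or ambiguous in chain {self.chain}"
                )
            out.append(int(sel[0]))
        return np.array(out, dtype=int)


def fit_helix_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Helix axis through an ordered point set, oriented first→last.

    Returns (unit axis, centroid). The axis is the screw axis of the
    least-squares rigid step mapping each point onto its successor — exact
    for an ideal helix regardless of how many complete turns the segment
    covers (a plain principal-axis fit is biased by the incomplete final
    turn). Degenerate, untwisted point sets fall back to the principal
    axis of the centred coordinates.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("axis fit needs at least 3 points in 3D")
    centroid = pts.mean(axis=0)

    x = pts[:-1] - pts[:-1].mean(axis=0)
    y = pts[1:] - pts[1:].mean(axis=0)
    u, _, vt = np.linalg.svd(x.T @ y)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, sign]) @ u.T
    axis = np.array([rot[2, 1] - rot[1, 2], rot[0, 2] - rot[2, 0], rot[1, 0] - rot[0, 1]])
    norm = np.linalg.norm(axis)
    if norm < 1e-8:  # no twist: straight-line points, use the principal axis
        _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
        axis = vt[0]
    else:
        axis = axis / norm
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis, centroid


def bend_angle(frame: Frame, topology: Topology, spec: HelixBendSpec) -> float:
    """Angle in degrees between the pre- and post-hinge flank axes."""
    frame.check(topology)
    a1, _ = fit_helix_axis(frame.coords[spec.flank_atoms(topology, "pre")])
    a2, _ = fit_helix_axis(frame.coords[spec.flank_atoms(topology, "post")])
    c = float(np.clip(np.dot(a1, a2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def backbone_hbond_distance(
    frame: Frame,
    topology: Topology,
    acceptor_resid: int,
    donor_resid: int,
    chain: str = "A",
    cutoff: float = BACKBONE_HBOND_CUTOFF,
) -> tuple[float, bool]:
    """O(i)···N(i+4) distance and its intact flag (closed boundary: ≤ cutoff)."""
    o = topology.atom(chain, acceptor_resid, "O")
    n = topology.atom(chain, donor_resid, "N")
    d = float(np.linalg.norm(frame.coords[o] - frame.coords[n]))
    return d, d <= cutoff


def contact_distance(
    frame: Frame,
    topology: Topology,
    group_a: AtomSelector | Sequence[int],
    group_b: AtomSelector | Sequence[int],
    mode: str = "min",
    cutoff: float = CONTACT_CUTOFF,
) -> tuple[float, bool]:
    """Distance between two atom groups and the R < cutoff contact flag.

    ``mode="min"`` (default) takes the minimum pairwise distance;
    ``mode="centroid"`` the centroid–centroid distance.
    """
    ia = group_a.resolve(topology) if isinstance(group_a, AtomSelector) else np.asarray(group_a, int)
    ib = group_b.resolve(topology) if isinstance(group_b, AtomSelector) else np.asarray(group_b, int)
    if ia.size == 0 or ib.size == 0:
        raise SelectionError("empty contact group")
    ca = frame.coords[ia]
    cb = frame.coords[ib]
    if mode == "min":
        d = float(np.min(np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)))
    elif mode == "centroid":
        d = float(np.linalg.norm(ca.mean(axis=0) - cb.mean(axis=0)))
    else:
        raise ConfigError(f"unknown contact mode {mode!r}")
    return d, d < cutoff


@dataclass
class GeometrySeries:
    """Per-frame helix observables (times ps, angle deg, distances Å)."""

    times: np.ndarray
    bend_angle: np.ndarray
    contact_distance: np.ndarray
    backbone_hbond_distance: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("bend_angle", "contact_distance", "backbone_hbond_distance"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.times.shape:
                raise ConfigError("series lengths disagree")
        if np.any((self.bend_angle < 0) | (self.bend_angle > 180)):
            raise ConfigError("bend angle out of [0, 180]")

    def window_mean(self, name: str, t_start: float, t_end: float) -> float:
        mask = (self.times >= t_start) & (self.times <= t_end)
        if not mask.any():
            raise ConfigError(f"window [{t_start}, {t_end}] contains no samples")
        return float(getattr(self, name)[mask].mean())


def geometry_timeseries(
    trajectory: Sequence[Frame],
    topology: Topology,
    spec: HelixBendSpec,
) -> GeometrySeries:
    """Bend angle, gating-contact and backbone H-bond distance per frame."""
    if not trajectory:
        raise ConfigError("empty trajectory")
    times, angles, contacts, backbones = [], [], [], []
    for frame in trajectory:
        times.append(frame.time)
        angles.append(bend_angle(frame, topology, spec))
        d_c, _ = contact_distance(frame, topology, spec.contact_a, spec.contact_b)
        contacts.append(d_c)
        d_b, _ = backbone_hbond_distance(
            frame, topology, spec.backbone_acceptor_resid, spec.backbone_donor_resid, spec.chain
        )
        backbones.append(d_b)
    return GeometrySeries(
        times=np.array(times),
        bend_angle=np.array(angles),
        contact_distance=np.array(contacts),
        backbone_hbond_distance=np.array(backbones),
    )
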