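"""Reading structures/trajectories into the package model, and tabular output.

PDB, DCD and XTC parsing is delegated to MDAnalysis; this module maps the
parsed atoms onto :class:`~porewire.model.Topology` / ``Frame`` objects,
classifies hydrogen-bonding roles from a role table, and infers hydrogen →
parent connectivity geometrically (nearest intra-residue heavy atom).

Fixture structures are written with the package's own fixed-column PDB
writer so that synthetic data round-trips byte-identically.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    WATER_RESIDUE_NAMES,
    AtomRecord,
    FormatError,
    Frame,
    Role,
    Topology,
    TopologyError,
    TrajectoryError,
)

__all__ = [
    "DEFAULT_ROLE_TABLE",
    "load_structure",
    "load_trajectory",
    "write_structure",
    "write_dcd",
    "write_table",
]

# Role table: (resname, atom name) -> Role. Water oxygens are handled
# separately (always donor_acceptor); hydrogens are detected by element.
DEFAULT_ROLE_TABLE: dict[tuple[str, str], Role] = {}


def _fill_default_table() -> None:
    backbone = {"O": Role.acceptor, "OXT": Role.acceptor, "N": Role.donor}
    side = {
        ("SER", "OG"): Role.donor_acceptor,
        ("THR", "OG1"): Role.donor_acceptor,
        ("TYR", "OH"): Role.donor_acceptor,
        ("GLU", "OE1"): Role.acceptor,
        ("GLU", "OE2"): Role.acceptor,
        ("ASP", "OD1"): Role.acceptor,
        ("ASP", "OD2"): Role.acceptor,
        ("ASN", "OD1"): Role.acceptor,
        ("ASN", "ND2"): Role.donor,
        ("GLN", "OE1"): Role.acceptor,
        ("GLN", "NE2"): Role.donor,
        ("ARG", "NE"): Role.donor,
        ("ARG", "NH1"): Role.donor,
        ("ARG", "NH2"): Role.donor,
        ("LYS", "NZ"): Role.donor,
        ("HIS", "ND1"): Role.donor_acceptor,
        ("HIS", "NE2"): Role.donor_acceptor,
        ("TRP", "NE1"): Role.donor,
    }
    DEFAULT_ROLE_TABLE.update(side)
    aa = (
        "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
        "SER THR TRP TYR VAL"
    ).split()
    for res in aa:
        for name, role in backbone.items():
            DEFAULT_ROLE_TABLE[(res, name)] = role


_fill_default_table()


def _guess_element(name: str, given: str | None) -> str:
    if given:
        return given.strip().capitalize()
    stripped = name.strip()
    # PDB convention: leading digits belong to hydrogen names like "1H".
    stripped = stripped.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _classify(name: str, resname: str, element: str,
              role_table: Mapping[tuple[str, str], Role]) -> Role:
    if element == "H":
        return Role.hydrogen
    if resname in WATER_RESIDUE_NAMES:
        return Role.donor_acceptor if element == "O" else Role.other
    return role_table.get((resname, name), Role.other)


def _infer_h_parents(atoms: Sequence[AtomRecord], coords: np.ndarray) -> dict[int, int]:
    """Attach each hydrogen to the nearest heavy atom of its residue (≤1.3 Å)."""
    by_res: dict[tuple[str, int], list[int]] = {}
    for a in atoms:
        by_res.setdefault((a.chain, a.resid), []).append(a.ordinal)
    parents: dict[int, int] = {}
    for members in by_res.values():
        heavies = [i for i in members if atoms[i].role is not Role.hydrogen]
        for i in members:
            if atoms[i].role is not Role.hydrogen:
                continue
            if not heavies:
                raise TopologyError(
                    f"hydrogen {atoms[i].name} in residue {atoms[i].resid} has no heavy atom"
                )
            d = np.linalg.norm(coords[heavies] - coords[i], axis=1)
            j = int(np.argmin(d))
            if d[j] > 1.3:
                raise TopologyError(
                    f"hydrogen {atoms[i].name}/{atoms[i].resid} is {d[j]:.2f} Å from "
                    "the nearest heavy atom; cannot infer bonded parent"
                )
            parents[i] = heavies[j]
    return parents


def _universe(path: str | os.PathLike, *more: str | os.PathLike):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return mda.Universe(str(path), *[str(m) for m in more])
        except (ValueError, OSError, EOFError, IndexError) as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc


def _box_of(ts) -> np.ndarray | None:
    dims = ts.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        return None
    return np.array(dims[:3], dtype=float)


def load_structure(
    path: str | os.PathLike,
    role_table: Mapping[tuple[str, str], Role] = DEFAULT_ROLE_TABLE,
) -> tuple[Topology, list[Frame]]:
    """Read a (possibly multi-MODEL) PDB file.

    Returns the topology plus one :class:`Frame` per MODEL. Crystallographic
    waters without hydrogens are accepted; their oxygens keep the
    ``donor_acceptor`` role so the heavy-atom-only H-bond criterion applies.
    """
    u = _universe(path)
    names = [str(n) for n in u.atoms.names]
    resnames = [str(r).upper() for r in u.atoms.resnames]
    resids = [int(r) for r in u.atoms.resids]
    try:
        chains = [str(c) for c in u.atoms.chainIDs]
    except AttributeError:
        chains = [str(s)[:1] for s in u.atoms.segids]
    try:
        given_elements = [str(e) for e in u.atoms.elements]
    except AttributeError:
        given_elements = [None] * len(names)

    atoms = []
    for i in range(len(names)):
        el = _guess_element(names[i], given_elements[i])
        role = _classify(names[i], resnames[i], el, role_table)
        atoms.append(
            AtomRecord(
                ordinal=i,
                name=names[i],
                resname=resnames[i],
                resid=resids[i],
                chain=chains[i] or "A",
                element=el,
                role=role,
            )
        )

    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            t = float(ts.time) if np.isfinite(ts.time) else 0.0
            frames.append(Frame(time=max(t, 0.0), coords=ts.positions.astype(float).copy(),
                                box=_box_of(ts)))
    if not frames:
        raise TrajectoryError(f"{path}: no coordinate models")
    h_parent = _infer_h_parents(atoms, frames[0].coords)
    topo = Topology(atoms, h_parent)
    # times of multi-MODEL PDBs are typically meaningless; enforce monotone
    for k, f in enumerate(frames):
        if k and f.time <= frames[k - 1].time:
            f.time = frames[k - 1].time + 1.0
    return topo, frames


def load_trajectory(
    topology: Topology,
    path: str | os.PathLike,
    stride_ps: float | None = None,
    structure_path: str | os.PathLike | None = None,
) -> list[Frame]:
    """Read a DCD/XTC/PDB trajectory as a list of frames.

    ``stride_ps`` subsamples to (approximately) the requested time spacing;
    when the file carries no usable times, frame times are assigned as
    ``stride_ps × index`` (or the native index when no stride is given).
    """
    from MDAnalysis.coordinates.core import reader as get_reader

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if structure_path is not None:
                u = _universe(structure_path, path)
                traj = u.trajectory
            else:
                traj = get_reader(str(path))
        except (ValueError, OSError, EOFError, IndexError) as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc

        if traj.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"trajectory has {traj.n_atoms} atoms, topology has {topology.n_atoms}"
            )
        raw: list[Frame] = []
        for ts in traj:
            raw.append(
                Frame(
                    time=float(ts.time) if np.isfinite(ts.time) else 0.0,
                    coords=ts.positions.astype(float).copy(),
                    box=_box_of(ts),
                )
            )
    if not raw:
        raise TrajectoryError(f"{path}: empty trajectory")

    times = np.array([f.time for f in raw])
    have_times = len(raw) > 1 and np.all(np.diff(times) > 0)
    native_dt = float(times[1] - times[0]) if have_times else None

    if stride_ps is None:
        step = 1
    elif native_dt:
        step = max(1, int(round(stride_ps / native_dt)))
    else:
        step = 1
    out = raw[::step]
    if not have_times:
        dt = stride_ps if stride_ps else 1.0
        for i, f in enumerate(out):
            f.time = i * dt
    return out


# ---------------------------------------------------------------------------
# writers

_PDB_LINE = (
    "{record:<6s}{serial:>5d} {name:<4s}{resname:>4s} {chain:1s}{resid:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}\n"
)


def _atom_line(a: AtomRecord, xyz: np.ndarray, serial: int) -> str:
    record = "HETATM" if a.resname in WATER_RESIDUE_NAMES else "ATOM"
    name = a.name if len(a.name) >= 4 else f" {a.name}"
    return _PDB_LINE.format(
        record=record, serial=serial, name=name, resname=a.resname, chain=a.chain,
        resid=a.resid, x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0, element=a.element,
    )


def write_structure(topology: Topology, frames: Frame | Sequence[Frame],
                    path: str | os.PathLike) -> None:
    """Write a (multi-MODEL) PDB file with fixed, deterministic formatting."""
    if isinstance(frames, Frame):
        frames = [frames]
    lines: list[str] = []
    box = frames[0].box
    if box is not None:
        lines.append(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
    multi = len(frames) > 1
    for m, frame in enumerate(frames, start=1):
        frame.check(topology)
        if multi:
            lines.append(f"MODEL     {m:4d}\n")
        for a in topology.atoms:
            lines.append(_atom_line(a, frame.coords[a.ordinal], (a.ordinal % 99998) + 1))
        if multi:
            lines.append("ENDMDL\n")
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def write_dcd(topology: Topology, frames: Sequence[Frame], path: str | os.PathLike,
              dt_ps: float | None = None) -> None:
    """Write frames to a binary DCD trajectory (via MDAnalysis)."""
    import MDAnalysis as mda

    if dt_ps is None:
        dt_ps = frames[1].time - frames[0].time if len(frames) > 1 else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms=topology.n_atoms, trajectory=True)
        with mda.Writer(str(path), n_atoms=topology.n_atoms, dt=dt_ps) as w:
            for f in frames:
                f.check(topology)
                u.atoms.positions = f.coords
                if f.box is not None:
                    u.dimensions = [*f.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)


def write_table(records, path: str | os.PathLike, columns: Iterable[str] | None = None) -> None:
    """Write tabular results as TSV with a header row and stable column order."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records, columns=columns)
    if columns is not None:
        df = df[list(columns)]
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc
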