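"""Shared fixtures: random water boxes, rigid motions, cached scenario runs."""

from __future__ import annotations

import numpy as np
import pytest

from porewire.model import AtomRecord, Frame, Role, Topology


def make_water_box(n_waters: int, extent: float = 15.0, seed: int = 0,
                   box: bool = False) -> tuple[Topology, Frame]:
    """Random water coordinates with random H orientations (OH 0.9572 Å)."""
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    h_parent: dict[int, int] = {}
    for w in range(n_waters):
        o_pos = rng.uniform(0.0, extent, 3)
        o = len(atoms)
        atoms.append(AtomRecord(o, "OW", "HOH", w + 1, "W", "O", Role.donor_acceptor))
        coords.append(o_pos)
        for hname in ("H1", "H2"):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            h = len(atoms)
            atoms.append(AtomRecord(h, hname, "HOH", w + 1, "W", "H", Role.hydrogen))
            coords.append(o_pos + 0.9572 * d)
            h_parent[h] = o
    topo = Topology(atoms, h_parent)
    frame = Frame(time=0.0, coords=np.array(coords),
                  box=np.array([extent] * 3) if box else None)
    return topo, frame


def random_rigid_motion(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random rotation matrix and a translation vector."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-20.0, 20.0, 3)
    return rot, t


def apply_rigid(frame: Frame, rot: np.ndarray, t: np.ndarray) -> Frame:
    return Frame(time=frame.time, coords=frame.coords @ rot.T + t, box=None)


@pytest.fixture(scope="session")
def scaffold():
    from porewire.synth import build_scaffold

    return build_scaffold(seed=0)


@pytest.fixture(scope="session")
def closure_run():
    """One cached pore-closure fixture trajectory (default study conditions)."""
    from porewire.synth import ScenarioSpec, generate_trajectory

    return generate_trajectory(ScenarioSpec.pore_closure(seed=42))


@pytest.fixture(scope="session")
def small_wire_run():
    """A short wire-formation fixture (20 events) for unit-level checks."""
    from porewire.synth import ScenarioSpec, generate_trajectory

    spec = ScenarioSpec.wire_formation(seed=7, n_events=20,
                                       length_counts={6: 15, 7: 5})
    return generate_trajectory(spec)
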