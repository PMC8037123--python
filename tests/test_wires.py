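"""Wire enumeration against a DFS oracle, event tracking, statistics."""

import numpy as np
import networkx as nx
import pytest

from porewire.model import AtomRecord, ConfigError, Role, Topology
from porewire.pore import AtomSelector
from porewire.wires import (
    WaterWire,
    WireEndpoints,
    find_wires,
    track_wires,
    wire_presence_series,
    wire_statistics,
)


def make_graph_topology(n_waters: int):
    """Toy topology: 2 source O, 2 sink O, 1 side-chain O, n water O."""
    atoms = [
        AtomRecord(0, "OE1", "GLU", 908, "A", "O", Role.acceptor),
        AtomRecord(1, "OE2", "GLU", 908, "A", "O", Role.acceptor),
        AtomRecord(2, "OE1", "GLU", 918, "A", "O", Role.acceptor),
        AtomRecord(3, "OE2", "GLU", 918, "A", "O", Role.acceptor),
        AtomRecord(4, "OG", "SER", 767, "A", "O", Role.donor_acceptor),
    ]
    for w in range(n_waters):
        atoms.append(AtomRecord(5 + w, "OW", "HOH", 2000 + w, "W", "O", Role.donor_acceptor))
    return Topology(atoms, {})


def dfs_oracle(graph, sources, sinks, waters, max_waters):
    """Exhaustive recursive enumeration of water-only simple paths."""
    found = set()

    def walk(node, visited, n_internal):
        for nxt in graph.neighbors(node):
            if nxt in sinks:
                found.add(frozenset(visited[1:]))
            if nxt in waters and nxt not in visited and n_internal < max_waters:
                walk(nxt, visited + [nxt], n_internal + 1)

    for s in sources:
        if graph.has_node(s):
            walk(s, [s], 0)
    return found


@pytest.mark.parametrize("seed", range(15))
def test_enumeration_matches_dfs_oracle(seed):
    rng = np.random.default_rng(seed)
    n_waters = int(rng.integers(5, 26))  # total nodes <= 30
    topo = make_graph_topology(n_waters)
    g = nx.gnp_random_graph(topo.n_atoms, 0.15, seed=seed)
    endpoints = WireEndpoints(max_waters=6)
    wires = find_wires(g, topo, endpoints)
    got = {w.water_set for w in wires}
    expected = dfs_oracle(g, {0, 1}, {2, 3}, set(range(5, topo.n_atoms)), 6)
    assert got == expected
    # every wire re-validates edge by edge, endpoints correct
    for w in wires:
        assert w.node_path[0] in (0, 1) and w.node_path[-1] in (2, 3)
        for a, b in zip(w.node_path, w.node_path[1:]):
            assert g.has_edge(a, b)
        assert all(topo.is_water(i) for i in w.node_path[1:-1])


def test_no_connectivity_yields_no_wires():
    topo = make_graph_topology(4)
    g = nx.Graph()
    g.add_nodes_from(range(topo.n_atoms))
    g.add_edge(0, 5)
    g.add_edge(6, 2)
    assert find_wires(g, topo, WireEndpoints()) == []


def test_path_through_sidechain_heteroatom_is_not_a_wire():
    """Internal nodes must be waters: a chain routed via Ser767 OG is rejected."""
    topo = make_graph_topology(2)
    g = nx.Graph()
    g.add_nodes_from(range(topo.n_atoms))
    nx.add_path(g, [0, 5, 4, 6, 2])  # water, OG, water
    assert find_wires(g, topo, WireEndpoints()) == []
    g2 = nx.Graph()
    g2.add_nodes_from(range(topo.n_atoms))
    nx.add_path(g2, [0, 5, 6, 2])  # all-water interior
    wires = find_wires(g2, topo, WireEndpoints())
    assert len(wires) == 1 and wires[0].water_count == 2


def test_deduplication_by_water_set_across_endpoint_atoms():
    topo = make_graph_topology(3)
    g = nx.Graph()
    g.add_nodes_from(range(topo.n_atoms))
    for src in (0, 1):
        g.add_edge(src, 5)
    nx.add_path(g, [5, 6, 7])
    for snk in (2, 3):
        g.add_edge(7, snk)
    wires = find_wires(g, topo, WireEndpoints())
    assert len(wires) == 1
    assert wires[0].water_set == frozenset({5, 6, 7})


@pytest.mark.parametrize("seed", range(5))
def test_raising_max_waters_never_reduces_wire_count(seed):
    topo = make_graph_topology(12)
    g = nx.gnp_random_graph(topo.n_atoms, 0.2, seed=100 + seed)
    counts = [len(find_wires(g, topo, WireEndpoints(max_waters=m))) for m in (2, 4, 6, 8)]
    assert counts == sorted(counts)


def _wire(waters, t=0.0):
    return WaterWire(frame_time=t, node_path=(0, *waters, 2))


# --- tracking -------------------------------------------------------------

def test_single_frame_event_has_spacing_lifetime():
    events = track_wires([[_wire((5, 6))], [], []], [0.0, 10.0, 20.0])
    assert len(events) == 1
    assert events[0].lifetime == pytest.approx(10.0)


def test_contiguous_frames_accumulate_lifetime():
    per_frame = [[] for _ in range(30)]
    for k in range(5, 25):  # frames 5..24 inclusive at 10 ps
        per_frame[k] = [_wire((5, 6, 7))]
    events = track_wires(per_frame, [10.0 * k for k in range(30)])
    assert len(events) == 1
    assert events[0].lifetime == pytest.approx(200.0)
    assert events[0].n_frames == 20


def test_gap_splits_event():
    per_frame = [[], [], [], [_wire((5, 6))], [], [_wire((5, 6))]]
    events = track_wires(per_frame, [10.0 * k for k in range(6)])
    assert len(events) == 2


def test_changed_water_set_starts_new_event():
    per_frame = [[_wire((5, 6))], [_wire((5, 7))]]
    events = track_wires(per_frame, [0.0, 10.0])
    assert len(events) == 2


def test_path_identity_mode_stricter_than_set_mode():
    a = WaterWire(0.0, (0, 5, 6, 2))
    b = WaterWire(10.0, (0, 6, 5, 2))  # same set, different order
    assert len(track_wires([[a], [b]], [0.0, 10.0], identity_mode="set")) == 1
    assert len(track_wires([[a], [b]], [0.0, 10.0], identity_mode="path")) == 2


def test_jaccard_mode_bridges_small_composition_changes():
    a = _wire((5, 6, 7, 8, 9))
    b = WaterWire(10.0, (0, 5, 6, 7, 8, 10, 2))  # jaccard 4/6 = 0.67
    assert len(track_wires([[a], [b]], [0.0, 10.0], identity_mode="jaccard",
                           jaccard_threshold=0.6)) == 1
    assert len(track_wires([[a], [b]], [0.0, 10.0], identity_mode="jaccard",
                           jaccard_threshold=0.8)) == 2


def test_non_uniform_spacing_rejected():
    with pytest.raises(ConfigError):
        track_wires([[], [], []], [0.0, 10.0, 25.0])


def test_conservation_of_frame_counts(small_wire_run):
    """Sum of event frame counts equals the per-frame wire total (no loss/overlap)."""
    from porewire.pipeline import RunConfig, per_frame_wires

    traj = small_wire_run
    wires = per_frame_wires(traj.frames, traj.topology, RunConfig(structure="x"))
    events = track_wires(wires, [f.time for f in traj.frames])
    assert sum(e.n_frames for e in events) == sum(len(w) for w in wires)


# --- statistics and presence ---------------------------------------------

def test_statistics_on_planted_mixture(small_wire_run):
    from porewire.pipeline import RunConfig, per_frame_wires

    traj = small_wire_run
    wires = per_frame_wires(traj.frames, traj.topology, RunConfig(structure="x"))
    events = track_wires(wires, [f.time for f in traj.frames])
    stats = wire_statistics(events)
    assert stats.n_events == len(traj.ground_truth.events) == 20
    assert stats.length_histogram == {6: 15, 7: 5}
    assert stats.dominant_length == 6
    assert stats.lifetime_quantiles["q0"] >= 150.0
    assert stats.lifetime_quantiles["q100"] <= 250.0
    assert stats.n_stable == 20


def test_empty_and_single_event_statistics():
    empty = wire_statistics([])
    assert empty.n_events == 0 and empty.dominant_length is None
    one = track_wires([[_wire((5,))]], [0.0])
    stats = wire_statistics(one)
    qs = set(stats.lifetime_quantiles.values())
    assert len(qs) == 1


def test_presence_series_and_first_passage():
    per_frame = [[], [], [_wire((5,))], [_wire((5,))]]
    presence, first = wire_presence_series(per_frame, [0.0, 10.0, 20.0, 30.0])
    assert presence.tolist() == [0, 0, 1, 1]
    assert first == 20.0
    presence0, first0 = wire_presence_series([[], []], [0.0, 10.0])
    assert presence0.tolist() == [0, 0]
    assert first0 is None
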