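"""Water-wire enumeration, temporal event tracking and lifetime statistics.

A water wire is a simple path in the per-frame hydrogen-bond graph that
starts on a source atom (default: Glu908 carboxylate oxygens), ends on a
sink atom (default: Glu918 carboxylate oxygens) and passes exclusively
through water oxygens. Wires are deduplicated by their internal water set,
so a chain reachable from either carboxylate oxygen of an endpoint counts
once.

Across frames, wires with the same (unordered) internal water set in
contiguous sampled frames form one event; an event observed for k frames at
spacing Δt has lifetime k·Δt, so a single-frame observation has the
sampling resolution as its lifetime. No gap tolerance is applied by
default. A stricter ordered-path identity and a looser Jaccard-overlap
identity are available as options.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .model import ConfigError, SelectionError, Topology
from .pore import AtomSelector

__all__ = [
    "WireEndpoints",
    "WaterWire",
    "WireEvent",
    "WireStatistics",
    "find_wires",
    "track_wires",
    "wire_statistics",
    "wire_presence_series",
]


@dataclass
class WireEndpoints:
    """Source/sink atom groups bounding a wire, and the length cap."""

    source: AtomSelector = field(default_factory=lambda: AtomSelector("A", 908, ("OE1", "OE2")))
    sink: AtomSelector = field(default_factory=lambda: AtomSelector("A", 918, ("OE1", "OE2")))
    max_waters: int = 8

    def __post_init__(self) -> None:
        if self.max_waters < 1:
            raise ConfigError("max_waters must be >= 1")

    def resolve(self, topology: Topology) -> tuple[set[int], set[int]]:
        src = {int(i) for i in self.source.resolve(topology)}
        snk = {int(i) for i in self.sink.resolve(topology)}
        if src & snk:
            raise SelectionError("source and sink atom sets overlap")
        return src, snk


@dataclass(frozen=True)
class WaterWire:
    """One endpoint-to-endpoint water chain in one frame."""

    frame_time: float
    node_path: tuple[int, ...]

    @property
    def water_count(self) -> int:
        return len(self.node_path) - 2

    @property
    def water_set(self) -> frozenset[int]:
        return frozenset(self.node_path[1:-1])


def find_wires(
    graph: nx.Graph,
    topology: Topology,
    endpoints: WireEndpoints,
    frame_time: float = 0.0,
) -> list[WaterWire]:
    """All water-only simple paths from any source to any sink atom.

    Paths are deduplicated by internal water set and returned in a
    deterministic order (water count, then lexicographic node ordinals).
    """
    src, snk = endpoints.resolve(topology)
    waters = {int(i) for i in topology.water_oxygens() if graph.has_node(int(i))}
    allowed = waters | src | snk

    # restrict the search graph: internal hops may only touch waters
    sub = graph.subgraph(n for n in graph.nodes if n in allowed)

    best: dict[frozenset[int], tuple[int, ...]] = {}
    cutoff = endpoints.max_waters + 1  # edges per path
    for s in sorted(src & set(sub.nodes)):
        for t in sorted(snk & set(sub.nodes)):
            for path in nx.all_simple_paths(sub, s, t, cutoff=cutoff):
                if any(p in src or p in snk for p in path[1:-1]):
                    continue
                if not all(p in waters for p in path[1:-1]):
                    continue
                key = frozenset(path[1:-1])
                cand = tuple(path)
                if key not in best or cand < best[key]:
                    best[key] = cand
    ordered = sorted(best.values(), key=lambda p: (len(p) - 2, p))
    return [WaterWire(frame_time=frame_time, node_path=p) for p in ordered]


@dataclass
class WireEvent:
    """Persistence of one wire identity across contiguous sampled frames."""

    start_time: float
    end_time: float
    frame_spacing: float
    water_set: frozenset[int]
    representative_path: tuple[int, ...]
    n_frames: int

    @property
    def lifetime(self) -> float:
        return self.end_time - self.start_time + self.frame_spacing

    @property
    def water_count(self) -> int:
        return len(self.water_set)


def _wire_key(wire: WaterWire, mode: str):
    if mode == "path":
        return wire.node_path
    return wire.water_set


def track_wires(
    per_frame_wires: Sequence[Sequence[WaterWire]],
    times: Sequence[float],
    identity_mode: str = "set",
    jaccard_threshold: float = 0.8,
) -> list[WireEvent]:
    """Merge per-frame wires into temporal events.

    ``identity_mode``: ``"set"`` (default; identical unordered water sets),
    ``"path"`` (identical ordered node path) or ``"jaccard"`` (water-set
    Jaccard similarity ≥ ``jaccard_threshold`` links consecutive frames).
    Frames must be uniformly spaced; an event covers contiguous frames only.
    """
    times = np.asarray(times, dtype=float)
    if len(per_frame_wires) != len(times):
        raise ConfigError("per_frame_wires and times must have equal length")
    if len(times) == 0:
        return []
    if len(times) > 1:
        spacings = np.diff(times)
        if not np.allclose(spacings, spacings[0], rtol=0, atol=1e-6):
            raise ConfigError("frames are not uniformly spaced")
        spacing = float(spacings[0])
    else:
        spacing = 1.0
    if identity_mode not in ("set", "path", "jaccard"):
        raise ConfigError(f"unknown identity_mode {identity_mode!r}")

    events: list[WireEvent] = []
    open_events: dict = {}  # key -> WireEvent (still extendable)
    for k, (t, wires) in enumerate(zip(times, per_frame_wires)):
        still_open: dict = {}
        if identity_mode in ("set", "path"):
            for w in wires:
                key = _wire_key(w, identity_mode)
                ev = open_events.pop(key, None)
                if ev is not None and np.isclose(ev.end_time + spacing, t, atol=1e-6):
                    ev.end_time = t
                    ev.n_frames += 1
                else:
                    if ev is not None:
                        events.append(ev)
                    ev = WireEvent(t, t, spacing, w.water_set, w.node_path, 1)
                still_open[key] = ev
        else:  # jaccard linking, greedy best-overlap
            unmatched = list(wires)
            for key, ev in list(open_events.items()):
                if not np.isclose(ev.end_time + spacing, t, atol=1e-6):
                    continue
                scored = []
                for w in unmatched:
                    inter = len(ev.water_set & w.water_set)
                    union = len(ev.water_set | w.water_set)
                    jac = inter / union if union else 0.0
                    if jac >= jaccard_threshold:
                        scored.append((jac, tuple(w.node_path), w))
                if scored:
                    scored.sort(key=lambda x: (-x[0], x[1]))
                    w = scored[0][2]
                    unmatched.remove(w)
                    ev.end_time = t
                    ev.n_frames += 1
                    ev.water_set = w.water_set
                    still_open[w.water_set] = ev
                    open_events.pop(key, None)
            for w in unmatched:
                still_open.setdefault(w.water_set, WireEvent(t, t, spacing, w.water_set, w.node_path, 1))
        # events that did not extend into this frame are closed
        for key, ev in open_events.items():
            events.append(ev)
        open_events = still_open
    events.extend(open_events.values())
    events.sort(key=lambda e: (e.start_time, tuple(sorted(e.water_set))))
    return events


@dataclass
class WireStatistics:
    """Summary over wire events."""

    n_events: int
    length_histogram: dict[int, int]
    dominant_length: int | None
    lifetime_quantiles: dict[str, float]
    n_stable: int
    stable_threshold_ps: float


def wire_statistics(events: Sequence[WireEvent], stable_threshold_ps: float = 150.0) -> WireStatistics:
    """Event count, water-count histogram, lifetime quantiles, stable count."""
    if not events:
        return WireStatistics(0, {}, None, {"q0": 0.0, "q25": 0.0, "q50": 0.0, "q75": 0.0, "q100": 0.0},
                              0, stable_threshold_ps)
    lengths: dict[int, int] = {}
    for e in events:
        lengths[e.water_count] = lengths.get(e.water_count, 0) + 1
    dominant = max(sorted(lengths), key=lambda k: lengths[k])
    lifetimes = np.array([e.lifetime for e in events])
    qs = np.percentile(lifetimes, [0, 25, 50, 75, 100])
    return WireStatistics(
        n_events=len(events),
        length_histogram=dict(sorted(lengths.items())),
        dominant_length=int(dominant),
        lifetime_quantiles={k: float(v) for k, v in zip(("q0", "q25", "q50", "q75", "q100"), qs)},
        n_stable=int((lifetimes >= stable_threshold_ps).sum()),
        stable_threshold_ps=stable_threshold_ps,
    )


def wire_presence_series(
    per_frame_wires: Sequence[Sequence[WaterWire]],
    times: Sequence[float],
) -> tuple[np.ndarray, float | None]:
    """Binary wire-presence series and the first-passage time of formation.

    Returns ``(presence, first_passage)``; ``first_passage`` is ``None``
    when no wire ever forms (the closed-pore phenotype).
    """
    times = np.asarray(times, dtype=float)
    presence = np.array([1 if len(w) else 0 for w in per_frame_wires], dtype=int)
    if presence.any():
        first = float(times[int(np.argmax(presence))])
    else:
        first = None
    return presence, first


def events_to_table(events: Sequence[WireEvent]) -> list[dict]:
    """Rows for the per-event TSV (start, end, lifetime, length, water ids)."""
    return [
        {
            "start_ps": e.start_time,
            "end_ps": e.end_time,
            "lifetime_ps": e.lifetime,
            "water_count": e.water_count,
            "water_ordinals": ",".join(str(i) for i in sorted(e.water_set)),
        }
        for e in events
    ]
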