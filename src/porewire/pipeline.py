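"""Orchestration: one configuration → hydration, wires and helix geometry.

The three analyses mirror the three questions asked of the pump's
trajectories: does the C-terminal pore hydrate, do hydrogen-bonded water
wires bridge Glu908 and Glu918, and does the M5 hinge close the pore. Every
number in the report is also written to a TSV next to it. All
residue-resolving configuration is validated before any trajectory frame is
touched (fail fast).

Paper-unspecified defaults (H-bond cutoffs, cylinder radius and padding,
helix flank ranges) are surfaced in :class:`RunConfig` and documented in
``docs/methods.md``.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
import time as _time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from . import io as pio
from .hbonds import HBondCriteria, build_graph, detect_hbonds
from .helix import HelixBendSpec, geometry_timeseries
from .model import ConfigError, Frame, SelectionError, Topology
from .pore import (
    AtomSelector,
    PoreDefinition,
    hydration_timeseries,
    match_crystal_waters,
    superpose,
    waters_in_pore,
)
from .wires import (
    WireEndpoints,
    events_to_table,
    find_wires,
    track_wires,
    wire_presence_series,
    wire_statistics,
)

__all__ = ["RunConfig", "run", "default_sidechain_nodes", "per_frame_wires"]


def default_sidechain_nodes(chain: str = "A") -> tuple[AtomSelector, ...]:
    """Polar side-chain atoms of the proton-pathway residues (H-bond graph nodes)."""
    return (
        AtomSelector(chain, 908, ("OE1", "OE2")),
        AtomSelector(chain, 918, ("OE1", "OE2")),
        AtomSelector(chain, 767, ("OG",)),
        AtomSelector(chain, 911, ("OD1", "ND2")),
        AtomSelector(chain, 836, ("NE", "NH1", "NH2")),
        AtomSelector(chain, 837, ("OH",)),
    )


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    structure: str
    trajectory: str | None = None
    output_dir: str = "porewire_out"
    stride_ps: float | None = None
    interval_ps: float | None = None
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    pore: PoreDefinition = field(default_factory=PoreDefinition)
    endpoints: WireEndpoints = field(default_factory=WireEndpoints)
    helix: HelixBendSpec = field(default_factory=HelixBendSpec)
    sidechain_nodes: tuple[AtomSelector, ...] = field(default_factory=default_sidechain_nodes)
    windows: tuple[tuple[float, float], ...] = ()
    stable_threshold_ps: float = 150.0
    crystal_structure: str | None = None
    overlap_cutoff: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def sel(d) -> AtomSelector:
            return AtomSelector(d.get("chain", "A"), int(d["resid"]), tuple(d["names"]))

        kw: dict = {}
        for key in ("structure", "trajectory", "output_dir", "stride_ps", "interval_ps",
                    "stable_threshold_ps", "crystal_structure", "overlap_cutoff", "seed"):
            if key in raw:
                kw[key] = raw[key]
        if "structure" not in kw:
            raise ConfigError("config must name a structure file")
        if "criteria" in raw:
            kw["criteria"] = HBondCriteria(**raw["criteria"])
        if "pore" in raw:
            p = dict(raw["pore"])
            if "axis_start" in p:
                p["axis_start"] = sel(p["axis_start"])
            if "axis_end" in p:
                p["axis_end"] = sel(p["axis_end"])
            if "lining_residues" in p:
                p["lining_residues"] = tuple(
                    (c, int(r)) for c, r in p["lining_residues"]
                )
            kw["pore"] = PoreDefinition(**p)
        if "endpoints" in raw:
            e = dict(raw["endpoints"])
            if "source" in e:
                e["source"] = sel(e["source"])
            if "sink" in e:
                e["sink"] = sel(e["sink"])
            kw["endpoints"] = WireEndpoints(**e)
        if "helix" in raw:
            h = dict(raw["helix"])
            for rng in ("pre_hinge", "post_hinge", "hinge"):
                if rng in h:
                    h[rng] = tuple(h[rng])
            for grp in ("contact_a", "contact_b"):
                if grp in h:
                    h[grp] = sel(h[grp])
            kw["helix"] = HelixBendSpec(**h)
        if "sidechain_nodes" in raw:
            kw["sidechain_nodes"] = tuple(sel(d) for d in raw["sidechain_nodes"])
        if "windows" in raw:
            kw["windows"] = tuple((float(a), float(b)) for a, b in raw["windows"])
        return cls(**kw)

    def validate(self, topology: Topology) -> None:
        """Resolve every configured residue before any analysis starts."""
        self.pore.axis_start.resolve(topology)
        self.pore.axis_end.resolve(topology)
        self.endpoints.resolve(topology)
        for s in self.sidechain_nodes:
            s.resolve(topology)
        self.helix.flank_atoms(topology, "pre")
        self.helix.flank_atoms(topology, "post")
        self.helix.contact_a.resolve(topology)
        self.helix.contact_b.resolve(topology)
        for chain, resid in self.pore.lining_residues:
            topology.residue_atoms(resid, chain=chain)


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def graph_nodes(topology: Topology, sidechain_nodes: Sequence[AtomSelector]) -> np.ndarray:
    parts = [topology.water_oxygens()]
    for s in sidechain_nodes:
        parts.append(s.resolve(topology))
    return np.unique(np.concatenate(parts))


def per_frame_wires(frames: Sequence[Frame], topology: Topology, config: RunConfig):
    """H-bond graph and wire enumeration for every frame."""
    nodes = graph_nodes(topology, config.sidechain_nodes)
    out = []
    for frame in frames:
        g = build_graph(detect_hbonds(frame, topology, config.criteria, nodes), nodes)
        out.append(find_wires(g, topology, config.endpoints, frame_time=frame.time))
    return out


def run(config: RunConfig, frames: Sequence[Frame] | None = None,
        topology: Topology | None = None) -> dict:
    """Execute all analysis stages; returns the consolidated report dict.

    ``frames``/``topology`` may be supplied directly (e.g. from the
    synthetic generator); otherwise they are loaded from the configured
    paths.
    """
    t0 = _time.monotonic()
    if topology is None or frames is None:
        topology, struct_frames = pio.load_structure(config.structure)
        if config.trajectory:
            frames = pio.load_trajectory(topology, config.trajectory,
                                         stride_ps=config.stride_ps,
                                         structure_path=config.structure)
        else:
            frames = struct_frames
    config.validate(topology)
    os.makedirs(config.output_dir, exist_ok=True)
    _log(f"[porewire] {len(frames)} frames, {topology.n_atoms} atoms")

    times = np.array([f.time for f in frames])

    # --- hydration -----------------------------------------------------
    stage = _time.monotonic()
    hyd = hydration_timeseries(frames, topology, config.pore,
                               interval_ps=config.interval_ps)
    pio.write_table(
        {"time_ps": hyd.times, "n_waters": hyd.counts},
        os.path.join(config.output_dir, "hydration.tsv"),
    )
    hydration_summary = {
        "mean": float(hyd.counts.mean()),
        "min": int(hyd.counts.min()),
        "max": int(hyd.counts.max()),
        "window_means": [
            {"t_start_ps": a, "t_end_ps": b, "mean": hyd.window_mean(a, b)}
            for a, b in config.windows
        ],
    }
    _log(f"[porewire] hydration done in {_time.monotonic() - stage:.1f}s")

    # --- wires ---------------------------------------------------------
    stage = _time.monotonic()
    wires = per_frame_wires(frames, topology, config)
    events = track_wires(wires, times)
    stats = wire_statistics(events, stable_threshold_ps=config.stable_threshold_ps)
    presence, first_passage = wire_presence_series(wires, times)
    pio.write_table(events_to_table(events),
                    os.path.join(config.output_dir, "wire_events.tsv"),
                    columns=["start_ps", "end_ps", "lifetime_ps", "water_count",
                             "water_ordinals"] if events else None)
    pio.write_table({"time_ps": times, "wire_present": presence},
                    os.path.join(config.output_dir, "wire_presence.tsv"))
    wire_summary = {
        "n_events": stats.n_events,
        "length_histogram": stats.length_histogram,
        "dominant_length": stats.dominant_length,
        "lifetime_quantiles_ps": stats.lifetime_quantiles,
        "n_stable": stats.n_stable,
        "stable_threshold_ps": stats.stable_threshold_ps,
        "first_passage_ps": first_passage,
    }
    _log(f"[porewire] wires done in {_time.monotonic() - stage:.1f}s "
         f"({stats.n_events} events)")

    # --- helix geometry ------------------------------------------------
    stage = _time.monotonic()
    geo = geometry_timeseries(frames, topology, config.helix)
    pio.write_table(
        {
            "time_ps": geo.times,
            "bend_angle_deg": geo.bend_angle,
            "contact_distance_A": geo.contact_distance,
            "backbone_hbond_distance_A": geo.backbone_hbond_distance,
        },
        os.path.join(config.output_dir, "geometry.tsv"),
    )
    geometry_summary = {
        "bend_angle_final_deg": float(geo.bend_angle[-1]),
        "bend_angle_mean_deg": float(geo.bend_angle.mean()),
        "contact_final_A": float(geo.contact_distance[-1]),
        "backbone_final_A": float(geo.backbone_hbond_distance[-1]),
        "window_means": [
            {
                "t_start_ps": a,
                "t_end_ps": b,
                "bend_angle_deg": geo.window_mean("bend_angle", a, b),
                "contact_distance_A": geo.window_mean("contact_distance", a, b),
                "backbone_hbond_distance_A": geo.window_mean("backbone_hbond_distance", a, b),
            }
            for a, b in config.windows
        ],
    }
    _log(f"[porewire] helix geometry done in {_time.monotonic() - stage:.1f}s")

    # --- crystal overlap (optional) ------------------------------------
    overlap_summary = None
    if config.crystal_structure:
        cry_topo, cry_frames = pio.load_structure(config.crystal_structure)
        cry_frame = cry_frames[0]
        # superpose on shared CA atoms, then match final-frame pore waters
        shared = [
            (a.chain, a.resid, a.name)
            for a in cry_topo.atoms
            if a.name == "CA"
        ]
        mob_idx, ref_idx = [], []
        for key in shared:
            try:
                ref_idx.append(topology.atom(*key))
                mob_idx.append(cry_topo.atom(*key))
            except SelectionError:
                continue
        last = frames[-1]
        if len(mob_idx) >= 3:
            # move the crystal onto the simulation frame
            aligned = Frame(time=0.0, coords=cry_frame.coords.copy())
            tmp = Frame(time=0.0, coords=cry_frame.coords)
            moved, fit_rmsd = _superpose_subset(tmp, last, mob_idx, ref_idx)
            aligned = moved
        else:
            aligned, fit_rmsd = cry_frame, 0.0
        sim_waters = sorted(waters_in_pore(last, topology, config.pore))
        cry_waters = [int(i) for i in cry_topo.water_oxygens()]
        res = match_crystal_waters(last, sim_waters, aligned, cry_waters,
                                   cutoff=config.overlap_cutoff)
        pio.write_table(
            [
                {"sim_ordinal": s, "crystal_ordinal": c, "displacement_A": round(d, 3)}
                for s, c, d in res.matches
            ],
            os.path.join(config.output_dir, "overlap.tsv"),
            columns=["sim_ordinal", "crystal_ordinal", "displacement_A"] if res.matches else None,
        )
        overlap_summary = {
            "n_matches": res.n_matched,
            "n_crystal_waters": len(cry_waters),
            "n_sim_pore_waters": len(sim_waters),
            "cutoff_A": res.cutoff,
            "superposition_rmsd_A": fit_rmsd,
        }

    report = {
        "provenance": {
            "config_hash": hashlib.sha256(
                json.dumps(_config_fingerprint(config), sort_keys=True).encode()
            ).hexdigest()[:16],
            "seed": config.seed,
            "n_frames": int(len(frames)),
            "n_atoms": int(topology.n_atoms),
        },
        "hydration": hydration_summary,
        "wires": wire_summary,
        "geometry": geometry_summary,
        "overlap": overlap_summary,
    }
    with open(os.path.join(config.output_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    _log(f"[porewire] total {_time.monotonic() - t0:.1f}s")
    return report


def _superpose_subset(mobile: Frame, reference: Frame,
                      mob_idx: list[int], ref_idx: list[int]) -> tuple[Frame, float]:
    """Kabsch fit where mobile and reference index different topologies."""
    x = mobile.coords[mob_idx]
    y = reference.coords[ref_idx]
    xc, yc = x - x.mean(axis=0), y - y.mean(axis=0)
    u, _, vt = np.linalg.svd(xc.T @ yc)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, sign]) @ u.T
    moved = (mobile.coords - x.mean(axis=0)) @ rot.T + y.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((moved[mob_idx] - y) ** 2, axis=1))))
    return Frame(time=mobile.time, coords=moved), rmsd


def _config_fingerprint(config: RunConfig) -> dict:
    skip = {"output_dir"}  # analysis parameters only, not output placement

    def plain(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: plain(getattr(obj, k))
                    for k in obj.__dataclass_fields__ if k not in skip}
        if isinstance(obj, (list, tuple)):
            return [plain(x) for x in obj]
        if isinstance(obj, (str, int, float, bool)) or obj is None:
            return obj
        return str(obj)

    return plain(config)
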