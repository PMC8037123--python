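"""Pore hydration counting, crystal-water matching, superposition and RMSD."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi

from porewire.model import ConfigError, Frame, GeometryError
from porewire.pore import (
    PoreDefinition,
    hydration_timeseries,
    match_crystal_waters,
    residue_rmsd_series,
    superpose,
    waters_in_pore,
    waters_near_lining,
)
from porewire.synth import ScenarioSpec, generate_trajectory

from conftest import apply_rigid, random_rigid_motion


# --- waters_in_pore -------------------------------------------------------

def test_empty_pore_and_planted_waters(closure_run):
    traj = closure_run
    pore = PoreDefinition()
    counts = [len(waters_in_pore(f, traj.topology, pore)) for f in traj.frames]
    assert counts == traj.ground_truth.occupancy


def test_pore_boundary_is_closed():
    spec = ScenarioSpec.two_phase_hydration(seed=0, n_frames=2, counts=(1, 1))
    spec = ScenarioSpec(**{**spec.__dict__, "noise_sigma_A": 0.0})
    traj = generate_trajectory(spec)
    topo = traj.topology
    pore = PoreDefinition()
    frame = traj.frames[0]
    # move the single pore water exactly onto the cylinder wall
    ow = topo.atom("W", traj.ground_truth.pore_water_resids[0][0], "OW")
    p0 = frame.coords[topo.atom("A", 908, "CD")]
    p1 = frame.coords[topo.atom("A", 918, "CD")]
    axis = (p1 - p0) / np.linalg.norm(p1 - p0)
    mid = (p0 + p1) / 2
    radial = np.cross(axis, [0.0, 0.0, 1.0])
    radial = np.array([1.0, 0.0, 0.0]) if np.linalg.norm(radial) < 1e-6 else radial
    radial = radial - axis * (radial @ axis)
    radial /= np.linalg.norm(radial)
    frame.coords[ow] = mid + pore.cylinder_radius * radial
    assert ow in waters_in_pore(frame, topo, pore)
    frame.coords[ow] = mid + (pore.cylinder_radius + 1e-6) * radial
    assert ow not in waters_in_pore(frame, topo, pore)


def test_pore_count_invariant_under_rigid_motion(closure_run):
    traj = closure_run
    pore = PoreDefinition()
    frame = traj.frames[-1]
    before = {traj.topology.water_resid_of(i) for i in waters_in_pore(frame, traj.topology, pore)}
    rot, t = random_rigid_motion(3)
    moved = apply_rigid(frame, rot, t)
    after = {traj.topology.water_resid_of(i) for i in waters_in_pore(moved, traj.topology, pore)}
    assert before == after


def test_lining_proximity_mode_sees_planted_waters(closure_run):
    traj = closure_run
    frame = traj.frames[0]
    near = waters_near_lining(frame, traj.topology, PoreDefinition())
    planted = {traj.topology.atom("W", r, "OW")
               for r in traj.ground_truth.pore_water_resids[0]}
    assert planted <= near


# --- hydration_timeseries -------------------------------------------------

def test_two_phase_window_means_exact():
    traj = generate_trajectory(ScenarioSpec.two_phase_hydration(seed=1))
    series = hydration_timeseries(traj.frames, traj.topology, PoreDefinition())
    total = traj.spec.n_frames * traj.spec.frame_spacing_ps
    assert series.window_mean(0.0, total / 2 - 1) == 4.0
    assert series.window_mean(total / 2, total) == 9.0


def test_constant_and_empty_series():
    spec = ScenarioSpec.two_phase_hydration(seed=2, n_frames=10, counts=(4, 4))
    traj = generate_trajectory(spec)
    series = hydration_timeseries(traj.frames, traj.topology, PoreDefinition())
    assert series.counts.tolist() == [4] * 10
    empty = ScenarioSpec.two_phase_hydration(seed=2, n_frames=10, counts=(0, 0))
    traj0 = generate_trajectory(empty)
    s0 = hydration_timeseries(traj0.frames, traj0.topology, PoreDefinition())
    assert s0.counts.tolist() == [0] * 10


def test_interval_below_frame_spacing_rejected(closure_run):
    traj = closure_run
    with pytest.raises(ConfigError):
        hydration_timeseries(traj.frames, traj.topology, PoreDefinition(), interval_ps=1.0)


def test_counts_match_naive_recount(closure_run):
    """Cylinder membership agrees with an independent per-water recount."""
    traj = closure_run
    pore = PoreDefinition()
    topo = traj.topology
    for frame in traj.frames[::17]:
        p0 = frame.coords[topo.atom("A", 908, "CD")]
        p1 = frame.coords[topo.atom("A", 918, "CD")]
        axis = p1 - p0
        L = np.linalg.norm(axis)
        u = axis / L
        n = 0
        for ow in topo.water_oxygens():
            rel = frame.coords[ow] - p0
            t = rel @ u
            r = np.linalg.norm(rel - t * u)
            if -pore.axis_padding <= t <= L + pore.axis_padding and r <= pore.cylinder_radius:
                n += 1
        assert n == len(waters_in_pore(frame, topo, pore))


# --- crystal-water matching ----------------------------------------------

def _cloud_frames(sim_pts, cry_pts):
    return (Frame(time=0.0, coords=np.asarray(sim_pts, float)),
            Frame(time=0.0, coords=np.asarray(cry_pts, float)))


def test_identical_coordinates_match_at_zero():
    pts = np.random.default_rng(0).uniform(0, 10, (4, 3))
    sim, cry = _cloud_frames(pts, pts)
    res = match_crystal_waters(sim, range(4), cry, range(4))
    assert res.n_matched == 4
    assert all(d == pytest.approx(0.0) for *_, d in res.matches)


def test_beyond_cutoff_is_unmatched():
    sim, cry = _cloud_frames([[0, 0, 0]], [[2.5, 0, 0]])
    res = match_crystal_waters(sim, [0], cry, [0], cutoff=2.0)
    assert res.n_matched == 0
    assert res.unmatched_crystal == [0]


@pytest.mark.parametrize("seed", range(20))
def test_greedy_matching_equals_optimal_assignment(seed):
    """On <=10-water instances greedy matching attains the optimal match count."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 11))
    sim_pts = rng.uniform(0, 8, (n, 3))
    cry_pts = sim_pts + rng.normal(0, 1.2, (n, 3))
    sim, cry = _cloud_frames(sim_pts, cry_pts)
    res = match_crystal_waters(sim, range(n), cry, range(n), cutoff=2.0)
    d = np.linalg.norm(sim_pts[:, None] - cry_pts[None, :], axis=2)
    # Hungarian oracle: maximize the number of pairs strictly under cutoff
    cost = np.where(d < 2.0, 0.0, 1.0)
    rows, cols = linear_sum_assignment(cost)
    optimal = int((cost[rows, cols] == 0).sum())
    assert res.n_matched == optimal
    assert all(disp < 2.0 for *_, disp in res.matches)


@pytest.mark.parametrize("seed", range(5))
def test_shrinking_cutoff_never_gains_matches(seed):
    rng = np.random.default_rng(seed + 50)
    sim_pts = rng.uniform(0, 8, (6, 3))
    cry_pts = sim_pts + rng.normal(0, 1.0, (6, 3))
    sim, cry = _cloud_frames(sim_pts, cry_pts)
    counts = [match_crystal_waters(sim, range(6), cry, range(6), cutoff=c).n_matched
              for c in (2.5, 2.0, 1.5, 1.0, 0.5)]
    assert counts == sorted(counts, reverse=True)
    assert all(c <= 6 for c in counts)


# --- superposition & residue RMSD ----------------------------------------

def test_superpose_identity_and_rigid_motion(scaffold):
    topo, frame = scaffold
    _, rmsd = superpose(frame, frame, list(range(topo.n_atoms)))
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    rot, t = random_rigid_motion(9)
    moved = apply_rigid(frame, rot, t)
    back, rmsd = superpose(moved, frame, list(range(topo.n_atoms)))
    assert rmsd == pytest.approx(0.0, abs=1e-6)
    assert np.abs(back.coords - frame.coords).max() < 1e-6


def test_superpose_half_displaced_cube_closed_form():
    """Displacing half of a centred cube by d along x gives RMSD d/2.

    For this construction the cross-covariance is symmetric positive
    definite, so the optimal rotation is the identity and the residual per
    atom is exactly +/- d/2 along x.
    """
    cube = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
                    dtype=float)
    mobile = cube.copy()
    mobile[cube[:, 0] > 0] += [1.0, 0.0, 0.0]
    _, rmsd = superpose(Frame(0.0, mobile), Frame(0.0, cube), list(range(8)))
    assert rmsd == pytest.approx(0.5, abs=1e-9)


def test_superpose_rejects_degenerate_fits(scaffold):
    topo, frame = scaffold
    with pytest.raises(GeometryError):
        superpose(frame, frame, [0, 1])
    collinear = Frame(0.0, np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float))
    with pytest.raises(GeometryError):
        superpose(collinear, collinear, [0, 1, 2])


def test_residue_rmsd_static_trajectory_is_zero(scaffold):
    topo, frame = scaffold
    fit = topo.select(chain="A", names=("CA",))
    mean, sd, _ = residue_rmsd_series([frame, frame, frame], topo, 836, frame, fit)
    assert mean == pytest.approx(0.0, abs=1e-9)
    assert sd == pytest.approx(0.0, abs=1e-9)


def test_residue_rmsd_gaussian_jitter_matches_chi_expectation(scaffold):
    """iid N(0, sigma^2) jitter on an m-atom residue: RMSD ~ sigma*chi(3m)/sqrt(m)."""
    topo, frame = scaffold
    rng = np.random.default_rng(12)
    sigma = 0.3
    res = topo.residue_atoms(836, chain="A")
    m = len(res)
    fit = topo.select(chain="A", names=("CA",))
    n_frames = 400
    frames = []
    for _ in range(n_frames):
        c = frame.coords.copy()
        c[res] += rng.normal(0, sigma, (m, 3))
        frames.append(Frame(0.0, c))
    mean, _, _ = residue_rmsd_series(frames, topo, 836, frame, fit)
    expected = sigma * chi.mean(3 * m) / np.sqrt(m)
    se = sigma * chi.std(3 * m) / np.sqrt(m) / np.sqrt(n_frames)
    assert abs(mean - expected) < 3 * se


def test_residue_rmsd_monotone_under_planted_drift(scaffold):
    topo, frame = scaffold
    res = topo.residue_atoms(836, chain="A")
    fit = topo.select(chain="A", names=("CA",))
    frames = []
    for i in range(8):
        c = frame.coords.copy()
        c[res] += [0.15 * i, 0.0, 0.0]
        frames.append(Frame(float(i), c))
    _, _, per_frame = residue_rmsd_series(frames, topo, 836, frames[0], fit)
    assert np.all(np.diff(per_frame) > 0)
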