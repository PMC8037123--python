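# Methods

This note records the models, defaults and numerical choices behind each
analysis, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the underlying definitions were genuinely
open.

## Hydrogen-bond detection

A hydrogen bond is accepted geometrically: donor–acceptor heavy-atom
distance ≤ 3.5 Å and donor–H···acceptor angle (measured at the hydrogen)
≥ 150°. The literature on this pathway speaks of "hydrogen-bonded water
wires" without stating a criterion, so both thresholds are design choices
— they are the most common geometric definition in MD analysis — and both
are exposed in configuration. When hydrogens are unavailable
(crystallographic waters), `heavy_only` mode accepts on the distance
alone; mixed systems should be analysed in the mode matching their worst
component.

Donor/acceptor capability comes from a role table keyed on
(residue name, atom name): water oxygens are both donor and acceptor;
carboxylate oxygens acceptors; guanidine and amide nitrogens donors;
hydroxyls both. Hydrogen→parent connectivity is inferred geometrically
(nearest intra-residue heavy atom, ≤ 1.3 Å) at load time — no force-field
topology files are required or parsed.

Candidate pairs are found with a k-d tree (`scipy.spatial.cKDTree`, with
`boxsize` for orthorhombic periodic frames, i.e. the minimum-image
convention; plain otherwise). Tests assert exact equality of the resulting
edge set with an all-pairs brute-force evaluation, which is the guarantee
that matters; the tree is purely a speedup.

One residue-identity caveat carried from the source literature: the
pathway description once credits stabilisation to "Tyr377", a residue that
appears nowhere else, while Tyr837 appears throughout. The package treats
this as a typo for Tyr837 (its hydroxyl is a default graph node) but
records the discrepancy here rather than silently correcting it. The same
applies to two isolated mentions of "Glu318"/"Glu309" as wire endpoints
where every figure and all other text use Glu908/Glu918: the defaults are
Glu908→Glu918 and the endpoints are fully configurable, so either reading
is runnable. The gating-contact partner is implemented as Ser915 (per the
body text) although one figure label reads "Arg915".

## Water wires and events

A wire is a simple path in the per-frame H-bond graph from any source atom
(default: Glu908 carboxylate oxygens) to any sink atom (default: Glu918
carboxylate oxygens) whose internal nodes are exclusively water oxygens,
with at most `max_waters` = 8 internal waters (the observed wires have 6–7;
one of headroom). Paths are enumerated by bounded depth-first search and
deduplicated by internal water set, so a chain reachable through either
carboxylate oxygen counts once; ordering is deterministic (water count,
then lexicographic ordinals). Enumeration is verified against exhaustive
DFS on random graphs.

Wire identity across frames defaults to the strictest deterministic rule —
identical unordered water sets in contiguous sampled frames — because
"stable" is defined in the source only through a lifetime range. An
ordered-path mode (stricter) and a Jaccard ≥ 0.8 mode (looser, tolerant of
single-water exchange) are available. An event seen in k contiguous frames
at spacing Δt has lifetime k·Δt, so a single-frame observation reports the
sampling resolution; reported lifetimes of interest (150–250 ps) sit far
above any sensible frame spacing, so the convention is immaterial to
comparisons but is fixed. There is no gap tolerance: one missing frame
ends the event. Simultaneous wires sharing waters are reported separately.

## Pore hydration

The pore has no published geometric definition — only its lining residues
(Glu908, Ser767, Arg836, Tyr837, Asn911, Asn914, Glu918). The default
envelope is the minimal faithful choice: a capped cylinder of radius 5 Å
between the two endpoint carboxylate carbons, extended 2 Å beyond each
cap, with closed boundaries (a water exactly on the wall counts). An
alternative mode counts waters within 4.5 Å of any lining-residue polar
atom; when the two modes disagree a user can report both — they answer
slightly different questions (axial channel vs. first shell). Counts are
reported at a configurable interval (default: the frame spacing; intervals
below the spacing are rejected), with windowed means for user-defined time
windows.

## Crystal-water overlap

The published comparison applies an "RMSD < 2 Å" rule to individual
waters, which for a single atom reduces to a displacement bound after
superposition. The matcher maximises the number of simulation↔crystal
pairs with displacement strictly under the cutoff
(maximum-cardinality bipartite matching, Hopcroft–Karp) and reports them
in ascending displacement order. A purely greedy ascending-distance
pairing was considered and rejected: it is deterministic but can drop a
feasible match (two waters competing for one partner), and tests verify
the implemented matcher against an optimal-assignment oracle
(`scipy.optimize.linear_sum_assignment`) on small instances.
Superposition is a standard Kabsch least-squares fit (SVD with reflection
guard); per-residue positional RMSD series superpose each frame on a
configurable fit set (transmembrane Cα by default — the fit set used for
the published per-residue numbers is unstated) and then measure the
residue's heavy atoms without refitting.

## Helix geometry

The hinge-bend angle is the angle between axes fitted to the Cα atoms of
the two helix segments flanking the Ile761–Ile765 hinge (defaults 748–760
and 766–778; ≥ 6 residues per flank enforced). How the published bending
angle was computed is unstated, so the flank definition, lengths and
Cα-only fitting are package choices, all configurable. Each axis is the
screw axis of the least-squares rigid transform mapping each flank point
to its successor: exact for an ideal helix regardless of fractional turns,
whereas a plain principal-component fit is biased by the incomplete final
turn (~1.8° for a 13-residue flank at 100°/residue); degenerate untwisted
inputs fall back to the principal axis. Axes are sign-oriented N→C.

The O(i)···N(i+4) backbone bond (Ile761→Ile765) is flagged broken above
3.5 Å (consistent with the H-bond default; boundary closed). The gating
contact is the minimum distance from the three Arg762 guanidine nitrogens
to the Ser915 backbone oxygen, with contact declared at R < 5 Å, the
clustering criterion used for the closed state. A centroid–centroid mode
exists; note that min ≤ centroid is *not* a universal ordering (a group
surrounding the partner atom inverts it) — it holds in the physical
contact geometry, and the tests pin both the property there and a
counterexample.

## Synthetic data: what is emulated, what is not

The generator builds a ~200-atom stand-in scaffold — an ideal 31-residue
helix (rise 1.5 Å, 100°/residue, carbonyl O and amide N offset ±1.72 Å so
O(i)···N(i+4) ≈ 3.0 Å), a 19.6 Å pore axis bounded by two carboxylate
groups, lining-residue polar atoms placed ≥ 3.5 Å off the wire path, and
TIP3P-like waters (O–H 0.9572 Å) — carrying the pump's residue names and
numbers so real configurations resolve verbatim. It is emphatically not a
homology model: no lipids, no physical water dynamics, no energetics. What
passing tests show is that the *analyses* recover planted structure
exactly; they say nothing about force fields or sampling on real
trajectories.

Scenario scripts mirror the three study regimes at desk scale:

* `hydration_onset` (80 frames × 10 ps): occupancy steps 0 → 2 → 4 → 5,
  ending with five pore waters; an optional crystal-style reference places
  k waters within an exact jitter radius of planted positions (direction
  rejection-sampled so a large jitter cannot land next to a *different*
  planted water) and the rest 3 Å away.
* `wire_formation` (~2600 frames × 10 ps): 130 back-to-back wire events,
  100 six-water (straight, O–O 2.8 Å) and 30 seven-water (planar zigzag,
  same spacing), durations uniform on 15–25 frames (150–250 ps). Waters
  rotate through a 14-molecule pool so consecutive events always differ in
  water set; idle waters park in a far reservoir at ≥ 5 Å spacing. Wire
  hydrogens point along the chain, giving 180° donor angles. Lengths other
  than 6–7 cannot span the planted endpoint separation at physical spacing
  and are rejected as infeasible.
* `pore_closure` (100 frames × 10 ps): 4–5 waters split between the two
  pore mouths with a > 5.5 Å dry gap (hydrated but wire-free — the closure
  phenotype), while the kink angle, the Arg762–Ser915 distance
  (8 → 4.2 Å) and the O(761)···N(765) separation (3.0 → 5.2 Å) ramp
  concomitantly over 20 frames from a common onset.

Coordinate noise (default σ = 0.05 Å, a realistic desk-scale thermal
jitter) is i.i.d. per atom with one deliberate exception: an active
planted wire, together with the two anchoring carboxylate groups, is
jittered as a single rigid unit (one shared displacement per frame). With
i.i.d. noise at σ = 0.2 Å the 150° angle criterion genuinely flickers
(angular sd ≈ 17° at the hydrogen), which would make "planted event"
ill-defined; modelling the scripted wire as a collectively moving unit
keeps the planted features exactly recoverable at any accepted noise level
while everything else fluctuates freely. Ground truth (per-frame pore
water ids, event schedules, per-frame kink/contact/backbone values) always
describes the pre-noise coordinates exactly and serialises to JSON.

Problem sizes throughout (2600-frame wire runs, 16-water oracle frames,
≤ 30-node wire graphs, 50–100 random instances per property) were chosen
as the smallest scales at which every planted statistic is
non-degenerate; the full suite runs in a few seconds.

## I/O and orchestration

PDB/DCD/XTC parsing is delegated to MDAnalysis behind the package's small
topology/frame model (0-based internal ordinals, 1-based residue ids
preserved verbatim; HOH/TIP3/SOL/WAT all normalised to one water flag).
Fixtures are written with the package's own fixed-column PDB writer so
round-trips are byte-stable; trajectories round-trip through DCD at
single precision (≤ 1e-3 Å). The frame-saving interval of the source
trajectories is not published beyond a 1 ns reporting interval for water
counts, so the analysis stride is a free configuration parameter.

The pipeline validates every configured residue selection against the
topology before reading any trajectory frame (fail fast), logs per-stage
timing to stderr, writes each series as TSV next to a consolidated JSON
report, and hashes the analysis parameters (not output paths) into the
report provenance. Identical inputs give identical reports.

## Known limitations

* The H-bond criterion is geometric only; no energetic or cooperative
  definitions.
* No pore-radius profiling along the axis, and no
  secondary-structure-based helix-kink decomposition (swivel/face angles).
* Wire analysis characterises connectivity and persistence; it does not
  simulate proton hopping or estimate free energies.
* The lining-proximity hydration mode and the cylinder mode can disagree
  near the pore mouths; neither is privileged by the source definition.
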