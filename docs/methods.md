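# Methods

This note documents the models implemented in `mvnflow`, the defaults and
why they were chosen, what the synthetic networks do and do not emulate,
and the numerical choices that affect results.

## Network representation and units

A microvascular network is a graph whose nodes are bifurcations with 3-D
positions in μm (`z` = cortical depth, 0 at the pial surface, increasing
downward; depth bins are half-open `[lower, upper)`) and whose edges are
vessels approximated as straight pipes carrying a diameter, a *tortuous*
length (the straight pipe is assigned the length and resistance of its
tortuous original, so only intra-vessel diameter variation is neglected)
and one of seven type labels (PA, DA, A, C, V, AV, PV). Pressures cross
the API in mmHg (1 mmHg = 133.322 Pa); all hydrodynamics is SI
internally. Flows are reported in m³/s (nl/s at the CLI), velocities in
mm/s.

### Vessel-type labeling corrections

Provisional labels are required input; morphology-based classification of
raw acquisitions is out of scope. Three corrections are applied, walking
each penetrating tree from its root: (1) the capillary bed starts as soon
as two consecutive vessels are narrower than 7.0 μm — the second of the
pair is the first capillary — and everything downstream is relabeled C;
(2) no capillary keeps a diameter > 9.0 μm (relabeled to the
neighbor-majority non-capillary class) and no arteriole/venule keeps a
diameter < 6.0 μm (relabeled C; small-caliber networks may need 4.8 μm to
avoid demoting most descending arterioles); (3) within arteriolar trees,
once the angle between two subsequent branch chords falls strictly below
125°, all downstream arteriolar vessels become A (ties at exactly 125°
are not relabeled; the same split is available for V/AV behind a flag).
A vessel violating both bounds at once is resolved toward the
neighbor-majority class and logged — the tie-break is not prescribed
anywhere authoritative, so it is at least deterministic and local.

### Trimming

`trim_network` cuts a fraction of the lateral extent on every side
(default 12.5 %) and everything below a depth plane (default 1200 μm,
matching the average mouse cortical thickness; all geometry arguments are
in μm). Vessels crossing a cut plane are severed at the plane; the
exposed node becomes a `deep_boundary` node and the tortuous length is
rescaled by the severed chord fraction. Crossings within 5 % of the
inside endpoint promote that node instead of creating a sliver stub —
sub-micrometre stubs otherwise dominate the transit-time distribution and
collapse the simulation time step. Components that lose their pial
connection are removed and logged. Re-trimming with fraction semantics
re-measures the already-trimmed extent, so idempotency is only defined at
fixed absolute cut planes (the `bounds` argument).

## Capillary diameter upscaling

Measured capillary diameters in these acquisitions are small against the
literature consensus (compare Hudetz, Hall, Gutiérrez-Jiménez: ~4 μm
means), so capillary diameters are upscaled to a goal beta distribution
with mean 4.0 μm and std 1.0 μm on [2.5, 9.0] μm. The interval and
moments give shape parameters a = 1.5, b = 5.0 by the standard moment
equations. The range is split into 500 bins (width 0.013 μm); integer
goal counts are the beta mass per bin times the vessel count, rounded
half-up with the remainder carried into the next bin so totals match
exactly. Processing runs from the smallest bin upward: a bin holding more
vessels than its goal keeps the smallest ones up to the goal count and
shifts the rest (ties broken by vessel id) upward by the constant
`bin upper edge − cut diameter`, spilling them into later bins; deficits
are never back-filled. The algorithm is deterministic, never decreases a
diameter, and — when the input is stochastically smaller than the goal —
reproduces the goal histogram bin-exactly. Only vessels labeled C are
touched.

## Rheology

The in-vitro viscosity law is used rather than the in-vivo one: the
in-vivo fits were calibrated on mesenteric networks for 4–40 μm diameters
while roughly a third of cortical capillaries are narrower than 4 μm.
Tube hematocrit `ht` (instantaneous volume fraction) converts to
discharge hematocrit `hd` through

```
ht/hd = hd + (1 − hd)(1 + 1.7 e^(−0.415 d) − 0.6 e^(−0.011 d))
```

which is quadratic in `hd`; the closed-form root in [0, 1) is the
production path and a bracketed bisection serves as the test oracle. For
d ≳ 2.7 μm this gives `hd ≥ ht` (Fåhraeus effect); below ~2.5 μm the
relation is an extrapolation and a warning is emitted. The relative
apparent viscosity is

```
μ_vitro = 1 + (μ_0.45 − 1) · ((1−hd)^C − 1) / (0.55^C − 1)
μ_0.45  = 220 e^(−1.3 d) + 3.2 − 2.44 e^(−0.06 d^0.645)
C       = (0.8 + e^(−0.075 d)) (−1 + 1/(1+10⁻¹¹ d¹²)) + 1/(1+10⁻¹¹ d¹²)
```

Plasma viscosity defaults to 1.2 mPa·s (config-overridable); with
pressure boundary conditions it scales flows only, not the pressure
field's shape.

## Pressure/flow solve

Conductances `1/R_e` assemble the weighted graph Laplacian; Dirichlet
rows implement the pressure BCs; the reduced system is solved by sparse
direct factorization (CG at 1e-12 beyond 10⁵ nodes — desk-scale networks
never reach it). Node balances hold to ~1e-10 relative and interior
pressures obey the discrete maximum principle. A connected component
without a BC raises immediately rather than producing a singular solve.

The plasma/blood flow ratio diagnostic reports, per edge,
`γ = q_plasma / (μ_vitro · q_blood)` — equal to 1 everywhere if the cells
merely raised every resistance homogeneously — plus the fraction of
edges within 5 % and the median relative difference, split by
capillary/non-capillary. The plain ratio `q_plasma/q_blood` is available
behind `include_viscosity_factor=False`.

## Discrete RBC tracking

Cells are points with an effective exclusion length
`ℓ = V_rbc / (π d²/4)` capped at the vessel length; the default cell
volume is 49 fL (mouse). Per-edge tube hematocrit is
`n · V_rbc / (A · L)`, clipped at 0.99. Each constant time step performs
two stages: (1) solve the pressure/flow field at the instantaneous
hematocrit, (2) propagate the cells at `v_rbc = v_bulk · max(1, hd/ht)`
(the standard Fåhraeus closure consistent with the hematocrit model).
The time step is the largest `Δt` with `Δt ≤ L/v` on at least 99.8 % of
vessels, fixed once from the initial pure-plasma solve (velocities only
sharpen locally afterwards, and a fixed step keeps runs reproducible);
several bifurcation events per cell and step are allowed.

Bifurcation rules: at divergent bifurcations with a capillary (or
venular) parent the cell deterministically takes the outgoing branch with
the largest bulk velocity — the pressure-force rule — with ties to the
lowest edge id; the largest-flow-rate alternative is evaluated alongside
and the agreement fraction is reported (the two rules coincide on
symmetric fixtures by construction; on heterogeneous networks the
agreement is an emergent diagnostic). With an arteriolar parent the RBC
flux fractions follow the empirical phase-separation law in its logit
parameterization,

```
logit(FQE) = A + B·logit((FQB − X0)/(1 − 2X0)),
A = −13.29 ((dα²−dβ²)/(dα²+dβ²)) (1−hd)/df,  B = 1 + 6.98 (1−hd)/df,
X0 = 0.964 (1−hd)/df
```

(diameters in μm, `df` the parent, `hd` the parent discharge
hematocrit); no cells enter a daughter below the threshold `X0`, all
enter above `1 − X0`, symmetric daughters split evenly, and each cell
samples the fractions with the run's seeded RNG. Coefficients live in
config so other calibrations can be swapped. More than two daughters —
rare — fall back to a thresholded proportional split. Convergent
bifurcations merge fluxes additively.

Non-overlap is enforced two ways: admission (a cell may only enter a
vessel whose entrance has ≥ ℓ of headroom; otherwise it waits at the node
and is re-admitted first-blocked-first-admitted as soon as it fits) and a
per-edge spacing clamp after each propagation (front-to-back, the leader
bounded by the vessel end; a numba kernel, since this is the hot loop).
Cells are injected at every inflow boundary edge at a rate
`v_rbc · ht_bc · A / V_rbc` (accumulator with seeded random phase) so the
edge's tube hematocrit matches the boundary value (0.3, the physiological
inflow value) in expectation; injection defers when the entrance is
occupied, so congestion throttles inflow naturally. Cell count is
conserved exactly: injected = exited + resident at every step.

A run consists of a warm-up of 15 turn-over times (turn-over time = total
vascular volume / total boundary inflow), a recording window of 1
turn-over during which newly injected cells get full path records (edge,
entry node, entry time, entry-node pressure), and a drain phase that
follows recorded cells to their exits (capped at 10 turn-overs; cells
still inside are counted as incomplete and excluded from trajectories).

## Artificial networks

The synthetic generator provides the boundary-condition host and all test
fixtures. The capillary bed is a stack of honeycomb layers: a third of
the rung edges (grouped cyclically by row) is rewired into vertical
links between alternating layer pairs, which preserves the degree-3
property at every interior bifurcation and connects the slab. Hexagon
edge length defaults to 60 μm (capillary segment lengths and densities in
the literature range; config-exposed), layer spacing likewise 60 μm, and
capillary diameters are drawn from the goal beta distribution.
Penetrating trees are parametric — a trunk descending in equal segments
with `branches_per_level` lateral side branches per level, diameters
tapering by a per-level factor (default 1/√2, area-halving), depths
scaled by the mouse/rat cortical-thickness ratio 0.66, a short pial stub
carrying the boundary node — standing in for measured penetrating-tree
anatomy, which is not available; only their role (feeding/draining the
bed over depth) matters to the pipeline. Tree roots sit on a rhombic
lattice (default spacing 350 μm) with arteriole and venule kinds
alternating; every leaf is stitched to its nearest capillary node (ties
to the lowest node id). What these networks do *not* emulate: tortuosity,
measured diameter-depth profiles, realistic DA:AV ratios and densities,
or any specific measured angio-architecture — so passing tests show the
pipeline's mechanics and invariants, not agreement with a particular
cortex.

## Hierarchical boundary conditions

Pial arteriolar pressures follow a degree-3 polynomial in diameter fitted
at build time to a bundled table emulating the classic micropipette
measurements (Harper, Werber, Hudetz, Shapiro); the bundled points are
*synthetic* — hand-placed to follow the published trend from ~35 mmHg at
10 μm to ~90 mmHg at 350 μm, since the original fit coefficients are not
published — and should be replaced by user data where absolute accuracy
matters. Pial venular pressure is uniform at 10 mmHg. For a trimmed
network, a hole of its bounding box is cut from the artificial host
(vessels with both endpoints inside removed), the implant's deep boundary
nodes are stitched to the nearest remaining artificial capillary
vertices, and one steady solve of the compound at constant tube
hematocrit (0.3, mirroring the inflow value — the constant is not
otherwise constrained) yields the deep pressures. These are applied as
pressure BCs for the discrete simulation on the implant alone — also at
nodes the compound marks as outflows. At constant hematocrit the implant
solve under the transferred pressures reproduces the compound's interior
flows to numerical precision (tested at 1e-8).

## Trajectory analysis

A correct path is PA → DA+A → C → V+AV → PV; to be robust against
labeling errors a path may deviate for at most two subsequent branches
provided it resumes at a stage at least as advanced as before the
excursion. The deviation budget resets after every valid stretch
(a per-excursion reading; a global budget would conflate independent
labeling errors). Paths satisfying only (PA or DA+A) → C → (V+AV or PV)
are accepted for capillary-bed analyses; others are invalid with an exit
class (arteriole outlet / capillary outlet / other). The capillary start
(end) point is the entry node of the first arteriole→C (C→venule)
transition; analysis layers are 200 μm slabs over the upper 1000 μm of
the start-point depth.

Preferred end points require the largest relative end-point frequency
> 0.5 with the runner-up < 0.3 (preferred paths analogously). The five
path characteristics correlated with the frequencies — euclidean
start–end distance, mean path length, mean summed vessel resistance,
mean flow rate, mean RBC velocity — are averaged over the *unique paths*
between a start/end pair, normalized per start point by the maximum over
its end points, and pooled over all pairs for the Pearson coefficients
(start points with a single end point are excluded and counted).
Pooling across networks, when several are analyzed, is the caller's
choice; correlations are computed per trajectory collection.

Averaged pressure/diameter curves resample each full-valid trajectory
onto a 100-point uniform grid of normalized path length `s/s_tot`
(linear interpolation for pressures, step-wise for diameters), average
pointwise per layer and rescale the abscissa by the layer's mean total
path length. The pressure-drop decomposition takes, per trajectory, the
pressure and cumulative path length at the first edge of each type group
in path order; the per-type drop fraction is the difference of
consecutive group-inlet means over the total drop (PA inlet → PV inlet),
attributed to the group in which the drop occurs. Two modified labelings
(first capillary counted as DA+A; last DA+A counted as C) shift the
arteriole/capillary boundary by one branch for sensitivity analysis.

Transit statistics per layer: capillary transit time `tt_C` (std = CTH),
transit path length `ts_C`, velocity `ts_C/tt_C`, the number of unique
capillary paths (distinct edge sequences between start and end), the
number of distinct feeding branches (arteriole→capillary transition
edges with start point in the layer) and the blood/RBC flow they carry.
Feeding identity uses the injection origin node (which pial inflow the
cell entered at) and the exit node, giving each drainage vessel a primary
feeder fraction. The in-plane fit regresses capillary end depth on start
depth (mm) over all capillary-valid trajectories (per-RBC weighting; a
per-start-point weighting would be an easy variant but is not exposed).

## Orchestration and reproducibility

The pipeline stages (generate → label → upscale → assign-bc → simulate →
analyze) read and write plain CSV/ND-JSON artifacts with provenance
sidecars; a stage whose artifacts exist is skipped, and a global seed
fans out to per-stage seeds via `numpy.random.SeedSequence([seed,
stage_index])`. Identical configurations reproduce byte-identical
trajectory files. The built-in demonstration uses a ~2,400-vessel implant
(2 DAs, 2 AVs, 580 μm deep) in a ~12,000-vessel host with trees tapering
at 0.85/level so that deeper analysis layers receive measurable RBC flux;
these sizes keep a full 15+1 turn-over run with ~6,000–17,000 resident
cells at a few minutes on a single core while populating three analysis
layers.

## Known limitations

- Cells are rigid points with an exclusion length; no deformation,
  lingering at junctions, or endothelial surface layer.
- No oxygen transport or discharge — hypotheses about oxygenation are
  outside what this tool computes.
- The in-vitro viscosity and phase-separation laws are extrapolated below
  ~3 μm, where a third of capillaries live; results there inherit the
  empirical laws' uncertainty.
- The artificial networks are topological stand-ins; absolute flow
  magnitudes depend on the synthetic pial pressure fit and should not be
  read as measurements.
- Venular convergent bifurcations merge fluxes additively; no reverse
  phase-separation model is applied.
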