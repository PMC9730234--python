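# Methods

## Scope and model

`simet` models the *computational* side of mechanically scanned electron
therapy: energy selection, scan-sequence construction, path-length
optimization, and a closed-form delivery-time estimate. It deliberately
excludes dose computation (no Monte Carlo transport, lateral profiles, or
abutment effects), CT/DICOM import and contouring, robustness analysis, and
machine control. The arm is assumed kinematically ideal (constant speed, no
acceleration limits) and spot positioning perfect.

## Synthetic PDD curves

Measured PDD curves are machine-specific and not shipped; `synth_pdd`
generates curves with the canonical electron-beam shape: entrance dose
`surface_dose` (default 80%), sinusoidal buildup to 100% at depth
`peak_frac · R90` (default 0.6), then a logistic distal falloff
`100·g(z)/g(z_peak)` with `g(z) = 1/(1+exp(s(z−z50)))`. The midpoint `z50`
is solved by Brent root-finding so the curve's interpolated R₉₀ equals the
request; the steepness default `s = 12/R90` (1/mm) makes the distal falloff
width scale with beam range, as it does physically (R₉₀−R₁₀ ≈ 4.4/s ≈ 3.3 mm
for the 9 mm beam, ≈ 13.5 mm for the 37 mm beam). Curves live on a uniform
0.01 mm grid from 0 to 1.5× the deepest R₉₀ (shared across a library so
curves can be mixed pointwise) with linear interpolation everywhere; the
self-consistency requirement `r90_of(synth_pdd(r)) = r ± 0.05 mm` holds with
large margin (interpolation error is O(grid²·curvature)).

These synthetic curves reproduce the *structure* of a real library — pure
entries at 9/19/29/37 mm, two-energy composites in between — but not any
particular machine's mixing weights: the composite R₉₀ as a function of
`w_low` depends on the curve shapes, and near shoulder regions (where the
90% crossing migrates from the high-energy falloff to the low-energy
falloff) it is steep in `w`, so a 0.5% weight step can leave up to ≈0.25 mm
of residual R₉₀ error with the default shapes. That is within the 0.5 mm
half-step tolerance the 1 mm table implies, and is a property of the
synthetic shapes, not of the search (a 0.1% search grid reduces it).

## R₉₀ table and energy assignment

The table maps every integer millimetre in [9, 37] to a pure or composited
entry. Compositing always uses the *adjacent* bracketing pair; the
exhaustive weight search evaluates all 201 weights on the 0.5% grid and
breaks ties toward larger `w_low` (the shallower, hence safer, composite).
The required R₉₀ at a beam position is `ceil(distal − proximal)` mm —
conservative by design, never undershooting the distal edge. Depths below
9 mm are clamped to the shallowest beam with a logged warning (the beam then
overshoots a shallow target; with an exposed bed there is no organ proximal
to it). Depths beyond 37 mm raise an error unless an explicit tolerance is
given, since no beam reaches them.

## Sequencing conventions

Rows are binned on exact lattice y-values (1e-6 mm tolerance for float
drift), scanned top-to-bottom; the topmost occupied row goes left-to-right
and occupied rows alternate direction thereafter. Absent lattice sites are
simply skipped. Energy groups are delivered in ascending energy id: the
delivery order is not observable in the time model (N_E − 1 switches either
way), so the convention is arbitrary and fixed for determinism.

## Fast simulated annealing

Each energy group is an open-path TSP optimized independently (an energy
switch costs ~2 s, dwarfing any single move, so inter-group travel is
excluded from all path lengths). The annealer:

* starts from the zigzag order; T₀ defaults to half the initial path
  length, large enough that early worsening moves are almost always
  accepted;
* cools as T(k) = T₀·k^(−1/N) over k = 1…1000 temperature steps (N moves
  per step, so 1000·N proposals per restart; 3 restarts, best kept). The
  classic T₀/k schedule is available via `FSAConfig(schedule="classic")`
  because the power schedule cools very slowly for large N;
* proposes 2-opt segment reversals whose extent is `round(|c|·scale)` with
  `c` standard Cauchy and `scale = max(1, (T/T₀)·N)`: heavy-tailed long
  jumps while hot, local refinements when cold. The reversal's cost change
  touches only the two boundary edges, so each proposal is O(1) to price;
* accepts worsening moves with probability exp(−Δf/T) and tracks the best
  order ever seen, so the returned length never exceeds the zigzag length
  on any input or seed;
* is deterministic: one `numpy` generator seeded per group with
  `config.seed + energy_id`.

Because the power schedule stays warm for moderate N, convergence relies on
the best-so-far record plus restarts rather than on a frozen final state.
With the default budget the annealer recovers the brute-force open-path
optimum on ≥95% of random instances with N ≤ 8; on larger instances it is
guaranteed only to land between the optimum and the zigzag. On complete
rectangular lattices the zigzag already attains the open-path lower bound
(N−1)·spacing, so the annealer reports exactly 0% change there; the gain
concentrates in sparse or fragmented spot distributions, where the zigzag
crosses gaps repeatedly.

The brute-force oracle enumerates all N! orders in vectorised blocks
(refusing N > 10), treats a path and its reverse as equals, and breaks ties
lexicographically.

## Delivery-time model

`T_delivery = (D_P/Ḋ)·N_B + L/V_S + T_E·(N_E−1) + 2·T_O·N_S`, with the
irradiation term counting beam *positions* (a composited pair splits one
position's dose between two spots, it does not double the dwell) and the
gating term counting *spots* (the beam stops and restarts around each).
Defaults describe the reference machine: Ḋ = 15 Gy/s, V_S = 50 mm/s,
T_E = 2 s, T_O = 20 ms. Raw floats are kept internally; the reporting view
rounds totals to the nearest second and components to 0.01 s, matching the
precision such results are usually quoted at. Percent path-length changes
are reported to two decimals.

## Synthetic phantoms

The phantom generator stands in for patient CT, which cannot be shipped.
It emulates IORT targets: an exposed bed (proximal depth 0) whose distal
edge varies smoothly over a 5 mm lateral lattice within 9–37 mm. Kinds:
`flat` (single energy everywhere — the degenerate baseline), `hemiellipsoid`
(a dome, radially monotone), `gaussian_bumps` (2–4 random mounds), and
`random_smooth` (band-limited random cosine surface). All are seeded and
bit-reproducible, and depth fields are clipped to the declared range.

What the phantoms do *not* emulate: real anatomical discontinuities
(duodenum/vessel sparing carving holes in the aperture), non-zero proximal
edges, setup uncertainty, and the correlation structure of real tumour
beds. Tests passing on these phantoms therefore validate the algorithmic
pipeline — table construction, spot bookkeeping, ordering, annealing
contracts, timing arithmetic — not clinical dose coverage or the specific
path-length reductions achievable on patient geometry.

## Problem sizes

Default test and demonstration runs use apertures up to ~60 mm (≤ ~170 beam
positions), annealing budgets of 1000·N moves × 3 restarts, and exhaustive
verification up to N = 8–10; these sizes were chosen to exercise every code
path, including multi-energy plans with hundreds of spots, while keeping a
full run interactive on one CPU core.

## Known limitations

* Composited entries assume the two-energy mix's dose adds linearly at all
  depths — true for PDDs by superposition, but lateral profiles (out of
  scope) would not compose as simply.
* The annealer's returned order for large sparse groups is good but not
  certified optimal; only N ≤ 10 instances can be verified exactly.
* The time model ignores arm acceleration, per-spot dwell modulation for
  nonuniform intensities, and all setup/imaging time.
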