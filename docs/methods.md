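# Methods

`wingpol` models how the Fat/Dachsous/Four-jointed (Ft/Ds/Fj) system orients
core planar cell polarity (PCP) in the fly wing through polarized apical
microtubules, and implements the image- and track-quantification procedures
used to measure that biology.  This note records the model, its assumptions,
the numerical choices, and what the synthetic data do and do not emulate.

## The cell grid

Cells are pointy-top hexagons in an offset-row lattice, by default 6 rows x
30 columns; +x is distal, +y posterior (image convention, y down).  Each
cell has six edges with outward normals at 0°, 60°, ..., 300°; interior
edges are paired with the apposed edge of the neighbour.  **Boundary edges
are mirror-reflective**: a boundary edge is treated as apposed to the cell's
own mirror image in both the binding layer and the core network.  Nothing
crosses the tissue edge, and — unlike partnerless no-flux edges — a uniform
tissue is an *exact* fixed point all the way to the boundary.  This matters
because the core network below is bistable: partnerless edges act as
heterogeneities that nucleate spurious polarity fronts from the tissue edge,
whereas mirror edges leave symmetry breaking entirely to the imposed cues.
A pure x-mirror is not an automorphism of an offset-row hex lattice, but the
180° rotation is (for even row counts); the mirror-symmetry invariant is
therefore tested as "reversing both gradients yields the 180°-rotated
polarity field", which holds to machine precision.

## Layer 1: Ft-Ds heterodimer binding (quasi-static)

Ft and Ds form intercellular heterodimers; Fj phosphorylation increases
Ft's affinity for Ds (`a_Ft(F) = 1 + alpha_ft*F`) and decreases Ds's
affinity for Ft (`a_Ds(F) = 1 / (1 + alpha_ds*F)`).  At the junction between
cell *i* (edge *e*) and neighbour *j*, the heterodimer with Ft from *i*
equilibrates to

    H[i,e] = (k_on/k_off) * a_Ft(Fj_i) * a_Ds(Fj_j) * Ft_free_i * Ds_free_j

subject to per-cell conservation of total Ft (uniform 1 by default) and
total Ds (set by the per-column gradient).  Because the tissue gradients are
fixed inputs and binding is fast relative to core-PCP dynamics, the layer is
solved as an equilibrium before the ODE integration, by iterating the
equivalent Langmuir form on the free pools (every iterate non-negative;
tolerance 1e-12, typically < 100 iterations).  Nondimensional defaults
`k_on = k_off = alpha_ft = alpha_ds = 1`.

Per-cell readouts: anchoring weight `w(i,e) = H[i,e]` (bound Ft anchors MT
minus ends), bias vector `b_i = -sum_e w(i,e) n_e` (plus ends point away
from the Ft-rich side), and asymmetry `A_i = |b_i|`.  The propagation
measurement counts consecutive columns distal to a Ds step whose interior
column-mean `A` exceeds 5% of the maximum column mean; lattice-boundary
cells are excluded because their missing neighbours create a spurious
transverse asymmetry.

## Layer 2: MT bias and transport weights

Delivery weights per edge:

* `coupled` (default): `m(i,e) ∝ floor + max(b_i · n_e, 0)^q` with
  `floor = 0.02`, `q = 1` — delivery toward plus ends;
* `random`: uniform 1/6 (unoriented MTs);
* `oriented_unbiased`: 1/2 on each of the two P-D edges (P-D-aligned MTs
  with no plus-end bias, as seen distally in pupal wings);
* `imposed`: user-supplied.

A region mask restricts a named mode to (for instance) the distal half
while the proximal region stays coupled.

## Layer 3: core PCP network

Species per cell: cytoplasmic Dsh (`Dc`) and Pk (`Pc`).  Per (cell, edge):
free Fz `F`, free Vang `V`, delivered membrane Dsh `M`, Dsh-Fz complex
`DF`, membrane Pk `PV` (bound at Vang-rich membrane; sequesters Pk, not
Vang), and intercellular bridges `C0` (Fz:Vang) and `C1` (DshFz:Vang),
indexed on their Fz side.  Reactions (full rate laws in the
`wingpol.model.core` docstring):

1. directed transport `Dc -> M(i,e)` at `k_T·m(i,e)`, return `k_ret·M`;
2. Dsh capture `M + F -> DF` (rate `k1`, inhibited by same-membrane `PV`
   through `1/(1+beta·PV)`, gated by free scaffold sites `phi`), plus
   cluster-driven recruitment straight from the cytoplasm,
   `Dc + F -> DF` at `k1_cyto·Dc·F·(DF+C1)·phi/(1+beta·PV)`;
3. bridges `F/DF + V(across) -> C0/C1` at `k2`; `C0` dissociates at
   `k2_off`, `C1` at `s_D·k2_off` and releases its Dsh at `s_D·k1_off`
   (Dsh-bound bridges are stabilized — the polarity ratchet);
4. Pk recruitment `Pc -> PV(i,e)` at
   `k3·Vtot·(1 + delta·S^n/(K^n+S^n))/(1 + beta2·(DF+C1))`, where `S` is
   the Fz-side complex level on the *apposed* membrane — a cooperative
   trans-junctional switch;
5. lateral diffusion of `F, V, M` between adjacent edges at `D_m`;
   complexes are junction-anchored.

No synthesis or degradation; per-cell totals of Dsh, Fz, Vang and Pk
(all 1) are conserved to integrator precision (observed ~1e-13).

### Why this structure

Three ingredients make the network behave like wing tissue:

* **Junction bistability.**  The cooperative trans switch (Hill `K = 0.1`,
  `n = 4`, `delta = 200`) plus strong capture inhibition (`beta = 200`)
  makes each junction a toggle: Fz-side complexes on one membrane, Pk on
  the other.  Polarity persists after the orienting cue is removed and
  propagates cell-to-cell, which is what lets a steep proximal gradient
  polarize a flat distal region (with a distance-dependent delay).
* **Site capacity.**  Each edge holds at most `site_cap = 0.25` Fz-side
  complexes.  A focused cue would otherwise concentrate complexes on the
  single distal edge while cue-free cells spread them over the distal
  half, giving geometry-dependent polarity magnitudes; the cap makes the
  saturated pattern — and hence the vector-sum amplitude — the same
  whether or not delivery is focused.  This is what makes the steady
  state insensitive to the gradient shape (measured spread 0.6%).
* **Seed/maintenance separation.**  MT-delivered Dsh (`k1` channel)
  nucleates clusters, so *kinetics* follow the MT architecture (P-D
  oriented distal MTs shorten the distal delay ~5% versus randomized
  MTs); cytoplasmic recruitment (`k1_cyto` channel, zero without
  clusters) dominates maintenance, so the *steady state* does not.

The published ODE model this design descends from couples the same
feedback topology (intercellular Fz:Vang stabilization, intracellular
mutual antagonism with cooperative nonlinearity, limited pools, membrane
diffusion) to directed transport; rate constants here are nondimensional
and were calibrated so the model reproduces the qualitative behaviours
above, which is the declared contract for the defaults.

### Readout

Per-cell polarity `P_i = sum_e (M + DF + C1)(i,e) · n_e` — the vector sum
of membrane-associated Dsh, matching what a Dsh reporter shows.  The
boundary readout adds the Dsh on both sides of each shared junction
(light-microscopy view).  Kinetics: `t90` per column is the first sampled
time at which the column's mean |P| reaches 90% of its final value; if the
trajectory has not reached steady state the kinetics table carries a
warning flag.

### Clones

A clone zeroes one species' total in a cell block (no synthesis in the
model, so null = absent).  `ft`/`ds` clones act on the binding layer
(wildtype neighbours then bind Ds strongly at the clone-facing junction
and reorient their MT bias); core-species clones zero the core totals.
Scoring: the largest angular deviation of polarity from distal among
clone-adjacent wildtype cells with non-negligible magnitude.  Declared
threshold for domineering non-autonomy: 60° (measured: fz 88°, dsh 47°).
An `ft` clone 2 columns wide does not block propagation: its interior
polarizes distally (mean angle ~-5°) and cells distal to it are
unperturbed.

## Numerics

Explicit adaptive Runge-Kutta (scipy `RK45`, rtol 1e-6, atol 1e-9) on the
packed state (7,920 components for 6 x 30); the right-hand side has a
numba kernel with a numpy reference path, equivalence-tested at 1e-12.
Integration proceeds in chunks; steady state is declared when the
chunk-averaged rate of change `max|Δy|/Δt` drops below `tol_ss = 1e-6`.
Halving the maximum step changes steady-state |P| by < 0.1%.  Uniform
initial conditions (free Fz/Vang spread over edges, Dsh/Pk cytoplasmic);
optional seeded multiplicative noise for symmetry-breaking studies
(default off, so all grid simulations are deterministic).  Typical run
times (single core): 6 x 30 grid to steady state in 20-60 s; the full
acceptance recomputation ~7 minutes.  Simulation horizons: 4000 time
units for gradient-shape comparisons (steady-stop usually triggers
earlier), 1500 for kinetics, 2500 for clones — chosen as the scales on
which the slowest experiment (distal front propagation, ~13 time units
per column) completes.

## Quantification modules

* **MT orientation** — Gaussian-derivative structure tensor
  (`sigma_grad = 1`, `sigma_window = 4`, reflective padding); fiber
  direction is orthogonal to the dominant gradient direction; coherence
  is the normalized eigenvalue anisotropy with a zero-trace guard.
  Rose-plot histograms use 36 bins of 5° on [0, 180), weighted by
  coherence x energy with pixels below coherence 0.2 discarded;
  axial circular statistics use doubled angles.  Display alignment adds
  a recorded offset so the P-D axis plots horizontally.
* **Anchoring sites** — angles from cell centroid (0° = distal), 20 bins
  of 18°; raw and doubled-angle resultants; exact two-sided binomial test
  of the half-plane split by sign(cos); sites exactly on ±90° are
  excluded from the test and counted in the output.
* **Vesicle tracks** — tracks must be visible in ≥ 2 consecutive apical
  frames (the track is trimmed to its longest apical run).  Stuck: every
  consecutive displacement ≤ `stuck_eps` (0 for synthetic data — the
  scoring that matches pixel-exact manual annotation; ~0.5 px suggested
  for real data).  Net direction from the first-to-last vector; ties
  |v_x| = |v_y| count as axial, and a zero net vector with
  super-threshold wiggling falls to the v_x-sign rule (both rules are
  recorded in the summary).  The axial fraction is reported with both
  denominators (all analyzed tracks, and moving tracks only) because
  published percentages rarely state which was used.  Exact binomial
  test of distal vs proximal, two-sided by default.  Motion modes:
  transcytotic iff straightness ≥ 0.8 and pause fraction ≤ 0.2 (declared
  defaults; no published values exist).
* **Shift colocalization** — Pearson correlation over the valid
  (non-wrapped) overlap at each signed integer shift; wrap-around would
  contaminate the small-shift peaks this method reads out.  Peaks are
  strict 3-point local maxima with prominence ≥ 0.01 in r, refined by
  parabolic interpolation; A and B are the peaks nearest zero on the
  negative (proximal) and positive (distal) sides, and the imposed dot
  offset is recovered as (|B| - |A|)/2.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic per seed and every output carries machine-
readable ground truth.  Fiber images draw anti-aliased segments with
axial angles von Mises-distributed on doubled angles, Gaussian-blurred
with additive Gaussian read noise — no point-spread function, no Poisson
statistics, no fiber crossings-with-occlusion.  Dot/membrane pairs place
one Gaussian punctum per hexagonal cell at a known proximal offset inside
rendered outlines; geometry is seed-independent, only noise varies.
Track mixtures (default 75% transcytotic, 10% wandering, 15% stuck at
5-second frames, distal probability 0.58, 3 px per frame) reproduce the
published classification structure — linear processive transcytosis with
a modest distal bias versus pausing random walks — not real vesicle
speeds, which are unreported; step sizes are free parameters of the
generator.  Mode counts are rounded expectations, so category totals are
deterministic while per-track behaviour is seeded.  Anchoring angles are
von Mises mixtures on the full circle.  Passing recovery tests therefore
demonstrates correctness of the estimators on data matching the model's
assumptions, not robustness to real-microscopy nuisances (uneven
illumination, segmentation error, tracking failures).

## Known limitations

* Rate constants are nondimensional and calibrated to qualitative tissue
  behaviour; absolute time units and concentrations are arbitrary.
* No cell rearrangement, growth, division or mechanics; the grid is
  static.  No Pk/Sple isoform distinction; Fmi is implicit in the
  bridges.  No stochastic vesicle-level transport inside the ODE model.
* Domineering non-autonomy around fz clones appears as strong neighbour
  repolarization (up to ~88°) extending ~1 cell, weaker than the
  multi-cell reversal seen in adult wings — consistent with a model
  lacking the hair-outgrowth amplification step.
* The mirror-symmetry invariant is exact only for even row counts (where
  the 180° rotation is a lattice automorphism); odd-row grids raise on
  `rotate180_map`.
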