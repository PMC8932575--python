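# Methods

## Model

`epivertex` simulates a confluent epithelium as a 2D vertex model: the
tissue is a planar tiling of polygonal cells over shared vertices, and
its mechanics derive from the normalized energy

```
E' = Σ_cells ½ (A − A0)²  +  Σ_edges Λ l  +  Σ_cells (Γ/2) L²
```

with per-cell area `A`, preferred area `A0`, perimeter `L`, and edge
lengths `l`. Every undirected edge is counted **once** in the tension
sum; boundary edges carry an elevated tension `Λ_b`. Differentiated
(inactive) cells keep their geometry but contribute no energy, and all
of their vertices are pinned (immotility).

Dynamics are quasistatic: between state updates the tissue sits at a
local energy minimum. The default solver is a quasi-Newton minimizer
(L-BFGS with the analytic gradient; gradient tolerance 1e-6, progress
tolerance 1e-11 in normalized units) interleaved with topological
transitions until none fires (at most 50 rounds):

- **T1** — an interior edge shorter than the T1 threshold collapses and
  reopens perpendicular at 1.05× the threshold, unconditionally;
  energetic favorability is enforced by the relaxation round that
  follows. Candidates fire shortest-edge-first, one per round. The
  inverse T1 of a shrinking cell is the same operator.
- **T2** — a cell below the apoptotic area threshold (0.05), or a
  triangle smaller than 4× that threshold, is replaced by a vertex.
  Sub-threshold cells with more than three sides are first shrunk by
  collapsing their shortest edges. Every removal is dry-run checked so
  the repair cannot leave an edge with more than two owners; blocked
  removals are skipped and retried later.
- **T3** — a vertex of rank > 3 is split by a short new edge between
  two of its incident cells; all rotations of the split are scored by
  total energy and the split is accepted only if it lowers the energy
  (ties break on the lowest participating cell id).
- **Division** — a new edge is cut along a uniformly random line
  through the area centroid; daughters inherit the mother's
  concentration, region and mechanical parameters and restart their
  cycle volume at V_d/2. Cells crushed below twice the apoptotic
  threshold do not divide (they await T2).

An overdamped viscous solver is provided as the alternative update
rule: per mechanical interval the vertices take a fixed 100 explicit
force steps `r ← r + (F/η) δt`; it makes no convergence claim, and its
units for the viscosity η are arbitrary.

Cellular pressure uses the virial formula
`p = −(1/A) Σ_i (∂E_cell/∂r_i)·(r_i − r_c)` on the cell's own energy
terms. Because each term is translation-invariant and homogeneous in
the coordinates, this collapses exactly to
`p = −2K(A−A0) − (ΓL² + Σ_e Λ_e l_e)/A`; a compressed area-only cell
has `p = −2K(A−A0) > 0`. Reported pressures are rescaled `p' = 1000 p`
and visualized on the signed-log scale `±log10(|p'|+1)`.

## Parameters

| symbol | meaning | default | notes |
| --- | --- | --- | --- |
| K | area elasticity | 1 | normalization |
| A0 | preferred area | 1 | normalization |
| Λ | bulk edge tension | 0.12 | classic proliferating-epithelium point |
| Γ | perimeter contractility | 0.04 | idem |
| Λ_b | boundary tension | 0.40 | see below |
| T1 threshold | edge length | 0.1 (uniform), 0.05 (eye disc) | lower in the eye disc so constricted furrow cells do not migrate |
| T2 threshold | apoptotic area | 0.05 | not stated upstream; config default |
| V_d | division volume | 1 | threshold of the cycle variable |
| β | baseline cycle rate | 1 | enters only as β·t_norm |
| μ | mechanosensing amplitude | 0.04 | area-dependent cycle modulation |
| D_c | morphogen diffusion | 0.7 /h | see signaling |
| P_c | autoproduction | 2 /h | steady state c* = P_c/λ = 2 |
| c0 | production threshold | 0.2 | |
| λ | decay | 1 /h | |
| MF band | concentration | [0.4, 1] | cells transit the band as c rises to c* |
| constriction factor | A0 reduction in the MF | 0.15 | see below |

**Boundary tension.** With each edge counted once in the tension sum,
the confining pressure on a circular tissue is `Λ_b / R`, while the
bulk can sustain at most ≈ 0.28 (in normalized units) before boundary
cells are crushed; a ~50-cell tissue (R ≈ 2.8) therefore collapses
above `Λ_b ≈ 0.5` — both a mean-field argument and capped-step descent
confirm this, and occasional fixture realizations collapse already at
0.45. The default 0.40 is the strongest confinement the 50-cell start
sustains across realizations, and already puts the outline circularity
in its saturation regime (≈ 0.96). Implementations that count tension
per half-edge shift this balance, which is why larger nominal boundary
tensions appear elsewhere.

**Constriction.** A constricted cell is stable only while its area
term can balance tension + contractility, which under these parameters
requires `A0(1−f) ≳ 0.72`, i.e. constriction factors below ≈ 0.28;
beyond that furrow cells collapse to the apoptotic threshold (the 2D
model cannot support the ~15-fold apical constriction observed in
vivo). The default "intermediate" factor is 0.15 and sweeps use
0–0.25.

**Growth normalization.** The per-interval cycle increment is
`ΔV = max(0, V_d [β + μ(A−Ā)/A0] · t_norm)` with
`t_norm = k·dt / (2 V_d β)`, so a cell at the mean area divides with
doubling time 1/k. The uniform scenario uses a constant k; the eye
disc uses `k = k0 exp(−δ_PL L_p)` keyed to the posterior length. δ_PL
is anchored so the rate has decayed ~80% when the furrow has traversed
half of its full path (the furrow's path is ≈ 0.6 of the nominal
pre-relaxation axis, because the relaxed tissue is compressed and the
furrow midpoint stops short of the anterior tip).

**Signaling.** The effective morphogen obeys
`dc/dt = D_c ∇²c + P_c θ(c − c0) − λ c` on the cell-center lattice,
discretized with uniform symmetric weights `2/(3h²)` per shared-edge
neighbor (`h² = 2 Ā /√3` from the mean cell area of the *initial*
relaxed tissue; the scenario drivers pin this weight for the whole
run) — a hexagonal-packing approximation that deliberately ignores
physical distances, so the front advances a fixed number of cell rows
per hour regardless of how packed the cells later become, and stronger
constriction (smaller cells) should slow it in microns per hour. The step nonlinearity is kept discontinuous; `scipy`'s adaptive
RK45 integrates each 4-minute interval on the frozen lattice. The wave
is seeded by a boundary source of `0.4 P_c` into posterior boundary
cells (x within 20% of the AP extent) until the flux cutoff; cells in
the band [0.4, 1] are the furrow, cells exiting above the band become
posterior and are frozen 2.5 h later. The defaults above give a front
speed of ≈ 1.9 simulation lengths per hour (≈ 3 cell rows/h) and a
furrow ~1–2 cells wide at desk scale, proportionate to the ~10-cell
furrow of a full-size disc.

## Calibration

Physical units are anchored exactly as the study design prescribes:
the mean posterior cell area maps to 9 µm², and the measured furrow
speed maps to 3.4 µm/h. The speed is the slope of posterior length
vs time, fitted after the initialization phase (the boundary-flux
window) is excluded; the posterior length is measured from the
posterior edge to the mean x of furrow cells within the central 20%
dorsal-ventral band. Uniform-growth runs reuse the area anchor: the
run's post-burn-in mean cell area maps to 9 µm², which converts the
0.1 µm² avalanche-detection threshold into simulation units.

## Scenarios and study scales

Both scenario drivers advance in 4-minute developmental-time steps:
(eye disc only: reaction-diffusion step, furrow state update), cycle
advance, divisions, mechanical relaxation with transitions, frame
record. All randomness flows from one seeded generator (cycle
initialization, then division orientations in cell-id order), making
runs bit-reproducible.

Full-scale presets match the study conditions (50-cell circle of
radius 11 µm, 6 h doubling, termination at 350× the initial area or
3·10⁵ µm²; 10,000 µm² ellipse, 10 h flux window). The desk presets
used by the tests and the acceptance script shrink the problem to
minutes per run on one CPU:

- uniform: 3 h doubling (the constant-rate model is freely rescalable
  in time), termination at 8× the initial area (~10 h, ~300 cells);
- eye disc: 1,600 µm² ellipse (~180 cells), flux window 2.5 h,
  δ_PL·L preserved.

**What the desk scale does and does not show.** At 50→300 cells the
avalanche-active regime is the *early, boundary-packed* phase: the
event rate falls from ~2.5/h to ~0 as the tissue outgrows boundary
dominance, the reverse of the late-onset pattern seen when tissues
grow 350-fold. The avalanche mechanism (packing buildup → collective
release, negative packing–magnitude rank correlation) is the same, but
the magnitude distribution is dominated by its finite-size exponential
cutoff (x* within a factor ~2 of the detection floor), so the
power-law exponent is poorly constrained at this scale; reproducing
the full-scale exponent requires the full-scale ensemble. The desk
burn-in is therefore a 0.5 h settling window (excluding fixture
equilibration) rather than the 30 h of the full-scale protocol, whose
purpose — skipping the pre-avalanche regime — does not transfer to the
shifted regime.

**Avalanche magnitudes.** An avalanche is detected as a ≥ 0.1 µm² jump
of the mean cell area between consecutive frames; each discontinuity
counts as one event. Its magnitude is the percent jump of the total
area over the same frame pair; the study pipeline reports the *excess*
over the run's smooth-growth baseline (median per-frame percent growth
of quiescent frames), because at a 3 h doubling time the baseline
(~1.5%/frame) is comparable to small avalanches. The magnitude
distribution is fitted on log-spaced histogram bins from the histogram
mode (detection censoring makes the density rise up to an apparent
mode) to the finite-size cutoff, which is located by fitting
`p ∝ x^−τ exp(−x/x*)`; the exponent is the linear log-log slope of the
pre-cutoff bins, with the cutoff-aware exponent reported alongside.
When no cutoff is resolvable inside the data the fit range is chosen
by maximizing R² instead. A semi-log linear fit is always reported for
exponential-model comparison.

## Numerical choices

- Minimization accepts a round only if the energy does not increase;
  non-convergence is reported, never raised.
- Fixture generation Voronoi-tessellates perturbed hexagonal points,
  clips the target shape, collapses clipping slivers, simplifies
  near-collinear boundary arcs, and relaxes with the boundary tension
  ramped up in stages (a raw tessellation is far from equilibrium and
  a full-strength boundary can throw the minimizer across basins).
- Ties everywhere (T1 candidates, T3 splits, simultaneous divisions)
  break on shortest edge / lowest cell id, for determinism.
- The mechanical interval is 4 min; halving it leaves ensemble-mean
  macroscopic observables within 2% (per-run trajectories diverge
  chaotically, so the invariance is checked on ensemble means).
- Snapshots are versioned JSON with exact float round-trip.

## Known limitations

- The exponent of the avalanche magnitude distribution is not
  measurable at desk scale (see above); the packing correlation is
  directionally negative but weak and ensemble-dependent
  (ρ ≈ −0.05 … −0.2 across seeds) compared to the full-scale −0.46.
- Boundary tension and constriction ranges differ numerically from
  implementations that count edge tension per half-edge.
- The furrow band at desk scale is 1–2 cells wide, so band statistics
  (e.g. furrow midpoint) are noisier than on a full-size disc, and the
  constriction-slows-the-furrow effect does not resolve in a
  desk-scale sweep (the anterior lattice barely repacks over ~200
  cells; the strongest-constriction arm even loses furrow cells, which
  perturbs the front).
- The pre-avalanche high-pressure-outlier signature is likewise not
  resolved at desk scale: single events involve too few cells for a
  stable pressure-tail comparison.
- The viscous solver does not converge to the quasistatic solver even
  at low viscosity; it reproduces the fixed-100-substep scheme and no
  attempt is made to reconcile the two.
- No second mitotic wave, no peripodial membrane, no multi-species
  gene network: the morphogen is a single effective autocatalytic
  factor.
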