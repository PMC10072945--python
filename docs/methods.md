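# Methods

`retmosaic` is an agent-based model of how retinal mosaics — the semi-regular
planar arrangements of the cell bodies of each retinal cell type — can
self-organize from purely local, homotypic chemical interactions. It
implements three candidate developmental mechanisms and the spatial
statistics used to score their outcomes.

## Model

### Space, cells, time

Cells are spheres living in a thin slab. The reference layout is a
1000 × 1000 µm core used for statistics plus a 150 µm margin on every side
(cells in the margin simulate normally but are excluded from analysis, which
removes edge effects), with a 22 µm slab thickness. Cells are seeded
uniformly at random in 3D at 7–8 µm diameter, forming a loose multi-layer.
One simulated day is 160 steps and runs last at most 14 days (2240 steps).
No cells are ever created after initialization.

Each step executes, in order: substance secretion → diffusion → behaviour
updates (fate first, until every cell is differentiated; afterwards death,
then migration) → mechanical overlap relaxation → diameter growth →
z-collapse. Mechanics run last so the non-overlap contract holds at the end
of every step.

Three slab processes shape the population independently of the chemical
mechanisms:

* **Mechanics** — overlapping spheres repel: each overlapping pair is
  displaced symmetrically along its centre axis by half the overlap, iterated
  until the worst overlap is below 0.5% of the mean diameter (or an iteration
  cap); candidate pairs come from a k-d tree query with a 1 µm slack radius
  reused across iterations within a step.
* **Growth** — diameters grow linearly from their initial draw to 14 µm over
  days 1–6 (the death period). Growth is what creates the transient packing
  pressure: at 8600 cells/mm² the slab fits a monolayer of 7–8 µm cells but
  not of 14 µm cells, so the z-distribution widens mid-run and relaxes into a
  monolayer as death thins the population.
* **z-collapse** — every living cell's z moves up to 0.1 µm/step toward the
  slab mid-plane, pulling the population into a monolayer when packing
  permits.

### Substance fields

Every cell type secretes its own diffusible substance; all behaviours are
homotypic (a cell reads only its own type's field, and an undifferentiated
cell reads the fields of candidate types). Fields live on a regular cubic
voxel lattice (2 µm edge at reference scale) and evolve by the explicit
central-difference update

    u'[i,j,k] = (u + α Δ6 u) (1 − μ),   α = ν Δt / Δx²

with diffusion coefficient ν = 2 µm²/step and decay μ = 0. A single update
with Δt = 1 at Δx = 2 µm would have α = 0.5 — unstable for the 3D 7-point
scheme (stability requires α ≤ 1/6) — so each simulation step applies
`ceil(8ν/Δx²)` sub-steps with α ≤ 1/8: four sub-steps at 2 µm voxels, one at
the 4 µm desk-scale voxel. The stability bound is enforced at construction.
Secretion adds one concentration unit per cell per step into the voxel
containing the cell centre; concentration lookups are voxel-granular (no
interpolation) and gradients are central differences between neighbouring
voxels (one-sided at the lattice boundary).

**Boundary condition.** The lattice supports both reflecting (zero-flux
mirror) and absorbing (outside voxels held at zero) boundaries. Reflecting
boundaries conserve mass exactly for μ = 0 and are the default for the
`SubstanceGrid` API and its invariant tests. Simulation runs, however,
default to absorbing boundaries: with μ = 0, constant secretion, and a closed
box, the mean concentration rises without bound (≈1 unit/day at reference
scale) and every cell eventually crosses any fixed threshold, so no
death steady state can exist. Physically, the absorbing slab faces represent
loss of the cue into the tissue adjacent to the ganglion cell layer. In the
thin absorbing slab an isolated, continuously secreting cell reaches a
screened steady state within ~200 steps: its own voxel settles at a baseline
*u*₀ (≈0.89 concentration units at 4 µm voxels) and the lateral profile
decays roughly exponentially with a screening length set by the slab
thickness (≈7 µm), reaching ~0.002 units at 32 µm. This screened kernel is
what makes every interaction local.

### The three mechanisms

All threshold comparisons are strict (the behaviour fires only *above* the
threshold).

**Cell fate (CF).** Cells start undifferentiated and secrete nothing. Each
step, an undifferentiated cell attempts a fate choice with probability 0.02;
a type is inhibited if its substance at the cell exceeds that type's
inhibition threshold; the cell adopts one non-inhibited type with probability
proportional to the type's remaining target count (plain target-density
weighting is available); if every type is inhibited it waits. Differentiated
cells begin secreting immediately, so early adopters suppress same-type
choices nearby. Two calibrations matter here. First, the attempt rate must
be slow enough that inhibitory plumes mature (~30–60 steps) before most
neighbours choose, and fast enough that differentiation completes early in
development; with 0.02 the last cells differentiate around steps 320–530
(days 2–3.3). Second, the inhibition threshold is *per type*: a single
threshold cannot serve a 17-fold density range, because at a level that
regularizes mid-density types the densest type's inhibition radius exceeds
its own target spacing — late in fate determination no position remains
where it can still be adopted, and it ends up under-assigned by a third.
Each type's threshold is therefore the kernel value at 0.6× its target mean
spacing, floored at 0.003 units (`auto_cf_thresholds`; e.g. ≈0.036 for the
densest type, the floor for everything at or below ~300 cells/mm²). With
these defaults the across-type average Regularity Index at completion is
≈2.37 and per-type assigned counts match their targets. Death and migration
are gated until differentiation is complete.

**Cell death (CD).** A differentiated cell removes itself when its own-type
concentration exceeds its death threshold, so homotypic clusters thin out
first. Because every cell carries its own steady plume, thresholds are
parameterized as *u*₀ + δ: only the margin δ above the self-level
discriminates neighbours, which is why the original parameter table needs
four significant figures. `calibrate_thresholds` bisects the per-type margins
on a log scale (all 43 types share each evaluation run, since death depends
only on the own-type field) until each type's steady-state death rate matches
the observed 60–65% developmental loss; the aggregate rate is checked and a
table-dialect CSV of calibrated thresholds is emitted. For dense types the
death rate is a smooth function of δ; for the sparsest types (57 cells/mm²)
the homotypic kernel at their spacing is below the resolvable margin, the
achievable rate saturates below the target at any margin above the numeric
floor, and the bisection settles at the closest achievable value. Death stops
(steady state, <0.1% of living cells per day) around day 5–7 at ≈63%
overall loss.

**Cell migration (CM).** When the own-type concentration exceeds the (lower)
migration threshold, the cell moves 0.25 µm per step against the normalized
in-plane gradient of its own field; z is owned by the collapse, and a cell on
a flat field does not move. Migration thresholds are also parameterized as
*u*₀ + δm. Two principles set δm: (i) *locality* — repulsion should act only
within ~42 µm (δm at least the kernel value there, ≈0.002 units), so sparse
types, whose neighbours sit far beyond that radius, barely migrate; and (ii)
*settling* — a type dense enough that several neighbours sit inside the
locality radius would otherwise walk indefinitely, so its margin is raised to
3× the kernel at 0.8× its adult mean spacing, letting each type freeze once
it reaches the spacing its density allows. (The reference parameter table
shows the same structure: denser types carry higher migration thresholds.)
The fixed locality radius is what produces the density–regularity law: dense
types interact strongly relative to their spacing and become very regular,
sparse types stay near random, and the correlation between adult density and
final RI is strongly positive. With these defaults surviving cells migrate
~9 µm on average and ~98% stay below the 30 µm bound reported in vivo.
Migration margins are capped at 0.9× the death margin so migration always
triggers before death. In the combined condition, death thresholds are
calibrated over nearly the full 14-day horizon (12 days): with migration
active the death rate keeps creeping for days after the nominal steady
state, and thresholds tuned on a short horizon over-thin the dense types by
the end of the run.

### Experiment conditions

The packaged catalogue holds 43 retinal ganglion cell types (12 on-off, 19
on, 12 off) with start densities summing to 8564 cells/mm² and adult
densities to 3000 (every row has adult/start = 0.35, i.e. 65% loss). The
conditions are: `D` (death only, typed at creation from start densities),
`FD` (fate then death), `FDM` (all three), `CM_ONLY` (migration only at adult
densities), and `CF_ONLY` (fate only at adult densities). Conditions without
death initialize at the summed adult density; conditions with death at the
summed start density.

### SAC experiments

Starburst amacrine cells form two mosaics, one per layer (GCL and INL, the
INL denser), which in mouse exclude each other far more than independent
mosaics would. The model forms both mosaics by migration only, mixed in one
slab, then separates the layers along z with x,y frozen (planar statistics
are unchanged by construction). Two hypotheses: `one_cue` — both populations
secrete and sense one shared substance, so they space out against each other
and end up anti-aligned; `two_cue` — each population has its own substance
(cross-population mechanics still applies, cells being physical). The shared
migration threshold (identical for both layers) is tuned per condition so
the simulated layer RIs match the values measured in mouse for that
condition; regularity is not monotone in the threshold (tiny margins mean
long-range, never-settling drift; moderate margins act like a clean local
hard core; large margins disable migration), so the tuner scans a log grid
of margins rather than bisecting. Per-layer densities are not reported by
the imaging studies this model is built against; the defaults (GCL 250,
INL 400 cells/mm²) are chosen so that, once the RIs are tuned, the
between-layer geometry is in the regime where a 32 µm exclusion diameter
discriminates the two hypotheses (at several-fold higher densities the
combined mosaic spacing falls below the exclusion diameter and the measured
exclusion factor is near zero for *any* mechanism). With the defaults the
shared-cue condition yields an exclusion factor ≈0.7 and the independent-cue
condition ≈0.3, with the shared cue higher on every paired seed.

## Statistics

* **Regularity Index (RI)** — mean of the per-cell nearest-neighbour
  distances divided by their standard deviation (sample s.d., ddof = 1; a
  population-s.d. mode is available). Planar (x,y) distances only.
  ~1.8–2 for uniform-random patterns, higher for regular mosaics; a perfect
  lattice (zero spread) is reported as `inf`. Neighbours are searched among
  all cells but only cells inside the analysis window contribute distances.
* **Exclusion factor** — for two populations, the fraction of cells whose
  nearest other-population cell lies strictly beyond the exclusion diameter
  (32 µm default), symmetrized over the two directions: 1 = perfect
  exclusion, 0 = coincident populations.
* **Migration distance** — planar displacement between a cell's birth and
  final positions, survivors only by default.
* **Across-type averages** — each type contributes one RI, weighted equally.
  At desk scale a single window holds only a handful of cells of the
  sparsest types, and per-run RIs of tiny samples are wildly variable; the
  experiment drivers therefore pool nearest-neighbour distances across
  replicate seeds per type before forming mean/s.d. (checked by Monte Carlo
  to be unbiased for uniform-random patterns at all densities used).
* Pearson correlation and the Mann–Whitney U test wrap the standard SciPy
  implementations.

## Synthetic data

`make_pattern` generates uniform-random, lattice, jittered-lattice, and
randomly thinned planar point patterns with known RI behaviour; these are
the fixtures for the metrics layer. The simulation experiments generate all
their own inputs from the packaged catalogue and seeds. What the generator
does *not* emulate: real retinas grow (surface expansion is absent here, and
measured migration distances are accordingly at the low end of the in vivo
range), death may depend on retrograde signalling and electrical activity
(absent), and dendritic contact interactions are out of scope. Passing tests
therefore show that the *mechanisms as modelled* reproduce the reported
statistics, not that the retina uses these mechanisms.

## Desk scale and reproduction

The shipped experiments run on a 400 µm core with a 100 µm margin and 4 µm
voxels (one diffusion sub-step), 8 replicate seeds, ~2 s per simulated day
on one CPU; `scripts/acceptance.py` completes the full battery in roughly
15 minutes. Substance lattices use float32 in runs (the smallest calibrated
margins, ~1e-4 units, are three orders of magnitude above float32 resolution
at the baseline level); the grid API defaults to float64, under which the
conservation invariants hold to 1e-9 relative. All randomness flows from a
single integer seed through `numpy` generators; identical configuration and
seed reproduce trajectories bit-for-bit.

## Known limitations

* The sparsest catalogue types cannot be driven to 65% death by a homotypic
  screened kernel at any threshold margin; their achieved death rates
  saturate lower, and — conversely — near-floor margins make their death
  spatially selective at long range, so their mosaics come out somewhat more
  regular than the reference simulations report. This lifts the death-only
  across-type average RI slightly above the reported value.
* The same long-range selectivity shifts the death-rate/regularity dome:
  sweeping the death threshold for a dense type traces the expected
  rise-and-fall, but the peak sits at ~40–60% death rather than below 30%,
  and at ~90% death too few cells survive a desk-scale window to measure
  the return to randomness cleanly.
* The measured mean migration distance is sensitive to the locality radius
  and step length; the defaults land within ~10% of the reported mean but
  not within its (very tight) replicate s.d., and ~2% of cells exceed the
  30 µm bound (the reference reports ≥99% below it).
* Fate determination completes around days 2–3 rather than strictly within
  day 1; pushing the differentiation rate high enough to finish inside 160
  steps leaves the inhibitory plumes too immature to reach the reported
  fate-only regularity.
* SAC layer densities are free parameters of the model, not measured inputs.
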