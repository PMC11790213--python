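# Methods

## The question

On a mountainside, where should species richness peak?  The available area
shrinks toward the summit on a cone-shaped mountain, so any area-dependent
process — colonization, local extinction, diversification — is entangled
with geometry.  `edgsim` separates these forces with a mechanistic,
spatially explicit simulation of an endemic clade radiating on a banded
mountain, and complements it with a state-dependent
speciation–extinction (SSE) likelihood framework that asks the same
question of real phylogenies.

## Population-based simulation model

### State space

The landscape is a lattice of cells partitioned into four concentric
elevational bands (band 0 = lowlands ... band 3 = highlands).  The unit of
simulation is the *population*: one species occupying one cell.  A species
is the set of its populations plus the band where it originated; a cell can
hold at most `K` species (its band's niche width, or species-level carrying
capacity).  Each population carries a temperature preference `Tp`; each
cell has a temperature `Tc` set by its band (20 °C in the lowlands, 5 °C
less per band).

### Processes

All rates are per population; a species with more populations therefore has
a proportionally higher total rate (continuous-time Gillespie simulation,
exponential waiting times on the summed rate).

* **Colonization** (rate `gamma`): the focal population's species attempts
  to occupy one cell drawn uniformly from the cells adjacent to its range
  that it does not already occupy and whose capacity is unsaturated.  With
  local adaptation on, the attempt succeeds with probability
  `exp(-((Tp - Tc)^2) / (2 V))`; `V` is the stabilizing-selection strength
  (V = 5 is strong selection; V > ~1000 effectively disables it).  The new
  population's preference is the focal `Tp` plus a Normal(0, 1)
  perturbation; the source population is unchanged.  Blocked or
  fitness-rejected attempts consume the event (time advances, no state
  change), which keeps the total-rate formula exact.
* **Extirpation** (rate `mu`): the population is removed; a species losing
  its last population is extinct.
* **Diversification** (rate `lambda` of the population's band): the focal
  population is carved off as a new one-cell species, inheriting `Tp`
  unchanged.  Its origin band is that cell's band.  When the parent had a
  single population this is anagenetic replacement (species count
  unchanged); it is logged distinctly.

### Landscape realization

The default cone assigns 58 / 24 / 13 / 5.8 % of the area to the bands
from lowlands to highlands; the plateau variant 20 / 19 / 16 / 40 %.
Neither set sums to 100, so `total_cells` is treated as a *nominal budget*:
each band receives `round(fraction x budget)` cells (cone budget 1000 →
580/240/130/58 cells, 1008 in total; plateau → 200/190/160/400, 950 in
total).  Bands are realized as concentric rings of cells on a polar grid:
cyclic adjacency within a ring, angular-overlap adjacency between
consecutive rings.  This realization reproduces the band areas to the cell
and satisfies the structural invariants (symmetric irreflexive adjacency,
neighbours within one band step, every band internally connected, whole
mountain connected).  Any lattice with those properties would serve; a
square lattice with square rings cannot hit these area fractions,
which is why the polar grid is used.

Elevation-dependent rate profiles are geometric across bands (equal fold
per band step); the profile minimum equals the base rate and the max/min
ratio equals the fold: nine-fold for `lambda` (two-fold robustness
variant), four-fold for `K`.  Cell capacities are the band `K` rounded to
the nearest integer (minimum 1).

### Parameters and calibration

| parameter | default | meaning |
|---|---|---|
| `gamma` | 1.0 | per-population colonization rate (sets the time unit) |
| `mu` | 0.05 | per-population extirpation rate |
| `base_lambda` | 0.005 | per-population diversification rate (profile minimum) |
| `base_K` | 4 | species capacity per cell (profile minimum) |
| `V` | 5 | stabilizing-selection strength when local adaptation is on |
| `total_cells` | 1000 | nominal landscape budget |

`gamma`, `mu`, `base_lambda` and `base_K` are calibration constants of this
implementation, not empirical estimates.  They were chosen, once, so that (i)
clades typically survive and saturate the landscape, (ii) the
geometry-only scenario yields a lowland-peaked gradient in every
replicate, and (iii) species ranges sit in the target occupancy regime
(highland species covering roughly 40 % of their band on average, lowland
species roughly 8 %).  The ratio `mu / lambda` is the
lever that matters: the mean range of a species at saturation scales
almost linearly with it (measured factor ~1.1), because speciation
fragments ranges while extirpation-driven turnover frees the space that
lets the remaining species regrow.

### Initialization, equilibrium, replication

A run starts with one population in a uniformly random cell of the
configured origin band (lowlands or highlands), with `Tp` equal to that
cell's temperature.  Regional richness is sampled every `1 / gamma` time
units; the run stops when the species accumulation curve flattens:
equilibrium is declared at the first time `t` where the least-squares
slope over the trailing window (10 % of elapsed time) is below
`slope_tol` (0.5 species per window) *and* the window mean is within 5 %
of the following window's mean.  The detector is translation-invariant in
time and scales with the richness units.  In local-adaptation runs the
mean `|Tc - Tp|` mismatch is tracked per band; it flattens no later than
richness does, so richness equilibrium defines the end of a run.  Runs are
capped by `max_events` / `max_time`; a clade that dies beforehand is
flagged extinct and excluded from aggregates.

Replicate seeds derive from `(base_seed, scenario_id, replicate)` through
a SHA-256 digest, so grids are reproducible and execution-order invariant.

### Summary metrics

* **EDG strength**: for per-band richness `R`, the peak band is
  `argmax R` (ties to the lowest band) and the strength is
  `(R_max - R_second) / R_max` — the relative drop from the richest band
  to the next richest, in [0, 1].
* **Dispersal provenance**: per band, the fraction of resident species
  whose origin band differs; computed over the standing species at
  evaluation time (cumulative uphill/downhill event counts are available
  from the event log).
* **Proportional occupancy**: per band, the mean over resident species of
  (populations in band) / (band area).
* Gradient strength is evaluated at the equilibrium detection time;
  provenance and occupancy at the final state (the run ends roughly one
  detection window later, well inside the stationary regime).

### What the simulation reproduces, and what it does not

At desk scale (250–500-cell budgets, 16–50 replicates) the model
reproduces: a lowland richness peak in 100 % of geometry-only replicates;
steepening of the gradient when niche width decreases with elevation and
flattening when it increases, with the K profile never relocating the
peak on its own; a flattened gradient under a nine-fold lambda increase; a
peak above the lowlands when lambda and K both increase with elevation
("highlands-have-it-all"); several-fold higher proportional occupancy of
highland than lowland species (~38 % vs ~8 % in the geometry-only
scenario); and a strong provenance asymmetry (highland diversity is
maintained by uphill immigrants far more than lowland diversity by
downhill ones).

One expected contrast does not emerge: a nine-fold lambda increase
combined with a four-fold K decrease yielding a roughly even
highland/lowland split of peak bands.  In this implementation that
scenario remains lowland-peaked.  The reason is quantitative, not a
failed run: with all rates per population, mean range size at saturation
scales as ~1.1 x `mu/lambda_band`, so per-band richness scales as
`area x K x lambda`, and the highland:lowland ratio in the counteraction
scenario is bounded near (1/10) x (1/4) x 9 ≈ 0.23 — further reduced by
downhill spillover of upland-origin species, which inflates lowland
presence counts.  Across the calibrations explored (`mu/lambda` from 2.5
to 50, 250–500-cell grids, whole-range and focal-cell colonization) the
bound held.  A mechanism beyond the processes stated above would be needed
to lift the highland side of this contrast; the corresponding acceptance
test is left failing rather than weakened.

The generator also idealizes real mountains: bands are perfectly
concentric and internally homogeneous, temperature is constant in time,
there is no immigration from outside the mountain, no explicit population
sizes or genetics, and no reproductive isolation.  Passing tests therefore
demonstrate the internal logic of the geometric/ecological argument, not a
fitted description of any empirical system.

## State-dependent diversification framework

### Band discretizer

Species elevations (meters) are cut into three equal-width bands spanning
the clade's recorded range, boundaries at one and two thirds; a species
exactly on a boundary goes to the lower band.

### Model space

Fifteen models cross five transition structures — (a) adjacent bands,
symmetric; (b) adjacent, asymmetric (uphill vs downhill); (c) any band,
symmetric; (d) any band, asymmetric; (e) all six rates free — with three
diversification structures: constant rates (CR), examined-trait-dependent
(ETD: speciation depends on the band), and concealed-trait-dependent
(CTD: speciation depends on a hidden three-state trait).  ETD varies
speciation only; extinction is shared (one `mu`).  CTD mirrors the three
observed states with three concealed states whose transition rates are
tied to the examined transition parameters of the same structure, so CTD
has the same free-parameter count as ETD; tips are summed over concealed
states.  Transition parameter counts: a 1, b 2, c 1, d 2, e 6.

### Likelihood

The standard SSE pruning equations govern the extinction probabilities
`E_i(t)` and subtree likelihoods `D_i(t)` along branches; daughters
combine at nodes with the state's speciation rate.  Because trees are
ultrametric with uniformly sampled tips, `E` is a global function of time
and the `D` equation is linear given `E`; the implementation integrates,
per inter-node epoch, the joint system of `E` and the fundamental matrix
of the `D` equation (adaptive Dormand–Prince 5(4), rtol 1e-8, atol 1e-10,
compiled with numba) and advances all live lineages with one matrix
product, with per-lineage log rescaling.  This is exact to integrator
tolerance and was verified to ~1e-10 against an independent per-branch
`solve_ivp` pruning and against the closed-form constant-rate birth–death
x Markov factorization.

Root treatment: prior = equilibrium frequencies of the transition
generator (uniform fallback for degenerate generators; a uniform or custom
prior is available), and by default the likelihood is conditioned on the
survival of both root lineages by dividing by
`sum_i pi_i lambda_i (1 - E_i)^2`.  An optional global sampling fraction
`f` initializes `E = 1 - f` and scales tip likelihoods by `f`.

### Fitting and model selection

`ElevationSSE(tree, tip_states, ...)` is the model object; `fit()`
maximizes the likelihood with bounded L-BFGS-B on log-rates (bounds
1e-6–1e3) from `n_starts` dispersed start points: a method-of-moments
guess (net diversification from tip count and height, transitions of
order one per tree height) plus log-uniform perturbations within a factor
of ten.  Standard errors come from the finite-difference observed
information in log-rate space (delta method); `summary()` prints the
usual table.  `fit_model_set` fits all fifteen structures and reports AIC
(`2k - 2 logL`), Akaike weights, and pooled family weights
(by diversification structure, dispersal symmetry {a, c} vs {b, d, e},
and adjacency {a, b} vs {c, d, e}).  Models for which no start converges
are flagged and excluded from the weights with a warning.

A forward Gillespie tree simulator (`simulate_sse_tree`) generates
ultrametric trees with Markov state changes under any of the fifteen
structures (stopping when the target tip count is first reached, extinct
subtrees pruned, retries on clade death); it backs the oracle tests and
the simulation-based calibration: on 40-tip trees simulated under the
adjacent-symmetric constant-rate model, the constant-rate family wins the
pooled AIC weight in the large majority of replicates.

### Numerical choices and limitations

Optimizer tolerance 1e-11 on the scaled objective, maxiter 500; the
integrator returns `-inf` for parameter regions where the step size
underflows, which the optimizer treats as a rejected region.  Likelihoods
under ~-1e11 are treated as invalid.  Fits on trees much larger than a
few hundred tips, non-ultrametric trees, time-varying rates and Bayesian
uncertainty are out of scope.  The desk-scale problem sizes used by the
test suite and the acceptance script (250-cell budgets, 4–50 replicates
per scenario, 40-tip trees, 10–20 recovery replicates, single-start fits
in the recovery loop) were chosen as the smallest sizes at which the
qualitative contrasts are stable.
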