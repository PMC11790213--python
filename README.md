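# edgsim

Mechanistic simulation and phylogenetic model selection for **elevational
diversity gradients** (EDGs): why does species richness peak in the
lowlands on some mountains, but at mid or high elevation on others?

The package is aimed at macroecologists and phylogeneticists who want to
disentangle four entangled forces on a mountainside — **geometry** (less
area toward the summit), **niche width** (how many species a site can
hold, `K`), **diversification rate** (`lambda`) and **local adaptation**
to the temperature gradient — and to test the resulting predictions on
real clades.

It has two halves:

1. **A spatially explicit Gillespie simulator** of an endemic clade
   radiating on a banded mountain (cone or plateau).  Populations (one
   species in one cell) colonize adjacent unsaturated cells at rate
   `gamma` (modulated by the fitness
   `exp(-((Tp - Tc)^2)/(2V))` when local adaptation is on), go locally
   extinct at rate `mu`, and bud off new one-cell species at the
   band-dependent rate `lambda`.  Runs proceed to a dynamic equilibrium of
   regional richness; 36 scenarios (3 `K` directions x 3 `lambda`
   directions x adaptation on/off x lowland/highland origin) are run with
   replication through a scenario grid.
2. **A state-dependent speciation–extinction (SSE) framework** over three
   elevational bands: fifteen models crossing five transition structures
   (adjacent/any band, symmetric/asymmetric, all-free) with three
   diversification structures (constant-rate, band-dependent,
   concealed-trait-dependent), fitted to a rooted ultrametric phylogeny
   plus a species-elevation table by maximum likelihood and compared with
   AIC weights (including pooled family weights).

See `docs/methods.md` for the model definitions, parameter meanings,
calibration choices and known limitations.

## Worked example: geometry alone tilts diversity downhill

```python
from edgsim import ScenarioConfig, run_simulation, edg_strength
from edgsim.metrics import dispersal_provenance, proportional_occupancy

cfg = ScenarioConfig(total_cells=250, seed=0, record_events=False,
                     check_every=50, max_events=600_000)
res = run_simulation(cfg)
print("equilibrium:", res.equilibrium, "at t=%.0f" % res.equilibrium_time)
print("per-band richness (low->high):", res.band_richness)
print("peak band, EDG strength:", edg_strength(res.band_richness))
print("provenance:", dispersal_provenance(res.state).round(2))
print("occupancy:", proportional_occupancy(res.state).round(3))
```

prints

```
equilibrium: True at t=40
per-band richness (low->high): [49 24 16 10]
peak band, EDG strength: (0, 0.5102040816326531)
provenance: [0.08 0.17 0.38 0.6 ]
occupancy: [0.082 0.167 0.25  0.4  ]
```

Everything here is uniform across elevation except the mountain's shape,
yet the lowlands hold five times the highland richness (peak band 0 with a
gradient strength of ~0.51): the larger lowland area accumulates and
retains more species.  The provenance row shows the flip side: 60% of
highland residents originated at lower elevations, while lowland
diversity is almost entirely home-grown — and highland species each
occupy a far larger fraction of their band (~40%) than lowland species do
(~8%).

Fitting the model set to a phylogeny:

```python
from edgsim.sse import ElevationSSE, fit_model_set

model = ElevationSSE.from_files("tree.nwk", "elevations.tsv")
results = fit_model_set(model.tree, model.tip_states, n_starts=3, seed=0)
print(results.summary())            # AIC table + pooled family weights
print(results.best.summary())       # estimates and standard errors
```

A single-model fit prints a statsmodels-style table:

```
State-dependent diversification fit
====================================================
model:            a_CR (transition a, CR)
tips:             15
log-likelihood:   -35.4452
free parameters:  3
AIC:              76.8904
converged:        True (1 start(s))
----------------------------------------------------
parameter               estimate     std err
lambda                   0.60762      0.3285
mu                       0.32884      0.5491
q                        0.39847      0.2749
```

## Command line

```bash
edgsim simulate --config scenario.yaml --replicates 10 --seed 1 --out runs/
edgsim grid --landscape cone --total-cells 250 --replicates 10 --seed 1 --out grid_out/
edgsim sse-fit --tree tree.nwk --states elevations.tsv --seed 0 --out fit/
```

`simulate` writes per-replicate event logs (gzipped TSV) and richness
trajectories (CSV); `grid` writes an aggregate CSV, per-replicate metrics
and a JSON manifest of configs and seeds; `sse-fit` writes the model table
and pooled family weights.

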