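# cooccupancy

Multi-species occupancy modelling and circular activity-pattern analysis for
camera-trap surveys of interacting carnivores in human-dominated landscapes.

The package answers two questions about a community of sympatric mesocarnivores
sampled with camera traps:

1. **Spatial**: do species use the same sites more or less often than expected
   from habitat alone, and how does human disturbance (settlements, roads,
   free-ranging dogs) shape site use?
2. **Temporal**: how much do their nocturnal activity patterns overlap?

## The model

Site use is modelled with a multivariate-Bernoulli multi-species occupancy
model (Rota et al. 2016, *Methods in Ecology and Evolution*). For `S` species,
the latent presence vector `z ∈ {0,1}^S` at site `i` has probability

```
ψ(z) ∝ exp( Σ_s z_s f_s + Σ_{s<t} z_s z_t f_st )
```

where the first-order natural parameters `f_s = x_iᵀ β_s` are logit-linear in
site covariates and the second-order parameters `f_st` capture pairwise
co-occurrence beyond independence (negative `f_st` → avoidance). Detection of
species `s` at site `i` on night `j` is Bernoulli with

```
logit p_sij = w_sijᵀ α_s
```

where the nightly design can include camera placement (on/off trail) and the
number of dog photo-events that night (never for the dog itself). Camera
nights with no active camera contribute nothing to the likelihood. Models are
fit by MCMC (affine-invariant ensemble sampler, `N(0,10)` priors on all
coefficients), compared by WAIC, and pruned by backward selection on 80%
credible intervals. Activity patterns are estimated by von Mises kernel
density on the 24-h circle and compared with the overlap coefficient
`Δ₁ = 1 − ½∮|f₁ − f₂|`, with smoothed-bootstrap confidence intervals
(Ridout & Linkie 2009).

## Tests

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, property and oracle checks of
the core scientific claims (likelihood enumeration oracles, closed-form
reductions, WAIC arithmetic, parameter-recovery and interval-calibration
checks on synthetic data). The calibration tests refit many small models and
take several minutes each.

## Worked example

Simulate a study at the default design (40 sites × 6 nights × 4 species,
233 of 240 camera-nights active, 31 of 40 cameras on trails), fit the
generating model, and summarize:

```python
from cooccupancy import simulate, ingest, activity as act
from cooccupancy.occupancy import fit
from cooccupancy.derived import marginal_occupancy, conditional_occupancy

scn = simulate.preset("study_scale")
study = simulate.simulate_study(scn, seed=1)
data = study.study_data()
spec, theta = simulate.scenario_model(scn)

res = fit(spec, data, chains=2, iterations=800, warmup=300, seed=0)
print(f"max R-hat: {res.rhat.max():.3f}")
print(f"WAIC: {res.waic['waic']:.1f}")

m = marginal_occupancy(res, data, "indian_fox")
print(f"fox habitat use: {m.mean:.3f} (80% CRI {m.lo:.3f}-{m.hi:.3f})")
on = conditional_occupancy(res, data, "indian_fox", "jackal", "present")
off = conditional_occupancy(res, data, "indian_fox", "jackal", "absent")
print(f"fox | jackal present: {on.mean:.3f}   fox | jackal absent: {off.mean:.3f}")

events = ingest.collapse_photos_to_events(study.photos)
events = events[act.nocturnal_filter(events["start_time"])]
samples = {sp: act.clock_to_radians(list(g["start_time"]))
           for sp, g in events.groupby("species")}
est = act.bootstrap_overlap(samples["indian_fox"], samples["dog"],
                            B=200, seed=0, species=("indian_fox", "dog"))
print(f"fox-dog nocturnal overlap D1: {est.delta1:.3f} "
      f"(80% CI {est.lo:.3f}-{est.hi:.3f})")
```

Output (about a minute on one CPU):

```
max R-hat: 1.096
WAIC: 706.1
fox habitat use: 0.400 (80% CRI 0.317-0.485)
fox | jackal present: 0.637   fox | jackal absent: 0.354
fox-dog nocturnal overlap D1: 0.717 (80% CI 0.678-0.798)
```

At 40 sites the pairwise interaction is weakly identified, so the sign of a
fitted conditional contrast can differ from the generating value in a single
realization; the test suite checks calibration over many replicates instead
of any single fit.

## Command line

```sh
cooccupancy simulate --preset study_scale --seed 4 --outdir run/
cooccupancy fit      --config model.yaml --indir run/ --outdir run/fit --seed 2
cooccupancy select   --indir run/ --outdir run/sel --seed 3
cooccupancy overlap  --indir run/ --outdir run/ov --seed 9
cooccupancy report   --rundir run/
```

`fit` accepts `--paper-settings` to use the long sampler configuration
(3 chains × 6000 iterations, 2000 warmup) instead of the reduced default.

## Reproducing results

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The script simulates a study at the default design, fits the generating
co-occurrence model and an independence (null) model with the reduced sampler,
and writes the headline quantities — active trap-nights, WAIC for both models
and their difference, maximum R-hat, marginal habitat-use per species,
baseline detection probabilities, and the nocturnal activity-overlap `Δ₁` for
all species pairs — as JSON, each entry `{"value": ..., "n": ...}` where `n`
is the number of draws, sites or events behind the value. All randomness
derives from `--seed`; repeated runs at the same seed are byte-identical.
Runtime is roughly one minute on a single CPU.

## Layout

- `src/cooccupancy/ingest.py` — photo records → collapsed events → detection
  histories, schedules, covariate standardization, collinearity screen
- `src/cooccupancy/occupancy.py` — model spec, likelihood, MCMC fit, R-hat, WAIC
- `src/cooccupancy/selection.py` — credible intervals, backward selection,
  interaction-term selection, WAIC tables
- `src/cooccupancy/derived.py` — marginal/conditional habitat use, response
  curves, detection summaries
- `src/cooccupancy/activity.py` — circular KDE, overlap `Δ₁`, smoothed bootstrap
- `src/cooccupancy/simulate.py` — synthetic-study generator and presets
- `src/cooccupancy/cli.py` — the `cooccupancy` command
- `docs/methods.md` — modelling assumptions and numerical choices
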