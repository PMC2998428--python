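# reefassoc

Habitat-association analysis for juvenile coral-reef fish surveyed on belt
transects, at three nested ecological scales:

1. **Habitat occupancy** — is a species more likely to occur on coral reefs
   or in adjacent macroalgal meadows? Modelled as a Bayesian hierarchical
   logistic regression (habitat covariate, location random intercept)
   fitted with the package's own Metropolis-within-Gibbs sampler.
2. **Live vs. dead coral preference** — does a species sit on live or dead
   coral more than those substrates' benthic availability would predict?
   Tested by whether the 95% confidence interval around the mean
   per-transect percentage of fish groups on a substrate clears the mean
   percent cover of that substrate.
3. **Coral growth-form electivity** — among live-coral users, which colony
   morphologies (branching, corymbose, encrusting, foliaceous, massive,
   plate, submassive) are used disproportionately? Quantified by a
   use/availability selection ratio with a transect-bootstrap confidence
   interval; an index whose CI lower bound exceeds 1 marks a preferred
   form.

Because raw observations for the motivating field study were never
deposited, the package ships a **synthetic survey generator** that emulates
the study design (two habitats, grouped fish, Dirichlet benthic cover,
multinomial microhabitat choice with known electivity weights) and returns
the generating truth, so every analysis stage is verified by parameter
recovery rather than by replaying archived data. The study-wide
species-tally table is included as a packaged fixture
(`reefassoc.load_table1()`).

## Worked example

Simulate a survey with one planted species — higher occurrence on coral
reefs, strong live-coral electivity and strong corymbose electivity — and
recover all three effects:

```python
from reefassoc import (
    McmcConfig, SimulationConfig, SpeciesTruth, generate_survey,
    occupancy_data_from_table, fit_occupancy, posterior_habitat_probabilities,
    classify_habitat_difference, mean_availability, species_preference,
    selectivity_indices, Habitat, Microhabitat, GrowthForm, GROWTH_FORMS,
)

live_w = {m: 1.0 for m in Microhabitat}
live_w[Microhabitat.LIVE_CORAL] = 10.0
gf_w = {g: 1.0 for g in GROWTH_FORMS}
gf_w[GrowthForm.CORYMBOSE] = 8.0
sp = SpeciesTruth(
    species="Demo damselfish", alpha0=1.0, alpha1=-2.5, sigma_loc=0.3,
    electivity_weights=live_w, growth_form_weights=gf_w,
    groups_rate=2.0, mean_group_size=3.0,
)
table, truth = generate_survey(
    SimulationConfig(n_locations=20, transects_per_location=(4, 8),
                     prop_coral_locations=0.6, species_params=[sp], seed=42)
)

fit = fit_occupancy(occupancy_data_from_table(table, "Demo damselfish"),
                    McmcConfig(seed=1))
probs = posterior_habitat_probabilities(fit)
classify_habitat_difference(fit)          # 'coral_greater'

avail = mean_availability(table, Habitat.CORAL_REEF)
pref = species_preference(table, "Demo damselfish", avail)

results = selectivity_indices(table, "Demo damselfish", n_boot=2000, seed=2)
```

Output of the full script (97 transects, 122 groups):

```
p(coral) = 0.75 [0.63, 0.86]
p(algal) = 0.20 [0.08, 0.36]
classification: coral_greater
live use 85.2% [77.0, 93.4] vs availability 39.2% -> prefers_live=True
corymbose index w = 9.98 [8.21, 12.03], preferred=True
```

All three planted effects (α₁ = −2.5 on the logit scale, 10× live-coral
electivity, 8× corymbose electivity) are flagged at their respective tiers.

## Command line

```sh
reefassoc simulate  --config sim.yaml --out-observations obs.csv --out-transects tr.csv
reefassoc summarize --observations obs.csv --transects tr.csv
reefassoc occupancy --observations obs.csv --transects tr.csv --species "Demo damselfish"
reefassoc preference --observations obs.csv --transects tr.csv
reefassoc selectivity --observations obs.csv --transects tr.csv
reefassoc run --config pipeline.yaml --out results/   # full pipeline
```

`reefassoc run` executes all stages (tallies → occupancy → preference →
selectivity, with the ≥5-individuals and ≥12-transects inclusion rules)
and renders byte-stable CSV/JSON reports; it exits nonzero if any stage
fails.

## Analysis scripts

`analysis/01…06` are thin numbered drivers that tell the story end to end
on a simulated survey: generate data, tally species, fit the occupancy
model, run the preference tests, compute growth-form electivities, and run
the validation studies. Each writes its tables under `results/`.

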