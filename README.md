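# thermochoice

Hierarchical Bayesian discrete-choice resource selection in dynamic
thermal landscapes.

`thermochoice` is for movement and thermal ecologists who want to analyse
— or to study the statistical behaviour of — resource selection by
radio-tracked ectotherms when one of the key resources, near-surface air
temperature, changes by the hour. It implements the full analysis
pipeline around a mixed (random-coefficient) conditional logit fitted by
MCMC, together with a synthetic-data generator that produces landscapes,
temperature fields and telemetry from *known* selection coefficients, so
every stage of the inference can be validated by parameter recovery
rather than by faith.

## The model

Each telemetry fix of individual *j* is treated as a discrete choice
among *I* alternatives (the used location plus *I* − 1 locations sampled
uniformly within the individual's daily-movement radius). The utility of
alternative *i* is linear in its standardized covariates,

```
U_ij = β_j' x_ij ,
```

and the probability the individual selects it is the conditional-logit
softmax

```
ψ_ij = exp(U_ij) / Σ_i exp(U_ij) .
```

Individual coefficient vectors are tied together by a normal population
distribution, `β_jk ~ N(μ_k, σ_k²)`, which absorbs the non-independence
of repeated fixes of the same animal. Priors are vague
(`μ_k ~ N(0, 100)`, `σ_k ~ U(0, 10)`); posteriors come from a
Metropolis-within-Gibbs sampler (adaptive random-walk updates for each
β_j and σ_k, conjugate draws for μ_k) run as three chains of 25,000
iterations, 10,000 burn-in, thinned 1-in-15 → 3,000 retained draws.

Covariates per location and time: buffer (15 m) mean and SD of canopy
cover, buffer mean of understory cover, buffer mean temperature, its
centered square, and buffer SD of temperature, plus seasonal
(day-of-year) interactions for everything except the linear/quadratic
temperature terms. Seven nested candidate models from a null
(random-choice) model up to the full habitat + temperature + season model
are ranked by WAIC, with Estrella's pseudo-R² reported per model.

## Worked example

The `thermochoice` CLI drives the pipeline from one YAML config (see
`docs/methods.md` for every knob). With 12 simulated individuals × 40
fixes on a 1 km² landscape, generating coefficients set to the
field-study signs (canopy −0.21, canopy SD +0.09, …, temp SD × day
+0.24) and a reduced chain schedule:

```bash
thermochoice simulate      -c demo.yaml   # rasters, telemetry, true betas
thermochoice build-choices -c demo.yaml   # availability radius + choice sets
thermochoice fit           -c demo.yaml   # MCMC for the full model
thermochoice evaluate      -c demo.yaml   # WAIC ranking
thermochoice predict       -c demo.yaml   # effect curves + use surfaces
```

`evaluate` prints (this run):

```
                      name    waic    lppd  p_waic  estrella_r2  n_sets
habitat_temperature_season 1592.03 -741.51   54.51         0.42     480
              habitat_only 1607.88 -785.70   18.24         0.28     480
          temperature_only 1652.33 -804.50   21.66         0.22     480
                      null 1720.09 -860.04    0.00         0.00     480
```

The generating model ranks first; the null model (random choice among the
6 alternatives of each set) scores Estrella's R² of exactly 0.00 and the
analytic WAIC 2·n·ln 6. The fitted coefficient summary recovers the
generating signs — e.g. this run gives canopy −0.36 (95% CrI −0.55,
−0.17) and temp SD × day-of-year +0.22 (0.07, 0.34) — and `predict`
writes five dated relative-probability-of-use surfaces (ESRI ASCII grids)
showing high scores along forest–field edges, with the preference for
open field cells declining from late April to late August.

## Layout

- `src/thermochoice/landscape.py` — synthetic forest/field mosaics, ASCII-grid I/O
- `src/thermochoice/temperature.py` — queryable space–time temperature field
- `src/thermochoice/telemetry.py` — choice-driven movement simulation with known β
- `src/thermochoice/covariates.py` — buffer statistics and z-scoring
- `src/thermochoice/choice_sets.py` — availability radius, used/available sampling
- `src/thermochoice/model.py` — hierarchical conditional logit + MCMC sampler
- `src/thermochoice/evaluation.py` — WAIC, Estrella's R², model ranking
- `src/thermochoice/prediction.py` — seasonal effect curves, use surfaces
- `src/thermochoice/cli.py` — the `thermochoice` command

`docs/methods.md` documents the model, the generator's assumptions,
numerical choices and known limitations.
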