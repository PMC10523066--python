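# paleocmr

Capture–mark–recapture estimation of extinction selectivity in the
fossil record: does a genus's **geographical range** or its **body
size** better predict whether it survives a geologic stage, and does
that change during mass extinctions?

The package is aimed at palaeobiologists working with stage-resolved
genus occurrence data (Paleobiology Database downloads) and genus-level
body-size compilations. It treats genera as individuals in a
capture–recapture design whose occasions are geologic stages, so that
true extinction is separated from mere non-sampling.

## The model

For genus *i* at stage *t*, three logit-linear parameter families are
estimated jointly under the Pradel seniority likelihood:

- survival φᵢₜ (extinction probability q = 1 − φ),
- seniority γᵢₜ (probability of having already been extant at t − 1;
  the time-reversed analogue of survival, which makes origination
  estimable),
- detection pᵢₜ (probability an extant genus is sampled — the
  fossil-record incompleteness term).

Each family's predictor combines stage fixed effects (`time`), the
class-standardized body size (`BS`, log10 biovolume), the
class-×-stage-standardized geographical range (`GR`, log10 maximum
great-circle distance in km), and 0/1 regime flags: extinction models
may interact traits with a mass-extinction indicator (`ME`, the Big
Five stages), origination models with the following recovery stage
(`Rec`). A model such as

    extinction ~ time + BS + GR × ME

says size selectivity is shared across regimes while range selectivity
has a distinct mass-extinction value. The canonical candidate set
crosses 11 extinction × 11 origination structures with one sampling
structure (`~time + BS`) — 121 models per class — ranked by AICc; the
coefficients of models holding ≥ 0.01 Akaike weight are averaged
(weights renormalized, absent terms contributing zero,
Burnham–Anderson unconditional SEs) and reported as the change in
log-odds of extinction, ln(q/(1−q)), per +1 SD of each trait. Negative
range coefficients mean narrowly distributed genera die more.

A fully seeded synthetic fossil-record generator (sizes, latent AR(1)
ranges, regime-dependent survival, size-biased detection,
occurrence coordinates with exact great-circle ranges) backs every
stage of the pipeline with parameter-recovery experiments, so the whole
analysis runs and validates without any external download.

## Worked example

Simulate the two-regime demonstration dataset (strong background range
selectivity, erased at three mass-extinction stages), prepare it, fit
the reduced 8-model set and average coefficients:

```bash
python analysis/01_simulate_fixtures.py
python analysis/02_prepare_histories.py
python analysis/03_fit_model_set.py
```

The first two steps print the record actually generated and encoded:

```
regime_demo : 2000 genera x 30 stages, 34363 occurrences, 1948 genera enter the record
Synthetica: 1948 capture histories over 30 stages; detection cell fill 0.10
```

and the third prints the AICc table and the model-averaged selectivity:

```
Synthetica: best model ~time + BS + GR × ME (weight 0.62)
 rank                extinction    dAICc   weight
    1      ~time + BS + GR × ME 0.000000 0.618507
    2 ~time + BS × ME + GR × ME 1.326612 0.318621
    3           ~time + BS + GR 5.599827 0.037615
    4      ~time + BS × ME + GR 6.396330 0.025258

model-averaged selectivity (log-odds of extinction per SD):
     class trait          regime  coefficient       se    ci_low   ci_high
Synthetica  size      background    -0.290904 0.016899 -0.324025 -0.257783
Synthetica  size mass_extinction    -0.248783 0.086620 -0.418555 -0.079010
Synthetica range      background    -0.294784 0.035212 -0.363799 -0.225769
Synthetica range mass_extinction     0.064117 0.167061 -0.263317  0.391552
```

Read: a two-regime extinction model ranks first with decisive support;
the background range coefficient is clearly negative (one SD more
geographical range lowers the log-odds of extinction by ≈ 0.29, i.e.
narrow-ranged genera die more), while the mass-extinction range
coefficient is indistinguishable from zero — range selectivity erased
during the flagged stages, exactly the truth built into the fixture.
Magnitudes through the occurrence pipeline are attenuated relative to
the generating value (−0.8) because unsampled span stages carry the
nominal 1 km range (see `docs/methods.md`); fitting the same fixture on
the generator's own covariates (`analysis/04_regime_recovery.py`, 10
replicates) recovers background −0.82 and mass-extinction −0.01.
Wald-interval calibration under the generating model is
`analysis/05_interval_calibration.py`.

The library surface mirrors the pipeline: `load_stage_table` /
`flag_big_five` (stage bins and regime flags), `read_occurrences` →
`prepare_class_histories` (filters, great-circle ranges, z-scores,
capture histories), `enumerate_model_set` / `fit_model` /
`rank_models` / `average_coefficients`, and `simulate` /
`make_fixture` for synthetic data. A `paleocmr` CLI wraps the same
steps (`prepare`, `fit`, `select`, `report`, `simulate`, `recover`)
with YAML configs, per-fit caching and seeded, header-stamped outputs.

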