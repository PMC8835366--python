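# comorbmap

Bayesian shared-component spatial modelling of childhood disease
co-morbidity on areal data.

## The problem

In low- and middle-income settings, children under five frequently
suffer acute respiratory infection (ARI), diarrhoea, and stunting
together, and the three conditions share risk factors (sanitation,
water quality, air pollution, nutrition).  Ecological analyses ask
whether this child-level co-occurrence is also visible at the level of
administrative areas: do the same areas carry elevated risk for several
conditions at once?  `comorbmap` is a toolkit for that question, built
around the joint spatial analysis of ARI, diarrhoea and stunting across
Nigeria's 36 states + FCT in the pooled 2008/2013/2018 Demographic and
Health Surveys.  The child-level survey micro-data are request-only, so
the package ships a faithful synthetic generator for method development
and validation.

## The model

For child *j* in area *i*, disease *d* ∈ {1=ARI, 2=diarrhoea,
3=stunting} is Bernoulli(π_ijd) with

    logit π_ij1 = α₁ + x′β₁ + ϑ·υ¹²ᵢ + θ·υ¹³ᵢ + ∂₁·υᵢ + s_i1
    logit π_ij2 = α₂ + x′β₂ + (1/ϑ)·υ¹²ᵢ + δ·υ²³ᵢ + ∂₂·υᵢ + s_i2
    logit π_ij3 = α₃ + x′β₃ + (1/θ)·υ¹³ᵢ + (1/δ)·υ²³ᵢ + ∂₃·υᵢ + s_i3

a **shared-component** decomposition of each disease's state random
effect: three pairwise-shared spatial fields υ¹², υ¹³, υ²³, one
all-disease field υ, and disease-specific residual fields s_d, each with
an intrinsic CAR (ICAR) prior on the areal adjacency graph and a
sum-to-zero constraint per connected component.  The positive *gradient
weights* ϑ, θ, δ, ∂ let each disease load asymmetrically on a shared
field (pairwise weights enter as w and 1/w; ∂₁∂₂∂₃ = 1).  Fixed effects
cover residence, mother's education, household wealth, child sex and age
band, mother's age, and survey year.  Posterior sampling is an adaptive
Metropolis-within-Gibbs scheme with conjugate precision updates and an
exact Gibbs step for the weakly identified field decomposition; model
comparison uses DIC.  See `docs/methods.md` for the full account.

The descriptive layer reproduces the study's summary machinery:
per-year/pooled frequency tables, maximum-likelihood tetrachoric
correlations between disease pairs, and per-area proportion
correlations.

## Worked example

`examples/01_descriptives_from_published_margins.py` rebuilds the pooled
study descriptives from the published per-year counts:

```
pooled children:        61,579
ARI cases:              2,923
diarrhoea cases:        6,675
stunted:                8,940
ARI and diarrhoea:      1,013
all three illnesses:    173
rural share:            68%
no-education share:     46%

ARI x diarrhoea 2x2 cells (n11, n10, n01, n00): (1013, 1910, 5662, 52994)
tetrachoric rho = 0.4186 (se 0.0108)
```

The pooled column is the sum of the three survey years; the 2×2 table
is assembled from the pooled margins, and the tetrachoric ρ is the
correlation of the latent bivariate normal underlying the two binary
indicators — 0.42 here, i.e. children with diarrhoea are far more likely
to also have ARI than independence would predict.  (The analogous
published estimate is 0.371; it was computed on child-level micro-data
whose pair-specific missingness the printed aggregates do not capture,
so the two differ — see `docs/methods.md`.)

The other examples simulate DHS-like data and exercise the full
pipeline:

- `02_simulate_and_describe.py` — generator + ecological correlations,
- `03_fit_shared_component_model.py` — full posterior fit, odds ratios,
  gradient-weight and latent-field recovery,
- `04_model_comparison_dic.py` — shared vs no-sharing DIC comparison.

A thin CLI mirrors the pipeline for shell use:

```sh
comorbmap simulate --seed 1 --out runs/sim
comorbmap describe --records runs/sim/records.csv --out runs/desc
comorbmap fit --records runs/sim/records.csv \
              --adjacency runs/sim/adjacency.txt --seed 1 --out runs/fit
comorbmap assess --chain runs/fit/chain \
              --records runs/sim/records.csv --out runs/assess
```

Every run writes a YAML manifest (inputs, seed, version, wall time);
identical config + seed gives byte-identical outputs.

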