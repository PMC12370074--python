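# crocsurvey

Analysis pipeline for drone-based crocodilian river surveys: mission-level
abundance indices, occupancy modelling with imperfect detection, and
two-species spatial co-occurrence, for the gharial (*Gavialis gangeticus*)
and mugger (*Crocodylus palustris*) populations of a 73 km stretch of the
East Rapti river system (Chitwan National Park, Nepal).

It is written for ecologists who have (or want to emulate) drone survey
products — georeferenced detection points, flight paths and a river-ribbon
polygon — and want the full chain from raw points to habitat-use
inference:

- **Survey metrics** — per-mission relative abundance index
  (RAI = detections per flight hour), observed density (OD = detections per
  km² imaged), campaign totals/means/SDs, and a boat-vs-drone cost-per-km
  comparison.
- **Gridding** — checkerboard lattice of 0.04 km² cells over the river
  ribbon, ~200 m flight-path segments as spatial replicates (1–5 per
  cell), single-linkage dedupe of same-animal re-captures across
  overlapping frames, and cells × replicates encounter histories.
- **Occupancy** — single-season models `ψ(.), p(.)` and `ψ(.), p(survey)`
  with the MacKenzie-type site likelihood
  `L_i = ψ Π_j p_j^{y_ij}(1−p_j)^{1−y_ij} + (1−ψ)·1[no detection]`,
  MLE on the logit scale with delta-method SEs, conditional occupancy,
  naive-vs-model comparison, used-area `ψ̂ × A`, and AIC machinery
  (ΔAIC, Akaike weights, ΔAIC < 2 competing rule).
- **Co-occurrence** — the two-species model with four latent states
  `(ψ_AB, ψ_A−ψ_AB, ψ_B−ψ_AB, 1−ψ_A−ψ_B+ψ_AB)`, `ψ_AB = φ ψ_A ψ_B`
  (φ = species interaction factor) and detection interaction δ,
  a log-scale Wald CI for φ, and the AIC comparison against forced
  independence (φ = 1).
- **Synthetic surveys** — a generator reproducing the campaign's
  statistical structure (809 cells, ψ = 0.47/0.24, φ = 1.94, weak
  survey-specific detection, clustered detection points), used by every
  test and the recovery studies.

## Worked example

```
$ python analysis/03_survey_metrics.py
field campaign (27 missions):
  total flight time 798 min, 205 gharials, 118 muggers
  mean RAI: gharial 14.86, mugger 9.21 detections/hour
  mean OD:  gharial 5.7, mugger 4.87 detections/km^2
  boat survey: US$1507 over 72.0 km -> US$20.93/km
  drone survey: US$431 over 702.66 km -> US$0.61/km
  drone saving vs boat: 97% per km
```

The campaign flew 798 minutes and counted 205 gharials and 118 muggers;
on average a flight hour yielded ~15 gharial and ~9 mugger detections, and
the drone surveyed a km of river for about 3% of the boat survey's cost.

Simulating a survey and fitting the co-occurrence model:

```
$ python analysis/01_simulate_survey.py --seed 1
simulated 809 cells (seed 1)
  gharial: 171 individuals generated (36% floating)
  mugger: 177 individuals generated (18% floating)
$ python analysis/05_fit_cooccurrence.py --seed 1
two-species co-occurrence model (synthetic survey):
  phi-hat 0.89 (SE 0.26, 95% CI 0.50-1.58)
  ...
  deltaAIC vs phi=1 model: 1.96 (weights 0.27 / 0.73)
  verdict: independent
```

A single weak-detection survey often cannot distinguish φ = 1.94 from
independence — which is exactly why the recovery study
(`analysis/06_parameter_recovery.py`) averages over many simulated
surveys; see `docs/methods.md` for what recovers and what is biased at
these detection levels.

The full pipeline (simulate → histories → metrics → fits → report tables
with a run manifest) is one command:

```
crocsurvey run --seed 1 --out results/pipeline
```

The numbered scripts under `analysis/` are thin drivers over the library
in `src/crocsurvey/`; every computation they print lives in the package
and is unit-tested.

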