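# adaptddm

Analysis pipeline for decomposing perceptual-adaptation aftereffects into
sensory (drift-rate) and decisional (bound-height) components with
drift-diffusion models of a two-alternative facial-expression judgment
(happy vs. sad along a 41-image morph line, stimulus strength in [0, 1]).

Because no raw behavioral data are publicly deposited for this design, the
pipeline ships a first-class synthetic-data generator with the same
statistical structure (unit-variance evidence accumulation between two
absorbing bounds, per-stimulus drift rates, Gaussian nondecision time),
and every estimator is validated by parameter recovery against that
generator's ground truth.

## What is implemented

- **`trial_data`** — trial-table I/O (delimited text), response-time
  outlier filtering (> 5 s), pooling across participants, and the
  PSE-alignment + 19-bin / two-thirds-participation binning procedure for
  designs where stimulus sets differ across subjects.
- **`synthetic_data`** — trial simulation via Euler–Maruyama with
  Brownian-bridge crossing corrections; multi-subject experiment builders
  for a fixed shared stimulus set and a per-subject "balanced" design
  recentred on the model-implied PSE; config-driven adaptation effects
  (drift shift toward the adaptor, bound reduction, bound asymmetry).
- **`psychometrics`** — maximum-likelihood logistic fits in the
  multiplicative form `logit P(sad) = b0 (S + b1)` (PSE = −b1), the joint
  three-condition variant with per-condition PSE changes and an adapted
  slope change, trial-level bootstrap SEs for PSE shifts, an
  across-subject bootstrap aggregation (10^4 iterations) for p-values,
  and the model-free per-stimulus logit-evidence profile.
- **`ddm_core`** — shared parameterization: bound mean `B`, bound offset
  `dB` (upper/sad bound = `B − dB`, lower/happy bound = `B + dB`),
  nondecision mean (SD = mean/3), and per-stimulus or reduced
  (linear-rule + free extremes) drift maps.
- **`ddm_analytic`** — closed-form choice probability and mean RT for the
  two-bound diffusion, and the fast 14-parameter fit (11 drifts + 2 bound
  parameters + nondecision mean) to per-stimulus choice fractions and
  mean RTs, with the drifts profiled out cell by cell.
- **`ddm_fpe`** — first-passage densities via Crank–Nicolson solution of
  the Fokker–Planck equation with absorbing bounds, RT densities by
  convolution with the truncated-Gaussian nondecision distribution, full
  joint choice/RT likelihood, the 7-parameter reduced-model MLE, and
  bootstrap parameter SEs (40–60 refits).
- **`contribution`** — counterfactual partition of an
  adapted-vs-unadapted PSE shift into sensitivity (C_S), bound (C_B), and
  interaction (C_BxS) components, with the interaction split evenly into
  the two overall contributions.
- **`cli`** — a `click` CLI (`simulate`, `fit`, `partition`, `report`,
  `all`) and a YAML-configured end-to-end pipeline driver.

## CLI

```sh
adaptddm all --out-dir run --seed 1          # simulate + fit + partition
adaptddm simulate --config config.yaml
adaptddm fit run/pooled_trials.csv --method fpe --condition unadapted --out fit.json
adaptddm partition fit_unadapted.json fit_happy_adapted.json
adaptddm report run                           # psychometric/chronometric figure
```

A YAML config can set any `PipelineConfig` field (`design_kind`,
`n_subjects`, `n_per_stimulus`, effect sizes under `effects:`, solver grid,
bootstrap counts, seeds); the resolved config is echoed into the run
directory along with a ground-truth manifest, per-stage tables, fit
records, and a log.

## Conventions

- Evidence has variance 1 per second; time is in seconds. Published bound
  values in the original report use an unstated internal scaling, so no
  numeric identity with those parameter tables is claimed.
- Positive drift and the upper bound correspond to "sad"; a positive
  bound offset moves the sad bound closer (zero-drift upper-absorption
  probability `(B + dB) / 2B`).
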