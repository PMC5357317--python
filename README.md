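# homestay

A tested pipeline from raw GPS traces and momentary affect ratings to a
48-effect grid of mixed-model estimates linking *homestay* (fraction of a
time window spent at the inferred home location, a proxy for social
isolation) to state affect, with depression and social-anxiety symptoms as
moderators — plus a synthetic-cohort generator with known ground truth so
every stage can be exercised and validated without any participant data.

## Pipeline

```
simulate --> preprocess --> features --> fit --> report
```

* **simulate** — synthetic cohort: per-participant home/away mobility
  episodes (nights at home, exact daytime home propensities), GPS fixes
  every 150 s with isotropic jitter and gap-run missingness, up to six EMA
  prompts per day in 2-hour windows (09:00–21:00) with partial compliance,
  and trait scores (SIAS, DASS-21 depression) from calibrated truncated
  normals. A configurable latent coupling (optionally lagged and
  SIAS-moderated) ties affect to homestay; ground truth is written to
  `truth.json`.
* **preprocess** — stay detection (30 m spatial / 30 min temporal
  thresholds, 5 min minimum dwell), agglomeration into stay clusters, home
  inference (modal nighttime locality, 00:00–06:00), last-observation-
  carried-forward gap imputation, and a completeness audit (fixes observed /
  possible in the 10:00–18:00 window).
* **features** — 4-hour prompt-pair change windows and daily 10:00–18:00
  windows with same-day / previous-day / next-day affect alignment; homestay
  as the personal-average-normalised ratio (log-transformed) and as the
  any-home binary coding.
* **fit** — 2 outcomes × 4 framings × 2 affect variables = 16 mixed models
  with crossed subject/day random intercepts (plus a subject-grouped random
  slope on window length for the 4-hour framing). Continuous outcomes use a
  profiled-REML linear mixed model (standardized betas); binary outcomes use
  a Laplace-approximation logistic mixed model (unstandardized betas). Also
  fits between-subjects trait models (SIAS + DASS predicting homestay).
* **report** — the 48-effect table, significance counts at α = .05, an exact
  binomial upper-tail test of the significance count, and an interaction
  plot of predicted next-day home probability at ±1 SD of SIAS.

## CLI

All stages share one working directory and one flat YAML config (defaults
are used when `--config` is omitted; every threshold is a key):

```sh
homestay simulate   --config study.yaml --out work/
homestay preprocess --config study.yaml --out work/
homestay features   --config study.yaml --out work/
homestay fit        --config study.yaml --out work/
homestay report     --config study.yaml --out work/
```

Example config:

```yaml
n_participants: 60
n_days: 14
gps_interval: 150
compliance_rate: 0.42
coupling_lag: 1
moderation_na_sias: 15.0
seed: 7
```

All interchange formats are plain CSV (`gps.csv`, `ema.csv`, `traits.csv`,
`stays.csv`, `home.csv`, `timeline.csv`, `completeness.csv`,
`features.csv`, `effects.csv`) plus JSON fits and per-stage run metadata.

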