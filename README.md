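# audiorules

Rule-based diagnosis of occupational noise-related hearing disorders
(ONRHD) from pure-tone audiograms, with the full validation apparatus
used to benchmark such a tool against expert judgment: diagnostic
validity metrics, Cohen's kappa, and a 5-fold cross-validation harness.
A seeded synthetic cohort generator makes the whole pipeline runnable
and testable without any external data.

The intended users are occupational-health practitioners and
epidemiologists who screen workers' hearing-conservation audiograms in
bulk: per worker and per ear, baseline and annual pure-tone thresholds
(dB HL at 500–8000 Hz) go in, and six binary diagnostic calls come out,
together with flags for audiograms that need repeating or reporting.

## The rules

Let `T(f)` be the annual-audiogram threshold (dB HL) at frequency `f`,
and define two pure tone averages:

```
PTA_speech = [T(500) + T(1000) + T(2000) + T(3000)] / 4
PTA_sts    = [T(2000) + T(3000) + T(4000)] / 3
```

Per ear:

- **Hearing loss** — `T(f) > 20 dB` at any tested frequency (strict).
- **Hearing impairment** — `PTA_speech ≥ 25 dB` relative to the 0-dB
  reference.
- **Standard threshold shift (STS)** — `PTA_sts(annual) −
  PTA_sts(baseline) ≥ 10 dB`. A retest within 92 days of the annual test
  resolves it: shift still present → **permanent (PSTS)**; resolved →
  **temporary (TSTS)**; no in-window retest → *pending* (repeat flag).
- **Noise-induced hearing loss (NIHL)** — the high-frequency notch
  conjunction: all five notch terms
  `T(3000)−T(1000), T(4000)−T(500), T(4000)−T(1000), T(6000)−T(500),
  T(6000)−T(1000) ≥ 15 dB`
  and ≥10 dB recovery at 8 kHz
  (`T(3000)−T(8000), T(4000)−T(8000), T(6000)−T(8000) ≥ 10 dB`).
- **Normal** — none of the five positive categories.

Worker-level calls are the union over ears (normal only when both ears
are normal). All cutoffs and the NIHL recovery-term sign are
configurable through `RuleConfig`; see `docs/methods.md` for the
rationale behind each default.

Validation compares the rules' calls with gold-standard labels per
category: sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`, PPV, NPV,
and Cohen's kappa `κ = (p_o − p_e)/(1 − p_e)` with Landis–Koch
interpretation bands, aggregated as mean ± SD across k seeded folds.

## Worked example

```
$ audiorules simulate --n 320 --seed 7 --out-prefix demo
wrote demo_audiograms.csv and demo_gold.csv (n=320, seed=7, 161 workers with >=1 finding)

$ audiorules classify --input demo_audiograms.csv --output demo_results.csv
classified 320 workers -> demo_results.csv (104 flagged for follow-up)

$ head -4 demo_results.csv
worker_id,ear,normal,hearing_loss,hearing_impairment,psts,tsts,nihl,sts_pending,repeat_required,report_required
W001,L,0,1,1,0,0,0,0,0,1
W001,R,0,1,1,0,0,0,0,0,1
W001,worker,0,1,1,0,0,0,0,0,1
```

The simulated cohort has 320 workers, 161 (50.3%) with at least one
noise-related finding; worker W001 has broadband threshold elevation in
both ears, so both the per-ear rows and the worker summary row call
hearing loss and hearing impairment, and the case is flagged for
reporting. Cross-validating the rules against the cohort's gold labels:

```
$ audiorules validate --input demo_audiograms.csv --gold demo_gold.csv \
      --folds 5 --seed 7 --report demo_report.csv
# audiorules 0.1.0 | k=5 seed=7 unit=worker sd=across-folds(sample) fold_sizes=[64, 64, 64, 64, 64]
category            sensitivity_mean_pct  ...  kappa_mean  kappa_sd
normal                             100.0  ...         1.0       0.0
hearing_loss                       100.0  ...         1.0       0.0
hearing_impairment                 100.0  ...         1.0       0.0
psts                               100.0  ...         1.0       0.0
tsts                               100.0  ...         1.0       0.0
nihl                               100.0  ...         1.0       0.0
```

Because the generator's gold labels are produced by an independent
transcription of the same rules, every category sits at the
self-consistency ceiling — 100.0 ± 0.0 for all validity metrics and
κ = 1.000 ± 0.000 in folds of 64. This is the expected deterministic
baseline; real expert labels diverge from the rules wherever clinical
judgment uses different criteria (NIHL in particular), which you can
emulate with `audiorules.simulate.flip_labels`.

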