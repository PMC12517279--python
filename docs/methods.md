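# Methods

## Scope and model

`audiorules` implements a deterministic, rule-based classifier for
occupational noise-related hearing disorder (ONRHD) surveillance. The
unit of analysis is a worker with per-ear baseline and annual pure-tone
audiograms (thresholds in dB HL at 500, 1000, 2000, 3000, 4000, 6000
and 8000 Hz) and, where a threshold shift needs resolution, a retest.
Six binary categories are called per ear and aggregated per worker:
normal hearing, hearing loss, hearing impairment, permanent standard
threshold shift (PSTS), temporary standard threshold shift (TSTS), and
noise-induced hearing loss (NIHL). The classifier has no fitted
parameters: every call is a conjunction of threshold inequalities over
the audiogram.

Assumptions baked into the rules:

- Thresholds are air-conduction dB HL referenced to audiometric zero;
  bone conduction, masking and conductive/sensorineural typing are out
  of scope.
- The annual audiogram is the diagnostic event: hearing loss,
  impairment and NIHL are evaluated on it, with the baseline used only
  for shift detection and the retest only for shift resolution. Whether
  a spreadsheet-style implementation would also rescreen the baseline
  is ambiguous; evaluating the surveillance event is the conventional
  reading and is what we implement.
- The population is of working age and screened for presbycusis by
  eligibility, so no age correction is applied.
- Severity grading (mild/moderate/...) is deliberately collapsed to a
  binary hearing-loss call.

## Rule parameters

All live in `RuleConfig`; defaults are the published criteria.

| parameter | default | meaning |
|---|---|---|
| `loss_cutoff_db` | 20 | hearing loss when any threshold is **strictly** above this |
| `impairment_cutoff_db` | 25 | impairment when speech PTA (500/1k/2k/3k Hz) is ≥ this |
| `sts_shift_db` | 10 | STS when the 2/3/4 kHz PTA worsens by ≥ this vs baseline |
| `nihl_notch_db` | 15 | minimum depth of each of the five notch terms |
| `nihl_recovery_db` | 10 | minimum 8-kHz recovery for each of the three recovery terms |
| `retest_window_days` | 92 | "within 3 months" retest window, in calendar days |
| `recovery_sign` | `corrected` | orientation of the NIHL recovery terms (below) |

Inclusivity follows the criteria as worded: the loss cutoff is strict
(`> 20`), everything else inclusive (`≥`). PTAs are exact arithmetic
means kept at full precision; report rounding (one decimal for
percentages, three for kappa, round-half-up) happens only in the report
layer.

Two defaults deserve comment because the published formulation is
internally inconsistent:

- **STS PTA frequency set.** The displayed shift formula names a
  9,000 Hz term, which is not a tested frequency; the accompanying
  prose and the standard threshold-shift convention both use 2000,
  3000, 4000 Hz. We use {2000, 3000, 4000} and treat the 9,000 as a
  typographical slip.
- **NIHL recovery sign.** The typeset recovery conditions read
  `T(8000) − T(notch) ≥ 10`, i.e. the 8-kHz threshold must be *worse*
  than the notch — the opposite of "recovery at the high frequency",
  which by the cited notch criteria means a *better* (lower) 8-kHz
  threshold. Default `corrected` mode implements true recovery
  (`T(notch) − T(8000) ≥ 10`); `literal` mode retains the typeset
  inequalities for auditability.
- **NIHL conjunction.** The prose describes a notch at "3, 4 **or**
  6 kHz", but the formula ANDs all five notch terms (and omits a
  `T(3000) − T(500)` term). We implement the formula exactly as
  printed — the conjunction — and add no terms.

Other genuinely open points, decided here: a *pending* (unresolved)
shift is not a diagnosis — normal is computed from the five confirmed
categories, and the pending marker is carried separately and surfaced
through the repeat flag; worker-level calls are the per-category union
over ears (the conservative surveillance choice), with the permanent
shift dominating when one ear resolves permanent and the other
temporary; action flags trigger on pending shifts (repeat) and on
PSTS/NIHL/impairment (report), all configurable.

## Validation apparatus

Each category is scored one-vs-rest at worker level (ear level is
available via `unit="ear"`): sensitivity, specificity, PPV and NPV from
the 2×2 table, plus Cohen's kappa
`κ = (p_o − p_e)/(1 − p_e)`. A metric whose denominator is zero is
*undefined* and excluded from fold aggregation with an explicit count —
never imputed as 0 or 1. When both raters are constant (`p_e = 1`),
kappa is defined as 1.0 under perfect observed agreement and 0.0
otherwise, so all-negative folds of rare categories behave sensibly. A
large-sample z-test of κ = 0 (Fleiss null standard error) accompanies
the pooled kappa.

The k-fold harness (default k = 5) shuffles workers with a seeded RNG
and splits contiguously into folds differing by at most one in size;
320 workers give five folds of 64. Because the rules have no tunable
parameters, the per-fold "training" step is a structural no-op — a rule
audit that validates the configuration and computes training-fold
prevalences — retained so the harness mirrors a conventional
train/test loop. Fold metrics are aggregated as mean ± SD; the SD
across folds is the sample SD (k − 1 denominator, conventional for
small k; population SD available via `sd_mode`). Pooled metrics over
the concatenated test folds equal whole-dataset metrics exactly, for
any seed, precisely because the classifier is deterministic and
untrained — a property the tests assert.

## Synthetic cohort generator

`generate_cohort` emulates the shape of a real surveillance dataset:
per worker, both ears' baseline/annual(/retest) audiograms plus a
multi-label gold diagnosis. Workers are drawn from a profile mixture
whose default gives a 48.6 % normal share, i.e. ~51.4 % of workers with
at least one finding — the prevalence this class of screening
population reports. Audiometric templates encode each intent: flat low
thresholds (≤15 dB) for normal; broadband elevation for
loss/impairment; a 3–6 kHz notch with 8-kHz recovery for NIHL; a
+15 dB shift on the 2–4 kHz PTA with a persisting or resolving
in-window retest for PSTS/TSTS. Gaussian test-retest noise (SD 2.5 dB,
the order of magnitude of audiometric repeatability) is added per
threshold and snapped to the 5-dB audiometer grid.

Two design choices matter for interpretation:

- **Gold labels come from the oracle, not the construction intent.**
  After building a record, its gold label is the output of an
  independent literal transcription of the rules (`oracle_classify`).
  This guarantees label consistency even when templates interact (a
  NIHL notch also constitutes hearing loss) or noise nudges a case
  across a cutoff.
- **What passing tests therefore show — and don't.** Perfect
  cross-validation scores on synthetic cohorts demonstrate the
  *self-consistency ceiling*: the engine reproduces its own rules under
  arbitrary partitions. They say nothing about agreement with human
  experts, whose criteria (for NIHL especially, where multiple
  published criteria sets coexist) can differ from the implemented
  formula. The `flip_labels` knob emulates that disagreement: flipping
  a fraction ε of one category's gold labels degrades that category's
  kappa monotonically while leaving the others perfect, qualitatively
  reproducing the imperfect-NIHL/perfect-others pattern expected
  against real expert labels.

Defaults chosen once for realism and kept: retest availability 1.0 for
shift cases (a surveillance programme that orders a retest obtains
one; the pending path is exercised in tests at lower availability),
PSTS:TSTS split 0.5, bilateral involvement 0.25. The generator does not
model demographics, exposure duration, or asymmetric noise exposure.

## Numerical and procedural notes

- Thresholds outside [−10, 120] dB HL are error findings; off-grid
  (non-multiple-of-5) values are warnings — both reported by
  `validate_record` rather than raised at construction, so nonconforming
  files can be inspected.
- Date arithmetic uses calendar days on ISO-8601 dates; the retest
  window comparison is inclusive (`≤ 92` days).
- The engine/oracle equivalence suite runs 10,000 random records with
  thresholds uniform on the 5-dB grid over the full audiometer range
  plus a 320-worker template cohort; problem sizes throughout the test
  suite (cohorts of 30–320, 1,000 random kappa tables) were chosen to
  exercise every code path while keeping the default run fast.
- CSV dialects are documented in `audiorules.io`; a column-mapping
  config adapts foreign layouts, so externally deposited datasets can
  be fed to `audiorules validate` without editing the file.

## Known limitations

- Only air-conduction pure-tone data; no bone conduction, masking, or
  severity grading.
- The NIHL rule is one fixed criteria set (plus the recovery-sign
  switch); alternative published notch criteria are an extension point,
  not implemented.
- Gold labels in the synthetic cohort are rule-derived; validation
  against them cannot surface disagreement with clinical judgment.
- The kappa z-test is large-sample; it is reported for the pooled
  table only and will be anti-conservative for very small folds.
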