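# yawnscope

A quantitative-ethology pipeline for analyzing yawning from tabular
behavioral event data: facial action-unit (FACS) morph discovery, dominance
indices, behavioral state-change slot analysis, yawn-contagion attribution,
mixed-model inference, and inter-observer reliability — plus a seeded
synthetic-ethogram generator with exported ground truth.

## What it does

| Module | Role |
| --- | --- |
| `yawnscope.ethogram_model` | Domain types, time conventions (half-open seconds-from-session-start intervals), daytime binning, tension/resting context assignment, CSV readers/writers with structured validation |
| `yawnscope.facs_morphology` | AU configuration codec, one-hot encoding, mixed-data PCA/MCA projection, k-means morph clustering (k=2), cluster purity, per-AU Fisher contrasts |
| `yawnscope.dominance` | Decided-conflict matrices and the Average Dominance Index (ADI) |
| `yawnscope.state_change` | C1/Y/C2/BL 1-minute slot construction around spontaneous yawns, shift detection (incl. 30-s Y halves), baseline selection, long-format model datasets |
| `yawnscope.contagion` | Yawn-response attribution in the 3-min seen/not-seen window, censoring, response-rate summaries, response-model dataset |
| `yawnscope.inference` | Exact two-sided Fisher test (integer enumeration), ML random-intercept mixed models (Gaussian profile likelihood; binomial Gauss–Hermite, cross-checked against lme4), likelihood-ratio tests, Tukey-style familywise pairwise contrasts |
| `yawnscope.reliability` | Cohen's kappa and the 2·|A∩B|/(|A|+|B|) FACS agreement index |
| `yawnscope.synthetic_data` | Full-bundle generator (morphs, durations, aggression, posture dynamics, post-yawn shift boost, contagion process) and the 25+39 AU-configuration reconstruction fixture |

## CLI

All stages run against a bundle directory of CSV tables (subjects, sessions,
state intervals, yawns, aggressions, exposures, visibility):

```bash
yawnscope simulate --out demo/ --seed 1     # generate a synthetic bundle
yawnscope validate demo/                    # invariant checks
yawnscope annotate-context demo/ --tail-s 180
yawnscope adi demo/
yawnscope contagion demo/ --window-s 180 --chain on
yawnscope slots demo/ --seed 7
yawnscope morphs demo/ --k 2 --seed 17 --restarts 10
yawnscope fit demo/ shift                   # duration|morphology|shift|yhalf|response
yawnscope reliability demo/ --epsilon 0.05
```

## Conventions

- All within-session times are seconds from session start; intervals are
  half-open `[start, end)`.
- The tension context covers an aggression plus a 180-s half-open tail.
- A yawn response falls in `(t_trigger, t_trigger + 180]`; exposure records
  not followable for the full window without a response are censored.
- Mixed models are fit by maximum likelihood (never REML) so
  likelihood-ratio tests on fixed effects are valid.
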