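# refback

Decomposing working-memory subprocesses with the reference-back paradigm:
a tested simulation-and-analysis pipeline for the behavioural and
event-related-potential (ERP) side of reference-back ageing studies.

## The problem

In the reference-back task, letters (X/O) appear inside a red frame
(*reference* trials — the letter becomes the referent held in working
memory) or a blue frame (*comparison* trials — the letter is only
matched against the current referent).  Crossing trial type with gate
switch (did the frame colour change from the previous trial?) and the
required same/different response yields eight conditions, and four
signed combinations of their means isolate the gating subprocesses of
working memory:

- **updating** = no-switch reference − no-switch comparison
- **substitution** = (different − same | ns reference) − (different − same | ns comparison)
- **gate opening** = switch reference − no-switch reference
- **gate closing** = switch comparison − no-switch comparison

applied both to reaction times (costs in ms, plus a ratio index
cost / mean-RT that discounts general slowing) and, sample-wise, to
per-condition averaged ERPs (difference potentials).

The package provides, as importable modules under `src/refback/`:

- `task_design` — balanced session generation and trial classification,
  BIDS-events-like TSV I/O;
- `simulate` — per-subject behaviour (additive subprocess costs, shifted
  lognormal RTs, lapses, deadline misses) and multichannel epochs
  (Gaussian components with condition weights, 1/f noise, step
  artifacts);
- `preprocessing` — Kaiser FIR zero-phase filtering (30 Hz low pass,
  β = 12.2653, 10 Hz transition band), baseline correction over
  [−100, 0) ms, 100 μV peak-to-peak rejection, correct-trial condition
  averaging;
- `decomposition` — the contrast algebra on RTs and evokeds, window mean
  amplitudes;
- `inference` — tmax sign-flip permutation tests with familywise error
  control, split-plot ANOVA with Greenhouse–Geisser correction and
  partial η², Bonferroni post-hocs, JZS Bayes-factor t-tests (Cauchy
  prior, r = 0.707), Mann–Whitney U with rank-biserial correlation, and
  BIC-approximated inclusion Bayes factors;
- `sources` — a simplified sLORETA standardized minimum-norm inverse on
  synthetic lead fields, with FDR-controlled group contrasts;
- `pipeline` — `run_study` orchestration producing report tables, and
  accuracy/miss summaries.

The numbered scripts under `analysis/` are thin drivers that run the
analyses and write their tables to `results/`.  See `docs/methods.md`
for the models, assumptions and numerical choices.

## Worked example

The subprocess estimators are pure functions of the eight condition cell
means, so the group-level costs of the two reference cohorts (24 younger,
23 older adults; raw recordings not public) can be recomputed from their
published condition mean RTs:

```sh
python analysis/01_published_cost_arithmetic.py
```

prints

```
  group   subprocess  cost_ms  ratio
younger     updating   53.145 0.1047
younger substitution   55.410 0.0914
younger gate_opening   32.885 0.0597
younger gate_closing   92.005 0.1746
  older     updating   60.980 0.0944
  older substitution  123.240 0.1713
  older gate_opening   55.200 0.0784
  older gate_closing   62.530 0.0967

                     quantity   value
    substitution_cost_diff_ms 67.8300
substitution_cost_weighted_ms 88.6030
      substitution_ratio_diff  0.0798
```

Reading: every subprocess carries a positive RT cost in both groups; the
substitution cost — replacing working-memory content with new
information — is 55.4 ms in the younger but 123.2 ms in the older
cohort, and the 0.080 difference in the ratio index shows the gap
survives correction for the older group's general slowing.  The other
drivers simulate a full study at the same design and run the
behavioural statistics (`02`), the epoch-level ERP chain with tmax maps
and window ANOVAs (`03`), and the source-localisation checks (`04`).

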