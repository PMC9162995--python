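# fragility

Fragility and reverse-fragility metrics for two-arm clinical trials with
dichotomous outcomes, together with the corpus-level statistics used in
meta-research on trial robustness, and a synthetic trial-corpus generator
so the whole pipeline can be exercised without any external data.

## Who this is for

Meta-researchers and trialists who want to compute — or critically
examine — fragility indices over a corpus of randomized-trial comparisons.
The fragility index is popular but contested: it is, in essence, a
repackaged *P* value that penalises small trials regardless of clinical
effect size. This package computes the metric and, alongside it, the
quantities that expose that relationship (S-values, exact post-hoc power,
and the correlation structure between them).

## The metrics

Every comparison is a 2×2 table: events *a* of *n_A* patients in the
intervention arm versus events *b* of *n_B* in the control arm, tested
with the two-sided Fisher's exact test (minimum-likelihood rule: the sum
of hypergeometric point probabilities no greater than the observed
table's, conditioning on all margins).

- **Fragility index (FI)** — for a significant comparison (*P* < α),
  the number of non-events converted to events in the arm with fewer
  events until *P* ≥ α. Nonsignificant baselines get FI = 0.
- **Reverse fragility index (RFI)** — for a nonsignificant comparison,
  the minimum number of single-patient outcome switches (either arm, arm
  sizes fixed) reaching any table with *P* < α; found by exhaustive
  search of the event-count grid.
- **Fragility quotient** — index / (*n_A* + *n_B*) × 100, in percent.
- **S-value** — −log₂ *P*, the information (bits) against the test
  hypothesis; *s* bits carry the surprisal of *s* consecutive heads from
  a fair coin.
- **Post-hoc power** — exact power of the Fisher test at the observed
  arm proportions: Σ Binom(x_A) · Binom(x_B) over all outcome pairs whose
  exact *P* falls below α (full enumeration; seeded Monte Carlo for very
  large trials).

At corpus level: branch classification (FI vs RFI), medians with IQRs,
Spearman correlations with 10,000-replicate percentile-bootstrap CIs,
Mood's median test, histogram/cumulative tables, and a sensitivity
variant restricted to 1:1-allocated trials.

## Worked example

Two hypothetical trials share *P* ≈ 0.02 but tell very different clinical
stories. The small trial (1/100 vs 9/100 events):

```
$ fragility compute 1 100 9 100
table            : 1/100 vs 9/100  (N = 200)
alpha            : 0.05
fisher_p         : 0.01849
s_value          : 5.76 bits
relative_risk    : 0.1111
direction        : fragility
fragility_index  : 1  (quotient 0.5%)
reverse_fragility: 0  (quotient 0%)
posthoc_power    : 0.6775  (enumeration)
```

The relative risk of 0.11 is a ninefold risk reduction, yet a single
switched outcome (FI = 1) would erase statistical significance. A trial
of 200/4000 vs 250/4000 has the same *P* ≈ 0.02 at a clinically modest
relative risk of 0.8 — and a larger fragility index. The index rewards
the larger trial and penalises the stronger effect, which is the core
argument against using it.

Library use mirrors the CLI:

```python
import fragility as fr

table = fr.FourfoldTable(1, 100, 9, 100)
fr.fisher_exact_p(table)            # 0.01849...
fr.fragility_index(table).index     # 1
fr.s_value(0.01849)                 # 5.76 bits

records = fr.generate_corpus(fr.CorpusConfig(n_comparisons=243, seed=1))
summary = fr.summarize_corpus(records, fr.RunConfig(seed=1))
summary.stats["fi"]                 # MedianIQR(median=4.0, q1=2.0, q3=7.0, n=110)
summary.correlations["fi_vs_p"].rho # -0.91 (FI falls as P grows)
```

The other subcommands: `fragility simulate --n 243 --seed 1 --out
corpus.csv` writes a synthetic corpus in the documented CSV schema
(`study_id, outcome_label, outcome_tier, events_intervention,
n_intervention, events_control, n_control[, reported_p]`), and
`fragility analyze corpus.csv --out-json report.json` produces the full
corpus summary with the run configuration embedded for bit-identical
re-runs.

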