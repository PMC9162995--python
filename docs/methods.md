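# Methods

## The model and its unit of analysis

A *comparison* is one outcome contrast within a publication: a 2×2 table
of dichotomous outcomes from a two-arm trial, events/size per arm, with
arm A fixed as the intervention arm. Comparisons — not publications —
are the analysis unit throughout; a publication may contribute several
tables, and no within-study clustering adjustment is applied.

Event counts are modelled as independent binomials per arm; all
significance statements come from the two-sided conditional Fisher's
exact test. Under the null, conditioning on all four margins makes the
intervention-arm event count hypergeometric; the two-sided *P* is the sum
of point probabilities no greater than the observed one (the
"minimum-likelihood" rule, the convention of R's `fisher.test`), with a
relative tolerance of 1e−7 when comparing point probabilities so that
analytically tied tables are counted together despite float round-off.

## Fragility index conventions

- **FI walk.** Starting from a significant table, one non-event is
  converted to an event in the arm with fewer events (tie → smaller arm,
  then arm A; re-evaluated each step), the exact *P* recomputed, and the
  walk stops at the first *P* ≥ α. The index is the number of
  conversions; total N is preserved at every step.
- **FI = 0 rule.** A comparison whose Fisher *P* is already ≥ α gets
  FI = 0, never an exclusion — even if the source trial reported it as
  significant under some other test. This is what allows an FI
  interquartile range with lower bound 0.
- **Saturation.** If the chosen arm runs out of non-events the walk
  continues in the other arm (flagged); if both arms saturate without
  collapse the result is the "not attainable" sentinel.
- **RFI.** The reverse index is defined as the *minimum* number of
  single-patient outcome switches (either arm, arm sizes fixed) reaching
  any table with *P* < α — the minimum L1 distance over the
  (n_A+1)×(n_B+1) grid of admissible event counts, found exhaustively.
  Verbal "keep adding events until significant" definitions are
  direction-ambiguous; the exact minimum is well defined, cheap at trial
  scale, and lower-bounds every greedy variant. A
  `greedy-toward-separation` strategy (each switch pushes the arm risks
  apart, choosing the move with the lower *P*) is available for
  comparability with stepwise implementations.
- **Quotients** are index / N × 100, reported in percent; sentinel
  indices propagate to sentinel quotients and are excluded from medians
  and correlations but counted separately.

## Numerical choices

- **Boundary guard.** Exact tail sums are rationals that can land
  exactly on α (e.g. 91/1820 = 0.05), where floating-point summation
  would decide significance arbitrarily. Every significance decision
  therefore uses *p* < α − 1e−9: a *P* within 1e−9 of α counts as at the
  boundary, i.e. not significant. For the table sizes of trial corpora
  the spacing between achievable *P* values is orders of magnitude
  larger, so no genuine decision is altered.
- **Grid computation.** *P* values over a whole event-count grid are
  computed one margin (anti-diagonal) at a time: cells on a margin share
  one hypergeometric distribution, so a single sort plus cumulative sum
  yields every cell's two-sided *P*. Grids are cached per arm-size pair.
- **Power.** Exact power enumerates all (n_A+1)(n_B+1) outcome pairs
  when that count is at most 4×10⁶; beyond that, a Monte Carlo estimate
  from 10⁵ seeded draws is used and the method is recorded in the
  result. Post-hoc power evaluates the observed arm proportions.
- **Quantiles** use linear interpolation of order statistics (type 7,
  the R default), which produces fractional medians such as 1.5.
- **Mood's median test** classifies values as > vs ≤ the pooled grand
  median (ties below) and applies the Pearson chi-square without
  continuity correction, df = 1; an all-tied pooled sample returns a
  zero statistic with a warning flag.
- **Spearman correlations** use average ranks; the *P* value is the
  t-approximation with n−2 df; the 95% CI is a percentile bootstrap of
  paired (case) resamples, default 10,000 repetitions, seeded and
  recorded. Resamples with a constant margin contribute no rho and are
  excluded from the percentiles. Each correlation in the corpus battery
  draws its own child seed from the run seed, so the summary is
  deterministic given (records, seed).
- **Correlation scope.** FI correlations are computed within the
  fragility branch, RFI correlations within the reverse branch; the
  power–*P* correlation pools both branches by default
  (`power_p_pooled=False` restricts it to the fragility branch).

## The synthetic corpus generator

The generator emulates the statistical structure of a meta-research
corpus of paediatric surgical trials: 243 comparisons grouped into
publications of 1–5 comparisons, total sample sizes bounded to 30–243
patients, 1:1 allocation (a configurable handful of 2:1 trials covers
the sensitivity analysis), and outcome tiers drawn as primary/secondary/
other with proportions 0.35/0.40/0.25 (a modelling choice; the true tier
distribution of any real corpus is not targeted).

Each comparison draws a design from a three-component effect mixture
(default 0.4/0.4/0.2):

- **null** — equal event rates, Uniform(0.10, 0.60), trial size uniform
  over the admissible range; these populate the reverse branch (an exact
  test keeps ≈95% of them nonsignificant at α = 0.05);
- **minimally powered** — control rate Uniform(0.20, 0.60), risk
  reduction Uniform(0.15, 0.35), per-arm n from the pooled-variance
  two-proportion formula at 80% power and α = 0.05
  (n = (z₁₋α/₂·√(2 p̄(1−p̄)) + z₁₋β·√(p₁(1−p₁)+p₂(1−p₂)))² / (p₁−p₂)²,
  rounded up, clipped to the size range) — trials sized to *just* detect
  their own effect, which is what makes real trials fragile;
- **large effect** — relative risk Uniform(0.05, 0.20) at small n
  (15–40 per arm), the "strong effect in a small trial" configuration
  whose fragility index is low despite overwhelming clinical relevance.

Event counts are binomial draws from a generator seeded by
(seed, comparison index); corpora are byte-identical under a fixed
config and seed. The mixture proportions and rate ranges are modelling
choices made once to exercise both branches and every corpus statistic —
they are not calibrated to any real corpus, so synthetic medians and
correlation magnitudes are *not* expected to match published full-corpus
values; what the synthetic corpora do reproduce robustly is the sign
structure (FI falls with *P*, RFI rises with *P*, power falls with *P*
and rises with FI) and the qualitative "most trials are fragile"
finding. Real extraction tables additionally carry journal/subject
covariates, non-binomial heterogeneity, and correlated outcomes within a
publication, none of which the generator emulates.

## Problem sizes

The exhaustive correctness sweep checks every 2×2 table with at most 12
patients per arm (8,100 tables) against exact-rational oracles. The
corpus-level checks run twenty 243-comparison corpora; those sign-pattern
runs reduce the bootstrap to 200 replicates because only the full-sample
rho is consumed, while any reported confidence interval uses the default
10,000.

## Known limitations

- Continuous and time-to-event outcomes are out of scope; the metric
  itself is defined only for 2×2 tables.
- Mid-P and unconditional (Barnard/Boschloo) tests are not offered, nor
  are continuity-corrected relative risks.
- The relative risk is flagged undefined when the control arm has zero
  events (no continuity correction is silently applied).
- Externally deposited corpora load through a user-supplied column
  mapping (`read_corpus(column_map=...)`); reproducing published
  full-corpus statistics additionally depends on that corpus's own
  extraction conventions.
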