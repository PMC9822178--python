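# Methods

## Evidence model

The frame of discernment is fixed at the three sentiment classes
Θ = (negative, neutral, positive); masses live on the explicit 8-subset
powerset, indexed by bitmask (bit 0 negative, bit 1 neutral, bit 2
positive). Fixing |Θ| = 3 keeps the combination loop exact and transparent;
a general-frame engine is deliberately out of scope.

Classifier probability vectors enter the evidence calculus as
singleton-focal BBAs with optional uniform discounting: m({c}) = α·p_c,
m(Θ) = 1 − α, α ∈ (0, 1]. Singleton embedding makes Dempster combination of
k classifiers reduce to the normalised elementwise product of their
probability triples — a closed form that doubles as an independent test
oracle — while the discount α expresses model unreliability by moving mass
to ignorance. The package does not attempt to learn α; it is a caller
choice (default 1).

Decisions take the singleton with maximal belief (equal to maximal mass for
singleton-focal BBAs). Ties within 1e-12 break toward the canonical class
order and are flagged rather than hidden.

### Conflict handling

Pairwise conflict K is the product mass on empty intersections. K ≥ 1 −
1e-12 raises an error naming the sources: silently renormalising a
near-total conflict would manufacture confident nonsense from contradictory
point masses. For n-ary combination the reported conflict is the global
normalisation deficit 1 − Π(1 − K_step). Unlike the stepwise K values,
this quantity is invariant to input order (the unnormalised combined masses
are associative, and the total kept mass is their sum), so it is the only
honest scalar summary of an n-way combination.

In the evaluation sweep, records whose combination totally conflicts are
excluded from the accuracy denominator and reported in a separate
`n_conflict` column — a forced decision from pre-normalisation masses would
not be comparable with the cleanly fused records. With soft (continuous)
probability inputs this path is unreachable; it exists for one-hot inputs.

## Backends

External pretrained models are reached only through an adapter contract (a
callable returning either 3-class or 5-star probabilities); nothing in the
package depends on their availability. Five-star review scores fold to
three classes by s₁+s₂ / s₃ / s₄+s₅ (fewer than 3 stars negative, 3
neutral, ≥4 positive).

The mock backend draws a predicted-tendency label from the confusion row of
the record's true label, then emits a Dirichlet draw with
α_j = 1 + c·[j = tendency]. The concentration c (default 20, giving ≈0.91
mean mass on the tendency class) makes outputs sharp but non-degenerate;
c → ∞ approaches one-hot outputs and c → 0 the uniform simplex. Mocks are
deterministic under their seed; the text-level `classify` contract derives
a per-text stream from a CRC-32 digest so equal inputs always yield equal
outputs.

A consequence worth stating: a uniform-confusion mock is uninformative only
*in expectation*. Its realized outputs are confident random votes, and
under product fusion those measurably degrade a strong partner's accuracy.
The remedy is discounting — as α → 0 the partner's BBA approaches the
vacuous identity — and the test suite pins both behaviours.

## Study-period and clock conventions

The two periods are half-open calendar years: [2019-01-01, 2020-01-01) and
[2020-01-01, 2021-01-01), both in UTC, so the shared boundary instant
belongs to the later period only. The clock buckets split the day at 1 PM:
local hours 13–23 are "before midnight" and 0–12 "after midnight"; the
hour starting at midnight is assigned to the after-midnight bucket (posts
in it are literally after midnight). Timestamps are normalised to UTC; a
fixed minute offset is exposed for sensitivity analyses because source
timestamps in this domain rarely document a user's local zone, and no
per-user localisation is attempted.

Inclusion filtering requires the keyword as a case-insensitive,
word-boundary token of the *cleaned* text (so `#insomnia` matches after the
sigil is stripped, `insomniac` does not) plus an exact language-field
match. No language detection model is embedded; the filter trusts the
metadata field.

## Text cleaning

Cleaning applies, in order: URL stripping, @-mention stripping, leading
retweet-marker removal, hashtag-sigil removal (strict mode drops the whole
token), emoji/emoticon removal (Unicode pictograph blocks plus a small
fixed emoticon list), removal of characters outside letters/digits and the
sentence punctuation `. , ! ? ' -`, and whitespace collapse. URL stripping
precedes punctuation stripping so URL fragments cannot survive. The exact
character classes are a declared convention of this package; cleaning is
idempotent, never lengthens a string, and `word_count` counts whitespace
tokens of the cleaned text.

## Statistics

Odds ratios are computed in closed form from 2×2 tables — identical to the
univariate logistic-regression estimate without optimizer dependence — with
Wald 95% intervals (z = 1.96), the Wald z statistic and a two-sided normal
p. A zero cell raises; the Haldane-Anscombe 0.5 correction is available
only behind an explicit flag. Chi-square on 2×2 tables is Pearson without
continuity correction (df 1), with the signed pooled-proportion
z = sign(ad−bc)·√χ². No multiple-testing adjustment is applied: the layer
reports raw per-contrast p values.

Published surveillance tables in this domain often *truncate* ratios to two
decimals rather than round (1.3979 prints as 1.39, 0.6058 as 0.60);
`format_ratio` supports both modes with `round` as the default and
`truncate` available to match such tables. Percentages for display round
half-away-from-zero to one decimal; machine outputs keep raw proportions.

Sample-size calculation treats "power of a chi-square test" exactly: power
at n is the noncentral chi-square survival function (λ = n·w²) at the
central critical value, and the returned n is minimal by integer bisection
over [1, 10⁷] — power(n−1) < target ≤ power(n). For w = 0.3, α = .05,
power = .80, df = 5 this gives n = 143.

## Synthetic study generator

The generator emulates the data-generating structure the analysis assumes:

* two period streams (defaults 13,956 + 16,576 records — one-tenth of a
  realistic two-year keyword harvest, keeping full-pipeline tests well
  under a minute);
* marginal sentiment prevalences per period (defaults 0.467/0.285/0.248 and
  0.550/0.283/0.167);
* an hour-of-day posting profile (default uniform) and an after-midnight
  negative-odds multiplier (default 1.43).

The multiplier is injected as a logistic tilt: hours are drawn first, and
the per-bucket probability of a negative label uses baseline odds o before
midnight and r·o after. The baseline is calibrated by root finding so that
the hour-weighted mixture equals the configured marginal prevalence
exactly. Consequently the within-period after-vs-before-midnight odds ratio
equals r exactly in the population and the marginal shares equal the
configured prevalences — the generating parameters are the estimands of
the downstream analysis, with no attenuation. Non-negative mass splits
between neutral and positive in the configured ratio, preserving those
marginals too. The pooled (period-mixed) contrast is mildly attenuated by
odds-ratio non-collapsibility across periods with different baselines;
recovery tests therefore target the within-period contrasts.

Texts are assembled from a small sentiment-keyed template lexicon, always
contain the study keyword, and are salted with URLs, hashtags, mentions and
emoji so cleaning and filtering are exercised end to end. Template text has
structure, not fluency: passing tests demonstrate pipeline correctness on
corpora with the assumed statistical structure, not classifier performance
on real language, real class imbalance drift, sarcasm, or code-switching.
All draws flow from one integer seed through numpy's PCG64 generator, which
is platform-stable; corpus files regenerate byte-identically under a fixed
seed.

## Numerical choices

* Probability and mass vectors validate to 1 within 1e-6 on input and are
  asserted to 1e-9 in tests; combination equivalence with the brute-force
  powerset oracle is checked at 1e-9.
* Total-conflict threshold 1e-12; decision-tie tolerance 1e-12.
* Degenerate metric ratios (zero denominators in sensitivity/precision/F1,
  κ with chance agreement 1) return NaN with an explicit undefined flag —
  never silently 0.
* The base-odds calibration solves on the log-odds scale with Brent's
  method on [−40, 40] (xtol 1e-13), exact for multiplier 1 by shortcut.

## Limitations

* The evidence layer fuses soft classifier scores; fusing hard one-hot
  labels works but degenerates to a voting scheme where total conflict
  becomes reachable.
* Odds ratios are unadjusted 2×2 contrasts; covariate-adjusted logistic
  regression, user-level clustering and retweet deduplication are out of
  scope.
* The generator's conditional-independence-given-gold assumption for mock
  ensembles is favourable to fusion; correlated real classifiers gain
  less.
* Validation against real annotated corpora and pretrained model weights
  requires external artifacts the package intentionally does not bundle;
  the adapter interface is the integration point.
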