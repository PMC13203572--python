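# Methods

This note documents the models, conventions, and numerical choices behind
`langalign`, in the order data flows through the package.

## Data model and time conventions

Utterances and language segments carry integer-millisecond times on
half-open intervals `[onset, offset)`, so duration sums are exact and
abutting segments never overlap. An utterance with no identifiable
segment time is *unknown*; one with segment time in both languages is
*mixed*. Language `A` denotes the community's English; `B` the community's
other language (French or Spanish). Session type `A` is a one-on-one
caregiver–child recording; type `B` is multi-party.

EAF ingestion is configured by a tier map (speaker tier → speaker id/role
plus an optional dependent language tier) rather than a hard-coded tier
scheme, because annotation tier conventions differ between coding
protocols. A language annotation is attached to the utterance whose span
contains its midpoint; spans left uncovered by the language tier remain
unknown. The canonical table is UTF-8, tab-delimited by default, one row
per language segment; a wholly unknown utterance is encoded as a single
`unknown` row spanning the utterance. Writing then reading a table is the
identity on valid records.

## Language profiles

Proportions are time-weighted, not utterance-counted: the share of
language A is A-milliseconds over identifiable milliseconds, while the
identifiable proportion divides by *total* speech time. Undefined
statistics are reported as nulls, never zero, so a silent or fully
unintelligible speaker is distinguishable from a monolingual one. Summary
tables weight families equally (one value per speaker per session), and
multiple other-household members are first averaged within their session
so a large household does not dominate its group cell. A
single-observation group reports SD as null.

## Turn extraction

Utterances are totally ordered by onset, then offset, speaker id, and
utterance id. A turn requires the two utterances to be strictly adjacent
in this global order — an intervening utterance by any third speaker
cancels the candidate pair (a `skip_other_speakers` option relaxes this
for sensitivity analyses; the strict rule is the conservative default for
multi-party sessions). Mixed and unknown utterances cannot be match-coded
and are dropped from the series, but they still occupy their position in
the sequence and hence break adjacency: they are real speech events even
when unusable for coding. Consecutive utterances by the same speaker never
form turns. Responses may chain (a response can serve as the previous
utterance of the next turn); `allow_chaining=False` disables reuse, since
annotation practice varies on this point. No maximum response gap is
imposed by default, and overlapping responses (negative gaps) are allowed
because onset order defines sequence.

## The Monte Carlo alignment test

Null hypothesis: speakers choose languages independently according to
their own preferences. Each replicate permutes the response-language
sequence uniformly at random across the series' turns, preserving both
roles' observed language counts exactly; permuting the previous-language
sequence as well is distributionally equivalent for the match statistic
(an option retained for verification), so the cheaper one-sided scheme is
the default. Tests are run per session × dyad × direction.

The p-value is the one-sided upper-tail add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + N)`: ties count toward the tail and
`p` is never zero (floor `1/(N+1)`). A degenerate single-language series
therefore yields `p = 1`. Cohen's h is reported signed
(observed − null mean); only its magnitude is meaningful for effect-size
benchmarks. The analytic independence rate
`Σ_l p̂_prev(l)·p̂_resp(l)` of the empirical marginals equals the exact
expectation of the permutation null and is reported alongside the Monte
Carlo mean as a self-check.

Inclusion filters: a series is flagged when either role's most frequent
language reaches 80% of its turns (dominance — chance matching near
ceiling) or when it has fewer than 30 turns. The dominance filter is
evaluated on the turn series' own language distributions, the stricter
reading; evaluating session-level profiles instead is possible via the
profile tables. Filters gate interpretation, not computation: excluded
sessions still receive full statistics, flagged `included=False`. The
attrition report partitions sessions as
`initial = excluded_dominance + excluded_turns + included`, counting
doubly-excluded sessions once (in the dominance column) and reporting the
overlap separately in `excluded_both`.

Floating-point comparisons at the filter and tail boundaries use a 1e-12
tolerance so that exact-fraction inputs (e.g. 80/100 turns) land on the
intended side of the cut-offs.

## Correspondence statistics

Pearson correlations (scipy) relate speakers' language-A proportions
across families. Two comparison tests are implemented:

* **Independent samples** (e.g. the same correlation in two communities):
  `z = (atanh r1 − atanh r2) / √(1/(n1−3) + 1/(n2−3))`, two-sided normal
  p, and a confidence interval for the correlation difference obtained by
  back-transforming the z-scale interval (an approximation — the interval
  is exact on the transformed scale).
* **Dependent overlapping correlations** (child–caregiver vs child–other,
  sharing the child variable): Steiger's Z using the average of the two
  compared correlations in the covariance term,
  `rm = (r12+r13)/2`, `psi = r23(1−2rm²) − rm²(1−2rm²−r23²)/2`,
  `s = psi/(1−rm²)²`, `Z = (atanh r12 − atanh r13)·√((n−3)/(2−2s))`.
  The correlation triple must form a positive semi-definite matrix.
  This is the standard variant of the overlapping-correlations test; no
  independent implementation ships in the environment, so the test suite
  validates it by its exact algebraic identities (Z = 0 at r12 = r13,
  monotonicity in r12) and by a seeded trivariate-normal calibration
  simulation at n = 50 over 500 replicates.

Both tests are asymptotic; p-values are two-sided throughout this module.

## Synthetic sessions and the coupling parameter

The generator emulates coded 20-minute play sessions: an alternating dyad
(or a Markov speaker sequence for multi-party sessions), uniform utterance
durations and inter-utterance gaps, and per-speaker parameters — a base
probability of language A, a coupling probability λ of copying the most
recent *identifiable* language produced by another speaker, and
unknown/mixed relabeling rates. Relabeled utterances never serve as copy
sources, so labeling noise acts as ignorable missingness, mirroring the
analysis's exclusion rules: unknown injection reduces the number of
codable turns without changing the match-rate expectation among retained
turns. λ = 0 realizes the test's null exactly; λ = 1 forces every codable
turn to match. λ is a generative construct of this package, not an
empirical model of alignment — its only claim is consistency with the
independence null.

Defaults chosen as realistic study conditions: children's unknown rate
0.55 vs caregivers' 0.07 (children's speech is identifiable less than
half the time, caregivers' over 90%), mixed rate 0.05 for both, caregiver
utterances 500–4000 ms, child utterances 300–2000 ms, gaps 200–1500 ms.
Durations only matter for profile statistics, not turn statistics. All
defaults are overridable per speaker.

The moment estimator inverts `E[match] = λ + (1−λ)·m0`, where `m0` is the
analytic independence rate of the series' own empirical marginals:
`λ̂ = (observed − m0)/(1 − m0)`, clipped to [−1, 1] with the raw value
reported alongside; it is undefined when `m0 = 1`. It returns exactly 0
when the observed rate equals the independence rate. The estimator is
unbiased at balanced base rates; with strongly asymmetric marginals the
plug-in `m0` introduces small finite-sample bias.

## Calibration, power, and problem sizes

Simulation-based checks in the test suite use directional
(child-responds) series from alternating dyads: in a pooled series the
response positions interleave the two speakers, so permuting responses is
not exchangeable under the null when their base rates differ — the
directional series is the correct exchangeable unit. Problem sizes: null
calibration uses 200 sessions × 60 turns × 1,000 iterations, checked
against the central 95% band of Binomial(200, 0.05) (the discrete
permutation distribution makes the test mildly conservative, which the
band accommodates); power uses λ = 0.5, 100 turns, balanced base rates,
200 replicates; parameter recovery uses λ ∈ {0.3, 0.6}, 200 turns, 100
replicates; exact-enumeration agreement uses series of ≤ 7 turns at
50,000 iterations, compared by total-variation distance < 0.02.

## Pipeline determinism

A run is fully determined by config and master seed: per-session Monte
Carlo seeds derive from the master seed through a spawned seed sequence in
session-id order, every table has a deterministic sort, and repeated runs
are byte-identical. The manifest records the config, package version, and
the row count of every file written.

## Known limitations

* The generator does not model age or exposure covariates of alignment,
  code-switching pragmatics, realistic transcripts, or within-utterance
  timing structure; passing tests show the statistics behave correctly
  under the generative model, not that the model captures real family
  dynamics.
* Mixed-effects regressions over turn-level data are out of scope by
  design; the turn table export is model-ready for external fitting.
* Correlation comparison tests are asymptotic and should be read with
  caution below n ≈ 10 families per group.
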