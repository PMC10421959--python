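# Methods

## Scope and data model

The package operates on the 80-term PRO-CTCAE item library (124
attribute questions; 78 distinct adverse events, with depression and
irregular menstruation each split over two terms). Each term carries up
to three attribute questions from five kinds — presence (binary),
severity, interference, frequency, amount (5-level ordinal, 0–4) — and
belongs to exactly one organ-system domain. The shipped
`data/proctcae_library.csv` encodes the public PRO-CTCAE attribute map
and domain grouping; term identifiers are lowercase snake-case of the
display names and are stable. The shipped `data/tailored_library.csv`
is the 30-term core survey that the reference elimination ledger
produces (58 items, 11 domains).

Responses are long-format records (patient, timepoint, term, attribute,
level). A *survey administration* is one patient-timepoint; pooled
analyses concatenate administrations across timepoints, so the unit of
every denominator is the administered survey, not the patient.

## Scores

* **Prevalence** = administrations with any attribute level > 0 for the
  term (presence "yes" for presence-only terms) / administrations where
  the term's items were presented. The numerator is a disjunction over
  attributes.
* **Attribute proportion score** = responses at/above the cut level
  (severity ≥ moderate, interference ≥ somewhat, frequency ≥
  occasionally, amount ≥ somewhat; all level 2) / responses above
  level 0. Undefined (0/0) scores are carried as explicit markers and
  never coerced to 0.
* **Physician impact proportion score** = panel ratings ≥ moderate /
  *all* ratings of the term. With the 9-member panel every defined
  value is a multiple of 1/9.

Threshold comparisons always use full precision; display rounding is
one-decimal percent, round half up (1/9 → 11.1, 13/33 → 39.4).

## Elimination rules

Elimination is strict `score < threshold`; a term exactly at the
threshold is retained. Defaults: 5% for prevalence, 25% for all
proportion-score steps including the physician step. Terms lacking a
step's attribute question are retained and flagged carried-forward. A
term whose prevalence is undefined was never administered and is
dropped at step 1 with reason "not administered"; an undefined
attribute score joins the carried-forward set (for asked attributes it
can only arise when prevalence was 0, in which case the term is already
gone). Scores for steps 1–5 are computed once from the pooled data;
only the reliability step is recomputed on the then-current working
set. Reintroduced terms must have been eliminated at an earlier step
and return with their full attribute sets.

## Reliability step

The composite item score entering Cronbach's alpha is, by default, the
maximum level over the term's answered attribute items in one
administration (presence contributes 0/1) — chosen to align with the
"any attribute" disjunction used for prevalence. Severity-only and
mean-of-attributes composites are available by configuration. Alpha
uses sample variances (n−1) with listwise deletion inside the domain;
the same complete rows are used for the full and every leave-one-out
alpha, so Δα reflects the column removed, not a changing row set.
Domains with ≤ 2 remaining terms are never pruned; with |α₁| < 1e−8
the percent change is undefined and the domain is skipped. "Lowest
percent change" is interpreted as the smallest *absolute* percent
change (the term whose removal affects the domain's reliability least);
a signed-minimum policy is available by configuration. Ties break
lexicographically on term id.

## Synthetic data generator

For each administered survey and each domain, a latent factor
`z ~ N(0,1)` is drawn; term *t* with loading λ_t draws
`u_t = λ_t z + sqrt(1 − λ_t²) ε`, giving a Gaussian copula with
correlation λ_s λ_t within a domain and independence across domains.
The term is symptomatic iff `Φ(u_t) > 1 − π_t`, so the marginal
prevalence equals π_t exactly. Given symptomatic, the conditional
uniform `v = (Φ(u_t) − (1 − π_t)) / π_t` is pushed through each
attribute's conditional level distribution (levels 1–4), making a
term's attributes comonotone (an independent-attributes option
exists). Attrition is independent Bernoulli retention per timepoint;
the study-like pattern (1, 191/219, 118/219) reproduces the reference
cohort's expected administration counts 219/191/118 from 219 patients.
All draws come from one seeded `numpy` Generator; identical
(config, seed) pairs give byte-identical CSV output.

Exact marginals make two oracles available: `analytic_marginals`
(expected prevalence and proportion scores) and, because the composite
score is a monotone transform of `u_t`, the population covariance of a
domain's composites via bivariate-normal quadrature — hence population
alpha and its leave-one-out percent changes in closed form.

### Study-like fixture

`study_like_fixture` packages a configuration whose analytic marginals
put every term on its published side of each elimination threshold with
a wide margin: π = 0.015 for the 18 low-prevalence terms and 0.30
otherwise; conditional distributions with 8% mass at/above the cut for
sub-threshold attributes and 55% otherwise; panel distributions with
1% / 99% mass at ≥ moderate. The study's exact per-term values are not
reproducible without its raw data and several sit too close to their
thresholds to survive sampling noise, so the fixture trades fidelity of
individual score values for a reproducible ledger. Loadings default to
0.7 (0.85 for presence-only terms, whose binary composites attenuate
copula correlation more). For each domain due a reliability removal,
the designated term's loading is solved by bisection on the population
covariance so that removing it leaves the domain's population alpha
unchanged, while removing any other term shifts alpha materially (the
smallest such gap across domains is ≈1.7% of α with runner-up terms
≈4–5 sampling SDs away at ~1,900 pooled surveys). At 800+ patients the
full pipeline therefore reproduces the published elimination ledger
end to end with failure probability well below 1%; at the reference
cohort's own size (219 patients) the reliability argmin is noisy and
exact reproduction is not expected.

Tests and the acceptance script run the end-to-end reproduction at
800–1,000 patients (~1,900–2,400 pooled administrations) — large
enough for the margins above, small enough that the whole suite runs
in well under a minute.

## Replay mode

Because the development cohort's raw responses are unavailable, the
pipeline can also be driven from a precomputed score table
(`run_patient_steps_from_scores`), with the reliability removals
supplied explicitly. `study.py` encodes the published per-step scores
and term lists; unpublished cells are synthetic placeholders above the
thresholds (0.20 prevalence / 0.60 proportion scores), which is
sufficient because threshold filters only compare against the cut
points. Replay validates the bookkeeping — survivor trajectory
62 → 50 → 45 → 45 → 44 → 37 → 30, the 58-item / 11-domain final
survey, and ledger conservation — not the unpublished score values
themselves.

## What the simulator does not model

No longitudinal symptom trajectories (onset/resolution between
timepoints — each administration is drawn independently), no
informative dropout (retention is independent of symptom burden), no
item-level missingness within an administered survey, and no
patient-level random effects linking a patient's repeated surveys.
Passing end-to-end tests therefore demonstrates correctness of the
scoring, reliability and bookkeeping machinery under the stated
statistical structure, not robustness to the dependence patterns of
real repeated-measures PRO data.

## Numerical conventions

Alpha is undefined (not 0) for < 2 items, < 2 complete rows, or a
degenerate total score. Conditional-uniform values are clipped to
(1e−12, 1 − 1e−12) before inverse-CDF mapping. Ledger JSON serialises
undefined scores as null. The tailoring pipeline contains no
randomness; all stochasticity lives in the generator.
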