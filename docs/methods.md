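# Methods

## Triage engine

A questionnaire is a directed acyclic graph of multiple-choice questions
with an entry *complaint filter* (four categories: red and/or painful
eye, painless visual disturbance, eyelid problems, eye injury). Routing
uses ordered conditional edges: each edge optionally carries a predicate
"the chosen options of question *q* intersect set *S*", evaluated only
against already-recorded answers; the first matching edge in declaration
order decides the successor, and every question must declare an
unconditional default edge last, so traversal is total and
deterministic. Load-time validation rejects cycles, unreachable
questions, questions with fewer than two options, symptom codes outside
the declared vocabulary, and any path asking more than 25 questions (the
cap is checked on the raw edge structure, which upper-bounds every
predicated traversal).

Sessions are append-only transcripts: answers must be given for the
currently pending question, single-select cardinality is enforced, and
the asserted-symptom set is the union of the chosen options' symptom
codes. Eligibility is age ≥ 13 with an explicit consent gate; telephone
completion (receptionist proxy) is an attribute, not a separate flow,
since the questionnaire content is identical. Timestamps are injected by
the caller so durations are testable.

### Wording is data, not code

The production instrument's item wording is proprietary, so the shipped
questionnaire, acuity table and archetype pool are *representative
fixtures*, versioned and loaded like any user-supplied configuration.
The engine itself is content-agnostic; everything structural (filter
question, conditional logic, 25-question cap, trauma fast-path) is
enforced on whatever definition is loaded.

## Acuity rating and disposition

The acuity table maps symptom-code predicates (all-of / any-of
combinators, hence monotone) to one of five ordinal urgency bands:
same-day emergency > within 24 h > within 48 h > within a week/routine >
self-care. The "within a week" and "routine" timeframes are collapsed
into a single ordinal band; self-care carries the pharmacist service.
Aggregation across triggered rules is maximum severity — the only
safety-consistent choice — so adding symptoms can never lower the
urgency. The service comes from the maximal rule's hint; conflicting
hints at equal level resolve by the fixed precedence ED/EEC > MECS/CUES
> community optometry > pharmacist (logged), and emergency/urgent bands
only ever route to ED/EEC or MECS/CUES because urgent appointments are
generally unavailable elsewhere. A chemical, blunt or high-velocity
trauma answer takes an unconditional fast path: same-day ED/EEC with a
first-aid notice, regardless of anything else in the transcript.
Load-time checks require every vocabulary code to be covered by at least
one rule and pin every emergency-class rule to same-day ED/EEC.

## Evaluation statistics

Urgent/non-urgent labels are derived by dichotomizing the urgency band
at the 24-hour boundary. The gold standard is adjudicated per record:
two reviewer labels, with a mandatory third casting vote exactly when
they disagree. Both triage arms are scored against the *same*
adjudicated vector.

- **McNemar (continuity-corrected).** χ² = (|b−c|−1)²/(b+c) on the
  discordant counts, p from the χ²(1) upper tail. With b+c = 0 the test
  is uninformative: statistic 0, p = 1 by convention. The published
  analysis reports one paired P per accuracy metric; this is implemented
  as McNemar on correctness disagreement restricted to gold-positives
  (sensitivity) and gold-negatives (specificity), the standard paired
  comparison of two diagnostic procedures on the same patients.
- **Cohen κ.** Point estimate from the 2×2 proportions; the 95% CI uses
  the Fleiss–Cohen–Everitt large-sample variance (the CI method was a
  genuinely open choice; this is the standard default and is isolated in
  one function should a bootstrap be preferred). κ is undefined (an
  error, not 0) when both raters are constant and identical. Band
  labels follow the fixed a-priori cut-points, applied at 2-decimal
  precision.
- **Mann-Whitney U.** Ties count one half toward U. The exact null
  distribution is used when both groups have ≤ 20 untied observations,
  otherwise the tie-corrected normal approximation with continuity
  correction (scipy's implementation behind the package surface).
- **Odds ratio.** (a·d)/(b·c) with a Woolf log-SE interval; any zero
  cell triggers the Haldane–Anscombe 0.5 correction to every cell.
- **Rates with empty denominators** (no gold-positive or gold-negative
  cases) raise an undefined-metric error rather than returning 0.
- Displayed percentages round to one decimal and κ to two; all internal
  values are unrounded.

## Synthetic cohorts

No record-level data from the motivating service evaluation were ever
deposited, so the simulator emulates the *structure* of that population
and is the test bed for everything downstream. Defaults:

| parameter | default | rationale |
|---|---|---|
| n | 209 | analyzed cohort size |
| category weights | 95:82:22:12 | complaint-filter frequencies |
| urgent prevalence | 0.25 | gold-urgent fraction (53/209) |
| age | truncated normal, mean 53.5, SD 17.5, bounds 13–90 (years) | printed moments and range; band frequencies are a goodness check, not a constraint |
| telephone fraction | 19/136 | phone completions among known-mode records |
| feedback response | 147/209; top-2 0.82 | voluntary Likert structure |
| completion time | lognormal matched to mean 297 s, SD 122 s, clipped 90–975 s | printed mean/SD/range; right-skew fits "highly variable" durations |
| answer noise | 0.05 | modest transcription/recall error; free parameter |
| optometry triager sens/spec | 0.77 / 0.80 | calibration condition for parameter recovery |
| reviewer sens/spec | 0.83 / 0.85 | chosen from the closed-form two-rater κ to give between-reviewer κ ≈ 0.40 at 25% prevalence |

Sampling draws a complaint category multinomially, then an archetype:
within categories that contain urgent vignettes the urgent stratum is
drawn with the common probability u solving Σ w_c·u = target prevalence
(a parameter error if unreachable). Each archetype's answer script is
optionally noise-perturbed — a perturbed single-select choice is
resampled among the question's *other* options — and re-walked through
the graph, so perturbed transcripts are always valid traversals (newly
reached questions get uniform answers). Rater labels come from
independent sensitivity/specificity error models; reviewer disagreement
is adjudicated by a third independent draw. The eyelid category contains
no urgent archetype, mirroring the clinical reality that lid complaints
rarely need 24-hour care. Exactly three archetypes are emergency-class,
matching the handful of true emergencies a cohort of this size presents.

Ground-truth columns carry a `truth_` prefix and are never read by the
evaluation module (tests corrupt them and assert the metrics are
unchanged). What passing tests show is therefore internal consistency —
the pipeline recovers the parameters that generated the data — not
real-world accuracy: the simulator has no practice-level clustering, no
appointment-availability or patient-anxiety effects on triager behavior,
no missing data beyond an optional unknown-mode fraction, and archetypes
are cleaner than real presentations.

## Numerical and design notes

- Problem sizes: exhaustive traversal enumeration runs on the shipped
  graph (hundreds of paths); oracle-equivalence checks enumerate every
  2×2 configuration at n ≤ 12 (statistics here are permutation-invariant,
  so this covers all label configurations); stochastic checks use 10,000
  random sessions and cohorts of 5,000–10,000, which keep Monte-Carlo
  error well inside the asserted tolerances while the full suite runs in
  well under a minute.
- 41/53 = 77.36%: sources print this variously as 77.3 or 77; tests and
  the acceptance script use the exact fraction and round to one decimal
  (77.4).
- The κ band function treats its cut-points inclusively on the upper
  edge (0.20 is none-to-slight, 0.21 is fair), matching the a-priori
  list.
- Whether multi-select answers are permitted was an open choice: both
  modes are supported per question; the default fixture uses
  single-select except for the symptom checklists.
- Report "delivery" writes JSON + rendered text into an outbox
  directory; transport (email/SMS/portal) is out of scope, as are PDF
  rendering, EPR integration, diagnosis and probabilistic risk scoring.
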