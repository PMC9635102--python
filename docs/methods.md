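# Methods

## The procedure

The package implements a candidate-prioritisation rubric for drug R&D
pipelines. A registry row is a candidate medicine (drug, biological or
dietary supplement) for an indication set drawn from {prevention,
treatment}, at a development phase in {preclinical, I, II, III, IV}, with
curated screening attributes. The analysis has three stages.

**Screening.** Six boolean exclusion rules remove candidates that cannot be
meaningfully prioritised: (1) already approved and marketed for the
indication, (2) recommended or in routine clinical use, (3) already
recommended or widely used for a subgroup, (4) inactive after negative
trial outcomes, (5) targeting one symptom rather than the underlying
pathology, (6) indicated as inferior to current treatments. These are
curator judgments recorded in the registry; the package applies, it does
not infer, them. When several rules fire, the candidate is counted once
under the lowest-numbered rule (all triggered rules are kept in a secondary
list), so flowchart counts are single-counted and conserve:
retained + Σ per-rule exclusions = input.

**Reconciliation.** Each retained clinical candidate-indication pair is
assessed per criterion by two reviewers on five levels — not met <
partially met < met minimum < met preferred, plus *unknown* outside the
order. Agreement stands; any disagreement is decided by a third reviewer
(adjudicator). A criterion assessed by exactly one of the two reviewers
counts as a disagreement (missing is not silent agreement); a criterion
assessed by neither is a gap, filled from registry attributes where the
criterion is mechanically derivable — setting (HIC∧LMIC → met preferred,
one of them → partially met, unstated → unknown), stability (no cold chain
→ met preferred, cold chain → not met, unsure → unknown) and WHO-EML
membership (listed → met preferred, else not met) — and otherwise as
unknown. A reconciled level always wins over a derived one, including a
reconciled *unknown*: reviewers saw the trial evidence the registry
attributes only summarise, and an explicit "not yet known" is information,
not a gap.

**Scoring and ranking.** With weights `w_c` and level scores `s(·)`,

    total = Σ_c w_c · s(level_c),   r = total / Σ_c w_c · s(met preferred)

and the rank is high if `r ≥ high(phase)`, medium if `r ≥ medium(phase)`,
else low. Both comparisons are inclusive — a deterministic, documented
tie-break. Ranking uses the normalised ratio `r` rather than the raw total
so per-phase cutoffs remain meaningful if a criterion is configured out.
Preclinical candidates are described (taxonomy by medicine subclass,
indication membership and archetype), never ranked: no clinical data exists
to match against the TPP. A candidate under investigation for both
prevention and treatment is scored and ranked once per indication, so
ranked rows can exceed unique candidates; unique-candidate counting
normalises names by trimming and case-folding only (no fuzzy matching,
which would silently merge distinct medicines).

## Parameters

| Parameter | Default | Why |
|---|---|---|
| level scores `s` | not met 0, partially met 1, met minimum 2, met preferred 3; unknown 0 | equally spaced ordinal coding; unknown contributes nothing but is tracked separately via completeness |
| weights `w_c` | efficacy = safety = 2, other seven = 1 | clinical efficacy and safety dominate implementation potential; the doubling is the smallest integer up-weighting |
| cutoffs | high ≥ 0.60, medium ≥ 0.40 of max attainable, all phases | chosen so all three rank classes are reachable on the discrete score lattice; per-phase values are config-replaceable |
| completeness | share of the nine criteria with informative (non-unknown) levels | distinguishes "scored low" from "not yet known" |
| activity window | active iff last activity year ≥ reference year − 3 (inclusive) | three-calendar-year publication window |

The whole scheme is a validated configuration (YAML/JSON): loading enforces
monotone level scores, positive weights with efficacy and safety strictly
above the rest, and `0 ≤ medium < high ≤ 1` per clinical phase. Analyses
that used different supplementary score codings are replayed by supplying
that table as the scheme — the engine then reproduces ranks assigned under
it, which the config-replay test demonstrates with planted data.

## Synthetic data

The generator emulates the statistical shape of a curated pipeline
registry. Defaults mirror a realistic landscape: phase mix 0.43 / 0.07 /
0.21 / 0.28 / 0.01 (preclinical through IV), product types 0.59 drug /
0.25 dietary / 0.16 biological, archetypes 0.75 repurposed, 60% active,
each exclusion rule firing independently at 8%, 10% of candidates pursuing
both indications, and per-criterion unknown injection at 10%. For each
retained clinical pair a rank is planted from a configurable mix and a
profile is rejection-sampled (cap 10,000 draws, then an infeasible-config
error) from independent per-criterion level draws until its normalised
score lands in the planted band. The three derivable criteria are sampled
only from the levels their registry encodings can express, so registry
attributes are generated consistently with the planted profile. Reviewer A
and the adjudicator report the truth; reviewer B deviates per criterion
with the configured probability, uniformly over the other four levels (the
simplest symmetric noise model). Consequently reconciliation provably
restores the planted profile, and 100% rank recovery under reviewer noise
is a structural property, not a statistical accident — the recovery test
checks the plumbing, not an estimator. All randomness flows through one
numpy PCG64 generator seeded from the config, giving byte-identical
outputs across runs.

What the generator does *not* emulate: real candidate names and literature
metadata, correlations between criteria (real safety and efficacy evidence
co-occur), reviewer biases that are systematic rather than symmetric, and
partially-assessed profiles (generated reviewers always cover all nine
criteria). Passing tests therefore demonstrate correctness of screening,
reconciliation, scoring, ranking and accounting — not robustness to
messy real-world assessment behaviour.

## Fixtures

Two registries are packaged as plain CSV. The preclinical fixture carries
40 unique candidates (11 prevention-only, 24 treatment-only, 5 dual) with
medicine subclass and archetype per candidate; its archetype column sums to
21 repurposed, one more than the 20 (50%) reported in the corresponding
summary figure — the fixture keeps the per-candidate values verbatim and
flags the discrepancy in the data module rather than resolving it.
Per-candidate product type and activity year are not part of the printed
tables; the fixture's product types are synthetic annotations from an
obvious drug-class heuristic and activity years are left absent. The
clinical fixture holds the 32 unique post-screening candidates (phase lists
10/5/2 prevention and 4/9/6 treatment, with esomeprazole, pravastatin,
ozagrel and metformin on both lists); archetype and product type there are
likewise plausible synthetic annotations. Nothing in the tests asserts the
synthetic annotation fields.

Published per-candidate match levels exist only as figure colorings and
supplementary tables, which are not machine-readable inputs here; headline
rank tallies over the full external database are therefore out of scope and
covered instead by the property suites and config-replay support.

## Numerical and design notes

- Percentages are rounded half-up to one decimal (decimal arithmetic, not
  binary), matching the conventional presentation style; rounding never
  turns a zero count nonzero or vice versa.
- Scores are exact floats: with integer-valued default weights and level
  scores all sums are integers below 2^53, so equality comparisons in
  tests are exact, not approximate.
- Matrix rows order by phase descending, then total score descending, then
  label alphabetically — a total, deterministic order.
- CSV is the canonical lossless matrix output (long format, one row per
  cell); HTML and SVG are presentation-only renderings with a legend.
  Color hex values are overridable; the level→color mapping is not.
- Empty-string booleans in registry CSV read as false (absent flags are
  logged by validation, not guessed); the cold-chain field is an explicit
  yes/no/unknown tri-state because "no cold chain" and "not yet known" rank
  differently.
- Problem sizes in the test and acceptance runs (200-candidate registries,
  1,000 random profiles, 10,000-draw mix checks) were chosen as the
  smallest sizes at which the binomial concentration and recovery
  properties are clearly non-degenerate.

## Known limitations

- Match levels are curated inputs; the package performs no evidence
  extraction or trial lookup.
- Quality of preclinical evidence is carried only as free-text annotation.
- The adjudicator is assumed authoritative; there is no model of
  adjudicator error, and an unresolved disagreement is a hard error rather
  than an imputation.
- Rank cutoffs act on the normalised ratio; configuring extremely sparse
  criterion sets (one or two criteria) makes the lattice coarse and some
  bands may become unreachable — the generator reports this as an
  infeasible configuration rather than silently re-drawing.
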