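# Methods

## The derivation model

The engine builds phrase structure top-down and left-to-right with a
single operation, merge, attaching each incoming lexical item to the
right edge of the structure built so far.  Lexical items carry ordered
categorial features (outermost first) and ordered select features =X
that, once the item is merged, project *expectations*: the categories
that must be integrated next.  Three merge modes cover the supported
schemata:

- **Selected merge** — the item's outer category matches the current
  expectation; it is integrated in place.
- **Stored merge** — an argument (outer category D) arrives while some
  other category is expected.  It is merged in its surface position and
  a copy is pushed onto a memory buffer, pending a later =D select
  feature.  This is how the filler–gap dependency of a cleft is
  represented: both the focalized object and the preverbal subject are
  stored, and both are retrieved at the verb.
- **Root / adjunct merge** — the first item of the sentence, or material
  merged after all expectations are discharged (spill-over adjuncts).

When a select feature is expanded and the buffer holds an item of the
selected category, the engine *retrieves* it (most recently stored
first) instead of expecting new input.  At the cleft verb the
nominative, agreement-bearing select feature is expanded before the
accusative one, so the subject (the most recent filler) is retrieved
with the full buffer (m = 2) and the focalized object afterwards
(m = 1).  A derivation that ends with open expectations raises an
"incomplete derivation" diagnostic; one that ends with a non-empty
buffer raises "unretrieved filler"; both carry the offending region.

The engine is schema-scoped by design: it covers the object-cleft,
subject-cleft and SVO-declarative schemata that the shipped paradigms
(and user paradigms of the same shape) instantiate.  It performs no
reanalysis, no probabilistic choice, and no timing simulation.  In the
declarative schema the subject roots the clause and its determiner entry
selects the predicate directly (a predicative spine), which is what
makes every category selected at merge time — nothing is stored.  The
exact attachment site of the focalized DP's store (relative to the focus
head) is not observable in any region cost, so the engine simply stores
at the DP1 merge.

## Retrieval cost

For retrievals i = 1..n at region x:

FRC(x) = ∏ᵢ (1 + nFᵢ)^mᵢ / (1 + dFᵢ)

- **m** — items in the buffer at retrieval time, target included,
  counted before removal.  Cost grows exponentially in memory load;
  counting the target itself is what makes the subject retrieval in a
  cleft a squared term.
- **nF** — features to recover.  Base loads per DP type: definite 2 (its
  D and its N), proper name 1 and bare pronoun 1 (retrieval rides the
  contextually salient D index), restricted pronoun 2 (a full D + N
  despite the pronominal determiner).  An agreement-bearing probe adds 1
  for a marked-person (1st/2nd) target — the marked person feature is
  one more thing to recover; the object slot of the verb bears no
  agreement, so only subject retrievals pay it.  A salient-index type
  (name or bare pronoun) loses its index shortcut (+1) when another
  salient item *with the same person value* is still in the buffer:
  confusability is evaluated against the buffer at the moment of
  retrieval, which is why the second (object) retrieval, with an empty
  buffer, is never boosted.
- **dF** — cued feature dimensions on which the target differs from
  every competitor.  Which dimensions count is configuration: the
  Italian finite verb probes person and number; the English past-tense
  predicate probes nothing, but overt case morphology (nominative "we")
  is usable as a cue.  Under hypothesis H2 (the default) only marked
  persons can be distinctive — 3rd person is the unmarked "non-person"
  and never earns a cue; under H1 any cued person mismatch counts.  Case
  counts only when the target itself is case-overt and matches the case
  the probe assigns.  With no competitors there is nothing to be
  distinct from and dF = 0.

The product is computed in exact rational arithmetic
(`fractions.Fraction`); the base-10 logarithm is applied only at
reporting, rounded half-up to 2 decimals (base 10 because the combined
verb score 2 + log(27) = 3.43 holds only in that base).  Grid
comparisons against published values use a tolerance of 0.005 on logs
(their printed precision) and exact equality on integers.

These weights are a reconstruction: the sources print region costs, not
a per-type assignment table.  The defaults above are the unique minimal
non-negative integer solution that reproduces all thirteen printed
retrieval products — {27, 12, 6, 18, 18, 4, 18, 8, 4} over the English
3×3 paradigm and {27, 24, 27, 48} over the Italian 2×2 — and they are
fully configurable through `AssignmentTable` / `CueConfig` (JSON or YAML
documents).  Two points the reconstruction fixes that the prose leaves
open: the bare pronoun's base load is 1, not 0 (the printed products
force one recovered unit even for "just a salient index"), and the
confusability penalty applies only to the index-shortcut types, not to
restricted pronouns (otherwise the matching-pronoun product would be 75,
not 48).

## Encoding cost

FEC(x) = Σ eF over the new features encoded at x.  Per DP type
(context-free): definite D+N = 2; proper name 1 (the salient D index is
free, the name's restriction costs 1); bare pronoun 0 (contextually
pre-activated); restricted pronoun D+N = 2, +1 out of the blue for
accommodating a speech-act participant into the restriction.  Two
context adjustments apply at the second DP: a lexical restriction of the
same category as the first DP's (N after N, name-restriction after
name-restriction) is re-encoded at weight 2 instead of 1 — forcing a
differentiation in a fully overlapping memory pattern recruits extra
units — and a marked-person match between the two DPs adds 1.  The
duplication upgrade applies only to argument DPs, not to nouns inside
spill-over adjuncts.  The verb encodes its temporal index and predicate
category (2); the copula and complementizer regions encode one unit
each.  Spill-over regions carry a per-paradigm fixture constant
(English 3, Italian 5) rather than a rule output: the published Italian
spill value is not derivable from the stated encoding rules (a P+D+N
adjunct yields at most 4), so it is shipped as data.

The combined FREC profile reports FEC for every region and
FEC(verb) + log₁₀ FRC(verb) at the verb.

## Memory-load baseline

The dependency-locality baseline scores each DP region by the
accessibility weight of its discourse referent and the verb by
event-referent cost (1) + crossing cost (1) + the intervening subject's
weight.  Three weightings are shipped: A1 (articles and pronominal
determiners referentially alike — all weights equal, 2), A2 (the
article-DP less accessible: definite 3, restricted pronoun 2), A3 (the
restricted pronoun less accessible: definite 2, restricted pronoun 3 —
the default, and the weighting under which the published Italian
baseline grid is reproduced).  Weights for the English-only types are
set by the referentiality hierarchy (proper name 1, bare pronoun 0)
under A2/A3; they do not enter any published cell.  The baseline's
spill value (4) is likewise a fixture constant.

## Paradigm fixtures and the generator of conditions

Costs depend only on the featural templates of the two DPs and the probe
configuration, so one schematic item per condition suffices; the 32
lexicalizations per condition used in the eye-tracking materials are not
reconstructed.  The English fixture sets: definites and names 3rd
person; "you" 2nd plural with no case morphology; "we" 1st plural,
overtly nominative — the one English cell where a retrieval cue applies.
The Italian fixture holds number (plural) and gender constant and marks
both pronominal determiners as out-of-the-blue (the materials provide no
licensing context).  The attached reading-time means are the published
per-condition averages, stored as printed; they are the correlation
input, never fitted.  What passing the grid regressions shows is that
the calculus reproduces the published *predictions*; only the
correlation against the reading-time table touches behavioural data, and
the eye-tracking record of the Italian experiment is outside this
package's scope.

## Numerical and design choices

- Retrieval order at the verb: subject select before object select;
  among multiple buffer matches of the same category the most recently
  stored is tried first (the shipped schemata never hit ambiguity).
- No weight fitting anywhere: the assignment table is configured, and
  the correlation is computed on the fixed default configuration.
- Rounding: half-up at 2 decimals for logs; Pearson r reported at 2
  decimals with df = n − 2 carried as metadata (no p-value machinery —
  for the fixed n = 9 design it adds nothing).
- The marked-person-match encoding increment fires on "same marked
  person value" (2nd with 2nd); whether a hypothetical 1st-with-1st
  configuration should also fire is untested by any shipped paradigm,
  and the rule treats it identically.
- Degenerate inputs: an empty retrieval list has FRC = 1 (empty
  product); log of a non-positive cost raises; correlation requires
  n ≥ 3 and non-zero variance in both vectors.

## Known limitations

- The engine is not a parser for arbitrary sentences; unsupported token
  sequences fail with a region-tagged diagnostic rather than a parse.
- Salience is a boolean template flag, not a context model; no semantic
  computation is performed for the pronominal-determiner denotation.
- dF never exceeds 1 in the shipped configurations; configurations where
  several dimensions are simultaneously distinctive (e.g. a language
  cueing gender as well as person) are expressible but not validated
  against published data.
- Per-region eye-tracking measures (first fixation, gaze duration,
  total time, second pass) and mixed-effects analyses are out of scope;
  the package produces predictors, not fits to trial-level data.
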