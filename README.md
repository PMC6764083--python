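# frec

**Feature Retrieval and Encoding Cost calculus for object-cleft processing.**

Object clefts ("it was **the banker** that **the lawyer** avoided at the
party") displace a direct object into a left-peripheral focus position.
To understand the sentence, a reader must hold the focalized DP in
memory, interpret the intervening subject, and retrieve the filler when
the verb's selection requirements finally license it.  How hard this is
depends on *what kind* of DPs occupy the two positions — definite
descriptions, proper names, bare pronouns, or pronominal determiners
with a lexical restriction ("you bankers") — and on which features the
verb can use as retrieval cues.

`frec` is a small modelling tool for computational psycholinguists: it
implements a top-down, left-to-right minimalist derivation engine with a
memory buffer, the cost calculus that turns its memory operations into
per-region complexity predictions, and a dependency-locality
(memory-load) baseline for comparison.

## The model

Structure is built top-down and left-to-right by a single operation,
merge.  Select features (=X) on merged items project expectations about
what comes next; an argument merged in an unselected position (the
focalized object, the preverbal subject) is **stored** in a memory
buffer and **retrieved** when a later select feature asks for its
category — at the cleft verb, subject first, then object.

Each region x is scored by two quantities:

- **Feature Retrieval Cost** over the retrievals i = 1..n at x:

  FRC(x) = ∏ᵢ (1 + nFᵢ)^mᵢ / (1 + dFᵢ)

  where mᵢ is the number of items in the buffer (target included), nFᵢ
  the number of features the retrieval must recover (2 for a full
  description, 1 for a salient-index type, plus a marked-person feature
  under an agreeing probe, plus a confusability penalty when the
  salient-index shortcut is lost to a same-person competitor), and dFᵢ
  the number of cued feature dimensions — person/number agreement, overt
  case — on which the target differs from every competitor.

- **Feature Encoding Cost**: FEC(x) = Σᵢ eFᵢ over the new features
  encoded at x — 1 per new categorial feature, 2 for re-encoding a
  duplicated lexical category as a selected argument, 0 for contextually
  salient material, +1 for accommodating an out-of-the-blue speech-act
  participant, +1 for a marked-person match between the two DPs.

The combined **FREC** profile scores DP regions by FEC and the verb by
FEC(verb) + log₁₀ FRC(verb).  The memory-load baseline instead scores
each DP by the accessibility weight of its discourse referent and the
verb by an event-referent cost plus an integration cost crossing the
verbal event and the intervening subject referent.

Two paradigms ship as fixtures: the 3×3 English cleft paradigm (definite
× name × pronoun in both positions) with published mean self-paced
reading times attached, and the 2×2 Italian paradigm crossing plural
definite articles with 2nd-person-plural pronominal determiners under
overt subject–verb agreement.

## Worked example

```
$ frec derive italian Pro1-Pro2
derivation: Pro1-Pro2
  1. [BE] merge [Cop Erano]
  2. [DP1] merge [D voi]
       store  <D voi banchieri>  (unselected)
  ...
  7. [VERB] merge [T avete evitato]
       retrieve voi avvocati  (m=2, nF=3, dF=0)
       retrieve voi banchieri  (m=1, nF=2, dF=0)
```

Both pronominal DPs are stored; at the verb the subject is retrieved
against two buffered items (m=2) with three features to recover and no
distinctive cue (both DPs are 2nd person), then the object (m=1, nF=2).
The region costs follow:

```
$ frec cost italian --metric frec
condition	BE	DP1	C	DP2	VERB	SPILL
Art1-Art2	1	2	1	3	3.43	5
Art1-Pro2	1	2	1	4	3.38	5
Pro1-Art2	1	3	1	3	3.43	5
Pro1-Pro2	1	3	1	5	3.68	5
```

The verb column is FEC(verb)=2 plus log₁₀ of the retrieval product —
log₁₀(27)=1.43 for the article conditions, log₁₀(24)=1.38 for the
mismatch condition whose 2nd-person subject is singled out by the
agreement cue, log₁₀(48)=1.68 for the matching-pronoun condition.  On
the English paradigm the same quantity tracks the published verb-region
reading times:

```
$ frec correlate --paradigm english
...
r(7) = 0.98  (n = 9)
P2 vs N2 subject advantage: 30 ms
N2 vs D2 subject advantage: 28 ms
```

`frec verify` re-derives every published grid (the English log-FRC
column, the 9×6 encoding grid, the Italian per-region prediction grids
for both models) and exits nonzero on any cell mismatch.

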