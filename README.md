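# emoscreen

Lexicon-based multipolarity sentiment screening of short social-media
texts for mental-disorder risk.

People with depressive, anxiety, obsessive-compulsive, bipolar and
panic disorders express distinguishable *mixtures* of emotion in what
they write. Binary positive/negative sentiment blurs those mixtures;
`emoscreen` instead scores short texts over eleven Plutchik-style
sentiment categories — anger, loathing, disgust, grief, sadness,
surprise, terror, fear, trust, joy, anticipation — and screens users by
comparing their sentiment distribution to per-condition prototype
vectors. It is a research tool for text-mining experiments, not a
diagnostic instrument.

## The model

**Lexicon.** An 8-emotion affect-intensity lexicon (3-column TSV in the
hashtag-emotion dialect) is refined into 11 categories: the intensities
of the disgust, sadness and fear vocabularies are each clustered by 1-D
2-means, the higher cluster taking the stronger label (loathing, grief,
terror). Optional synonym expansion adds candidates with sense
similarity > 0.7; each category is then min-max normalized to [0, 1].

**Scoring.** For sentence *s* with matched sentiment words *w_j*,

    q(s) = Σ_j ( Int(w_j) · Π_k α_k · β · η  +  γ + τ )

per category, where α_k are attached degree-adverb weights in [0, 2]
("very" = 1.5, "little" = 0.5), η = −1 under negation, β = 1.5 for
clauses after an adversative ("but"), and γ, τ are emoticon and
sentiment-punctuation weights in [0, 1]. Qualifiers attach to the
nearest sentiment word. Sentence vectors are summed over a user's texts
(a 14-day window by default), clamped at zero and normalized to the
11-dimensional sentiment distribution **D_s**.

**Diagnosis.** Each condition *c* has a prototype vector **Vs(c)**,
seeded by scoring a screening-scale text at maximum severity. The match
probability is the cosine similarity

    Prob(c) = ⟨Vs(c), D_s⟩ / (‖Vs(c)‖ ‖D_s‖) ∈ [0, 1]

with risk levels SMU (> 0.8), MMU (0.6–0.8) and NMU (< 0.6); MMU and
above is a positive screen. Conditions are scored independently, so a
user may flag several.

**Training.** Scale-derived prototypes deviate from social-media
language, so each profile is corrected by a stochastic accept/reject
loop: average an unlabeled user batch into **A_sd**, randomly pick one
of its top-2 positive and top-3 negative sentiments, add their
sentiment ratios to the profile, renormalize, and keep the candidate
only if the diagnostic error rate on a labeled cohort strictly drops.

A synthetic-data module generates every input — pseudo-word lexicons,
stand-in scale texts, labeled cohorts with known ground-truth
distributions — so the whole pipeline runs and is tested without any
download.

## Worked example

```python
from emoscreen import (LexiconEntry, MSAILexicon, make_modifier_tables,
                       score_text)

lex = MSAILexicon()
for word, cat, x in [("sad", "sadness", 0.6), ("happy", "joy", 0.8)]:
    lex.add(LexiconEntry(word, cat, x))
tables = make_modifier_tables()
for text in ["I am sad", "I am very sad", "not happy!"]:
    v = score_text(text, lex, tables)
    print(text, "->", {c: round(v[c], 2) for c in ("sadness", "joy") if v[c]})
```

prints

```
I am sad -> {'sadness': 0.6}
I am very sad -> {'sadness': 0.9}
not happy! -> {'joy': -0.5}
```

"very" multiplies the 0.6 intensity by 1.5; negation flips the 0.8 of
"happy" to −0.8 and the "!" adds 0.3 back. The `examples/` directory
walks through each capability (lexicon refinement, scoring, diagnosis,
training) as a runnable script; `emoscreen --help` lists the matching
shell subcommands (`simulate`, `build-lexicon`, `score`, `diagnose`,
`train`, `evaluate`).

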