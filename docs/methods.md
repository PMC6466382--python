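# Methods

This note records the model, its parameters, the numerical choices made
where the procedure was genuinely open, what the synthetic data does and
does not emulate, and the known limitations.

## Lexicon refinement

The source lexicon maps words to one of eight emotions (anger, disgust,
sadness, surprise, fear, trust, joy, anticipation) with a real-valued
affect intensity. Three negative emotions — disgust, sadness, fear —
mix mild and extreme vocabulary, so each is split in two by
one-dimensional k-means (K = 2) on intensity, yielding eleven
categories. The cluster with the larger center receives the stronger
Plutchik label (loathing, grief, terror): those names denote the
higher-arousal variant on the wheel, and nothing else in the procedure
distinguishes the two clusters. Anger, surprise, trust, joy and
anticipation pass through unchanged; anger in particular is never
split — its intensity distribution is treated as balanced.

K-means is Lloyd's algorithm with seeded random restarts (default 10).
Restart initialization draws distinct centers from the point values,
the first uniformly, the rest with squared-distance weighting; plain
uniform seeding demonstrably sticks in poor local optima on small
samples. Because the 1-D squared-loss optimum is always a contiguous
split of the sorted sample, one additional restart is seeded from the
best contiguous split, which makes the K = 2 solver exact while keeping
the stated algorithm (Lloyd iteration; cost non-increasing per
iteration; deterministic under a seed).

Synonym expansion is provider-injected: any callable mapping a word to
(candidate, similarity) pairs can serve; candidates are added only with
similarity strictly above the 0.7 threshold and inherit the seed word's
category and intensity (the procedure adds words, not new scores). On
collision the larger intensity wins; expansion never removes or lowers
an entry. Expansion runs before normalization so inherited raw
intensities are rescaled consistently.

Normalization is per-category min–max to [0, 1]; it preserves
within-category ranking and is idempotent on categories already
spanning the interval. A category whose intensities are all equal maps
to 1.0 — the words are equally, fully representative — rather than an
arbitrary 0 or 0.5.

## Qualifier tables and attachment

Degree adverbs carry weights in [0, 2]; only "very" = 1.5 and
"little" = 0.5 are fixed by the quantification rules, and the remaining
defaults (e.g. "extremely" = 1.8, "slightly" = 0.3) are editable
fixture values shipped as TSV. Negations weigh −1, adversatives give
the following clause weight 1.5, emoticons and sentiment punctuation
carry additive weights in [0, 1].

Attachment follows proximity, not parsing. Degree adverbs and negations
attach to the nearest sentiment word within a 3-token window (a guard
against cross-clause capture); ties between an equidistant preceding
and following word go to the following one, since qualifiers usually
precede what they modify. Emoticons and punctuation attach at sentence
scope; when several reach the same word the largest weight is used,
because the sentence formula has a single additive slot for each. An
odd number of attached negations flips the sign. Every qualifier token
attaches to at most one word, and a word after any adversative in its
sentence gets the 1.5 clause weight.

## Scoring and the sentiment distribution

Per sentiment word: intensity × Π(degree weights) × adversative ×
negation + emoticon + punctuation, accumulated into the word's category
dimension; sentences sum over a text, texts sum over the user's 14-day
observation window. Negation can drive a category negative; negative
mass is clamped to zero only at normalization, so within-window
cancellation (e.g. "not happy" against "happy") is preserved while the
final distribution remains a probability vector. A window with zero (or
wholly negative) mass yields a flagged empty distribution — an
"insufficient evidence" signal, never a silent zero vector.

## Profiles, similarity, risk levels

Condition profiles are built by scoring scale-item texts with every
matched word's degree factor forced to the maximum configured degree
weight (default 2.0): the prototype represents the most severe
presentation as the reference. Match probability is cosine similarity,
which for non-negative vectors lies in [0, 1] and is invariant to
positive rescaling of either side. Risk cuts: severe above 0.8,
moderate from 0.6 to 0.8 inclusive (boundary values fall to the
moderate band — the severe/none definitions use strict inequalities),
none-or-mild below 0.6. Positive screening means moderate or above.
Conditions are scored independently; comorbidity is expected, so no
argmax suppression is applied.

## Training

Each cycle, per condition: a batch of unlabeled users (default 1000;
sampled with replacement from smaller corpora) is averaged into A_sd
and renormalized; the eleven categories are partitioned by valence
(positive: joy, trust, anticipation, surprise — surprise grouped
positive so the top-2 positive pool is non-trivial; negative: the
seven others); one of the top-2 positive and one of the top-3 negative
categories by sentiment ratio is drawn uniformly; each chosen dimension
is incremented by its sentiment ratio, the ratio's percentage value
divided by 100. The candidate replaces the profile only if its
diagnostic error rate on the full labeled cohort is strictly lower, so
the accepted-error sequence is non-increasing by construction. The
error rate is the misclassified fraction at the 0.6 positive threshold,
computed on the full cohort each cycle (stabler than per-batch error).
Default 100 cycles per condition.

The increment scale is configurable (`learning_scale`): 1.0 — the
default — reads the ratio-over-100 rule as a percent-to-fraction
conversion, giving increments of roughly 0.05–0.4 simplex mass; 0.01
instead divides the fractional ratio by 100, giving increments near
0.001. The default was chosen because measured dynamics under the tiny
reading leave the accept gate essentially never satisfied (a step too
small to flip any user's diagnosis is always rejected, so the profile
never moves), while the percent reading produces the intended
convergence behaviour over 100 cycles.

The random choice among top sentiments trades per-step optimality for
less oscillation near convergence; the result is not guaranteed optimal.

## Synthetic data

The generator emulates the structure of a hashtag-collected cohort:
five condition groups plus controls, 14 tweets per user (within the
observed 12–18 median range) of ~8 words each over a two-week timeline.
Condition signatures are fixed target distributions echoing each
disorder's clinical description (depressive: grief/sadness; anxiety:
fear/anticipation; OCD: disgust/loathing; bipolar: joy alternating with
depressive mass; panic: terror/fear); controls follow a positive-heavy
background with light negative mass. A user's category mixture is one
Dirichlet draw at concentration 50 (default) around their target;
word counts are then apportioned deterministically (largest remainder,
weighted by inverse mean category intensity so the *intensity mass*
scored downstream matches the mixture), and each category's vocabulary
is used evenly so the realized mean intensity stays at the category
mean. Qualifiers are injected at rate 0.1 per word. Scale texts are
synthetic stand-ins — items naming each category's maximum-intensity
word with multiplicity proportional to target mass — not the text of
any published instrument.

Perturbed-profile experiments mix a profile 45% toward the background
and take one Dirichlet draw at concentration 80: that places controls
near the 0.6 decision boundary, which is the deviation regime (scale
prototype vs. social-media language) the training loop exists to
correct.

What passing synthetic tests shows: the arithmetic of every stage, the
clustering optimality, the simplex invariants, recovery when texts
truly follow category mixtures, and the training gate's guarantees.
What they do not show: performance on natural language — word salads
have no syntax, sarcasm, topic drift, polysemy or class imbalance, and
the pseudo-word lexicon has no out-of-vocabulary problem.

## Problem sizes and numerical conventions

Tests and the acceptance script use a 200-user labeled cohort
(5 × 20 + 100), a 200-user unlabeled corpus, batches of 100, and 100
training cycles per condition; the clustering oracle check enumerates
all 2-partitions of ≤ 12 points over 100 random fixtures. Distribution
sums are checked to 1e-9; k-means cost comparisons use a 1e-15 strict-
improvement margin so restart ties keep the first optimum found.
TSV round-trips write full-precision `repr` floats, so save→load is
bit-exact. Malformed lexicon rows are skipped with a warning up to a
10% budget, beyond which loading fails; an unknown category name always
fails (it indicates the wrong file, not a typo).

## Limitations

English-only heuristics (apostrophe handling, regex word tokens); no
POS tagging or dependency parsing, so qualifier attachment is purely
positional; no neutral class; no time-series modeling within the
window; the screening thresholds and qualifier weights are conventions,
not clinically validated quantities; none of the outputs are diagnoses.
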