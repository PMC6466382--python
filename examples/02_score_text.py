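"""Quantify the affect of short texts with qualifier rules.

Each sentiment word contributes intensity x degree x adversative x
negation + emoticon + punctuation to its category; sentence vectors sum
over a text and normalize to an 11-dimensional sentiment distribution.
"""

from emoscreen import (
    CATEGORIES_11,
    LexiconEntry,
    MSAILexicon,
    make_modifier_tables,
    normalize_distribution,
    score_text,
)

lex = MSAILexicon()
for word, cat, x in [("sad", "sadness", 0.6), ("happy", "joy", 0.8),
                     ("scared", "fear", 0.7)]:
    lex.add(LexiconEntry(word, cat, x))
tables = make_modifier_tables()

for text in ["I am sad", "I am very sad", "I am a little sad",
             "not happy!", "happy, but so scared :("]:
    v = score_text(text, lex, tables)
    nonzero = {c: round(v[c], 3) for c in CATEGORIES_11 if v[c] != 0}
    print(f"{text!r:32s} -> {nonzero}")

v = score_text("I am very sad. not happy! so scared", lex, tables)
ds = normalize_distribution(v)
print("\nfull text distribution:",
      {c: round(ds[c], 3) for c in CATEGORIES_11 if ds[c] > 0})
print(
    "\n'very' multiplies by 1.5 and 'little' by 0.5; negation flips the"
    "\nsign (the '!' adds 0.3 back); after 'but' the clause weighs 1.5."
    "\nNegative mass is clamped at 0 before normalizing to unit sum."
)
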