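"""Refine an 8-emotion affect lexicon into the 11-category lexicon.

Generates a small synthetic source lexicon (8 Plutchik emotions with
real-valued word intensities), splits disgust/sadness/fear into strong
and mild variants by 1-D 2-means on intensity, and min-max normalizes
each category to [0, 1].
"""

from emoscreen import GeneratorSpec, make_fixture_lexicon

msai, source = make_fixture_lexicon(GeneratorSpec(seed=1))

print(f"source lexicon: {len(source)} entries over 8 emotions")
print(f"refined lexicon: {len(msai)} entries over 11 sentiment categories\n")

for strong, mild in (("loathing", "disgust"), ("grief", "sadness"), ("terror", "fear")):
    s = sorted(round(e.intensity, 2) for e in msai.entries_for(strong))
    m = sorted(round(e.intensity, 2) for e in msai.entries_for(mild))
    print(f"{mild:8s} split -> {strong}: {s}  |  {mild}: {m}")

print(
    "\nEach pair partitions one source emotion: the higher-intensity"
    "\ncluster takes the stronger Plutchik label, and every category is"
    "\nrescaled so its most intense word scores 1.0."
)
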