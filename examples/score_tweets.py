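"""Score a few tweets with the rule-based valence engine.

Each tweet is tokenized and normalized, then the lexicon and grammar rules
(degree modifiers, ALL-CAPS/exclamation emphasis, negation, "but" contrast)
produce a raw valence sum, a squashed compound score in (-1, 1), and a
positive/negative/neutral label.
"""

from hookahsent import ValenceLexicon, score_tweet
from hookahsent.preprocess import preprocess_tweet

lexicon = ValenceLexicon.default()

texts = [
    "very happy smoking hookah",
    "the hookah here isn’t really all that great",
    "the place was boring but the shisha was great",
    "this is grrrrrreat!",
    "picked up coals for the hookah",
]

for text in texts:
    s = score_tweet(preprocess_tweet("t", text), lexicon)
    print(f"{text!r:60s} raw={s.raw_sum:+6.2f} compound={s.compound:+.3f} {s.label}")

print()
print("raw is the rule-weighted sum of token valences (each in [-4, 4]);")
print("compound squashes it to (-1, 1); labels use a symmetric ±0.05 band.")
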