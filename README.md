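# hookahsent

Debiased sentiment infoveillance for hookah-related tweet corpora.

Public-health researchers use social-media streams to gauge attitudes
toward tobacco products such as hookah (waterpipe). Raw Twitter data,
however, is contaminated by social bots and marketing accounts whose posts
do not reflect the sentiment of legitimate human users — and their presence
can flip the apparent sentiment of an entire corpus. `hookahsent`
implements the full surveillance pipeline:

1. **Corpus handling** — JSON-lines tweet/account corpora, collection-window
   validation, and case-insensitive root-term filtering
   (`hookah(s)`, `hooka(s)`, `sheesha(s)`, `shisha(s)`, `sesh(s)`, matching
   inside hashtags).
2. **Synthetic corpus generation** — seeded corpora with planted human,
   bot, and marketing accounts and exact per-tweet ground truth, standing
   in for undeposited platform data.
3. **Debiasing** — six account-level behavioral features (posting-time
   regularity, spam phrases, mobile:desktop client mix, follower:followee
   ratio, noun/verb/adverb content profile, sentiment dispersion) are
   combined into a single bot score; flagged accounts are removed, then
   marketing posts are stripped by keyword (e.g. `1100mah`).
4. **Rule-based valence scoring** — a lexicon on a [−4, 4] spectrum
   ("horrible" −2.5, "wonderful" +2.7) with grammar rules: degree modifiers
   ("very happy" counts "happy" twice), ALL-CAPS/exclamation emphasis,
   negation in a 3-token window, and "but"-contrast clause weighting. The
   raw sum *x* is squashed to a compound score
   *x* / √(*x*² + α), α = 15, and labeled with a symmetric ±0.05 band.
5. **Circumplex emotion tagging** — each tweet is placed at (valence,
   arousal) and assigned the nearest of 20 emotions on Russell's circumplex
   (four quadrants: highly positive, passive positive, subdued negative,
   highly negative), then reduced to 5 primary emotions (anger, fear, joy,
   sadness, disgust). A uni+bigram linear-SVM classifier provides the
   supervised counterpart to the rule engine, with F = 2PR/(P+R) evaluation.
6. **Reporting** — corpus-level label/quadrant percentages and
   primary-emotion probabilities, with biased-vs-debiased comparison
   tables.

## Worked example

```bash
python examples/score_tweets.py
```

```
'very happy smoking hookah'                    raw= +5.40 compound=+0.813 positive
'the hookah here isn’t really all that great'  raw= -6.20 compound=-0.848 negative
'the place was boring but the shisha was great' raw= +4.00 compound=+0.718 positive
'this is grrrrrreat!'                          raw= +6.20 compound=+0.848 positive
'picked up coals for the hookah'               raw= +0.00 compound=+0.000 neutral
```

"very happy" doubles the 2.7 valence of "happy" (booster rule); the
negated "isn't … great" example flips sign inside the negation window; the
"but" clause weights the trailing "great" at 1.5× and the leading "boring"
at 0.5×; the elongated "grrrrrreat!" is compressed back to "great" against
the dictionary and doubled by the exclamation.

The full pipeline on a default synthetic corpus (`python
examples/full_pipeline.py`, seed 3) recovers the planted human sentiment
mix after debiasing and shows the bias bots introduce:

```
label percentages (debiased): {'negative': 30.93, 'neutral': 10.26, 'positive': 58.82}
label percentages (biased):   {'negative': 40.8, 'neutral': 17.39, 'positive': 41.81}

joy probability: debiased 65.54% vs biased 50.61%
```

The debiased corpus matches the planted 59.5/30/10.5 mix; with bot tweets
left in, the corpus appears far more negative — the reason debiasing
matters for any attitude estimate drawn from platform data.

Other entry points: `examples/generate_corpus.py`,
`examples/debias_demo.py`, and the `hookahsent` CLI
(`synth`, `filter`, `debias`, `score`, `emotions`, `report`, `run`).

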