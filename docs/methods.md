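# Methods

## Scope and model

`hookahsent` estimates corpus-level sentiment toward hookah from tweet
corpora, after removing posts that do not reflect legitimate human
attitudes. The pipeline has four statistical components: a synthetic
corpus generator with planted structure, an account-level bot detector, a
rule-based valence scorer with a supervised n-gram counterpart, and a
valence–arousal circumplex emotion model. This note records the model
assumptions, the tunable parameters and their defaults, and the design
choices made where the design was genuinely open.

## Corpus model

A corpus is a set of tweets (id, account, UTC timestamp, text, client
source, retweet flag, mention count) plus account records (follower and
followee counts, ordered tweet list). On disk it is JSON-lines with a
versioned header record; timestamps are ISO-8601 in files and epoch
seconds in memory. The collection window is 2015-03-24 through 2016-12-02
(UTC, inclusive); window validation is opt-in (`strict_window`) because
read-time strictness is a policy, not a format property.

Root-term filtering matches `hookah`, `hooka`, `sheesha`, `shisha`, `sesh`
case-insensitively at token boundaries, each with an explicit plural-"s"
expansion rather than stemming, and matches inside hashtags. "waterpipe"
is excluded: it is academic register, essentially absent from organic
posts. Retweets are kept by default; `drop_retweets` removes them
(deduplication practice is a declared convention, not an inference).

## Synthetic corpus generator

The generator defines the study conditions for every simulation-based
result in the package; the tests and acceptance quantities are computed
under these defaults.

* **Population**: 120 human, 60 bot, 20 marketing accounts, each drawing
  Poisson(20) tweets (min 1). With equal rates this yields ~30% bot tweets
  and ~10% marketing tweets, the contamination level the debiasing step is
  designed around. The acceptance script scales all three counts by 12.5
  (~50,000 tweets) without changing proportions.
* **Human sentiment mix**: positive/negative/neutral = 0.595/0.30/0.105.
* **Bot sentiment mix**: 0.10/0.75/0.15 — bots skew the corpus negative,
  so debiasing visibly shifts the aggregate toward positive.
* **Timing**: human inter-arrival times are log-normal (median 6 h, shape
  σ = 1.2; interval CV ≈ 1.8 — bursty, heavy-tailed). Bots post at a fixed
  period (default 3600 s) with ±5% uniform jitter (CV ≈ 0.03). The CV gap
  is the separation the timing feature exploits and is tunable end to end.
* **Clients**: humans are 70% mobile / 25% desktop / 5% other per tweet;
  each bot account posts from a single client (desktop for 80% of bot
  accounts); marketing accounts are 50/50.
* **Followers**: humans draw followers ~ 10^U(1.5, 3) with followees
  within half a log10 of that; bots have ≤50 followers and thousands of
  followees.
* **Text**: slot-filling templates over the package's own valence lexicon,
  so the planted label is exact by construction. Positive tweets draw
  high-arousal words (happy, excited, …) with probability 0.62 and calm
  words (relaxed, serene, …) otherwise; negative tweets draw low-arousal
  words (sad, bored, …) with probability 0.54. Emphatic features are
  planted at fixed rates: boosters 0.15, exclamation 0.12, emoticons 0.10,
  ALL-CAPS 0.05, elongation 0.05, negation 0.05, "but" clauses 0.05.
  Negated and contrast templates are built so the planted label survives
  the grammar rules (negation wraps an opposite-polarity word; the
  trailing clause of a contrast uses a strong word against a weak opener),
  and are flagged in the ground-truth sidecar so "unambiguous" subsets can
  be selected. Bot accounts repeat one template/phrase/word combination
  (spam phrase present in 80% of their tweets); every marketing tweet
  carries a product keyword.

What the generator does **not** emulate: real linguistic diversity,
sarcasm, topic drift, retweet cascades, or adversarial bots that mimic
human timing. Passing tests therefore demonstrate that the pipeline's
machinery is correct and well-calibrated under its stated assumptions —
not that these accuracy levels transfer to live platform data, where
template-free language and stealthier bots will lower every figure.

## Preprocessing

Tokenization removes URLs (scheme-prefixed, `www.`, and trailing bare
domains), converts HTML tags to whitespace, drops undecodable replacement
characters, and splits on an emoticon-aware word pattern. Emphasis
(exclamation count, ALL-CAPS tokens) is counted on the raw surface before
lowercasing and stop-word removal, so emphasis is invariant to those
steps. The stop-word list is common English function words; negators,
boosters, and contrast words are deliberately not stop words because the
scorer consumes them. @-mentions are dropped as sentiment-free.

Normalization unifies all smile emoticons to one SMILE token and all
frowns to FROWN (two classes only); strips apostrophes so "don't"/"dont"
coincide; compresses character runs of length ≥3 to the shortest
dictionary-valid form ("grrrrrreat" → "great") and otherwise to length 2,
incrementing the elongation count; applies a small slang table; and
Porter-stems last. The Porter stemmer is implemented in-package (the
classic five-phase algorithm) and both unstemmed and stemmed streams are
kept, because lexicon lookup is exact-match-then-stemmed-fallback.

POS tagging is a coarse six-tag scheme (noun/verb/adjective/adverb/
preposition/other) from a shipped tag lexicon plus suffix rules, with
unknown words tagged `other`. Only noun/verb/adverb rates are consumed
downstream (the bot content feature), which is why a full treebank tagger
is unnecessary.

## Rule-based valence scoring

Token valences live on [−4, 4]; the shipped lexicon (~100 words plus
SMILE/FROWN) anchors "horrible" at −2.5 and "wonderful" at +2.7. Rules,
applied per valence-bearing token:

* ×2 if immediately preceded by a booster; ×2 if ALL-CAPS; ×2 if its
  clause ends with "!". Doublings multiply but cap at ×4 (stacking
  semantics are a declared convention).
* Sign flip if a negator occurs within the 3 preceding scoring tokens.
  The window is validated by the regression case "the hookah here isn't
  really all that great" → negative, which requires negation to reach
  "great" across the booster after stop-word removal.
* The first contrast word ("but", …) splits the tweet: tokens before it
  weigh 0.5, after it 1.5 — a polarity *shift* toward the trailing clause
  rather than a hard flip; both weights are configurable.

The compound score is x/√(x² + α) with α = 15 and the neutral band is
±0.05 (boundary inclusive); both constants follow the standard
social-media valence-rule method this scorer is modeled on. Precision,
recall, and F = 2PR/(P+R) are computed per class with zero-denominator
ratios reported as 0 and flagged; macro-F is the unweighted class mean.

## Bot detection

Each feature maps to [0, 1] with 1 maximally bot-like:

* timing regularity = 1/(1 + CV) of inter-tweet intervals;
* spam = fraction of tweets containing a known spam phrase (phrases are
  normalized through the same pipeline as tweets, so stop words inside a
  phrase drop out on both sides);
* client deviation = |observed mobile share − 0.7| / max(0.7, 0.3),
  "other" clients excluded;
* follower ratio = min(1, |log10((followers+1)/(followees+1))| / 2);
* content = total-variation distance of the pooled noun/verb/adverb
  profile from the human reference (0.45, 0.35, 0.20);
* sentiment dispersion = clip(1 − std(compounds)/0.6) — template
  repeaters score high.

The human baselines (mobile share 0.7, band half-width 2 log10 units, the
reference POS profile, compound std 0.6) are configured defaults — they
are pipeline parameters to be set per deployment, not estimates. The
combined score is a weighted mean (equal weights by default); missing
features (too few tweets, no tagged tokens, <3 scored tweets) drop out
with weight renormalization; an account with no computable feature is
"undecidable" and conservatively retained. The decision is account-level
(all features are behavioral signatures of the account), with threshold
0.5. Diffusion features are reduced to the per-account mention rate; full
cascade analysis would need graph data the corpus format does not carry.

Marketing removal happens **after** bot removal, so the three output
corpora (clean / bots-only / marketing-only) partition the input exactly
and a bot tweet containing a marketing keyword counts as bot. The
"biased comparison" corpus is clean + bots (marketing excluded).

## Circumplex emotion model

The 20 emotions are placed on the unit circle at equal angular spacing
within their quadrant, in the standard circumplex ordering: highly
positive (active, alert, excited, elated, happy, pleasant), passive
positive (contented, serene, calm, relaxed, subdued), subdued negative
(sad, unhappy, depressed, bored), highly negative (tense, nervous,
stressed, upset, unpleasant). Coordinates ship as a TSV so alternative
layouts can be swapped in. "subdued" is treated as a passive-positive
anchor name, per the quadrant listing it appears in.

Valence is the compound score; arousal is operationalized in one place as
the mean of an arousal-word lexicon plus a saturating emphasis term
(1 − e^(−E/2), gain 0.8, E = exclamations + caps + elongations), clipped
to [−1, 1]. Tagging is nearest-anchor in Euclidean distance with
alphabetical tie-break; the quadrant field follows the signs of (valence,
arousal); neutral-labeled tweets get quadrant "neutral" and primary
"none". The 20→5 reduction is a configurable table; the default maps both
positive quadrants to joy, {sad, unhappy, depressed, bored} → sadness,
{tense, nervous, stressed} → fear, upset → anger, unpleasant → disgust —
a declared convention, since no canonical table exists for this anchor
set.

The supervised counterpart is a uni+bigram count vectorizer into a linear
SVM (deterministic given seed), with stratified 5-fold cross-validated
macro-F reported at fit time. Tweets whose n-grams are entirely out of
vocabulary fall back to the training prior class with a flag. Training
uses the synthetic labeled corpus; users with access to external
emotion-labeled datasets can pass any (tokens, label) pairs to `fit`.

## Reporting conventions

Percentages are rounded half-up at two decimals. Quadrant percentages are
expressed within their parent label (share of positive tweets that are
highly positive, etc.). Primary-emotion probabilities are computed over
assigned (non-neutral) tweets only — neutral tweets carry no primary
emotion, so including them would deflate every probability; this is the
single place where a denominator convention had to be declared, and it is
configurable by passing explicit count tables.

## Problem sizes and numerical choices

The shared test corpus is ~4,000 tweets (200 accounts); the acceptance
script regenerates ~50,000 tweets (2,500 accounts), a scale at which every
simulation-based quantity is stable to well under a percentage point
across seeds. Determinism: all randomness flows from one integer seed
through `numpy.random.default_rng` (generator) and scikit-learn
`random_state` (classifier, folds); rerunning any stage with the same
config yields byte-identical files. Degenerate inputs are handled
explicitly: empty text → empty token list; no valence tokens → compound 0,
neutral; <2 timestamps, other-only clients, no tagged tokens, <3 scored
tweets → missing feature with weight renormalization; empty corpora are
rejected by `summarize` and the generator requires ≥1 account.

## Known limitations

Template-generated text makes the scorers look better than they would be
on real language (macro-F here is near 1.0; on real tweets rule engines of
this family score far lower). The bot/human separation is planted and
wide; adversarial bots would compress it. The arousal construction is this
package's own operationalization and has no external calibration. The
circumplex anchor angles are a layout convention, not psychometric
estimates. English only.
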