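"""Generate a synthetic tweet corpus with planted structure.

The generator emits human accounts (bursty timing, mixed clients, a
59.5/30/10.5 positive/negative/neutral mix), social bots (near-periodic
posting, spam phrases, extreme follower ratios), and marketing accounts
(product keywords in positive text). The ground-truth sidecar records every
tweet's planted role and sentiment.
"""

from hookahsent import GeneratorConfig, generate, ground_truth

corpus = generate(GeneratorConfig(seed=42))
truth = ground_truth(corpus)

print(f"tweets: {len(corpus)}, accounts: {len(corpus.accounts)}")
print("\nrole shares (tweets):")
print(truth.role.value_counts(normalize=True).round(3))
print("\nplanted sentiment mix (human tweets):")
human = truth[truth.role == "human"]
print(human.planted_sentiment.value_counts(normalize=True).round(3))
print("\nexample tweet text:", repr(corpus.tweets[0].text))
print("\nBot tweets are ~30% and marketing ~10% of the corpus; the human")
print("sentiment mix matches the configured 0.595/0.30/0.105 plant.")
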