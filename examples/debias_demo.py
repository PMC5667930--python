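"""Remove social-bot and marketing posts from a synthetic corpus.

Six behavioral features per account (timing regularity, spam, client mix,
follower ratio, content profile, sentiment dispersion) combine into one bot
score; flagged accounts lose all their tweets, then marketing posts are
removed by keyword. The three outputs partition the input exactly.
"""

from hookahsent import GeneratorConfig, debias_corpus, generate
from hookahsent.pipeline import preprocess_corpus, score_corpus

corpus = generate(GeneratorConfig(seed=7))
tokenized = preprocess_corpus(corpus)
scores = score_corpus(corpus, tokenized)
compounds = {tid: s.compound for tid, s in scores.items()}

clean, bots, marketing, report, account_scores = debias_corpus(
    corpus, tokenized, compounds
)

print(f"input tweets:      {report.n_input}")
print(f"bot tweets:        {report.n_bot_removed} ({report.pct_bot_removed}%)")
print(f"marketing tweets:  {report.n_marketing_removed} "
      f"({report.pct_marketing_removed}%)")
print(f"clean sample:      {report.n_clean}")
print(f"accounts flagged:  {report.n_accounts_flagged}")

truth = {a.account_id: a.ground_truth_role for a in corpus.accounts.values()}
tp = sum(1 for a, s in account_scores.items() if s.is_bot and truth[a] == "bot")
flagged = sum(1 for s in account_scores.values() if s.is_bot)
n_bots = sum(1 for r in truth.values() if r == "bot")
print(f"\nbot precision: {tp / flagged:.3f}, recall: {tp / n_bots:.3f}")
print("The clean corpus keeps only tweets from accounts scoring below the")
print("bot threshold and free of marketing keywords.")
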