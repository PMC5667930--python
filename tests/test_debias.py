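import numpy as np
import pytest

import hookahsent as hs
from hookahsent.corpus import Account, ClientSource, Corpus, Tweet, WINDOW_START
from hookahsent.debias import (
    BotFeatures,
    client_ratio_deviation,
    combine_bot_score,
    content_score,
    follower_ratio_score,
    marketing_filter,
    sentiment_feature_score,
    spam_score,
    timing_regularity,
)
from hookahsent.preprocess import preprocess_tweet


class TestTimingRegularity:
    def test_perfectly_periodic(self):
        assert timing_regularity([0, 60, 120, 180]) == pytest.approx(1.0)

    def test_cv_one_maps_to_half(self):
        # intervals [1, 1, 4 + 3*sqrt(2)] have CV exactly 1
        gaps = [1.0, 1.0, 4.0 + 3.0 * np.sqrt(2.0)]
        assert np.std(gaps) / np.mean(gaps) == pytest.approx(1.0)
        ts = np.concatenate([[0.0], np.cumsum(gaps)])
        assert timing_regularity(list(ts)) == pytest.approx(0.5)

    def test_missing_below_two_timestamps(self):
        assert timing_regularity([5.0]) is None
        assert timing_regularity([5.0, 5.0]) is None  # dedup collapses

    def test_bots_score_above_humans(self, default_corpus):
        by_role = {"bot": [], "human": []}
        for acc in default_corpus.accounts.values():
            if acc.ground_truth_role not in by_role:
                continue
            ts = [
                t.timestamp for t in default_corpus.tweets
                if t.account_id == acc.account_id
            ]
            r = timing_regularity(ts)
            if r is not None:
                by_role[acc.ground_truth_role].append(r)
        assert np.mean(by_role["bot"]) > np.mean(by_role["human"])


class TestSpamScore:
    def _tts(self, texts):
        return [preprocess_tweet(str(i), t) for i, t in enumerate(texts)]

    def test_no_match_zero(self):
        assert spam_score(self._tts(["nice hookah night"] * 4)) == 0.0

    def test_all_match_one(self):
        assert spam_score(self._tts(["click here for hookah"] * 3)) == 1.0

    def test_fraction(self):
        texts = ["click here now"] * 3 + ["plain hookah talk"] * 7
        assert spam_score(self._tts(texts)) == pytest.approx(0.3)

    def test_empty_phrase_list_rejected(self):
        with pytest.raises(ValueError):
            spam_score(self._tts(["x"]), spam_phrases=[])


def _tweet(i, client):
    return Tweet(f"t{i}", "a", WINDOW_START + i, "x", ClientSource(client))


class TestClientRatio:
    def test_matching_baseline_zero(self):
        tweets = [_tweet(i, "mobile") for i in range(5)] + [
            _tweet(i + 5, "desktop") for i in range(5)
        ]
        assert client_ratio_deviation(tweets, 0.5) == pytest.approx(0.0)

    def test_maximal_deviation(self):
        tweets = [_tweet(i, "mobile") for i in range(4)]
        assert client_ratio_deviation(tweets, 0.5) == pytest.approx(1.0)

    def test_formula(self):
        tweets = [_tweet(i, "mobile") for i in range(8)] + [
            _tweet(i + 8, "desktop") for i in range(2)
        ]
        # |0.8 - 0.6| / max(0.6, 1 - 0.6); the denominator is the largest
        # achievable deviation, so the score can never exceed 1
        assert client_ratio_deviation(tweets, 0.6) == pytest.approx(0.2 / 0.6)

    def test_other_only_missing(self):
        assert client_ratio_deviation([_tweet(0, "other")], 0.5) is None


class TestFollowerRatio:
    def test_balanced_is_zero(self):
        assert follower_ratio_score(500, 500) == pytest.approx(0.0)

    def test_extreme_clips_to_one(self):
        assert follower_ratio_score(0, 10_000) == pytest.approx(1.0)

    def test_halfway_through_band(self):
        # log10((99+1)/(9+1)) = 1 with half-width 2 -> 0.5
        assert follower_ratio_score(99, 9, band_halfwidth=2.0) == pytest.approx(0.5)


class TestContentScore:
    def test_identical_profiles_zero(self):
        tags = [["noun"] * 45 + ["verb"] * 35 + ["adverb"] * 20]
        assert content_score(tags, (0.45, 0.35, 0.20)) == pytest.approx(0.0)

    def test_disjoint_profiles_one(self):
        assert content_score([["noun"]], (0.0, 1.0, 0.0)) == pytest.approx(1.0)

    def test_tv_distance_arithmetic(self):
        tags = [["noun"] * 5 + ["verb"] * 3 + ["adverb"] * 2]
        assert content_score(tags, (0.4, 0.4, 0.2)) == pytest.approx(0.1)

    def test_no_content_tokens_missing(self):
        assert content_score([["other", "other"]]) is None


class TestSentimentFeature:
    def test_identical_compounds_max(self):
        assert sentiment_feature_score([0.4, 0.4, 0.4]) == pytest.approx(1.0)

    def test_half_baseline_std(self):
        assert sentiment_feature_score(
            [-0.3, 0.3, -0.3, 0.3], human_std=0.6
        ) == pytest.approx(0.5)

    def test_uniform_spread_near_zero(self):
        rng = np.random.default_rng(0)
        compounds = rng.uniform(-1, 1, 2000)
        # std of U(-1,1) is 1/sqrt(3); with that configured baseline the
        # feature sits near 0
        score = sentiment_feature_score(compounds, human_std=1 / np.sqrt(3))
        assert score < 0.05

    def test_missing_below_three(self):
        assert sentiment_feature_score([0.1, 0.2]) is None


class TestCombine:
    def test_extremes(self):
        zeros = BotFeatures(0, 0, 0, 0, 0, 0)
        ones = BotFeatures(1, 1, 1, 1, 1, 1)
        assert combine_bot_score("a", zeros).combined == 0.0
        assert not combine_bot_score("a", zeros).is_bot
        assert combine_bot_score("a", ones).combined == 1.0
        assert combine_bot_score("a", ones).is_bot

    def test_equal_weight_mean(self):
        f = BotFeatures(1, 1, 0, 0, 0, 0)
        assert combine_bot_score("a", f).combined == pytest.approx(1 / 3)

    def test_missing_features_renormalize(self):
        f = BotFeatures(1.0, None, None, None, None, None)
        s = combine_bot_score("a", f)
        assert s.combined == pytest.approx(1.0) and s.is_bot

    def test_all_missing_undecidable(self):
        s = combine_bot_score("a", BotFeatures())
        assert s.undecidable and not s.is_bot and s.combined is None

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            combine_bot_score("a", BotFeatures(1, 1, 1, 1, 1, 1),
                              weights={"spam_score": -1})


class TestMarketingFilter:
    def _corpus(self, texts):
        tweets = [
            Tweet(f"t{i}", "a", WINDOW_START + i, txt) for i, txt in enumerate(texts)
        ]
        tok = {t.tweet_id: preprocess_tweet(t.tweet_id, t.text) for t in tweets}
        return tweets, tok

    def test_keyword_removed_plain_kept(self):
        tweets, tok = self._corpus(
            ["new hookah pen 1100mah deal", "hookah with friends"]
        )
        kept, removed = marketing_filter(tweets, tok)
        assert [t.tweet_id for t in removed] == ["t0"]
        assert [t.tweet_id for t in kept] == ["t1"]

    def test_fixture_counts(self):
        texts = ["hookah coupon code"] * 5 + ["hookah night out"] * 15
        tweets, tok = self._corpus(texts)
        kept, removed = marketing_filter(tweets, tok)
        assert len(kept) == 15 and len(removed) == 5

    def test_empty_keywords_noop_with_warning(self):
        tweets, tok = self._corpus(["hookah coupon"])
        with pytest.warns(UserWarning):
            kept, removed = marketing_filter(tweets, tok, marketing_keywords=[])
        assert len(kept) == 1 and not removed


@pytest.fixture(scope="module")
def debiased(default_corpus, default_tokenized, default_scores):
    compounds = {k: s.compound for k, s in default_scores.items()}
    return hs.debias_corpus(default_corpus, default_tokenized, compounds)


class TestDebiasCorpus:
    def test_partition_conservation(self, default_corpus, debiased):
        clean, bots, marketing, report, _ = debiased
        assert len(clean) + len(bots) + len(marketing) == len(default_corpus)
        assert report.n_clean == len(clean)
        assert report.n_biased_comparison == len(clean) + len(bots)

    def test_bot_precision_and_recall(self, default_corpus, debiased):
        *_, scores = debiased
        truth = {
            a.account_id: a.ground_truth_role == "bot"
            for a in default_corpus.accounts.values()
        }
        tp = sum(1 for a, s in scores.items() if s.is_bot and truth[a])
        fp = sum(1 for a, s in scores.items() if s.is_bot and not truth[a])
        fn = sum(1 for a, s in scores.items() if not s.is_bot and truth[a])
        assert tp / (tp + fp) >= 0.9
        assert tp / (tp + fn) >= 0.9

    def test_account_classification_accuracy(self, default_corpus, debiased):
        """Planted behaviors are well separated; account-level bot
        classification accuracy exceeds 95%."""
        *_, scores = debiased
        truth = {
            a.account_id: a.ground_truth_role == "bot"
            for a in default_corpus.accounts.values()
        }
        correct = sum(1 for a, s in scores.items() if s.is_bot == truth[a])
        assert correct / len(scores) >= 0.95

    def test_threshold_monotonicity(
        self, default_corpus, default_tokenized, default_scores
    ):
        compounds = {k: s.compound for k, s in default_scores.items()}
        sizes = []
        for thr in (0.3, 0.5, 0.7):
            _, bots, *_ = hs.debias_corpus(
                default_corpus, default_tokenized, compounds, threshold=thr
            )
            sizes.append(len(bots))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_clean_corpus_without_planted_bots(self):
        c = hs.generate(hs.GeneratorConfig(
            seed=4, n_human_accounts=30, n_bot_accounts=0,
            n_marketing_accounts=0
        ))
        tok = {t.tweet_id: preprocess_tweet(t.tweet_id, t.text) for t in c.tweets}
        clean, bots, marketing, report, _ = hs.debias_corpus(c, tok)
        assert len(bots) == 0 and len(marketing) == 0
        assert len(clean) == len(c)
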