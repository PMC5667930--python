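import pytest

import hookahsent as hs
from hookahsent.pipeline import preprocess_corpus, score_corpus


@pytest.fixture(scope="session")
def lexicon():
    return hs.ValenceLexicon.default()


@pytest.fixture(scope="session")
def default_corpus():
    """One medium synthetic corpus shared across tests (seed fixed)."""
    return hs.generate(hs.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def default_tokenized(default_corpus):
    return preprocess_corpus(default_corpus)


@pytest.fixture(scope="session")
def default_scores(default_corpus, default_tokenized, lexicon):
    return score_corpus(default_corpus, default_tokenized, lexicon)


@pytest.fixture()
def tiny_corpus_path(tmp_path):
    """Hand-written JSONL fixture: 3 tweets, 1 account."""
    lines = [
        '{"record_type": "header", "schema_version": "1.0", "provenance": "raw"}',
        '{"record_type": "account", "account_id": "a1", "followers": 10,'
        ' "followees": 12, "tweet_ids": ["t1", "t2", "t3"]}',
        '{"record_type": "tweet", "tweet_id": "t1", "account_id": "a1",'
        ' "timestamp": "2015-04-01T12:00:00+00:00", "text": "loving this #hookah tonight",'
        ' "source_client": "mobile", "is_retweet": false, "mention_count": 0}',
        '{"record_type": "tweet", "tweet_id": "t2", "account_id": "a1",'
        ' "timestamp": "2015-04-02T12:00:00+00:00", "text": "off the hook ah well",'
        ' "source_client": "desktop", "is_retweet": false, "mention_count": 1}',
        '{"record_type": "tweet", "tweet_id": "t3", "account_id": "a1",'
        ' "timestamp": "2015-04-03T12:00:00+00:00", "text": "shisha with friends",'
        ' "source_client": "mobile", "is_retweet": true, "mention_count": 0}',
    ]
    p = tmp_path / "tiny.jsonl"
    p.write_text("\n".join(lines) + "\n")
    return p
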