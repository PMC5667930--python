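import numpy as np
import pytest

import hookahsent as hs
from hookahsent.circumplex import (
    PRIMARIES,
    CircumplexMap,
    NgramClassifier,
    aggregate_emotion_score,
    arousal_score,
    reduce_primary,
    tag_emotion,
)
from hookahsent.pipeline import preprocess_corpus
from hookahsent.preprocess import preprocess_tweet


@pytest.fixture(scope="module")
def cmap():
    return CircumplexMap.default()


class TestMap:
    def test_twenty_anchors_partitioned(self, cmap):
        assert len(cmap.anchors) == 20
        sizes = {}
        for e, q in cmap.quadrant_of.items():
            sizes[q] = sizes.get(q, 0) + 1
        assert sizes == {
            "highly_positive": 6,
            "passive_positive": 5,
            "subdued_negative": 4,
            "highly_negative": 5,
        }

    def test_anchors_on_unit_circle(self, cmap):
        for v, a in cmap.anchors.values():
            assert v * v + a * a == pytest.approx(1.0, abs=1e-3)

    def test_bad_partition_rejected(self, cmap):
        quad = dict(cmap.quadrant_of)
        quad["happy"] = "passive_positive"
        with pytest.raises(ValueError):
            CircumplexMap(dict(cmap.anchors), quad, dict(cmap.primary_of))


class TestTagEmotion:
    def test_exact_anchor_hit(self, cmap):
        v, a = cmap.anchors["happy"]
        tag = tag_emotion("t", v, a, cmap)
        assert tag.emotion == "happy" and tag.quadrant == "highly_positive"
        assert tag.primary == "joy"

    def test_positive_low_arousal_is_passive_positive(self, cmap):
        tag = tag_emotion("t", 0.6, -0.5, cmap)
        assert tag.quadrant == "passive_positive"

    def test_neutral_label_overrides_quadrant(self, cmap):
        tag = tag_emotion("t", 0.01, 0.0, cmap, label="neutral")
        assert tag.quadrant == "neutral" and tag.primary == "none"

    def test_out_of_range_rejected(self, cmap):
        with pytest.raises(ValueError):
            tag_emotion("t", 1.5, 0.0, cmap)

    def test_matches_brute_force_on_grid(self, cmap):
        """Nearest-anchor assignment equals exhaustive distance enumeration
        on a regular grid of the valence-arousal square."""
        names = list(cmap.anchors)
        coords = np.array([cmap.anchors[e] for e in names])
        grid = np.linspace(-1, 1, 40)
        for v in grid:
            for a in grid:
                d2 = ((coords - [v, a]) ** 2).sum(axis=1)
                best = min(
                    (float(d), name) for d, name in zip(d2, names)
                )[1]
                assert tag_emotion("t", float(v), float(a), cmap).emotion == best


class TestReducePrimary:
    @pytest.mark.parametrize(
        "emotion,primary",
        [("happy", "joy"), ("calm", "joy"), ("sad", "sadness"),
         ("bored", "sadness"), ("tense", "fear"), ("nervous", "fear"),
         ("upset", "anger"), ("unpleasant", "disgust")],
    )
    def test_default_table(self, emotion, primary, cmap):
        assert reduce_primary(emotion, cmap) == primary

    def test_total_and_surjective(self, cmap):
        images = {reduce_primary(e, cmap) for e in cmap.anchors}
        assert images == set(PRIMARIES)

    def test_unknown_emotion_rejected(self, cmap):
        with pytest.raises(KeyError):
            reduce_primary("ennui", cmap)


class TestArousal:
    def test_no_signal_zero(self):
        tt = preprocess_tweet("t", "picked up coals for the hookah")
        assert arousal_score(tt) == 0.0

    def test_maximal_emphasis_high(self):
        tt = preprocess_tweet("t", "HOOKAH NIGHT greattttt!!! :)")
        assert arousal_score(tt) > 0.5

    def test_calm_template_negative(self):
        tt = preprocess_tweet("t", "feeling calm and relaxed with this hookah")
        assert arousal_score(tt) < 0


class TestAggregate:
    def _tag(self, primary, tid="t"):
        return hs.EmotionTag(tid, 0.5, 0.5, "happy", "highly_positive", primary)

    def test_single_tweet_unit_mass(self):
        agg = aggregate_emotion_score([self._tag("joy")])
        assert agg["joy"] == 1.0 and sum(agg.values()) == 1.0

    def test_uniform_mix_equal_mass(self):
        tags = [self._tag(p, str(i)) for i, p in enumerate(PRIMARIES)]
        agg = aggregate_emotion_score(tags)
        assert all(v == pytest.approx(0.2) for v in agg.values())

    def test_weighted_linear_combination(self):
        tags = [self._tag("joy", "a"), self._tag("fear", "b")]
        agg = aggregate_emotion_score(tags, weights=[3.0, 1.0])
        assert agg["joy"] == pytest.approx(0.75)
        assert agg["fear"] == pytest.approx(0.25)

    def test_empty_warns_zero(self):
        with pytest.warns(UserWarning):
            agg = aggregate_emotion_score([])
        assert all(v == 0.0 for v in agg.values())


@pytest.fixture(scope="module")
def labeled(default_corpus, default_tokenized):
    truth = hs.ground_truth(default_corpus)
    human = truth[truth.role == "human"]
    toks = [default_tokenized[t].tokens for t in human.tweet_id]
    return toks, list(human.planted_sentiment)


class TestNgramClassifier:
    def test_separable_toy_memorization(self):
        toks = [["good", "day"]] * 5 + [["bad", "day"]] * 5
        labels = ["pos"] * 5 + ["neg"] * 5
        clf = NgramClassifier(seed=0, k_folds=2).fit(toks, labels)
        pred, _ = clf.predict(toks)
        assert pred == labels

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            NgramClassifier().fit([["a"], ["b"]], ["x", "x"])

    def test_untrained_predict_rejected(self):
        with pytest.raises(RuntimeError):
            NgramClassifier().predict([["a"]])

    def test_oov_falls_back_to_prior_with_flag(self):
        toks = [["good"]] * 6 + [["bad"]] * 4
        clf = NgramClassifier(k_folds=2).fit(toks, ["p"] * 6 + ["n"] * 4)
        pred, flags = clf.predict([["zzz"]])
        assert pred == ["p"] and flags == [True]

    def test_deterministic_given_seed(self, labeled):
        toks, labels = labeled
        p1, _ = NgramClassifier(seed=3).fit(toks, labels).predict(toks)
        p2, _ = NgramClassifier(seed=3).fit(toks, labels).predict(toks)
        assert p1 == p2

    def test_cv_macro_f_on_templates(self, labeled):
        toks, labels = labeled
        clf = NgramClassifier(seed=0).fit(toks, labels)
        assert clf.cv_macro_f >= 0.90
        assert len(clf.cv_fold_scores) == 5

    def test_permuted_labels_near_chance(self, labeled):
        toks, labels = labeled
        rng = np.random.default_rng(0)
        permuted = list(rng.permutation(labels))
        clf = NgramClassifier(seed=0).fit(toks, permuted)
        # macro-F under label permutation collapses toward chance level
        assert clf.cv_macro_f < 0.45

    def test_agreement_with_rule_engine(
        self, default_corpus, default_tokenized, default_scores, labeled
    ):
        """Classifier trained on planted labels agrees with the rule-based
        labels on >= 90% of unambiguous template tweets."""
        toks, labels = labeled
        clf = NgramClassifier(seed=0).fit(toks, labels)
        truth = hs.ground_truth(default_corpus)
        sub = truth[
            (truth.role == "human") & ~truth.has_negation & ~truth.has_contrast
        ]
        pred, _ = clf.predict([default_tokenized[t].tokens for t in sub.tweet_id])
        rule = [default_scores[t].label for t in sub.tweet_id]
        agree = np.mean([p == r for p, r in zip(pred, rule)])
        assert agree >= 0.90
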