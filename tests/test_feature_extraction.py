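import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from depscreen import (
    BOT,
    PARTICIPANT,
    EffectSizes,
    FeatureSpec,
    GenConfig,
    generate_corpus,
    validate_session,
)
from depscreen.feature_extraction import (
    DEFAULT_POS_LEXICON,
    DEFAULT_QUESTION_POOL,
    DEFAULT_SENTIMENT_LEXICON,
    DEFAULT_SPEC,
    FILLER_WORDS,
    FIRST_PERSON_WORDS,
    GLOBAL_FEATURES,
    answer_sentiment_features,
    avg_characters,
    avg_response_time,
    avg_sentiment,
    avg_sw_frequency,
    avg_unique_frequency,
    extract_corpus,
    extract_features,
    fp_avg,
    match_question,
    pos_frequencies,
    read_features,
    sentiment_score,
    speech_speed,
    write_features,
)
from conftest import make_session

FILLERS = frozenset(FILLER_WORDS)
FP = frozenset(FIRST_PERSON_WORDS)


def _p(text, start=0.0, stop=1.0):
    return (start, stop, PARTICIPANT, text)


def _single_comment(text, start=0.0, stop=1.0):
    return make_session([(start - 2.0, start - 1.0, BOT, "hello"),
                         _p(text, start, stop)])


# --------------------------------------------------------------------------
# Elementary scorers
# --------------------------------------------------------------------------

class TestSentimentScore:
    def test_symmetric_pair_cancels(self, toy_lexicon):
        assert sentiment_score("good bad", toy_lexicon) == 0.0

    def test_single_valence_mean(self, toy_lexicon):
        assert sentiment_score("good good", toy_lexicon) == 1.0

    def test_no_entries_scores_zero(self, toy_lexicon):
        assert sentiment_score("nothing matches here", toy_lexicon) == 0.0

    def test_equals_bruteforce_recount_on_synthetic_text(self):
        rng = np.random.default_rng(4)
        vocab = list(DEFAULT_SENTIMENT_LEXICON) + ["day", "work", "go"]
        for _ in range(20):
            words = [vocab[i] for i in rng.integers(len(vocab), size=15)]
            matched = [DEFAULT_SENTIMENT_LEXICON[w] for w in words
                       if w in DEFAULT_SENTIMENT_LEXICON]
            expected = sum(matched) / len(matched) if matched else 0.0
            assert sentiment_score(" ".join(words),
                                   DEFAULT_SENTIMENT_LEXICON) \
                == pytest.approx(expected)


class TestMatchQuestion:
    def test_containment_match(self):
        assert match_question("so what's your dream job",
                              DEFAULT_QUESTION_POOL) == "what's your dream job"

    def test_no_containment_returns_none(self):
        assert match_question("how are you today",
                              ("what's your dream job",)) is None

    def test_double_match_takes_first_in_pool_order(self):
        pool = ("alpha beta", "beta gamma")
        assert match_question("alpha beta gamma", pool) == "alpha beta"

    def test_matched_sets_equal_generator_plant(self, small_bundle):
        for session, plan in zip(small_bundle.sessions, small_bundle.plans):
            matched = {match_question(t.text, DEFAULT_QUESTION_POOL)
                       for t in session.bot_turns()} - {None}
            assert matched == set(plan.questions_asked)


# --------------------------------------------------------------------------
# Worked examples forced by the feature formulas
# --------------------------------------------------------------------------

class TestAnswerSentiment:
    def test_absent_question_imputes_zero(self, toy_spec, qa_session):
        values = answer_sentiment_features(qa_session, toy_spec)
        assert values["do you consider yourself an introvert"] == 0.0

    def test_single_word_answer(self, toy_spec, qa_session):
        values = answer_sentiment_features(qa_session, toy_spec)
        assert values["what's your dream job"] == 1.0

    def test_unanswered_question_scores_zero(self, toy_spec):
        s = make_session([
            (0.0, 2.0, BOT, "what's your dream job"),
            (3.0, 4.0, BOT, "okay moving on"),
            (5.0, 6.0, PARTICIPANT, "good"),
        ])
        values = answer_sentiment_features(s, toy_spec)
        assert values["what's your dream job"] == 0.0

    def test_answer_span_extends_to_next_bot_turn(self, toy_spec):
        s = make_session([
            (0.0, 1.0, BOT, "what's your dream job"),
            (2.0, 3.0, PARTICIPANT, "good"),
            (4.0, 5.0, PARTICIPANT, "bad bad bad"),
            (6.0, 7.0, BOT, "okay"),
        ])
        values = answer_sentiment_features(s, toy_spec)
        assert values["what's your dream job"] == pytest.approx((1 - 3) / 4)


class TestGlobalFeatures:
    def test_avg_sentiment_all_neutral(self, toy_spec):
        s = _single_comment("nothing to report today")
        assert avg_sentiment(s, toy_spec) == 0.0

    def test_avg_sentiment_single_comment_equals_its_score(self, toy_spec):
        s = _single_comment("good bad bad")
        assert avg_sentiment(s, toy_spec) == pytest.approx(-1 / 3)

    def test_avg_response_time_single_pair(self):
        s = make_session([(5.0, 10.0, BOT, "q"),
                          _p("a", 12.5, 13.5)])
        assert avg_response_time(s) == pytest.approx(2.5)

    def test_avg_response_time_mean_of_gaps(self):
        s = make_session([
            (0.0, 1.0, BOT, "q1"), _p("a", 2.0, 3.0),      # gap 1.0
            (4.0, 5.0, BOT, "q2"), _p("b", 8.0, 9.0),      # gap 3.0
        ])
        assert avg_response_time(s) == pytest.approx(2.0)

    def test_avg_response_time_clamps_overlap_to_zero(self):
        s = make_session([(0.0, 4.0, BOT, "q"), _p("a", 3.0, 5.0)])
        assert avg_response_time(s) == 0.0

    def test_speech_speed_single_comment(self):
        s = _single_comment("w1 w2 w3 w4 w5 w6 w7 w8 w9 w10 w11 w12",
                            0.0, 6.0)
        assert speech_speed(s) == pytest.approx(2.0)

    def test_speech_speed_unweighted_mean_of_ratios(self):
        s = make_session([
            (0.0, 0.5, BOT, "q"),
            _p("a b", 1.0, 2.0),            # 2 w/s
            _p("c d e f", 3.0, 4.0),        # 4 w/s
        ])
        assert speech_speed(s) == pytest.approx(3.0)

    def test_unique_frequency_with_repeats(self):
        s = _single_comment("the cat saw the cat")
        assert avg_unique_frequency(s) == pytest.approx(0.6)

    def test_unique_frequency_all_distinct(self):
        s = _single_comment("one two three")
        assert avg_unique_frequency(s) == 1.0

    def test_filler_frequency(self):
        s = _single_comment("um i think uh maybe")
        assert avg_sw_frequency(s, FILLERS) == pytest.approx(0.4)

    def test_filler_frequency_none(self):
        s = _single_comment("i think maybe")
        assert avg_sw_frequency(s, FILLERS) == 0.0

    def test_avg_characters(self):
        assert avg_characters(_single_comment("hello world")) == 5.0
        assert avg_characters(_single_comment("a b c")) == 1.0

    def test_pos_frequencies_dict_tagger(self, toy_tagger):
        s = _single_comment("dogs bark loudly")
        freqs = pos_frequencies(s, toy_tagger)
        assert freqs == pytest.approx({"avg_nouns": 1 / 3, "avg_verbs": 1 / 3,
                                       "adj_freq": 0.0, "avg_adv": 1 / 3})

    def test_pos_frequencies_all_unknown(self, toy_tagger):
        s = _single_comment("xyzzy quux")
        assert all(v == 0.0 for v in pos_frequencies(s, toy_tagger).values())

    def test_fp_avg(self):
        s = _single_comment("i think we should go")
        assert fp_avg(s, FP) == pytest.approx(0.4)
        assert fp_avg(_single_comment("think about going"), FP) == 0.0


# --------------------------------------------------------------------------
# Full vector, oracles, invariants
# --------------------------------------------------------------------------

def test_extract_features_shape_and_imputation(toy_spec):
    s = make_session([(0.0, 1.0, BOT, "hello there"),
                      _p("good morning", 2.0, 3.0)])
    vec = extract_features(s, toy_spec)
    assert len(vec.values) == 30
    assert set(vec.values) == set(toy_spec.feature_names)
    for q in toy_spec.question_pool:
        assert vec.values[q] == 0.0


def _recount(session, plan):
    """Independent brute-force recount of every feature from the planted
    token lists and raw turn times."""
    comments = plan.comment_tokens
    mean = lambda xs: sum(xs) / len(xs) if xs else 0.0
    ratio = lambda pred: mean([sum(map(pred, c)) / len(c)
                               for c in comments if c])
    exp = {
        "avg_unique_frequency": mean([len(set(c)) / len(c)
                                      for c in comments if c]),
        "avg_sw_frequency": ratio(lambda t: t in FILLERS),
        "avg_characters": mean([sum(len(t) for t in c) / len(c)
                                for c in comments if c]),
        "fp_avg": ratio(lambda t: t in FP),
        "avg_nouns": ratio(lambda t: DEFAULT_POS_LEXICON.get(t) == "noun"),
        "avg_verbs": ratio(lambda t: DEFAULT_POS_LEXICON.get(t) == "verb"),
        "adj_freq": ratio(lambda t: DEFAULT_POS_LEXICON.get(t) == "adjective"),
        "avg_adv": ratio(lambda t: DEFAULT_POS_LEXICON.get(t) == "adverb"),
    }
    pooled = [t for c in comments for t in c]
    matched = [DEFAULT_SENTIMENT_LEXICON[t] for t in pooled
               if t in DEFAULT_SENTIMENT_LEXICON]
    exp["avg_sentiment"] = mean(matched)
    turns = session.turns
    part = [t for t in turns if t.speaker == PARTICIPANT]
    exp["speech_speed"] = mean([len(c) / (t.stop_time - t.start_time)
                                for t, c in zip(part, comments) if c])
    gaps = [max(0.0, cur.start_time - prev.stop_time)
            for prev, cur in zip(turns, turns[1:])
            if prev.speaker == BOT and cur.speaker == PARTICIPANT]
    exp["avg_response_time"] = mean(gaps)
    for q in DEFAULT_SPEC.question_pool:
        tokens = plan.answer_tokens.get(q)
        if tokens is None:
            exp[q] = 0.0
        else:
            m = [DEFAULT_SENTIMENT_LEXICON[t] for t in tokens
                 if t in DEFAULT_SENTIMENT_LEXICON]
            exp[q] = mean(m)
    return exp


def test_every_feature_matches_bruteforce_recount(small_bundle):
    for session, plan in zip(small_bundle.sessions, small_bundle.plans):
        if plan.invalid:
            continue
        vec = extract_features(session, DEFAULT_SPEC)
        expected = _recount(session, plan)
        for name, want in expected.items():
            assert vec.values[name] == pytest.approx(want), name


def test_range_invariants_hold_corpus_wide(small_bundle):
    ratio_features = ("avg_unique_frequency", "avg_sw_frequency", "avg_nouns",
                      "avg_verbs", "adj_freq", "avg_adv", "fp_avg")
    for session in small_bundle.sessions:
        v = extract_features(session, DEFAULT_SPEC).values
        for name in ratio_features:
            assert 0.0 <= v[name] <= 1.0, name
        for q in DEFAULT_SPEC.question_pool:
            assert -1.0 <= v[q] <= 1.0
        assert -1.0 <= v["avg_sentiment"] <= 1.0
        assert v["speech_speed"] >= 0.0
        assert v["avg_response_time"] >= 0.0
        if any(session.participant_turns()):
            assert v["avg_characters"] >= 1.0


PER_COMMENT = ("avg_unique_frequency", "avg_sw_frequency", "avg_characters",
               "avg_nouns", "avg_verbs", "adj_freq", "avg_adv", "fp_avg")


def test_permuting_comments_leaves_per_comment_averages_unchanged():
    base = make_session([
        (0.0, 1.0, BOT, "hello"),
        _p("i go to work", 2.0, 4.0),
        _p("um the big day day", 5.0, 7.0),
        _p("we talk often", 8.0, 9.0),
    ])
    swapped = make_session([
        (0.0, 1.0, BOT, "hello"),
        _p("we talk often", 2.0, 3.0),
        _p("i go to work", 4.0, 6.0),
        _p("um the big day day", 7.0, 9.0),
    ])
    a = extract_features(base, DEFAULT_SPEC).values
    b = extract_features(swapped, DEFAULT_SPEC).values
    for name in PER_COMMENT:
        assert a[name] == pytest.approx(b[name]), name


def test_duplicating_comments_leaves_per_comment_averages_unchanged():
    rows = [(0.0, 1.0, BOT, "hello"),
            _p("i go to work", 2.0, 4.0),
            _p("um the big day day", 5.0, 7.0)]
    doubled = rows + [_p("i go to work", 8.0, 10.0),
                      _p("um the big day day", 11.0, 13.0)]
    a = extract_features(make_session(rows), DEFAULT_SPEC).values
    b = extract_features(make_session(doubled), DEFAULT_SPEC).values
    for name in PER_COMMENT + ("speech_speed",):
        assert a[name] == pytest.approx(b[name]), name


def test_timestamp_shift_invariance(small_bundle):
    from depscreen import Session, Turn
    session = next(s for s, p in zip(small_bundle.sessions,
                                     small_bundle.plans) if not p.invalid)
    shifted = Session(session.session_id, [
        Turn(t.start_time + 250.0, t.stop_time + 250.0, t.speaker, t.text)
        for t in session.turns])
    assert avg_response_time(shifted) == pytest.approx(
        avg_response_time(session), rel=1e-9, abs=1e-9)
    assert speech_speed(shifted) == pytest.approx(
        speech_speed(session), rel=1e-6)


def test_feature_matrix_round_trip(tmp_path, small_bundle):
    sessions = [s for s in small_bundle.sessions if validate_session(s)[0]]
    df = extract_corpus(sessions, small_bundle.labels)
    path = tmp_path / "features.csv"
    write_features(df, path)
    back = read_features(path)
    pd.testing.assert_frame_equal(back, df, check_exact=True)


def test_null_effect_calibration_rank_test():
    """With all effect sizes zero, a rank-based two-sample test on a global
    feature rejects at α = 0.01 in at most 5 of 100 seeded replicates."""
    rejections = 0
    for rep in range(100):
        cfg = GenConfig(n_sessions=200, n_depressed=60, n_invalid_sessions=0,
                        effect_sizes=EffectSizes(0.0, 0.0, 0.0, 0.0),
                        seed=20_000 + rep)
        bundle = generate_corpus(cfg)
        vals = np.array([speech_speed(s) for s in bundle.sessions])
        dep = np.array([bool(r.phq8_binary) for r in bundle.labels])
        p = mannwhitneyu(vals[dep], vals[~dep]).pvalue
        rejections += p < 0.01
    assert rejections <= 5
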