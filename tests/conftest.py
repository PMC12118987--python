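import pytest

from depscreen import (
    BOT,
    PARTICIPANT,
    FeatureSpec,
    GenConfig,
    Session,
    Turn,
    generate_corpus,
)
from depscreen.feature_extraction import DictTagger


def make_session(spec, session_id="s1"):
    """Build a Session from (start, stop, speaker, text) tuples."""
    return Session(session_id=session_id,
                   turns=[Turn(*row) for row in spec])


@pytest.fixture
def toy_lexicon():
    return {"good": 1.0, "bad": -1.0}


@pytest.fixture
def toy_tagger():
    return DictTagger({"dogs": "noun", "bark": "verb", "loudly": "adverb"})


@pytest.fixture
def toy_spec(toy_lexicon, toy_tagger):
    """FeatureSpec with a two-word lexicon and three-word tagger."""
    return FeatureSpec(lexicon=toy_lexicon, tagger=toy_tagger)


@pytest.fixture(scope="session")
def small_bundle():
    """20-session corpus with 2 broken sessions and default effect sizes."""
    return generate_corpus(GenConfig(n_sessions=20, n_depressed=6,
                                     n_invalid_sessions=2, seed=11))


@pytest.fixture(scope="session")
def default_bundle():
    """Full-size corpus under the default study conditions (188/56/3)."""
    return generate_corpus(GenConfig(seed=1))


@pytest.fixture
def qa_session():
    """Minimal bot/participant exchange with one pool question."""
    return make_session([
        (0.0, 2.0, BOT, "hi i'm ellie thanks for coming in today"),
        (3.0, 5.0, PARTICIPANT, "good thanks"),
        (6.0, 8.0, BOT, "so what's your dream job"),
        (10.5, 13.5, PARTICIPANT, "good good"),
    ])
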