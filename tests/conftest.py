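import pytest
from hypothesis import HealthCheck, settings

from ibd_dialog import load_lexicon
from ibd_dialog.lexicon import build_lexicon
from ibd_dialog.resources import default_stop_words

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    """The shipped eight-category default lexicon."""
    return load_lexicon()


@pytest.fixture(scope="session")
def stop_words():
    return default_stop_words()


@pytest.fixture(scope="session")
def toy_lexicon():
    """Three keyword categories plus fallback, for hand-checkable label tests."""
    return build_lexicon(
        [
            {"code": 1, "name": "alpha", "keywords": ["apple", "red apple"]},
            {"code": 2, "name": "beta", "keywords": ["banana"]},
            {"code": 3, "name": "gamma", "keywords": ["cherry", "kiwi"]},
            {"code": 4, "name": "misc", "fallback": True, "keywords": []},
        ]
    )
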