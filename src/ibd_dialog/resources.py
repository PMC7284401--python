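"""Loaders for the packaged default resources.

The package ships four plain-text/JSON resources: an English stop-word list,
greeting templates, automated-response templates, and a stand-in category
lexicon. Each has a ``load_*`` function accepting an optional path so every
resource can be overridden from a file of the same format.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources as _ir
from pathlib import Path


def _read_lines(text: str) -> list[str]:
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def _resource_text(name: str) -> str:
    return (_ir.files("ibd_dialog") / "data" / name).read_text(encoding="utf-8")


@lru_cache(maxsize=None)
def default_stop_words() -> frozenset[str]:
    return frozenset(_read_lines(_resource_text("stopwords.txt")))


@lru_cache(maxsize=None)
def default_greeting_templates() -> tuple[str, ...]:
    return tuple(_read_lines(_resource_text("greetings.txt")))


@lru_cache(maxsize=None)
def default_automated_templates() -> tuple[str, ...]:
    return tuple(_read_lines(_resource_text("automated.txt")))


def load_stop_words(path: str | Path | None = None) -> frozenset[str]:
    """Stop words, one lower-case token per line; ``#`` lines are comments."""
    if path is None:
        return default_stop_words()
    return frozenset(_read_lines(Path(path).read_text(encoding="utf-8")))


def load_templates(path: str | Path) -> tuple[str, ...]:
    """Greeting or automated templates, one per line."""
    return tuple(_read_lines(Path(path).read_text(encoding="utf-8")))


def default_lexicon_text() -> str:
    return _resource_text("default_lexicon.json")
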