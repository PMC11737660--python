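"""Packaged default stoplist and risk lexicon (plain-text token lists)."""

from __future__ import annotations

from importlib import resources

from .corpus import read_token_list


def _load(name: str) -> list[str]:
    ref = resources.files("sitr.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_token_list(path)


def default_stoplist() -> list[str]:
    return _load("stoplist.txt")


def default_risk_lexicon() -> list[str]:
    return _load("risk_lexicon.txt")
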