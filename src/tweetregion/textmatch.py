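"""Word-boundary term matching shared by the extraction and triangulation filters.

All matching is case-insensitive and token-based: text is split into maximal
alphanumeric runs, and a term matches iff its own token sequence occurs
contiguously in the text's token sequence.  Token matching is what keeps the
short state codes usable ("Hattiesburg, MS" matches the term "ms"; "MSU" does
not) and prevents homonym capture ("petal" does not match "Petaling Jaya").
A substring-compatibility mode reproduces the looser behaviour of naive
substring filters.
"""

from __future__ import annotations

import re
from functools import lru_cache

_TOKEN_RE = re.compile(r"[0-9a-z]+")


def tokenize(text: str) -> tuple[str, ...]:
    """Lowercased maximal alphanumeric tokens of ``text``, in order."""
    return tuple(_TOKEN_RE.findall(text.lower()))


@lru_cache(maxsize=4096)
def _term_tokens(term: str) -> tuple[str, ...]:
    return tokenize(term)


def term_matches(term: str, text: str, *, substring: bool = False) -> bool:
    """True iff ``term`` occurs in ``text``.

    Token mode (default): the term's token sequence must appear contiguously
    among the text's tokens.  Substring mode: plain case-insensitive substring
    containment (the compatibility switch).
    """
    if substring:
        return term.lower() in text.lower()
    needle = _term_tokens(term)
    if not needle:
        return False
    hay = tokenize(text)
    n = len(needle)
    return any(hay[i : i + n] == needle for i in range(len(hay) - n + 1))


def any_term_matches(terms, text: str, *, substring: bool = False) -> bool:
    return any(term_matches(t, text, substring=substring) for t in terms)


def matching_terms(terms, text: str, *, substring: bool = False) -> set[str]:
    """The subset of ``terms`` that match ``text``."""
    return {t for t in terms if term_matches(t, text, substring=substring)}
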