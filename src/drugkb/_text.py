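"""Shared text normalization used for drug names, synonyms and side-effect terms.

One normalization rule everywhere keeps name-based drug mapping, the
name index and diagnosis/side-effect matching mutually consistent:
case-fold, trim, collapse internal whitespace, strip punctuation.
"""

from __future__ import annotations

import re
import string

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})
_WS_RE = re.compile(r"\s+")

#: 7-character Anatomical Therapeutic Chemical code: letter, 2 digits, 2 letters, 2 digits.
ATC_RE = re.compile(r"^[A-Za-z][0-9]{2}[A-Za-z]{2}[0-9]{2}$")


def normalize(text: str) -> str:
    """Normalize a free-text name or term for matching.

    Case-folds, replaces punctuation with spaces, trims and collapses
    internal whitespace. Idempotent.
    """
    return _WS_RE.sub(" ", text.casefold().translate(_PUNCT_TABLE)).strip()


def is_valid_atc(code: str) -> bool:
    """True iff ``code`` is a full 7-character ATC code."""
    return bool(ATC_RE.match(code))
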