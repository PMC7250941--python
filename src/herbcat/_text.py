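"""Text normalization shared by matching and deduplication.

Verbatim label text (Portuguese localities, collector strings, name
authorships) is preserved everywhere in I/O; the folding here is applied
only inside comparison functions, never to stored values.
"""

from __future__ import annotations

import datetime
import re
import unicodedata

#: Earliest plausible collection year for herbarium material.
MIN_COLLECTION_YEAR = 1750
CURRENT_YEAR = datetime.date.today().year

_WS = re.compile(r"\s+")
_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_YEAR_TOKEN = re.compile(r"(?<!\d)(\d{4})(?!\d)")


def strip_accents(text: str) -> str:
    """Remove diacritics (NFKD decomposition, drop combining marks)."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def fold(text: str) -> str:
    """Case-fold, strip accents and collapse whitespace for comparison."""
    return _WS.sub(" ", strip_accents(text).casefold()).strip()


def fold_name(text: str) -> str:
    """Fold a scientific name: also drops hybrid markers ('×', 'x ')."""
    t = fold(text)
    t = t.replace("×", " ").replace("✕", " ")
    t = re.sub(r"(?:^|(?<= ))x(?= )", " ", t)
    return _WS.sub(" ", t).strip()


def fold_collector(text: str) -> str:
    """Fold a collector string: punctuation removed, not replaced.

    'A.C. Brade' -> 'ac brade'; 'BRADE, A. C.' -> 'brade a c'.
    """
    return _WS.sub(" ", _PUNCT.sub("", strip_accents(text).casefold())).strip()


def parse_year(date_text: str | None) -> int | None:
    """Extract a collection year from heterogeneous verbatim date text.

    Handles ISO-8601 full/partial dates, DD/MM/YYYY and bare years
    uniformly by scanning for the first standalone 4-digit token within
    [1750, current year]. Anything else yields None.
    """
    if not date_text:
        return None
    for tok in _YEAR_TOKEN.findall(date_text):
        year = int(tok)
        if MIN_COLLECTION_YEAR <= year <= CURRENT_YEAR:
            return year
    return None


def word_boundary_search(term_folded: str, text_folded: str) -> bool:
    """True iff ``term_folded`` occurs in ``text_folded`` bounded by
    non-word characters (or string edges) on both sides."""
    pattern = r"(?<!\w)" + re.escape(term_folded) + r"(?!\w)"
    return re.search(pattern, text_folded) is not None
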