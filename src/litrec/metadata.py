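"""Metadata utilities: DOI harvesting, exact-title lookup, filename patterns.

These support the library-management side of the tool: text extracted from a
PDF is scanned for DOIs (``10.<registrant>/<suffix>``, optional ``doi:``
prefix, trailing sentence punctuation trimmed) or, failing that, for a known
paper title embedded verbatim in the text; and files can be renamed after
their metadata with ``$``-wildcard patterns such as ``$FIRSTAUTHOR-$YEAR.pdf``.
"""

from __future__ import annotations

import dataclasses
import re

from .corpus import BiblioRecord, Corpus, tokenize

__all__ = [
    "extract_dois",
    "title_lookup",
    "RenamePattern",
    "render_filename",
    "WILDCARDS",
    "DEFAULT_MIN_TITLE_TOKENS",
]

# registrant: 10. followed by digits(.digits)*; suffix: no whitespace
_DOI_RE = re.compile(r"\b(?:doi:\s*)?(10\.\d{4,9}(?:\.\d+)*/\S+)", re.IGNORECASE)
_TRAILING_PUNCT = '.,;:)]}>"\''

DEFAULT_MIN_TITLE_TOKENS = 4


def extract_dois(text: str) -> list[str]:
    """All DOIs in the text, first-occurrence order, duplicates removed."""
    seen: dict[str, None] = {}
    for match in _DOI_RE.finditer(text):
        doi = match.group(1).rstrip(_TRAILING_PUNCT)
        if "/" in doi and doi.split("/", 1)[1]:
            seen.setdefault(doi, None)
    return list(seen)


def _subseq_index(haystack: list[str], needle: list[str]) -> bool:
    n = len(needle)
    if n == 0 or n > len(haystack):
        return False
    first = needle[0]
    for i in range(len(haystack) - n + 1):
        if haystack[i] == first and haystack[i : i + n] == needle:
            return True
    return False


def title_lookup(
    text: str, corpus: Corpus, min_title_tokens: int = DEFAULT_MIN_TITLE_TOKENS
) -> list[str]:
    """IDs of records whose normalized title occurs contiguously in the text.

    Titles shorter than ``min_title_tokens`` tokens are never matched (short
    generic titles would hit almost any text); matches are returned
    longest-title-first, ties broken by ascending record ID.
    """
    text_tokens = list(tokenize(text).tokens)
    hits: list[tuple[int, str]] = []
    for rec in corpus:
        title_tokens = list(rec.title_tokens().tokens)
        if len(title_tokens) < min_title_tokens:
            continue
        if _subseq_index(text_tokens, title_tokens):
            hits.append((len(title_tokens), rec.record_id))
    hits.sort(key=lambda h: (-h[0], h[1]))
    return [rid for _, rid in hits]


WILDCARDS = ("$TITLE", "$YEAR", "$JOURNAL", "$FIRSTAUTHOR", "$PMID")

_UNSAFE = re.compile(r'[<>:"/\\|?*\x00-\x1f]')
_WILDCARD_TOKEN = re.compile(r"\$[A-Z]*")

MISSING_FIELD_PLACEHOLDER = "unknown"
MAX_FIELD_LEN = 120


@dataclasses.dataclass(frozen=True)
class RenamePattern:
    """A filename template of literal text and ``$`` wildcards."""

    template: str

    def __post_init__(self) -> None:
        for token in _WILDCARD_TOKEN.findall(self.template):
            if token not in WILDCARDS:
                raise ValueError(
                    f"unknown wildcard {token!r}; known: {', '.join(WILDCARDS)}"
                )


def _sanitize(value: str) -> str:
    value = _UNSAFE.sub("_", value).strip()
    return value[:MAX_FIELD_LEN] if value else MISSING_FIELD_PLACEHOLDER


def _field_values(record: BiblioRecord) -> dict[str, str]:
    if record.authors:
        # normalized "lastname initials" -> surname only, capitalized
        first_author = record.authors[0].split()[0].capitalize()
    else:
        first_author = ""
    return {
        "$TITLE": record.title,
        "$YEAR": str(record.registered_date.year),
        "$JOURNAL": record.journal,
        "$FIRSTAUTHOR": first_author,
        "$PMID": record.record_id,
    }


def render_filename(pattern: RenamePattern, record: BiblioRecord) -> str:
    """Substitute and sanitize wildcards; literal text is preserved."""
    values = _field_values(record)
    out = pattern.template
    for wc in sorted(WILDCARDS, key=len, reverse=True):  # $PMID before $P...
        if wc in out:
            out = out.replace(wc, _sanitize(values[wc]))
    return out
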