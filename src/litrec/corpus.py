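"""Domain types, text normalization, and corpus readers/writers.

A corpus is a list of bibliographic records in the MEDLINE mould: a PMID-like
identifier, title, abstract, author list, journal name, NLM Journal Subject
Terms (the journal's scope), MeSH headings, and the date the record entered
the index. Two on-disk dialects are supported: a JSONL format (one UTF-8 JSON
object per line) and a small MEDLINE-XML subset. Both readers produce
identical in-memory corpora for equivalent content.

Text normalization (``tokenize``) is shared by every statistical module:
lowercase, split on non-alphanumerics, drop single-digit pure numbers, remove
stop words, then Porter-stem. It is deterministic and idempotent on its own
output.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import re
from typing import BinaryIO, Iterable, Union

from lxml import etree

from ._porter import porter_stem
from ._stopwords import STOP_WORDS

__all__ = [
    "BiblioRecord",
    "Corpus",
    "TokenStream",
    "CorpusFormatError",
    "tokenize",
    "normalize_author",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "read_corpus_medline_xml",
]

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")


class CorpusFormatError(ValueError):
    """Raised for malformed or inconsistent corpus input."""


def normalize_author(name: str) -> str:
    """Collapse an author name to lowercase, single-space form.

    MEDLINE-style names ("Smith JB", "de la Cruz A") are matched at this
    granularity throughout the package.
    """
    return " ".join(name.lower().split())


def tokenize(text: str, field_label: str = "fulltext") -> "TokenStream":
    """Normalize free text into a stream of stemmed tokens.

    Lowercases, splits on non-alphanumeric runs, drops pure numbers shorter
    than two digits, removes stop words, and Porter-stems the remainder.
    Stemming is iterated to a fixed point and stems that land on the stop
    list are dropped, so normalization is closed: re-tokenizing the joined
    token string reproduces the stream. Total on any string; empty input
    yields an empty stream.
    """
    tokens = []
    for raw in _TOKEN_SPLIT.split(text.lower()):
        if not raw:
            continue
        if raw.isdigit() and len(raw) < 2:
            continue
        if raw in STOP_WORDS:
            continue
        stem = porter_stem(raw)
        while stem != raw:
            raw, stem = stem, porter_stem(stem)
        if stem in STOP_WORDS:
            continue
        tokens.append(stem)
    return TokenStream(tokens=tokens, source_field=field_label)


@dataclasses.dataclass(frozen=True)
class TokenStream:
    tokens: tuple[str, ...]
    source_field: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclasses.dataclass(frozen=True)
class BiblioRecord:
    """One bibliographic record (the unit of every corpus)."""

    record_id: str
    title: str = ""
    abstract: str = ""
    authors: tuple[str, ...] = ()
    journal: str = ""
    journal_subject_terms: frozenset[str] = frozenset()
    mesh_terms: frozenset[str] = frozenset()
    registered_date: datetime.date = datetime.date(1970, 1, 1)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise CorpusFormatError("record_id must be non-empty")
        if not isinstance(self.registered_date, datetime.date):
            raise CorpusFormatError(
                f"registered_date must be a date, got {self.registered_date!r}"
            )
        # normalize authors, keep first occurrence order, drop duplicates
        seen: dict[str, None] = {}
        for a in self.authors:
            seen.setdefault(normalize_author(a), None)
        object.__setattr__(self, "authors", tuple(seen))
        object.__setattr__(
            self, "journal_subject_terms", frozenset(self.journal_subject_terms)
        )
        object.__setattr__(self, "mesh_terms", frozenset(self.mesh_terms))

    def title_tokens(self) -> TokenStream:
        return tokenize(self.title, "title")

    def abstract_tokens(self) -> TokenStream:
        return tokenize(self.abstract, "abstract")


class Corpus:
    """An ordered record collection with total ID lookup."""

    def __init__(self, records: Iterable[BiblioRecord]):
        self.records: list[BiblioRecord] = list(records)
        self.id_index: dict[str, BiblioRecord] = {}
        for rec in self.records:
            if rec.record_id in self.id_index:
                raise CorpusFormatError(f"duplicate record_id {rec.record_id!r}")
            self.id_index[rec.record_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: str) -> BiblioRecord:
        try:
            return self.id_index[record_id]
        except KeyError:
            raise KeyError(f"unknown record_id {record_id!r}") from None

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.id_index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.records == other.records


# ---------------------------------------------------------------------------
# JSONL dialect
# ---------------------------------------------------------------------------
#
# One JSON object per line, UTF-8:
#   {"record_id": str, "title": str, "abstract": str, "authors": [str, ...],
#    "journal": str, "journal_subject_terms": [str, ...],
#    "mesh_terms": [str, ...], "registered_date": "YYYY-MM-DD"}
# abstract / authors / journal / journal_subject_terms / mesh_terms optional.


def _record_from_obj(obj: dict, line_no: int) -> BiblioRecord:
    try:
        record_id = obj["record_id"]
        date = datetime.date.fromisoformat(obj["registered_date"])
    except KeyError as exc:
        raise CorpusFormatError(f"line {line_no}: missing field {exc}") from None
    except ValueError as exc:
        raise CorpusFormatError(f"line {line_no}: bad date: {exc}") from None
    return BiblioRecord(
        record_id=str(record_id),
        title=obj.get("title", ""),
        abstract=obj.get("abstract", ""),
        authors=tuple(obj.get("authors", ())),
        journal=obj.get("journal", ""),
        journal_subject_terms=frozenset(obj.get("journal_subject_terms", ())),
        mesh_terms=frozenset(obj.get("mesh_terms", ())),
        registered_date=date,
    )


def read_corpus_jsonl(stream: Union[BinaryIO, Iterable[bytes]]) -> Corpus:
    """Read the JSONL corpus dialect.

    Malformed lines and duplicate IDs raise :class:`CorpusFormatError`
    naming the offending line number(s).
    """
    records: list[BiblioRecord] = []
    first_line: dict[str, int] = {}
    for line_no, raw in enumerate(stream, start=1):
        if isinstance(raw, bytes):
            raw = raw.decode("utf-8")
        line = raw.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(f"line {line_no}: undecodable JSON: {exc}") from None
        rec = _record_from_obj(obj, line_no)
        if rec.record_id in first_line:
            raise CorpusFormatError(
                f"duplicate record_id {rec.record_id!r} on lines "
                f"{first_line[rec.record_id]} and {line_no}"
            )
        first_line[rec.record_id] = line_no
        records.append(rec)
    return Corpus(records)


def record_to_obj(rec: BiblioRecord) -> dict:
    return {
        "record_id": rec.record_id,
        "title": rec.title,
        "abstract": rec.abstract,
        "authors": list(rec.authors),
        "journal": rec.journal,
        "journal_subject_terms": sorted(rec.journal_subject_terms),
        "mesh_terms": sorted(rec.mesh_terms),
        "registered_date": rec.registered_date.isoformat(),
    }


def write_corpus_jsonl(corpus: Corpus, stream: BinaryIO) -> None:
    """Write the JSONL dialect; canonical key order, sorted term sets."""
    for rec in corpus:
        line = json.dumps(record_to_obj(rec), ensure_ascii=False, sort_keys=False)
        stream.write(line.encode("utf-8") + b"\n")


# ---------------------------------------------------------------------------
# MEDLINE-XML subset
# ---------------------------------------------------------------------------


def _text(elem) -> str:
    return "".join(elem.itertext()) if elem is not None else ""


def read_corpus_medline_xml(stream: Union[BinaryIO, bytes]) -> Corpus:
    """Read a MedlineCitation-style XML subset.

    Recognized per citation: PMID, ArticleTitle, AbstractText, AuthorList
    (LastName/Initials or CollectiveName), MedlineTA, JournalSubjectList/
    SubjectHeading, MeshHeadingList/MeshHeading/DescriptorName, DateCreated
    (Year/Month/Day, mapped to the registration date). Other elements are
    ignored. Non-well-formed XML or a citation without a PMID is a hard error.
    """
    if isinstance(stream, bytes):
        data = stream
    else:
        data = stream.read()
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"XML parse error: {exc}") from None

    records: list[BiblioRecord] = []
    for cit in root.iter("MedlineCitation"):
        pmid = cit.findtext("PMID")
        if not pmid:
            raise CorpusFormatError("MedlineCitation without PMID")
        authors = []
        for au in cit.iter("Author"):
            last, init = au.findtext("LastName"), au.findtext("Initials")
            if last:
                authors.append(f"{last} {init}" if init else last)
            else:
                coll = au.findtext("CollectiveName")
                if coll:
                    authors.append(coll)
        dc = cit.find(".//DateCreated")
        if dc is not None:
            date = datetime.date(
                int(dc.findtext("Year")),
                int(dc.findtext("Month")),
                int(dc.findtext("Day")),
            )
        else:
            date = datetime.date(1970, 1, 1)
        records.append(
            BiblioRecord(
                record_id=pmid.strip(),
                title=_text(cit.find(".//ArticleTitle")),
                abstract=" ".join(
                    _text(a) for a in cit.iter("AbstractText")
                ).strip(),
                authors=tuple(authors),
                journal=cit.findtext(".//MedlineTA", default=""),
                journal_subject_terms=frozenset(
                    _text(s) for s in cit.iter("SubjectHeading") if _text(s)
                ),
                mesh_terms=frozenset(
                    _text(d) for d in cit.iter("DescriptorName") if _text(d)
                ),
                registered_date=date,
            )
        )
    return Corpus(records)
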