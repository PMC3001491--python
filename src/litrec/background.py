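"""Corpus-wide background statistics.

Every statistical operation in the package — hypergeometric key-term scoring,
IDF-weighted associative search, MeSH tag suggestion — is computed against a
single background model of the corpus:

* an N-gram dictionary over the stemmed title+abstract token streams, holding
  for each N-gram (N = 1..max_n, default 5) the number of records containing
  it and its total occurrence count;
* an IDF table, idf(t) = ln(corpus_size / doc_count(t)), over all dictionary
  terms;
* per-MeSH-heading record counts.

N-grams never span the title/abstract boundary. Out-of-vocabulary terms are
assigned idf = ln(corpus_size), i.e. treated as occurring in one record.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections import Counter
from typing import BinaryIO, Iterable, Iterator

from .corpus import Corpus, BiblioRecord

__all__ = [
    "NgramDictionary",
    "BackgroundStats",
    "iter_ngrams",
    "record_ngram_fields",
    "build_ngram_dictionary",
    "build_background_stats",
    "write_index",
    "read_index",
]

DEFAULT_MAX_N = 5

INDEX_FORMAT_VERSION = 1


def iter_ngrams(tokens: Iterable[str], max_n: int) -> Iterator[str]:
    """All contiguous runs of 1..max_n tokens, space-joined, in order."""
    toks = list(tokens)
    for i in range(len(toks)):
        for n in range(1, min(max_n, len(toks) - i) + 1):
            yield " ".join(toks[i : i + n])


def record_ngram_fields(
    record: BiblioRecord, max_n: int
) -> tuple[list[str], list[str]]:
    """Title and abstract N-gram lists for one record (boundary respected)."""
    return (
        list(iter_ngrams(record.title_tokens(), max_n)),
        list(iter_ngrams(record.abstract_tokens(), max_n)),
    )


@dataclasses.dataclass
class NgramDictionary:
    max_n: int
    term_doc_count: dict[str, int]
    term_total_count: dict[str, int]
    corpus_size: int

    def __contains__(self, term: str) -> bool:
        return term in self.term_doc_count


@dataclasses.dataclass
class BackgroundStats:
    ngrams: NgramDictionary
    idf: dict[str, float]
    mesh_doc_count: dict[str, int]
    corpus_size: int

    def idf_of(self, term: str) -> float:
        """IDF with the out-of-vocabulary fallback ln(corpus_size)."""
        try:
            return self.idf[term]
        except KeyError:
            return math.log(self.corpus_size) if self.corpus_size > 1 else 0.0


def build_ngram_dictionary(corpus: Corpus, max_n: int = DEFAULT_MAX_N) -> NgramDictionary:
    """Tally N-gram document and occurrence counts over a corpus.

    Document counts count distinct records containing a term; total counts
    count occurrences. The corpus must be non-empty and max_n >= 1.
    """
    if max_n < 1:
        raise ValueError(f"max_n must be >= 1, got {max_n}")
    if len(corpus) == 0:
        raise ValueError("cannot build an N-gram dictionary from an empty corpus")
    doc_count: Counter[str] = Counter()
    total_count: Counter[str] = Counter()
    for rec in corpus:
        title_ngrams, abstract_ngrams = record_ngram_fields(rec, max_n)
        total_count.update(title_ngrams)
        total_count.update(abstract_ngrams)
        doc_count.update(set(title_ngrams) | set(abstract_ngrams))
    return NgramDictionary(
        max_n=max_n,
        term_doc_count=dict(doc_count),
        term_total_count=dict(total_count),
        corpus_size=len(corpus),
    )


def build_background_stats(corpus: Corpus, max_n: int = DEFAULT_MAX_N) -> BackgroundStats:
    """N-gram dictionary plus IDF table and MeSH document counts."""
    ngrams = build_ngram_dictionary(corpus, max_n)
    n = ngrams.corpus_size
    idf = {t: math.log(n / dc) for t, dc in ngrams.term_doc_count.items()}
    mesh: Counter[str] = Counter()
    for rec in corpus:
        mesh.update(rec.mesh_terms)
    return BackgroundStats(
        ngrams=ngrams, idf=idf, mesh_doc_count=dict(mesh), corpus_size=n
    )


# ---------------------------------------------------------------------------
# Serialized index container (JSON, versioned)
# ---------------------------------------------------------------------------


def write_index(stats: BackgroundStats, stream: BinaryIO) -> None:
    """Write the background index; IDF is recomputed on load."""
    payload = {
        "format_version": INDEX_FORMAT_VERSION,
        "corpus_size": stats.corpus_size,
        "max_n": stats.ngrams.max_n,
        "term_doc_count": stats.ngrams.term_doc_count,
        "term_total_count": stats.ngrams.term_total_count,
        "mesh_doc_count": stats.mesh_doc_count,
    }
    stream.write(json.dumps(payload, ensure_ascii=False).encode("utf-8"))


def read_index(stream: BinaryIO) -> BackgroundStats:
    payload = json.loads(stream.read().decode("utf-8"))
    version = payload.get("format_version")
    if version != INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index format version {version!r}")
    n = payload["corpus_size"]
    ngrams = NgramDictionary(
        max_n=payload["max_n"],
        term_doc_count=payload["term_doc_count"],
        term_total_count=payload["term_total_count"],
        corpus_size=n,
    )
    idf = {t: math.log(n / dc) for t, dc in ngrams.term_doc_count.items()}
    return BackgroundStats(
        ngrams=ngrams,
        idf=idf,
        mesh_doc_count=payload["mesh_doc_count"],
        corpus_size=n,
    )
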